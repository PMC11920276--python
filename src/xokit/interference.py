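"""Gamma-renewal crossover interference with an escaping (non-interfering) class.

The interfering class arises from chiasmata laid down on the four-strand
bivalent as a stationary gamma renewal process (shape ``nu``, rate
``2*nu*(1-p)`` per Morgan) and transmitted to the gamete by independent
1/2-thinning; the escaping class is a homogeneous Poisson process at rate
``p`` per Morgan on the gamete.  The two classes superpose, so the expected
gamete crossover rate is 1 per Morgan for any (nu, p).

The gamete-scale inter-arrival density of the interfering class is the
geometric gamma mixture

    f*(x) = sum_{k>=1} (1/2)^k Gamma(x; k*nu, 2*nu*(1-p))

and the likelihood of an observed crossover configuration sums over all
2^m assignments of the m observed crossovers to the two classes, scoring
the interfering subset with stationary start and right-censoring terms and
the escaping subset with the Poisson configuration density.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "StahlFit",
    "CrossoverData",
    "thinned_gamma_density",
    "thinned_gamma_survival",
    "chromosome_loglik",
    "stahl_loglik",
    "fit_stahl",
    "fit_gamma",
]

_LOG_HALF = -np.log(2.0)
_MAX_COMPONENTS = 64
_MAX_XO_PER_CHROM = 20


def _n_components(nu: float, lam: float, x_max: float) -> int:
    """Truncation point of the geometric mixture.

    Terms decay like (1/2)^k once k*nu exceeds lam*x, so keep enough
    components to cover the largest observed distance plus a 2^-40 tail.
    """
    k_peak = int(np.ceil(lam * max(x_max, 0.0) / nu)) if nu > 0 else 0
    return int(min(_MAX_COMPONENTS, max(40, k_peak + 40)))


def _log_fstar(x: np.ndarray, nu: float, lam: float, n_comp: int) -> np.ndarray:
    """log f*(x) for x > 0 (Morgans)."""
    k = np.arange(1, n_comp + 1, dtype=float)[:, None]
    a = k * nu
    with np.errstate(divide="ignore"):
        logx = np.log(x)[None, :]
    terms = k * _LOG_HALF + (a - 1.0) * logx - lam * x[None, :] + a * np.log(lam) - special.gammaln(a)
    return special.logsumexp(terms, axis=0)


def _log_sstar(x: np.ndarray, nu: float, lam: float, n_comp: int) -> np.ndarray:
    """log S*(x): survival of the gamete-scale inter-arrival distribution."""
    k = np.arange(1, n_comp + 1, dtype=float)[:, None]
    a = k * nu
    q = special.gammaincc(a, lam * x[None, :])
    with np.errstate(divide="ignore"):
        terms = k * _LOG_HALF + np.log(q)
    return special.logsumexp(terms, axis=0)


def _survival_integral(L: np.ndarray, nu: float, lam: float, n_comp: int) -> np.ndarray:
    """Closed-form integral of S* over [0, L] per mixture component."""
    k = np.arange(1, n_comp + 1, dtype=float)[:, None]
    a = k * nu
    w = 0.5 ** k
    part = L[None, :] * special.gammaincc(a, lam * L[None, :]) + (a / lam) * special.gammainc(
        a + 1.0, lam * L[None, :]
    )
    return np.sum(w * part, axis=0)


def _log_g0(L: np.ndarray, nu: float, p: float, lam: float, n_comp: int) -> np.ndarray:
    """log P(no interfering crossover on a chromosome of length L Morgans)."""
    g0 = 1.0 - (1.0 - p) * _survival_integral(L, nu, lam, n_comp)
    return np.log(np.clip(g0, 1e-300, 1.0))


def thinned_gamma_density(x, nu: float, p: float = 0.0):
    """Density of the distance between consecutive gamete crossovers of the
    interfering class (Morgans).  Integrates to 1 over [0, inf)."""
    if nu <= 0:
        raise ValueError("nu must be > 0")
    if not 0 <= p < 1:
        raise ValueError("p must be in [0, 1)")
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(arr < 0):
        raise ValueError("x must be >= 0")
    lam = 2.0 * nu * (1.0 - p)
    n_comp = _n_components(nu, lam, float(arr.max(initial=0.0)))
    out = np.exp(_log_fstar(arr, nu, lam, n_comp))
    return float(out[0]) if np.isscalar(x) else out


def thinned_gamma_survival(x, nu: float, p: float = 0.0):
    """Survival function paired with :func:`thinned_gamma_density`."""
    if nu <= 0:
        raise ValueError("nu must be > 0")
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    lam = 2.0 * nu * (1.0 - p)
    n_comp = _n_components(nu, lam, float(arr.max(initial=0.0)))
    out = np.exp(_log_sstar(arr, nu, lam, n_comp))
    return float(out[0]) if np.isscalar(x) else out


class CrossoverData:
    """Precomputed subset-enumeration layout for the 2^m class-assignment sum.

    Built once per dataset; every likelihood evaluation then reduces to
    vectorised density/survival lookups plus segmented reductions.
    Positions and lengths are supplied in cM and stored in Morgans.
    """

    def __init__(self, gametes: Sequence[tuple[Sequence[float], float]]):
        gap_x: list[float] = []
        gap_sub: list[int] = []
        surv_x: list[float] = []
        surv_sub: list[int] = []
        sub_j: list[int] = []
        sub_m: list[int] = []
        sub_Lidx: list[int] = []
        gam_start: list[int] = [0]
        L_index: dict[float, int] = {}
        n_sub = 0
        self.n_gametes = 0
        self.total_L = 0.0
        self.n_crossovers = 0
        for positions_cm, length_cm in gametes:
            L = float(length_cm) / 100.0
            if L <= 0:
                raise ValueError("chromosome length must be > 0")
            pos = np.sort(np.asarray(positions_cm, dtype=float)) / 100.0
            m = pos.size
            if m > _MAX_XO_PER_CHROM:
                raise ValueError(
                    f"{m} crossovers on one chromosome exceeds the exact-sum limit "
                    f"({_MAX_XO_PER_CHROM})"
                )
            if m and (pos[0] <= 0 or pos[-1] >= L):
                raise ValueError("crossover positions must lie strictly inside (0, length)")
            if m > 1 and np.any(np.diff(pos) <= 0):
                raise ValueError("crossover positions must be distinct")
            Lidx = L_index.setdefault(L, len(L_index))
            self.total_L += L
            self.n_crossovers += m
            for j in range(m + 1):
                for S in combinations(range(m), j):
                    if j > 0:
                        y = pos[list(S)]
                        surv_x.extend((y[0], L - y[-1]))
                        surv_sub.extend((n_sub, n_sub))
                        gap_x.extend(np.diff(y))
                        gap_sub.extend([n_sub] * (j - 1))
                    sub_j.append(j)
                    sub_m.append(m)
                    sub_Lidx.append(Lidx)
                    n_sub += 1
            self.n_gametes += 1
            gam_start.append(n_sub)
        self.gap_x = np.asarray(gap_x, dtype=float)
        self.gap_sub = np.asarray(gap_sub, dtype=np.int64)
        self.surv_x = np.asarray(surv_x, dtype=float)
        self.surv_sub = np.asarray(surv_sub, dtype=np.int64)
        self.sub_j = np.asarray(sub_j, dtype=np.int64)
        self.sub_m = np.asarray(sub_m, dtype=np.int64)
        self.sub_Lidx = np.asarray(sub_Lidx, dtype=np.int64)
        self.gam_start = np.asarray(gam_start, dtype=np.int64)
        self.unique_L = np.array(sorted(L_index, key=L_index.get), dtype=float)
        self.n_sub = n_sub
        self._x_max = float(
            max(
                self.gap_x.max(initial=0.0),
                self.surv_x.max(initial=0.0),
                self.unique_L.max(initial=0.0),
            )
        )

    def loglik(self, nu: float, p: float) -> float:
        if nu <= 0 or not 0 <= p < 1:
            return -np.inf
        lam = 2.0 * nu * (1.0 - p)
        n_comp = _n_components(nu, lam, self._x_max)
        sub_ll = np.zeros(self.n_sub)
        if self.gap_x.size:
            sub_ll += np.bincount(
                self.gap_sub, weights=_log_fstar(self.gap_x, nu, lam, n_comp), minlength=self.n_sub
            )
        if self.surv_x.size:
            sub_ll += np.bincount(
                self.surv_sub, weights=_log_sstar(self.surv_x, nu, lam, n_comp), minlength=self.n_sub
            )
        log_g0 = _log_g0(self.unique_L, nu, p, lam, n_comp)
        empty = self.sub_j == 0
        sub_ll[empty] += log_g0[self.sub_Lidx[empty]]
        sub_ll[~empty] += np.log1p(-p)  # stationary first-event rate factor
        n_escape = self.sub_m - self.sub_j
        if p > 0:
            sub_ll += n_escape * np.log(p) - p * self.unique_L[self.sub_Lidx]
        else:
            sub_ll[n_escape > 0] = -np.inf
        # segmented logsumexp over each gamete's subsets
        order_max = np.maximum.reduceat(sub_ll, self.gam_start[:-1])
        finite = np.isfinite(order_max)
        shifted = np.exp(sub_ll - np.repeat(np.where(finite, order_max, 0.0), np.diff(self.gam_start)))
        shifted[~np.isfinite(sub_ll)] = 0.0
        sums = np.add.reduceat(shifted, self.gam_start[:-1])
        gam_ll = np.where(finite, order_max + np.log(sums), -np.inf)
        return float(gam_ll.sum())


def stahl_loglik(
    gametes: Sequence[tuple[Sequence[float], float]], nu: float, p: float
) -> float:
    """Total log-likelihood of crossover positions (cM) over gamete-chromosomes."""
    return CrossoverData(gametes).loglik(nu, p)


def chromosome_loglik(
    positions_cM: Sequence[float], length_cM: float, nu: float, p: float
) -> float:
    """Log-likelihood of one gamete-chromosome's crossover configuration."""
    pos = np.asarray(positions_cM, dtype=float)
    if pos.size > 1 and np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be sorted and distinct")
    if np.any(pos <= 0) or np.any(pos >= length_cM):
        raise ValueError("positions must lie strictly inside (0, length_cM)")
    return CrossoverData([(pos, length_cM)]).loglik(nu, p)


@dataclass
class StahlFit:
    """Maximum-likelihood interference fit for one individual or pooled dataset."""

    nu_hat: float
    p_hat: float
    loglik: float
    n_gametes: int
    converged: bool
    model: str = "stahl"
    fid: object = None
    sex: str | None = None
    se_nu: float | None = None
    se_p: float | None = None
    n_evals: int = 0

    def as_dict(self) -> dict:
        return {
            "fid": self.fid,
            "sex": self.sex,
            "model": self.model,
            "nu_hat": self.nu_hat,
            "p_hat": self.p_hat,
            "loglik": self.loglik,
            "n_gametes": self.n_gametes,
            "converged": self.converged,
        }


_NU_BOUNDS = (0.05, 200.0)
_P_MAX = 0.5


def _hessian_se(data: CrossoverData, nu: float, p: float) -> tuple[float | None, float | None]:
    h_nu = max(1e-4, 1e-4 * nu)
    h_p = 1e-4
    try:
        f = data.loglik
        d2_nu = (f(nu + h_nu, p) - 2 * f(nu, p) + f(nu - h_nu, p)) / h_nu**2
        se_nu = float(np.sqrt(-1.0 / d2_nu)) if d2_nu < 0 else None
        if 0 < p < _P_MAX:
            d2_p = (f(nu, p + h_p) - 2 * f(nu, p) + f(nu, p - h_p)) / h_p**2
            se_p = float(np.sqrt(-1.0 / d2_p)) if d2_p < 0 else None
        else:
            se_p = None
        return se_nu, se_p
    except (ValueError, FloatingPointError):
        return None, None


def fit_gamma(
    gametes: Sequence[tuple[Sequence[float], float]],
    nu_grid: np.ndarray | None = None,
    fid=None,
    sex: str | None = None,
) -> StahlFit:
    """Fit the pure gamma (interfering-only) submodel: escape fraction fixed at 0."""
    data = gametes if isinstance(gametes, CrossoverData) else CrossoverData(gametes)
    if data.n_crossovers == 0:
        return StahlFit(np.nan, 0.0, data.loglik(1.0, 0.0), data.n_gametes, False, "gamma", fid, sex)
    if nu_grid is None:
        nu_grid = np.geomspace(0.5, 50.0, 12)
    n_evals = 0

    def neg(log_nu: float) -> float:
        nonlocal n_evals
        n_evals += 1
        return -data.loglik(float(np.exp(log_nu)), 0.0)

    grid_ll = np.array([-neg(np.log(nu)) for nu in nu_grid])
    nu0 = nu_grid[int(np.argmax(grid_ll))]
    res = optimize.minimize_scalar(
        neg,
        bounds=(np.log(_NU_BOUNDS[0]), np.log(_NU_BOUNDS[1])),
        method="bounded",
        options={"xatol": 1e-6},
    )
    nu_hat = float(np.exp(res.x))
    ll = -float(res.fun)
    if ll < grid_ll.max():  # bounded search drifted past the grid optimum
        nu_hat, ll = float(nu0), float(grid_ll.max())
    se_nu, _ = _hessian_se(data, nu_hat, 0.0)
    return StahlFit(
        nu_hat, 0.0, ll, data.n_gametes, bool(res.success), "gamma", fid, sex, se_nu, None, n_evals
    )


def fit_stahl(
    gametes: Sequence[tuple[Sequence[float], float]],
    nu_grid: np.ndarray | None = None,
    p_grid: np.ndarray | None = None,
    fid=None,
    sex: str | None = None,
) -> StahlFit:
    """Joint maximum-likelihood fit of interference shape and escape fraction.

    Two-stage search: a coarse grid over (nu, p) followed by a bounded
    Nelder-Mead polish; the p = 0 boundary is handled by also fitting the
    gamma submodel and keeping whichever attains the higher likelihood.
    """
    data = gametes if isinstance(gametes, CrossoverData) else CrossoverData(gametes)
    if data.n_crossovers == 0:
        return StahlFit(np.nan, np.nan, data.loglik(1.0, 0.0), data.n_gametes, False, "stahl", fid, sex)
    if nu_grid is None:
        nu_grid = np.geomspace(0.5, 50.0, 10)
    if p_grid is None:
        p_grid = np.arange(0.0, 0.21, 0.04)
    n_evals = 0

    def neg(theta) -> float:
        nonlocal n_evals
        n_evals += 1
        nu, p = float(theta[0]), float(theta[1])
        return -data.loglik(nu, p)

    best = (np.inf, None)
    for nu in nu_grid:
        for p in p_grid:
            val = neg((nu, p))
            if val < best[0]:
                best = (val, (nu, p))
    res = optimize.minimize(
        neg,
        x0=np.asarray(best[1], dtype=float),
        method="Nelder-Mead",
        bounds=[_NU_BOUNDS, (0.0, _P_MAX)],
        options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 400},
    )
    nu_hat, p_hat = float(res.x[0]), float(res.x[1])
    ll = -float(res.fun)
    converged = bool(res.success)
    sub = fit_gamma(data, nu_grid=nu_grid)
    if sub.loglik >= ll:  # optimum on the p = 0 boundary
        nu_hat, p_hat, ll = sub.nu_hat, 0.0, sub.loglik
        converged = converged or sub.converged
    se_nu, se_p = _hessian_se(data, nu_hat, p_hat)
    return StahlFit(
        nu_hat, p_hat, ll, data.n_gametes, converged, "stahl", fid, sex, se_nu, se_p, n_evals
    )


def gamete_tables_from_intervals(
    intervals: pd.DataFrame,
    gametes: pd.DataFrame,
    gmap,
    sex: str,
) -> list[tuple[np.ndarray, float]]:
    """Convert called crossover intervals to per-gamete-chromosome cM
    configurations on the transmitting parent's sex-specific map.

    ``gametes`` (columns fid, offspring) enumerates every scored gamete so
    that chromosomes without crossovers enter as empty configurations.
    Midpoints mapping onto flat map segments are nudged apart minimally.
    """
    chroms = gmap.chromosomes()
    lengths = {k: gmap.total_cM(k, sex) for k in chroms}
    by_gamete = (
        {k: g for k, g in intervals.groupby(["fid", "offspring"])} if len(intervals) else {}
    )
    out: list[tuple[np.ndarray, float]] = []
    for fid, off in gametes[["fid", "offspring"]].itertuples(index=False):
        sub = by_gamete.get((fid, off))
        for k in chroms:
            L = lengths[k]
            if sub is None:
                out.append((np.empty(0), L))
                continue
            mids = np.sort(sub.loc[sub["chrom"] == k, "midpoint_bp"].to_numpy(dtype=float))
            pos = np.asarray(gmap.bp_to_cM(k, sex, mids), dtype=float).reshape(-1)
            eps = 1e-6 * max(L, 1.0)
            pos = np.clip(pos, eps, L - eps)
            for i in range(1, pos.size):  # break ties from flat map segments
                if pos[i] <= pos[i - 1]:
                    pos[i] = pos[i - 1] + eps
            pos = pos[pos < L - eps / 2]
            out.append((pos, L))
    return out


def fit_per_fid(
    intervals: pd.DataFrame,
    gametes: pd.DataFrame,
    gmap,
    sex_of_fid: dict[int, str],
    model: str = "stahl",
) -> pd.DataFrame:
    """One (nu, p) maximum-likelihood fit per focal individual."""
    fits = []
    for fid, gam in gametes.groupby("fid"):
        sex = sex_of_fid[int(fid)]
        sub = intervals[intervals["fid"] == fid] if len(intervals) else intervals
        tables = gamete_tables_from_intervals(sub, gam, gmap, sex)
        fit_fn = fit_stahl if model == "stahl" else fit_gamma
        fit = fit_fn(tables, fid=int(fid), sex=sex)
        fit.n_gametes = int(len(gam))  # gametes, not gamete-chromosomes
        fits.append(fit.as_dict())
    return pd.DataFrame(fits)
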