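"""Pedigree REML animal models and mixed-linear-model LOCO association.

The animal model is y = Xb + Z_a a + (Z_pe pe) + e with a ~ N(0, A sigma_A)
structured by the pedigree; restricted likelihood is evaluated through the
sparse mixed-model equations and maximised directly over log-variances,
with an EM-REML update available for refinement and verification.  GWAS
uses a single-random-effect mixed model per chromosome with the genomic
relationship matrix built from all other chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.sparse.linalg import splu

from .genome import SnpPanel
from .pedigree import Pedigree

__all__ = [
    "VarianceComponents",
    "GwasRow",
    "a_matrix",
    "a_matrix_inverse",
    "reml_animal_model",
    "grm",
    "mlm_loco_gwas",
    "genomic_control",
    "bonferroni_threshold",
]

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.4549...
MISSING = -1


def a_matrix(ped: Pedigree) -> np.ndarray:
    """Dense additive relationship matrix by the recursive tabular method."""
    n = len(ped)
    A = np.zeros((n, n))
    srow = np.array([ped._row.get(int(s), -1) for s in ped.sire])
    drow = np.array([ped._row.get(int(d), -1) for d in ped.dam])
    for i in range(n):
        s, d = srow[i], drow[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        if s >= 0 or d >= 0:
            contrib = np.zeros(i)
            if s >= 0:
                contrib += 0.5 * A[:i, s]
            if d >= 0:
                contrib += 0.5 * A[:i, d]
            A[:i, i] = A[i, :i] = contrib
    return A


def _henderson(ped: Pedigree, inbreeding: bool = False) -> tuple[sparse.csr_matrix, float]:
    """Sparse inverse of A by Henderson's rules; also returns log|A|."""
    n = len(ped)
    if inbreeding:
        F = ped.inbreeding()
    rows, cols, vals = [], [], []
    logdet = 0.0
    for i in range(n):
        s = ped._row.get(int(ped.sire[i]), -1)
        d = ped._row.get(int(ped.dam[i]), -1)
        known = [r for r in (s, d) if r >= 0]
        # Mendelian-sampling variance: 1, 3/4, 1/2 for 0/1/2 known parents,
        # reduced by each known parent's inbreeding when requested
        dii = 1.0 - sum(0.25 * (1.0 + (F[r] if inbreeding else 0.0)) for r in known)
        alpha = 1.0 / dii
        logdet += np.log(dii)
        rows.append(i), cols.append(i), vals.append(alpha)
        for r in known:
            rows.extend((i, r)), cols.extend((r, i)), vals.extend((-alpha / 2, -alpha / 2))
        for r1 in known:
            for r2 in known:
                rows.append(r1), cols.append(r2), vals.append(alpha / 4)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return Ainv, float(logdet)


def a_matrix_inverse(ped: Pedigree, inbreeding: bool = False) -> sparse.csr_matrix:
    """Sparse A-inverse (Henderson's rules; inbreeding optional)."""
    return _henderson(ped, inbreeding=inbreeding)[0]


@dataclass
class VarianceComponents:
    V_A: float
    V_PE: float
    V_E: float
    loglik: float
    converged: bool
    se: dict = field(default_factory=dict)
    n_records: int = 0
    trace: list = field(default_factory=list)

    @property
    def V_P(self) -> float:
        return self.V_A + self.V_PE + self.V_E

    @property
    def h2(self) -> float:
        return self.V_A / self.V_P

    @property
    def pe2(self) -> float:
        return self.V_PE / self.V_P

    def as_dict(self) -> dict:
        return {
            "V_A": self.V_A,
            "V_PE": self.V_PE,
            "V_E": self.V_E,
            "V_P": self.V_P,
            "h2": self.h2,
            "pe2": self.pe2,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_records": self.n_records,
            **{f"se_{k}": v for k, v in self.se.items()},
        }


class _AnimalModel:
    """Sparse MME machinery for one dataset; variances enter per evaluation."""

    def __init__(
        self,
        records: pd.DataFrame,
        ped: Pedigree,
        repeated: bool,
        covariates: Sequence[str] = (),
    ):
        if not set(records["fid"]).issubset(set(int(i) for i in ped.ids)):
            raise ValueError("records reference individuals absent from the pedigree")
        self.y = records["y"].to_numpy(dtype=float)
        self.N = self.y.size
        X_cols = [np.ones(self.N)]
        for c in covariates:
            X_cols.append(records[c].to_numpy(dtype=float))
        self.X = np.column_stack(X_cols)
        self.p = np.linalg.matrix_rank(self.X)
        self.q = len(ped)
        rows = np.arange(self.N)
        arow = np.array([ped.row_of(int(f)) for f in records["fid"]])
        self.Za = sparse.coo_matrix(
            (np.ones(self.N), (rows, arow)), shape=(self.N, self.q)
        ).tocsr()
        self.repeated = repeated
        if repeated:
            fids = sorted(set(int(f) for f in records["fid"]))
            pe_idx = {f: j for j, f in enumerate(fids)}
            self.q_pe = len(fids)
            pcol = np.array([pe_idx[int(f)] for f in records["fid"]])
            self.Zpe = sparse.coo_matrix(
                (np.ones(self.N), (rows, pcol)), shape=(self.N, self.q_pe)
            ).tocsr()
        else:
            self.q_pe = 0
            self.Zpe = None
        self.Ainv, self.logdet_A = _henderson(ped)
        W = [sparse.csr_matrix(self.X), self.Za] + ([self.Zpe] if repeated else [])
        self.W = sparse.hstack(W).tocsr()
        self.WtW = (self.W.T @ self.W).tocsc()
        self.Wty = self.W.T @ self.y
        self.yty = float(self.y @ self.y)
        self.nf = self.X.shape[1]

    def _coefficient(self, sA: float, sPE: float, sE: float) -> sparse.csc_matrix:
        blocks = [sparse.csc_matrix((self.nf, self.nf)), self.Ainv / sA]
        if self.repeated:
            blocks.append(sparse.identity(self.q_pe, format="csc") / sPE)
        Gstar = sparse.block_diag(blocks, format="csc")
        return (self.WtW / sE + Gstar).tocsc()

    def solve(self, sA: float, sPE: float, sE: float) -> tuple[np.ndarray, float]:
        C = self._coefficient(sA, sPE, sE)
        lu = splu(C)
        theta = lu.solve(self.Wty / sE)
        logdet_C = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        return theta, logdet_C

    def restricted_loglik(self, sA: float, sPE: float, sE: float) -> float:
        if min(sA, sE) <= 0 or (self.repeated and sPE <= 0):
            return -np.inf
        theta, logdet_C = self.solve(sA, sPE, sE)
        yPy = (self.yty - theta @ self.Wty) / sE
        logdet_G = self.q * np.log(sA) + self.logdet_A
        if self.repeated:
            logdet_G += self.q_pe * np.log(sPE)
        m2ll = self.N * np.log(sE) + logdet_G + logdet_C + yPy
        return -0.5 * m2ll

    def em_step(self, sA: float, sPE: float, sE: float) -> tuple[float, float, float]:
        """One EM-REML update (dense C inverse; small problems only)."""
        C = self._coefficient(sA, sPE, sE).toarray()
        Cinv = np.linalg.inv(C)
        theta = Cinv @ (self.Wty / sE)
        a_sl = slice(self.nf, self.nf + self.q)
        a_hat = theta[a_sl]
        Caa = Cinv[a_sl, a_sl]
        sA_new = float(a_hat @ (self.Ainv @ a_hat) + np.trace(self.Ainv @ Caa)) / self.q
        if self.repeated:
            pe_sl = slice(self.nf + self.q, None)
            pe_hat = theta[pe_sl]
            sPE_new = float(pe_hat @ pe_hat + np.trace(Cinv[pe_sl, pe_sl])) / self.q_pe
        else:
            sPE_new = 0.0
        sE_new = float(self.yty - theta @ self.Wty) / (self.N - self.p)
        return sA_new, sPE_new, sE_new


def reml_animal_model(
    records: pd.DataFrame,
    ped: Pedigree,
    repeated: bool = False,
    covariates: Sequence[str] = (),
    max_iter: int = 400,
    tol: float = 1e-8,
    compute_se: bool = True,
) -> VarianceComponents:
    """REML variance components for the pedigree animal model.

    ``records`` needs columns fid and y (plus any covariates); ``repeated``
    adds a permanent-environment effect indexed by FID.  Maximisation is
    direct Nelder-Mead on log-variances of the MME restricted likelihood,
    finished with EM-REML polish steps when the problem is small.
    """
    if len(records) == 0:
        raise ValueError("no phenotype records")
    model = _AnimalModel(records, ped, repeated, covariates)
    vy = float(np.var(model.y, ddof=1))
    if vy == 0:
        raise ValueError("phenotype has zero variance")

    def unpack(z: np.ndarray) -> tuple[float, float, float]:
        if repeated:
            return float(np.exp(z[0])), float(np.exp(z[1])), float(np.exp(z[2]))
        return float(np.exp(z[0])), 0.0, float(np.exp(z[1]))

    def neg(z: np.ndarray) -> float:
        return -model.restricted_loglik(*unpack(z))

    if repeated:
        z0 = np.log([0.3 * vy, 0.2 * vy, 0.5 * vy])
    else:
        z0 = np.log([0.4 * vy, 0.6 * vy])
    res = optimize.minimize(
        neg, z0, method="Nelder-Mead", options={"fatol": tol, "xatol": 1e-6, "maxiter": max_iter * len(z0)}
    )
    sA, sPE, sE = unpack(res.x)
    ll = -float(res.fun)
    trace = [(sA, sPE, sE, ll)]
    # EM polish (monotone in the restricted likelihood) on small problems
    dim = model.nf + model.q + model.q_pe
    if dim <= 1500:
        for _ in range(5):
            sA2, sPE2, sE2 = model.em_step(sA, max(sPE, 1e-12), sE)
            if not repeated:
                sPE2 = 0.0
            ll2 = model.restricted_loglik(sA2, sPE2, sE2)
            if not np.isfinite(ll2) or ll2 < ll - 1e-9:
                break
            sA, sPE, sE, ll = sA2, sPE2, sE2, ll2
            trace.append((sA, sPE, sE, ll))
            if len(trace) > 1 and abs(trace[-1][3] - trace[-2][3]) < tol:
                break
    floor = 1e-10 * vy
    sA, sPE, sE = max(sA, floor), (max(sPE, 0.0) if repeated else 0.0), max(sE, floor)
    se: dict = {}
    if compute_se:
        se = _vc_standard_errors(model, sA, sPE, sE, repeated)
    return VarianceComponents(
        V_A=sA,
        V_PE=sPE,
        V_E=sE,
        loglik=ll,
        converged=bool(res.success),
        se=se,
        n_records=model.N,
        trace=trace,
    )


def _vc_standard_errors(
    model: _AnimalModel, sA: float, sPE: float, sE: float, repeated: bool
) -> dict:
    """Observed-information SEs by finite differences, delta method for ratios."""
    params = [sA, sPE, sE] if repeated else [sA, sE]

    def f(v: np.ndarray) -> float:
        if repeated:
            return model.restricted_loglik(v[0], v[1], v[2])
        return model.restricted_loglik(v[0], 0.0, v[1])

    k = len(params)
    h = np.array([max(1e-6, 1e-4 * p) for p in params])
    H = np.zeros((k, k))
    v0 = np.asarray(params, dtype=float)
    f0 = f(v0)
    try:
        for i in range(k):
            for j in range(i, k):
                vi, vj = np.zeros(k), np.zeros(k)
                vi[i], vj[j] = h[i], h[j]
                if i == j:
                    H[i, i] = (f(v0 + vi) - 2 * f0 + f(v0 - vi)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(v0 + vi + vj) - f(v0 + vi - vj) - f(v0 - vi + vj) + f(v0 - vi - vj)
                    ) / (4 * h[i] * h[j])
        cov = np.linalg.inv(-H)
        if np.any(np.diag(cov) < 0):
            return {}
    except (np.linalg.LinAlgError, ValueError, FloatingPointError):
        return {}
    names = ["V_A", "V_PE", "V_E"] if repeated else ["V_A", "V_E"]
    out = {n: float(np.sqrt(cov[i, i])) for i, n in enumerate(names)}
    vp = sum(params)
    # delta method for h2 = V_A / V_P
    g = np.full(k, -params[0] / vp**2)
    g[0] += 1.0 / vp
    var_h2 = float(g @ cov @ g)
    if var_h2 >= 0:
        out["h2"] = float(np.sqrt(var_h2))
    return out


def grm(
    genotypes: pd.DataFrame,
    panel: SnpPanel | None = None,
    exclude_chromosome: int | None = None,
) -> np.ndarray:
    """Centred-and-scaled genomic relationship matrix (aggregate scaling:
    G = WW' / sum 2 p_j (1 - p_j)).  Missing genotypes are mean-imputed."""
    if exclude_chromosome is not None:
        if panel is None:
            raise ValueError("panel required to exclude a chromosome")
        keep = panel.chrom != exclude_chromosome
        genotypes = genotypes.loc[:, keep]
    M = genotypes.to_numpy(dtype=float)
    M[M == MISSING] = np.nan
    freq = np.nanmean(M, axis=0) / 2.0
    poly = (freq > 0) & (freq < 1)
    M, freq = M[:, poly], freq[poly]
    if M.shape[1] < 2:
        raise ValueError("fewer than 2 polymorphic markers remain")
    inds = np.where(np.isnan(M))
    M[inds] = 2.0 * freq[inds[1]]
    W = M - 2.0 * freq
    denom = float(np.sum(2.0 * freq * (1.0 - freq)))
    return (W @ W.T) / denom


def _reml_single_kernel(
    y: np.ndarray, X: np.ndarray, K: np.ndarray
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """REML of y = Xb + g + e, g ~ N(0, sg K): eigen-rotation profile over
    delta = se/sg.  Returns (sg, se, eigvals, eigvecs)."""
    n, p = X.shape
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    _, logdet_XtX = np.linalg.slogdet(X.T @ X)

    def negll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = d + delta
        XtWX = (Xt / w[:, None]).T @ Xt
        b = np.linalg.solve(XtWX, (Xt / w[:, None]).T @ yt)
        r = yt - Xt @ b
        rss = float(np.sum(r**2 / w))
        sg = rss / (n - p)
        _, logdet_XtWX = np.linalg.slogdet(XtWX)
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * sg)
            + np.sum(np.log(w))
            + logdet_XtWX
            - logdet_XtX
            + (n - p)
        )
        return -ll

    res = optimize.minimize_scalar(negll, bounds=(-12.0, 12.0), method="bounded")
    delta = float(np.exp(res.x))
    w = d + delta
    XtWX = (Xt / w[:, None]).T @ Xt
    b = np.linalg.solve(XtWX, (Xt / w[:, None]).T @ yt)
    r = yt - Xt @ b
    sg = float(np.sum(r**2 / w)) / (n - p)
    return sg, sg * delta, d, U


@dataclass
class GwasRow:
    marker: str
    chrom: int
    bp: int
    maf: float
    beta: float
    se: float
    chi2: float
    p_raw: float


def mlm_loco_gwas(
    pheno: pd.DataFrame,
    genotypes: pd.DataFrame,
    panel: SnpPanel,
    covariates: Sequence[str] = (),
    gc_correct: bool = True,
) -> pd.DataFrame:
    """Per-SNP mixed-model association, leaving the tested SNP's chromosome
    out of the genomic relationship matrix.

    ``pheno`` needs columns fid and y (one record per individual) plus any
    covariates; genotype rows are matched to fid by index.  Effects are
    reported for the minor allele.  Monomorphic SNPs are skipped.
    """
    ids = pheno["fid"].to_numpy()
    try:
        G = genotypes.loc[ids]
    except KeyError as e:
        raise ValueError(f"phenotyped individual missing from genotypes: {e}") from None
    y = pheno["y"].to_numpy(dtype=float)
    n = y.size
    X = np.column_stack([np.ones(n)] + [pheno[c].to_numpy(dtype=float) for c in covariates])
    rows: list[GwasRow] = []
    skipped: list[tuple[str, str]] = []
    for chrom in np.unique(panel.chrom):
        chrom = int(chrom)
        K = grm(G, panel, exclude_chromosome=chrom)
        sg, se_, dvals, U = _reml_single_kernel(y, X, K)
        w = sg * dvals + se_
        yt, Xt = U.T @ y, U.T @ X
        idx = panel.markers_on(chrom)
        M = G.iloc[:, idx].to_numpy(dtype=float)
        M[M == MISSING] = np.nan
        freq = np.nanmean(M, axis=0) / 2.0
        for j, col in enumerate(idx):
            f = freq[j]
            if not (0 < f < 1):
                skipped.append((str(panel.ids[col]), "monomorphic"))
                continue
            x = M[:, j]
            x = np.where(np.isnan(x), 2 * f, x)
            maf = min(f, 1 - f)
            if f > 0.5:
                x = 2.0 - x  # report the minor allele
            xt = U.T @ x
            Xs = np.column_stack([Xt, xt])
            A = (Xs / w[:, None]).T @ Xs
            rhs = (Xs / w[:, None]).T @ yt
            try:
                cov = np.linalg.inv(A)
            except np.linalg.LinAlgError:
                skipped.append((str(panel.ids[col]), "collinear"))
                continue
            b = cov @ rhs
            beta = float(b[-1])
            se_b = float(np.sqrt(cov[-1, -1]))
            chi2 = (beta / se_b) ** 2
            rows.append(
                GwasRow(
                    marker=str(panel.ids[col]),
                    chrom=chrom,
                    bp=int(panel.bp[col]),
                    maf=float(maf),
                    beta=beta,
                    se=se_b,
                    chi2=float(chi2),
                    p_raw=float(stats.chi2.sf(chi2, 1)),
                )
            )
    out = pd.DataFrame([r.__dict__ for r in rows]).sort_values(["chrom", "bp"]).reset_index(drop=True)
    if gc_correct and len(out):
        lam, p_gc = genomic_control(out["chi2"].to_numpy())
        out["lambda_gc"] = lam
        out["p_gc"] = p_gc
    out.attrs["skipped"] = skipped
    return out


def genomic_control(chi2_values: np.ndarray) -> tuple[float, np.ndarray]:
    """Genomic-control inflation factor and corrected P-values (1 df).

    lambda = median(chi2) / 0.4549...; statistics are deflated only when
    lambda > 1 (no inflation of significance for lambda < 1).
    """
    chi2_values = np.asarray(chi2_values, dtype=float)
    if chi2_values.size == 0:
        raise ValueError("empty chi-square vector")
    lam = float(np.median(chi2_values) / CHI2_MEDIAN_1DF)
    corrected = chi2_values / lam if lam > 1 else chi2_values
    return lam, stats.chi2.sf(corrected, 1)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
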