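"""Synthetic meiosis: gametes under the gamma-escape crossover process,
pedigrees, SNP-array genotypes with error, and pedigree-structured phenotypes.

Every stochastic entry point takes a seed or a ``numpy.random.Generator``;
no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .genome import ChromosomeDef, GeneticMap, SnpPanel
from .pedigree import Pedigree

__all__ = [
    "SimConfig",
    "TrueGamete",
    "simulate_stahl_positions",
    "simulate_pedigree",
    "simulate_gametes",
    "simulate_phenotypes_direct",
]


@dataclass
class QtlSpec:
    marker_id: str
    allele_freq: float
    effect: float


@dataclass
class SimConfig:
    """Knobs for a full synthetic dataset (see CLI ``simulate``)."""

    nu: float = 8.0
    p_escape: float = 0.0
    n_sires: int = 5
    n_dams: int = 20
    offspring_per_pair: int = 8
    generations: int = 1
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 1
    marker_spacing_bp: int = 1_000_000
    mean: float = 0.0
    V_A: float = 1.0
    V_PE: float = 0.0
    V_E: float = 1.0
    qtl: QtlSpec | None = None

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("nu must be > 0")
        for name in ("p_escape", "genotyping_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _equilibrium_first_arrival(u: float, nu: float, lam: float) -> float:
    """Quantile of the stationary forward-recurrence time of a gamma(nu, lam)
    renewal process.  CDF(x) = (lam x / nu) S(x; nu) + F(x; nu+1)."""

    def cdf(x: float) -> float:
        return (lam * x / nu) * special.gammaincc(nu, lam * x) + special.gammainc(nu + 1.0, lam * x)

    hi = (nu + 1.0) / lam
    while cdf(hi) < u:
        hi *= 2.0
    return optimize.brentq(lambda x: cdf(x) - u, 0.0, hi, xtol=1e-12)


def simulate_stahl_positions(
    length_cM: float, nu: float, p_escape: float, seed
) -> np.ndarray:
    """Crossover positions (cM, sorted) on one transmitted chromosome.

    Interfering chiasmata: stationary gamma renewal on the bivalent with
    shape ``nu`` and rate ``2 nu (1 - p_escape)`` per Morgan, each passed to
    the gamete independently with probability 1/2.  Escaping crossovers:
    Poisson at ``p_escape`` per Morgan on the gamete.  Expected gamete count
    equals the length in Morgans for any parameters.
    """
    if length_cM < 0:
        raise ValueError("length_cM must be >= 0")
    if nu <= 0:
        raise ValueError("nu must be > 0")
    if not 0 <= p_escape < 1:
        raise ValueError("p_escape must be in [0, 1)")
    rng = _rng(seed)
    L = length_cM / 100.0
    if L == 0:
        return np.empty(0)
    lam = 2.0 * nu * (1.0 - p_escape)
    events: list[float] = []
    x = _equilibrium_first_arrival(rng.random(), nu, lam)
    while x < L:
        events.append(x)
        x += rng.gamma(nu, 1.0 / lam)
    chiasmata = np.asarray(events)
    class1 = chiasmata[rng.random(chiasmata.size) < 0.5]
    n2 = rng.poisson(p_escape * L)
    class2 = rng.uniform(0.0, L, n2)
    return np.sort(np.concatenate([class1, class2])) * 100.0


def simulate_pedigree(
    n_sires: int, n_dams: int, offspring_per_pair: int, generations: int, seed
) -> Pedigree:
    """Random-mating pedigree: each dam mates one random sire per generation,
    producing a litter; later generations draw parents from the previous one."""
    if min(n_sires, n_dams, offspring_per_pair, generations) < 1:
        raise ValueError("all design counts must be >= 1")
    rng = _rng(seed)
    rows: list[tuple[int, int, int, str]] = []
    next_id = 1
    sires = []
    dams = []
    for _ in range(n_sires):
        rows.append((next_id, 0, 0, "M"))
        sires.append(next_id)
        next_id += 1
    for _ in range(n_dams):
        rows.append((next_id, 0, 0, "F"))
        dams.append(next_id)
        next_id += 1
    for _ in range(generations):
        new_m: list[int] = []
        new_f: list[int] = []
        for dam in dams:
            sire = sires[rng.integers(len(sires))]
            for _ in range(offspring_per_pair):
                sex = "M" if rng.random() < 0.5 else "F"
                rows.append((next_id, sire, dam, sex))
                (new_m if sex == "M" else new_f).append(next_id)
                next_id += 1
        if new_m and new_f:
            sires = list(rng.choice(new_m, size=min(n_sires, len(new_m)), replace=False))
            dams = list(rng.choice(new_f, size=min(n_dams, len(new_f)), replace=False))
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"]))


@dataclass
class TrueGamete:
    """Ground truth for one transmitted gamete."""

    fid: int
    offspring: int
    sex: str  # sex of the transmitting parent
    xo_bp: dict[int, np.ndarray] = field(default_factory=dict)
    xo_cM: dict[int, np.ndarray] = field(default_factory=dict)
    start_hap: dict[int, int] = field(default_factory=dict)

    @property
    def n_crossovers(self) -> int:
        return int(sum(v.size for v in self.xo_bp.values()))

    def hap_index_at(self, chrom: int, bp: np.ndarray) -> np.ndarray:
        """Which parental haplotype (0 = hapA, 1 = hapB) is carried at each bp.

        A crossover falling exactly on a marker position acts to its right,
        so the marker itself stays with the left-hand segment.
        """
        xo = self.xo_bp.get(chrom, np.empty(0))
        return (self.start_hap[chrom] + np.searchsorted(xo, bp, side="left")) % 2


def _meiosis(
    parent_haps: np.ndarray,
    sex: str,
    fid: int,
    offspring: int,
    chrom_defs: Sequence[ChromosomeDef],
    gmap: GeneticMap,
    panel: SnpPanel,
    nu: float,
    p_escape: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, TrueGamete]:
    gamete = np.empty(panel.n_markers, dtype=np.int8)
    truth = TrueGamete(fid=fid, offspring=offspring, sex=sex)
    for cdef in chrom_defs:
        k = cdef.index
        pos_cm = simulate_stahl_positions(gmap.total_cM(k, sex), nu, p_escape, rng)
        pos_bp = np.asarray(gmap.cM_to_bp(k, sex, pos_cm), dtype=float).reshape(-1)
        truth.xo_cM[k] = pos_cm
        truth.xo_bp[k] = pos_bp
        truth.start_hap[k] = int(rng.integers(2))
        idx = panel.markers_on(k)
        hap_idx = truth.hap_index_at(k, panel.bp[idx].astype(float))
        gamete[idx] = parent_haps[hap_idx, idx]
    return gamete, truth


def simulate_gametes(
    ped: Pedigree,
    chrom_defs: Sequence[ChromosomeDef],
    gmap: GeneticMap,
    panel: SnpPanel,
    nu: float = 8.0,
    p_escape: float = 0.0,
    genotyping_error_rate: float = 0.0,
    missing_rate: float = 0.0,
    founder_freqs: np.ndarray | None = None,
    seed=1,
) -> tuple[pd.DataFrame, dict[int, np.ndarray], list[TrueGamete]]:
    """Drop haplotypes through the pedigree by simulated meiosis.

    Returns (genotype table, true phased haplotypes per individual as a
    (2, n_markers) array with row 0 = sire-derived, and the ground-truth
    gamete list).  Genotypes are 0/1/2 with -1 for missing; genotyping
    error flips each of the two alleles independently.
    """
    if panel.n_markers == 0:
        raise ValueError("marker panel is empty")
    rng = _rng(seed)
    n_markers = panel.n_markers
    if founder_freqs is None:
        founder_freqs = rng.uniform(0.05, 0.5, n_markers)
    haps: dict[int, np.ndarray] = {}
    truths: list[TrueGamete] = []
    true_geno = np.empty((len(ped), n_markers), dtype=np.int8)
    for r, ind in enumerate(ped.ids):
        ind = int(ind)
        sire, dam = ped.parents(ind)
        if sire == 0 and dam == 0:
            h = rng.binomial(1, founder_freqs, (2, n_markers)).astype(np.int8)
        else:
            pat, t_pat = _meiosis(
                haps[sire], "M", sire, ind, chrom_defs, gmap, panel, nu, p_escape, rng
            )
            mat, t_mat = _meiosis(
                haps[dam], "F", dam, ind, chrom_defs, gmap, panel, nu, p_escape, rng
            )
            truths.extend([t_pat, t_mat])
            h = np.stack([pat, mat])
        haps[ind] = h
        true_geno[r] = h.sum(axis=0)
    obs = true_geno.copy()
    if genotyping_error_rate > 0:
        for r in range(len(ped)):
            h = haps[int(ped.ids[r])]
            e = rng.random((2, n_markers)) < genotyping_error_rate
            obs[r] = ((h ^ e)).sum(axis=0)
    if missing_rate > 0:
        obs[rng.random(obs.shape) < missing_rate] = -1
    geno = pd.DataFrame(obs, index=ped.ids, columns=panel.ids)
    geno.index.name = "id"
    return geno, haps, truths


def simulate_phenotypes_direct(
    ped: Pedigree,
    V_A: float,
    V_PE: float,
    V_E: float,
    mean: float = 0.0,
    n_records_per_fid: int = 1,
    fids: Sequence[int] | None = None,
    qtl_dosage: np.ndarray | None = None,
    qtl_effect: float = 0.0,
    seed=1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotype records with pedigree-structured additive values.

    Breeding values follow a_i = (a_sire + a_dam)/2 + m_i with Mendelian
    sampling variance V_A/2 (inbreeding ignored); y_ij = mean + a_i + pe_i
    + qtl_i + e_ij.  Returns (records, truth) where truth holds each
    individual's breeding value and permanent-environment deviation.
    """
    if min(V_A, V_PE, V_E) < 0:
        raise ValueError("variances must be >= 0")
    rng = _rng(seed)
    n = len(ped)
    a = np.zeros(n)
    for r, ind in enumerate(ped.ids):
        sire, dam = ped.parents(int(ind))
        if sire == 0 and dam == 0:
            a[r] = rng.normal(0.0, np.sqrt(V_A))
        else:
            mid = 0.5 * (a[ped.row_of(sire)] + a[ped.row_of(dam)])
            a[r] = mid + rng.normal(0.0, np.sqrt(0.5 * V_A))
    pe = rng.normal(0.0, np.sqrt(V_PE), n) if V_PE > 0 else np.zeros(n)
    if fids is None:
        fids = [int(i) for i in ped.ids]
    if qtl_dosage is not None and len(qtl_dosage) != n:
        raise ValueError("qtl_dosage must have one entry per pedigree individual")
    rows = []
    for ind in fids:
        r = ped.row_of(int(ind))
        q = qtl_effect * float(qtl_dosage[r]) if qtl_dosage is not None else 0.0
        e = rng.normal(0.0, np.sqrt(V_E), n_records_per_fid)
        for j in range(n_records_per_fid):
            rows.append((int(ind), j + 1, mean + a[r] + pe[r] + q + e[j]))
    records = pd.DataFrame(rows, columns=["fid", "record", "y"])
    truth = pd.DataFrame({"id": ped.ids, "breeding_value": a, "pe": pe})
    return records, truth
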