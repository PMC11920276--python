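"""Per-gamete and per-individual crossover phenotypes and descriptive statistics.

Phenotypes: autosomal crossover count; intra-chromosomal allelic shuffling
(probability a random within-chromosome locus pair is uncoupled in the
gamete); mean distance from a crossover to the nearest telomere on its arm.
Crossover point positions are interval midpoints throughout.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import InheritanceVector
from .genome import ACROCENTRIC, ChromosomeDef, genome_fractions

__all__ = [
    "crossover_count",
    "r_intra",
    "r_intra_from_proportions",
    "distance_to_telomere",
    "gamete_phenotypes",
    "aggregate_fid",
    "summarize_descriptives",
]

PHENOTYPE_COLS = ("crossover_count", "r_intra", "dist_telomere_mb")


def crossover_count(intervals: pd.DataFrame) -> int:
    """Total autosomal crossover count for one gamete's interval table."""
    return int(len(intervals))


def r_intra_from_proportions(p: np.ndarray, fractions: np.ndarray) -> float:
    """sum_k 2 p_k (1 - p_k) L_k^2 with L_k the genome fraction of chromosome k.

    ``p`` may contain NaN for chromosomes without origin information; those
    contribute nothing (their true p is unknown, not 0.5).
    """
    p = np.asarray(p, dtype=float)
    L = np.asarray(fractions, dtype=float)
    if p.shape != L.shape:
        raise ValueError("p and fractions must align per chromosome")
    terms = 2.0 * p * (1.0 - p) * L**2
    return float(np.nansum(terms))


def r_intra(
    ivs: Iterable[InheritanceVector],
    chrom_defs: Sequence[ChromosomeDef],
    weight: str = "markers",
) -> float:
    """Shuffling probability for one gamete from its per-chromosome origin calls.

    ``weight='markers'`` (default) takes p_k as the proportion of informative
    markers carrying the hapA (paternal) allele; ``weight='length'`` weights
    each marker by the physical segment it tags (midpoint partition of the
    chromosome).  A chromosome of the genome with no origin calls raises.
    """
    fractions = genome_fractions(chrom_defs)
    by_index = {c.index: j for j, c in enumerate(chrom_defs)}
    p = np.full(len(chrom_defs), np.nan)
    seen = set()
    for iv in ivs:
        j = by_index[iv.chrom]
        seen.add(iv.chrom)
        if iv.origin.size == 0:
            raise ValueError(f"chromosome {iv.chrom}: no phased markers for gamete")
        if weight == "markers":
            p[j] = float(np.mean(iv.origin == 0))
        elif weight == "length":
            cdef = chrom_defs[j]
            bp = np.asarray(iv.bp, dtype=float)
            mid = 0.5 * (bp[1:] + bp[:-1])
            edges = np.concatenate([[0.0], mid, [float(cdef.bp_length)]])
            seg = np.diff(edges)
            p[j] = float(np.sum(seg[iv.origin == 0]) / cdef.bp_length)
        else:
            raise ValueError(f"unknown weight {weight!r}")
    missing = set(by_index) - seen
    if missing:
        raise ValueError(f"chromosome {sorted(missing)[0]}: no phased markers for gamete")
    return r_intra_from_proportions(p, fractions)


def distance_to_telomere(
    intervals: pd.DataFrame, chrom_defs: Sequence[ChromosomeDef]
) -> float:
    """Mean distance (Mb) from the nearest telomere, one crossover per arm.

    Crossovers are placed at interval midpoints and assigned to the p or q
    arm by the centromere; per arm only the crossover closest to that arm's
    telomere counts.  Gametes with zero crossovers return NaN (excluded,
    not zero).
    """
    if len(intervals) == 0:
        return float("nan")
    by_index = {c.index: c for c in chrom_defs}
    dists: list[float] = []
    for chrom, grp in intervals.groupby("chrom"):
        cdef = by_index[int(chrom)]
        mids = grp["midpoint_bp"].to_numpy(dtype=float)
        if cdef.arm_class == ACROCENTRIC:
            # single arm; the telomere is the terminus opposite the centromere
            if cdef.centromere_bp == 0:
                d = (cdef.bp_length - mids) / 1e6
            else:
                d = mids / 1e6
            dists.append(float(d.min()))
        else:
            p_arm = mids[mids < cdef.centromere_bp]
            q_arm = mids[mids >= cdef.centromere_bp]
            if p_arm.size:
                dists.append(float(p_arm.min() / 1e6))
            if q_arm.size:
                dists.append(float((cdef.bp_length - q_arm).min() / 1e6))
    return float(np.mean(dists))


def gamete_phenotypes(
    intervals: pd.DataFrame,
    ivs: Sequence[InheritanceVector],
    chrom_defs: Sequence[ChromosomeDef],
    r_intra_weight: str = "markers",
) -> pd.DataFrame:
    """All three per-gamete phenotypes for every (fid, offspring) gamete."""
    iv_by_gamete: dict[tuple[int, int], list[InheritanceVector]] = {}
    for iv in ivs:
        iv_by_gamete.setdefault((iv.fid, iv.offspring), []).append(iv)
    groups = (
        dict(tuple(intervals.groupby(["fid", "offspring"]))) if len(intervals) else {}
    )
    empty = intervals.iloc[0:0]
    rows = []
    for (fid, off), gam_ivs in sorted(iv_by_gamete.items()):
        sub = groups.get((fid, off), empty)
        rows.append(
            (
                fid,
                off,
                crossover_count(sub),
                r_intra(gam_ivs, chrom_defs, weight=r_intra_weight),
                distance_to_telomere(sub, chrom_defs),
            )
        )
    return pd.DataFrame(rows, columns=["fid", "offspring", *PHENOTYPE_COLS])


def aggregate_fid(
    gamete_pheno: pd.DataFrame, sex_of_fid: dict[int, str] | None = None
) -> pd.DataFrame:
    """Per-FID arithmetic means; undefined telomere distances are excluded
    from that mean only."""
    out = (
        gamete_pheno.groupby("fid")
        .agg(
            n_gametes=("offspring", "size"),
            crossover_count=("crossover_count", "mean"),
            r_intra=("r_intra", "mean"),
            dist_telomere_mb=("dist_telomere_mb", lambda s: s.dropna().mean()),
        )
        .reset_index()
    )
    if sex_of_fid is not None:
        out.insert(1, "sex", out["fid"].map(sex_of_fid))
    return out


def summarize_descriptives(
    pheno: pd.DataFrame, sex_col: str = "sex", phenotypes: Sequence[str] = PHENOTYPE_COLS
) -> dict[str, pd.DataFrame]:
    """Sex-wise means/SDs, Welch t-tests, and Pearson correlations.

    Returns {'means': ..., 'welch': ..., 'correlations': ...}; correlations
    are reported overall and within each sex.
    """
    sexes = sorted(pheno[sex_col].dropna().unique())
    mean_rows, welch_rows, corr_rows = [], [], []
    for ph in phenotypes:
        for s in sexes:
            v = pheno.loc[pheno[sex_col] == s, ph].dropna()
            mean_rows.append((ph, s, len(v), v.mean(), v.std(ddof=1)))
        if len(sexes) == 2:
            a = pheno.loc[pheno[sex_col] == sexes[0], ph].dropna()
            b = pheno.loc[pheno[sex_col] == sexes[1], ph].dropna()
            if len(a) < 2 or len(b) < 2:
                raise ValueError(f"need >= 2 observations per sex for {ph}")
            if a.nunique() == 1 and b.nunique() == 1:  # degenerate: t undefined
                welch_rows.append((ph, np.nan, np.nan, True))
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
                welch_rows.append((ph, float(t), float(p), False))
    for i, ph1 in enumerate(phenotypes):
        for ph2 in phenotypes[i + 1 :]:
            for scope in ["all", *sexes]:
                sub = pheno if scope == "all" else pheno[pheno[sex_col] == scope]
                pair = sub[[ph1, ph2]].dropna()
                if len(pair) >= 3 and pair[ph1].var() > 0 and pair[ph2].var() > 0:
                    r, p = stats.pearsonr(pair[ph1], pair[ph2])
                else:
                    r, p = np.nan, np.nan
                corr_rows.append((ph1, ph2, scope, float(r), float(p), len(pair)))
    return {
        "means": pd.DataFrame(mean_rows, columns=["phenotype", "sex", "n", "mean", "sd"]),
        "welch": pd.DataFrame(welch_rows, columns=["phenotype", "t", "p", "zero_variance"]),
        "correlations": pd.DataFrame(
            corr_rows, columns=["phenotype_1", "phenotype_2", "scope", "r", "p", "n"]
        ),
    }
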