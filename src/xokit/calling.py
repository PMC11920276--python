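"""Crossover recovery from phased parental haplotypes and offspring genotypes.

A deterministic stand-in for likelihood-based phase-change callers: origin
calls are made at markers where transmission is unambiguous, short origin
runs are absorbed as genotyping error, and crossovers are placed between
the surviving runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import SnpPanel
from .pedigree import Pedigree

__all__ = [
    "InheritanceVector",
    "CrossoverInterval",
    "qc_genotypes",
    "infer_inheritance",
    "call_crossovers",
    "call_pedigree",
]

MISSING = -1


@dataclass
class InheritanceVector:
    """Origin calls along one chromosome of one transmitted gamete.

    origin codes: 0 = hapA (the focal parent's sire-derived haplotype),
    1 = hapB.  Only unambiguous informative markers appear.
    """

    fid: int
    offspring: int
    chrom: int
    bp: np.ndarray
    origin: np.ndarray
    n_inconsistent: int = 0


@dataclass
class CrossoverInterval:
    fid: int
    offspring: int
    chrom: int
    left_bp: int
    right_bp: int

    @property
    def midpoint_bp(self) -> float:
        return 0.5 * (self.left_bp + self.right_bp)


def qc_genotypes(
    genotypes: pd.DataFrame,
    maf_min: float = 0.01,
    callrate_min: float = 0.95,
    hwe_chi2_max: float = 600.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marker QC: minor allele frequency, call rate and Hardy-Weinberg chi2.

    Returns (filtered genotype table, per-marker report with pass/fail flags).
    Genotypes are 0/1/2 with -1 (or NaN) for missing, markers in columns.
    """
    if genotypes.shape[1] == 0 or genotypes.shape[0] == 0:
        raise ValueError("empty genotype table")
    g = genotypes.to_numpy(dtype=float)
    g[g == MISSING] = np.nan
    called = ~np.isnan(g)
    n_called = called.sum(axis=0)
    callrate = n_called / g.shape[0]
    with np.errstate(invalid="ignore"):
        freq = np.nansum(g, axis=0) / (2.0 * np.maximum(n_called, 1))
    maf = np.minimum(freq, 1.0 - freq)
    n0 = np.sum(g == 0, axis=0)
    n1 = np.sum(g == 1, axis=0)
    n2 = np.sum(g == 2, axis=0)
    n = n0 + n1 + n2
    chi2 = np.zeros(g.shape[1])
    poly = (maf > 0) & (n > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e0 = n * (1 - freq) ** 2
        e1 = n * 2 * freq * (1 - freq)
        e2 = n * freq**2
        chi2_all = (n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2
    chi2[poly] = chi2_all[poly]
    fail_maf = maf < maf_min
    fail_call = callrate < callrate_min
    fail_hwe = chi2 > hwe_chi2_max
    keep = ~(fail_maf | fail_call | fail_hwe)
    report = pd.DataFrame(
        {
            "marker": genotypes.columns,
            "maf": maf,
            "callrate": callrate,
            "hwe_chi2": chi2,
            "fail_maf": fail_maf,
            "fail_callrate": fail_call,
            "fail_hwe": fail_hwe,
            "pass": keep,
        }
    )
    return genotypes.loc[:, keep], report


def infer_inheritance(
    focal_haps: np.ndarray,
    other_geno: np.ndarray,
    offspring_geno: np.ndarray,
    bp: np.ndarray,
    fid: int = 0,
    offspring: int = 0,
    chrom: int = 0,
) -> InheritanceVector:
    """Origin of the transmitted allele at each unambiguous informative marker.

    ``focal_haps`` is (2, m) phased alleles of the focal parent for the
    markers of one chromosome; genotypes are 0/1/2 with -1 missing.
    Markers where both parents and the offspring are heterozygous are
    ambiguous and skipped; Mendelian inconsistencies are counted and skipped.
    """
    hapA, hapB = focal_haps[0].astype(int), focal_haps[1].astype(int)
    other = np.asarray(other_geno, dtype=int)
    off = np.asarray(offspring_geno, dtype=int)
    informative = (hapA != hapB) & (off != MISSING) & (other != MISSING)
    # transmitted allele from the focal parent, -9 where undetermined
    t = np.full(off.shape, -9, dtype=int)
    t[informative & (off == 0)] = 0
    t[informative & (off == 2)] = 1
    het = informative & (off == 1)
    t[het & (other == 0)] = 1
    t[het & (other == 2)] = 0
    # Mendelian check: the other parent must be able to supply off - t
    ok = t != -9
    t_other = off - t
    bad = ok & (
        (t_other < 0)
        | (t_other > 1)
        | ((other == 0) & (t_other != 0))
        | ((other == 2) & (t_other != 1))
    )
    ok &= ~bad
    origin = np.where(t[ok] == hapA[ok], 0, 1).astype(np.int8)
    return InheritanceVector(
        fid=fid,
        offspring=offspring,
        chrom=chrom,
        bp=np.asarray(bp)[ok],
        origin=origin,
        n_inconsistent=int(bad.sum()),
    )


def _runs(origin: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode -> list of (start, stop_exclusive, value)."""
    if origin.size == 0:
        return []
    change = np.flatnonzero(np.diff(origin)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [origin.size]])
    return [(int(a), int(b), int(origin[a])) for a, b in zip(starts, stops)]


def call_crossovers(iv: InheritanceVector, min_support: int = 3) -> list[CrossoverInterval]:
    """Place crossovers between consecutive accepted origin runs.

    Runs shorter than ``min_support`` informative markers (including runs at
    chromosome ends) are treated as genotyping error: their markers are
    discarded and runs are rebuilt until all survivors are long enough.
    Interval endpoints are the last marker of the left run and the first
    marker of the right run.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    bp = np.asarray(iv.bp)
    origin = np.asarray(iv.origin)
    while True:
        runs = _runs(origin)
        short = [r for r in runs if r[1] - r[0] < min_support]
        if not short or len(runs) == len(short):
            if short:  # nothing credible left
                runs = []
            break
        keep = np.ones(origin.size, dtype=bool)
        for a, b, _ in short:
            keep[a:b] = False
        bp, origin = bp[keep], origin[keep]
    out: list[CrossoverInterval] = []
    for (a1, b1, _), (a2, _, _) in zip(runs, runs[1:]):
        out.append(
            CrossoverInterval(
                fid=iv.fid,
                offspring=iv.offspring,
                chrom=iv.chrom,
                left_bp=int(bp[b1 - 1]),
                right_bp=int(bp[a2]),
            )
        )
    return out


def intervals_to_frame(intervals: Sequence[CrossoverInterval]) -> pd.DataFrame:
    rows = [
        (iv.chrom, iv.left_bp, iv.right_bp, iv.fid, iv.offspring, iv.midpoint_bp)
        for iv in intervals
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "left_bp", "right_bp", "fid", "offspring", "midpoint_bp"]
    )


def call_pedigree(
    ped: Pedigree,
    haplotypes: dict[int, np.ndarray],
    genotypes: pd.DataFrame,
    panel: SnpPanel,
    fids: Sequence[int] | None = None,
    min_support: int = 3,
) -> tuple[pd.DataFrame, list[InheritanceVector]]:
    """Call crossovers for every (focal parent, offspring, chromosome).

    Focal parents default to every phase-known individual with offspring.
    Returns the interval table and the inheritance vectors (needed for the
    shuffling phenotype).
    """
    if fids is None:
        fids = [int(i) for i in ped.ids if i in haplotypes and ped.offspring_of(int(i))]
    geno = genotypes.to_numpy(dtype=int)
    intervals: list[CrossoverInterval] = []
    ivs: list[InheritanceVector] = []
    for fid in fids:
        fid = int(fid)
        for child in ped.offspring_of(fid):
            sire, dam = ped.parents(child)
            other = dam if sire == fid else sire
            if other == 0:
                continue
            off_row = geno[ped.row_of(child)]
            other_row = geno[ped.row_of(other)]
            for chrom in np.unique(panel.chrom):
                idx = panel.markers_on(int(chrom))
                iv = infer_inheritance(
                    haplotypes[fid][:, idx],
                    other_row[idx],
                    off_row[idx],
                    panel.bp[idx],
                    fid=fid,
                    offspring=child,
                    chrom=int(chrom),
                )
                ivs.append(iv)
                intervals.extend(call_crossovers(iv, min_support=min_support))
    return intervals_to_frame(intervals), ivs
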