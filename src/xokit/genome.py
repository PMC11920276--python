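"""Physical and genetic coordinate systems: chromosomes, centromeres, sex-specific maps.

Coordinates are 1-based inclusive base pairs (bp 0 is accepted as the left
terminus for map interpolation).  Genetic positions are chromosome-local
centiMorgans with origin 0 at the left terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

METACENTRIC = "metacentric"
ACROCENTRIC = "acrocentric"
SEXES = ("M", "F")


@dataclass(frozen=True)
class ChromosomeDef:
    """One autosome: physical length, centromere position, arm class."""

    index: int
    bp_length: int
    centromere_bp: int
    arm_class: str

    def __post_init__(self) -> None:
        if self.bp_length <= 0:
            raise ValueError(f"chromosome {self.index}: bp_length must be > 0")
        if self.arm_class not in (METACENTRIC, ACROCENTRIC):
            raise ValueError(f"chromosome {self.index}: unknown arm_class {self.arm_class!r}")
        if self.arm_class == METACENTRIC:
            if not (0 < self.centromere_bp < self.bp_length):
                raise ValueError(
                    f"chromosome {self.index}: metacentric centromere must be interior"
                )
        else:
            if self.centromere_bp not in (0, self.bp_length):
                raise ValueError(
                    f"chromosome {self.index}: acrocentric centromere must be at a terminus"
                )


class GeneticMap:
    """Sex-specific piecewise-linear bp<->cM maps, one anchor track per (chromosome, sex)."""

    def __init__(self) -> None:
        self._anchors: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}

    def set_anchors(self, chrom: int, sex: str, bp: Sequence[float], cM: Sequence[float]) -> None:
        bp_arr = np.asarray(bp, dtype=float)
        cm_arr = np.asarray(cM, dtype=float)
        if bp_arr.ndim != 1 or bp_arr.shape != cm_arr.shape or bp_arr.size < 2:
            raise ValueError("anchors must be two equal-length 1-d sequences of length >= 2")
        if not np.all(np.diff(bp_arr) > 0):
            raise ValueError(f"chromosome {chrom} sex {sex}: anchor bp not strictly increasing")
        if not np.all(np.diff(cm_arr) >= 0):
            raise ValueError(f"chromosome {chrom} sex {sex}: anchor cM decreasing")
        if cm_arr[0] != 0.0:
            raise ValueError(f"chromosome {chrom} sex {sex}: first anchor must be at 0 cM")
        self._anchors[(chrom, sex)] = (bp_arr, cm_arr)

    def anchors(self, chrom: int, sex: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self._anchors[(chrom, sex)]
        except KeyError:
            raise KeyError(f"no map for chromosome {chrom}, sex {sex}") from None

    def chromosomes(self) -> list[int]:
        return sorted({c for c, _ in self._anchors})

    def total_cM(self, chrom: int, sex: str) -> float:
        return float(self.anchors(chrom, sex)[1][-1])

    def bp_to_cM(self, chrom: int, sex: str, bp) -> np.ndarray | float:
        """Piecewise-linear interpolation of genetic position; exact at anchors."""
        bp_arr, cm_arr = self.anchors(chrom, sex)
        pos = np.asarray(bp, dtype=float)
        if np.any(pos < 0) or np.any(pos > bp_arr[-1]):
            raise ValueError(f"position out of range for chromosome {chrom}")
        out = np.interp(pos, bp_arr, cm_arr)
        return float(out) if np.isscalar(bp) else out

    def cM_to_bp(self, chrom: int, sex: str, cM) -> np.ndarray | float:
        """Inverse interpolation; flat map segments resolve to their right edge."""
        bp_arr, cm_arr = self.anchors(chrom, sex)
        pos = np.asarray(cM, dtype=float)
        if np.any(pos < 0) or np.any(pos > cm_arr[-1]):
            raise ValueError(f"cM position out of range for chromosome {chrom}")
        # np.interp on a non-decreasing x grid picks the left edge of ties;
        # reverse both tracks so ties resolve rightward instead.
        out = bp_arr[-1] - np.interp(cm_arr[-1] - pos, cm_arr[-1] - cm_arr[::-1], bp_arr[-1] - bp_arr[::-1])
        return float(out) if np.isscalar(cM) else out


@dataclass
class SnpPanel:
    """Marker coordinates: parallel arrays of chromosome index, bp position, id."""

    chrom: np.ndarray
    bp: np.ndarray
    ids: np.ndarray

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SnpPanel":
        return cls(
            chrom=df["chrom"].to_numpy(dtype=int),
            bp=df["bp"].to_numpy(dtype=np.int64),
            ids=df["id"].to_numpy(dtype=object),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "bp": self.bp, "id": self.ids})

    @property
    def n_markers(self) -> int:
        return int(self.chrom.size)

    def markers_on(self, chrom: int) -> np.ndarray:
        """Indices of markers on one chromosome, in panel order."""
        return np.flatnonzero(self.chrom == chrom)


def genome_fractions(chrom_defs: Sequence[ChromosomeDef]) -> np.ndarray:
    """Physical length of each chromosome as a fraction of total genome length."""
    if len(chrom_defs) == 0:
        raise ValueError("no chromosomes")
    lengths = np.array([c.bp_length for c in chrom_defs], dtype=float)
    return lengths / lengths.sum()


def validate_genome(
    chrom_defs: Sequence[ChromosomeDef],
    gmap: GeneticMap | None = None,
    panel: SnpPanel | None = None,
) -> list[str]:
    """Collect invariant violations; an empty list means the config is consistent."""
    violations: list[str] = []
    indices = [c.index for c in chrom_defs]
    if sorted(indices) != list(range(1, len(chrom_defs) + 1)):
        violations.append(f"chromosome indices not contiguous from 1: {sorted(indices)}")
    by_index = {c.index: c for c in chrom_defs}
    for c in chrom_defs:
        if c.arm_class == METACENTRIC and not (0 < c.centromere_bp < c.bp_length):
            violations.append(f"chromosome {c.index}: metacentric centromere not interior")
        if c.arm_class == ACROCENTRIC and c.centromere_bp not in (0, c.bp_length):
            violations.append(f"chromosome {c.index}: acrocentric centromere not terminal")
    if gmap is not None:
        for chrom in gmap.chromosomes():
            for sex in SEXES:
                try:
                    bp_arr, cm_arr = gmap.anchors(chrom, sex)
                except KeyError:
                    violations.append(f"chromosome {chrom}: missing map for sex {sex}")
                    continue
                if not np.all(np.diff(bp_arr) > 0):
                    violations.append(f"map chromosome {chrom} sex {sex}: bp anchors not increasing")
                if not np.all(np.diff(cm_arr) >= 0):
                    violations.append(f"map chromosome {chrom} sex {sex}: cM anchors decreasing")
                if cm_arr[0] != 0:
                    violations.append(f"map chromosome {chrom} sex {sex}: origin not at 0 cM")
                cdef = by_index.get(chrom)
                if cdef is not None and bp_arr[-1] > cdef.bp_length:
                    violations.append(
                        f"map chromosome {chrom} sex {sex}: anchor beyond chromosome end"
                    )
    if panel is not None:
        for chrom in np.unique(panel.chrom):
            idx = panel.markers_on(int(chrom))
            pos = panel.bp[idx]
            if np.any(np.diff(pos) <= 0):
                violations.append(f"panel chromosome {chrom}: positions not sorted/unique")
            cdef = by_index.get(int(chrom))
            if cdef is None:
                violations.append(f"panel chromosome {chrom}: unknown chromosome")
            else:
                for j in idx[pos > cdef.bp_length]:
                    violations.append(
                        f"marker {panel.ids[j]} at {panel.bp[j]} beyond end of chromosome {chrom}"
                    )
    return violations


def default_genome(
    n_autosomes: int = 18,
    n_metacentric: int = 12,
    longest_mb: float = 270.0,
    shortest_mb: float = 55.0,
    female_cm_per_mb: float = 1.10,
    male_cm_per_mb: float = 0.82,
    anchor_spacing_mb: float = 5.0,
) -> tuple[list[ChromosomeDef], GeneticMap]:
    """Pig-like synthetic genome: 18 autosomes, 1-12 metacentric, 13-18 acrocentric.

    Lengths taper linearly from ``longest_mb`` to ``shortest_mb``; maps are
    mildly non-uniform but strictly increasing, with female maps longer than
    male (heterochiasmy in the female direction, as in pig).
    """
    if not 0 <= n_metacentric <= n_autosomes:
        raise ValueError("n_metacentric out of range")
    lengths_mb = np.linspace(longest_mb, shortest_mb, n_autosomes)
    chrom_defs: list[ChromosomeDef] = []
    gmap = GeneticMap()
    for k in range(1, n_autosomes + 1):
        bp_len = int(round(lengths_mb[k - 1] * 1e6))
        if k <= n_metacentric:
            centro = int(round(bp_len * (0.35 + 0.02 * (k % 5))))
            arm = METACENTRIC
        else:
            centro = 0
            arm = ACROCENTRIC
        chrom_defs.append(ChromosomeDef(k, bp_len, centro, arm))
        n_anchors = max(3, int(round(lengths_mb[k - 1] / anchor_spacing_mb)) + 1)
        bp_anchors = np.linspace(0, bp_len, n_anchors)
        # smooth rate modulation (suppressed ends, enriched middle) kept > 0
        frac = bp_anchors / bp_len
        density = 1.0 + 0.5 * np.sin(np.pi * frac)
        seg = np.diff(bp_anchors) / 1e6 * 0.5 * (density[:-1] + density[1:])
        seg = seg / seg.sum()
        for sex, rate in (("F", female_cm_per_mb), ("M", male_cm_per_mb)):
            total_cm = rate * lengths_mb[k - 1]
            cm_anchors = np.concatenate([[0.0], np.cumsum(seg) * total_cm])
            gmap.set_anchors(k, sex, bp_anchors, cm_anchors)
    return chrom_defs, gmap


def uniform_panel(
    chrom_defs: Sequence[ChromosomeDef], spacing_bp: int = 1_000_000, offset_bp: int = 500_000
) -> SnpPanel:
    """Evenly spaced marker panel across all chromosomes."""
    chroms, bps, ids = [], [], []
    for c in chrom_defs:
        pos = np.arange(offset_bp, c.bp_length, spacing_bp, dtype=np.int64)
        chroms.append(np.full(pos.size, c.index))
        bps.append(pos)
        ids.extend(f"snp{c.index}_{i}" for i in range(pos.size))
    return SnpPanel(
        chrom=np.concatenate(chroms), bp=np.concatenate(bps), ids=np.array(ids, dtype=object)
    )
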