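"""Plain-TSV readers and writers for every pipeline table.

Dialect: tab-separated, '#'-prefixed ``key=value`` header comments, NA for
missing.  Writers are deterministic so that write(read(x)) is byte-identical
apart from header metadata.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .genome import ChromosomeDef, GeneticMap, SnpPanel
from .pedigree import Pedigree


class DataError(Exception):
    """Malformed input data (CLI exit code 2)."""


def _header_lines(meta: dict | None) -> str:
    lines = [f"# xokit={__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, na_rep="NA")
    path.write_text(_header_lines(meta) + buf.getvalue())


def read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], **kwargs)
    except pd.errors.ParserError as e:
        raise DataError(f"{path}: {e}") from None


def read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


# -- genome -----------------------------------------------------------------

def write_chromosomes(chrom_defs: Sequence[ChromosomeDef], path, meta=None) -> None:
    df = pd.DataFrame(
        [(c.index, c.bp_length, c.centromere_bp, c.arm_class) for c in chrom_defs],
        columns=["chrom", "bp_length", "centromere_bp", "arm_class"],
    )
    write_tsv(df, path, meta)


def read_chromosomes(path) -> list[ChromosomeDef]:
    df = read_tsv(path)
    try:
        return [
            ChromosomeDef(int(r.chrom), int(r.bp_length), int(r.centromere_bp), str(r.arm_class))
            for r in df.itertuples()
        ]
    except (ValueError, TypeError) as e:
        raise DataError(f"{path}: {e}") from None


def write_genetic_map(gmap: GeneticMap, path, meta=None) -> None:
    rows = []
    for chrom in gmap.chromosomes():
        for sex in ("M", "F"):
            try:
                bp, cm = gmap.anchors(chrom, sex)
            except KeyError:
                continue
            for b, c in zip(bp, cm):
                rows.append((chrom, sex, float(b), c))
    write_tsv(pd.DataFrame(rows, columns=["chrom", "sex", "bp", "cM"]), path, meta)


def read_genetic_map(path) -> GeneticMap:
    df = read_tsv(path)
    gmap = GeneticMap()
    for (chrom, sex), grp in df.groupby(["chrom", "sex"]):
        try:
            gmap.set_anchors(int(chrom), str(sex), grp["bp"].to_numpy(), grp["cM"].to_numpy())
        except ValueError as e:
            raise DataError(f"{path}: {e}") from None
    return gmap


def write_panel(panel: SnpPanel, path, meta=None) -> None:
    write_tsv(panel.to_frame(), path, meta)


def read_panel(path) -> SnpPanel:
    df = read_tsv(path)
    for col in ("chrom", "bp", "id"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    return SnpPanel.from_frame(df)


# -- pedigree and genotypes --------------------------------------------------

def write_pedigree(ped: Pedigree, path, meta=None) -> None:
    write_tsv(ped.df[["id", "sire", "dam", "sex"]], path, meta)


def read_pedigree(path) -> Pedigree:
    try:
        return Pedigree(read_tsv(path))
    except ValueError as e:
        raise DataError(f"{path}: {e}") from None


def write_genotypes(geno: pd.DataFrame, path, meta=None) -> None:
    out = geno.replace(-1, pd.NA).reset_index()
    write_tsv(out, path, meta)


def read_genotypes(path) -> pd.DataFrame:
    df = read_tsv(path)
    if "id" not in df.columns:
        raise DataError(f"{path}: missing 'id' column")
    df = df.set_index("id")
    vals = df.to_numpy(dtype=object)
    bad = pd.isna(vals) | np.isin(vals, [0, 1, 2])
    if not bad.all():
        r, c = np.argwhere(~bad)[0]
        n_header = sum(1 for line in open(path) if line.startswith("#"))
        raise DataError(
            f"{path}: invalid genotype {vals[r, c]!r} for marker {df.columns[c]} "
            f"at line {n_header + 2 + r} (expected 0/1/2/NA)"
        )
    out = df.fillna(-1).astype(np.int8)
    return out


def write_haplotypes(haps: dict[int, np.ndarray], marker_ids: Sequence, path, meta=None) -> None:
    rows = []
    for ind in sorted(haps):
        for h in (0, 1):
            rows.append([ind, "AB"[h], *haps[ind][h].tolist()])
    df = pd.DataFrame(rows, columns=["id", "hap", *list(marker_ids)])
    write_tsv(df, path, meta)


def read_haplotypes(path) -> dict[int, np.ndarray]:
    df = read_tsv(path)
    haps: dict[int, np.ndarray] = {}
    for ind, grp in df.groupby("id"):
        grp = grp.sort_values("hap")
        if list(grp["hap"]) != ["A", "B"]:
            raise DataError(f"{path}: individual {ind} needs exactly haplotypes A and B")
        haps[int(ind)] = grp.drop(columns=["id", "hap"]).to_numpy(dtype=np.int8)
    return haps


# -- crossover tables --------------------------------------------------------

XO_COLUMNS = ["chrom", "left_bp", "right_bp", "fid", "offspring", "midpoint_bp"]


def write_crossovers(df: pd.DataFrame, path, meta=None) -> None:
    write_tsv(df[XO_COLUMNS], path, meta)


def read_crossovers(path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = [c for c in XO_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    return df


def write_inheritance(ivs, path, meta=None) -> None:
    rows = []
    for iv in ivs:
        for bp, o in zip(iv.bp, iv.origin):
            rows.append((iv.fid, iv.offspring, iv.chrom, int(bp), "AB"[int(o)]))
    write_tsv(
        pd.DataFrame(rows, columns=["fid", "offspring", "chrom", "bp", "origin"]), path, meta
    )


def read_inheritance(path) -> list:
    from .calling import InheritanceVector

    df = read_tsv(path)
    out = []
    for (fid, off, chrom), grp in df.groupby(["fid", "offspring", "chrom"]):
        origin = grp["origin"].map({"A": 0, "B": 1})
        if origin.isna().any():
            raise DataError(f"{path}: origin codes must be A or B")
        out.append(
            InheritanceVector(
                fid=int(fid),
                offspring=int(off),
                chrom=int(chrom),
                bp=grp["bp"].to_numpy(np.int64),
                origin=origin.to_numpy(np.int8),
            )
        )
    return out


def write_truth_crossovers(truths, path, meta=None) -> None:
    rows = []
    for t in truths:
        for chrom in sorted(t.xo_bp):
            for bp, cm in zip(t.xo_bp[chrom], t.xo_cM[chrom]):
                rows.append((t.fid, t.offspring, t.sex, chrom, bp, cm))
    write_tsv(
        pd.DataFrame(rows, columns=["fid", "offspring", "sex", "chrom", "bp", "cM"]), path, meta
    )
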