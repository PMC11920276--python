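"""End-to-end driver: simulate -> call -> phenotype -> interference -> h2 -> gwas.

Each stage writes its outputs under the run directory and records itself in
``manifest.json`` (version, seed, parameters, input checksums).  Stages can
be toggled from the configuration; a disabled stage is marked skipped and
downstream stages that need its outputs fail with a stage-scoped error.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import tables
from .calling import call_pedigree, qc_genotypes
from .genome import default_genome, uniform_panel, validate_genome
from .interference import fit_per_fid
from .phenotypes import aggregate_fid, gamete_phenotypes, summarize_descriptives
from .quantgen import mlm_loco_gwas, reml_animal_model
from .simulate import simulate_gametes, simulate_pedigree
from .tables import DataError

STAGES = ("simulate", "call", "phenotype", "interference", "h2", "gwas")

DEFAULT_CONFIG = {
    "seed": 1,
    "genome": {"n_autosomes": 18, "n_metacentric": 12, "marker_spacing_bp": 2_000_000},
    "simulate": {
        "enabled": True,
        "nu": 8.0,
        "p_escape": 0.0,
        "n_sires": 4,
        "n_dams": 12,
        "offspring_per_pair": 6,
        "generations": 1,
        "genotyping_error_rate": 0.0,
        "missing_rate": 0.0,
    },
    "call": {"enabled": True, "min_support": 3, "maf_min": 0.01, "callrate_min": 0.95,
             "hwe_chi2_max": 600.0},
    "phenotype": {"enabled": True, "r_intra_weight": "markers"},
    "interference": {"enabled": True, "model": "stahl"},
    "h2": {"enabled": True, "phenotype": "crossover_count", "repeated": True},
    "gwas": {"enabled": True, "phenotype": "crossover_count", "covariates": []},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineError(DataError):
    """Stage-scoped pipeline failure."""


def run_pipeline(config: dict | None = None, out_dir="run", seed: int | None = None) -> dict:
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    meta = {"seed": cfg["seed"]}
    state: dict = {}

    def record(stage: str, status: str, outputs: list[str] = ()) -> None:
        manifest["stages"][stage] = {
            "status": status,
            "outputs": list(outputs),
            "checksums": {o: _checksum(out / o) for o in outputs if (out / o).exists()},
            "params": cfg.get(stage, {}),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    def require(stage: str, key: str):
        if key not in state:
            raise PipelineError(f"stage '{stage}' needs output of a skipped/failed upstream stage: {key}")
        return state[key]

    # genome is always materialised (cheap, needed by everything)
    gcfg = cfg["genome"]
    chrom_defs, gmap = default_genome(
        n_autosomes=gcfg["n_autosomes"], n_metacentric=gcfg["n_metacentric"]
    )
    panel = uniform_panel(chrom_defs, spacing_bp=gcfg["marker_spacing_bp"])
    problems = validate_genome(chrom_defs, gmap, panel)
    if problems:
        raise PipelineError(f"genome config invalid: {problems[:3]}")
    tables.write_chromosomes(chrom_defs, out / "genome.tsv", meta)
    tables.write_genetic_map(gmap, out / "map.tsv", meta)
    tables.write_panel(panel, out / "panel.tsv", meta)
    state.update(chrom_defs=chrom_defs, gmap=gmap, panel=panel)

    if cfg["simulate"]["enabled"]:
        s = cfg["simulate"]
        ped = simulate_pedigree(
            s["n_sires"], s["n_dams"], s["offspring_per_pair"], s["generations"], cfg["seed"]
        )
        geno, haps, truths = simulate_gametes(
            ped, chrom_defs, gmap, panel,
            nu=s["nu"], p_escape=s["p_escape"],
            genotyping_error_rate=s["genotyping_error_rate"],
            missing_rate=s["missing_rate"], seed=cfg["seed"] + 1,
        )
        tables.write_pedigree(ped, out / "pedigree.tsv", meta)
        tables.write_genotypes(geno, out / "genotypes.tsv", meta)
        tables.write_haplotypes(haps, panel.ids, out / "haplotypes.tsv", meta)
        tables.write_truth_crossovers(truths, out / "truth_crossovers.tsv", meta)
        state.update(ped=ped, geno=geno, haps=haps, truths=truths)
        record("simulate", "complete",
               ["pedigree.tsv", "genotypes.tsv", "haplotypes.tsv", "truth_crossovers.tsv"])
    else:
        record("simulate", "skipped")

    if cfg["call"]["enabled"]:
        c = cfg["call"]
        ped, geno, haps = require("call", "ped"), require("call", "geno"), require("call", "haps")
        _, qc_report = qc_genotypes(geno, c["maf_min"], c["callrate_min"], c["hwe_chi2_max"])
        xo, ivs = call_pedigree(ped, haps, geno, panel, min_support=c["min_support"])
        tables.write_tsv(qc_report, out / "qc_report.tsv", meta)
        tables.write_crossovers(xo, out / "crossovers.tsv", meta)
        tables.write_inheritance(ivs, out / "inheritance.tsv", meta)
        state.update(xo=xo, ivs=ivs)
        record("call", "complete", ["qc_report.tsv", "crossovers.tsv", "inheritance.tsv"])
    else:
        record("call", "skipped")

    sex_of = {}
    if "ped" in state:
        sex_of = {int(i): state["ped"].sex_of(int(i)) for i in state["ped"].ids}

    if cfg["phenotype"]["enabled"]:
        xo, ivs = require("phenotype", "xo"), require("phenotype", "ivs")
        gp = gamete_phenotypes(xo, ivs, chrom_defs, cfg["phenotype"]["r_intra_weight"])
        fp = aggregate_fid(gp, sex_of)
        tables.write_tsv(gp, out / "gamete_phenotypes.tsv", meta)
        tables.write_tsv(fp, out / "fid_phenotypes.tsv", meta)
        outputs = ["gamete_phenotypes.tsv", "fid_phenotypes.tsv"]
        if fp["sex"].nunique() == 2 and (fp.groupby("sex").size() >= 2).all():
            gp_sex = gp.assign(sex=gp["fid"].map(sex_of))
            desc = summarize_descriptives(gp_sex)
            for name, df in desc.items():
                tables.write_tsv(df, out / f"descriptives_{name}.tsv", meta)
                outputs.append(f"descriptives_{name}.tsv")
        state.update(gp=gp, fp=fp)
        record("phenotype", "complete", outputs)
    else:
        record("phenotype", "skipped")

    if cfg["interference"]["enabled"]:
        xo, gp = require("interference", "xo"), require("interference", "gp")
        fits = fit_per_fid(xo, gp[["fid", "offspring"]], gmap, sex_of,
                           model=cfg["interference"]["model"])
        tables.write_tsv(fits, out / "interference.tsv", meta)
        state.update(fits=fits)
        record("interference", "complete", ["interference.tsv"])
    else:
        record("interference", "skipped")

    if cfg["h2"]["enabled"]:
        gp, ped = require("h2", "gp"), require("h2", "ped")
        h = cfg["h2"]
        records = gp.rename(columns={h["phenotype"]: "y"})[["fid", "y"]].dropna()
        vc = reml_animal_model(records, ped, repeated=h["repeated"])
        (out / "h2.json").write_text(json.dumps(vc.as_dict(), indent=2))
        tables.write_tsv(pd.DataFrame([vc.as_dict()]), out / "h2.tsv", meta)
        state.update(vc=vc)
        record("h2", "complete", ["h2.tsv", "h2.json"])
    else:
        record("h2", "skipped")

    if cfg["gwas"]["enabled"]:
        fp, geno = require("gwas", "fp"), require("gwas", "geno")
        g = cfg["gwas"]
        pheno = fp.rename(columns={g["phenotype"]: "y"})[["fid", "y", *g["covariates"]]].dropna()
        res = mlm_loco_gwas(pheno, geno, panel, covariates=g["covariates"])
        tables.write_tsv(res, out / "gwas.tsv", meta)
        state.update(gwas=res)
        record("gwas", "complete", ["gwas.tsv"])
    else:
        record("gwas", "skipped")

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
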