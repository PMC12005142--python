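"""End-to-end orchestration: simulate -> GL -> filters -> SFS -> scan -> structure.

A single YAML config drives every stage; unknown keys are rejected before
anything runs, a resolved copy of the config is written next to the outputs,
and one master seed fans out to per-stage child seeds through a fixed
derivation so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gl as glmod
from . import scan as scanmod
from . import sfs as sfsmod
from . import sitefilters as filtmod
from . import structure as structmod
from .simdata import SimulationConfig, Sweep, simulate_dataset

logger = logging.getLogger("pbscan")

_DEFAULTS = {
    "seed": 0,
    "log_level": "INFO",
    "simulate": {
        "n_sites": 5000,
        "chrom_length": 5_000_000,
        "n_individuals": [33, 25, 25],
        "drift": [0.068, 0.020, 0.012],
        "mean_depth": 2.0,
        "error_rate": 0.01,
        "maf_floor": 0.05,
        "sweep": None,  # {population, start, end, delta}
        "chrom": "1",
    },
    "input": {"beagle": None, "populations": None},
    "gl": {"min_base_quality": 20, "maf_threshold": 0.05},
    "filters": {
        "enabled": True,
        "min_individuals": 10,
        "min_depth": 1,
        "het_p": 1e-6,
        "strand_p": 1e-4,
    },
    "sfs": {"tol": 1e-6, "max_iter": 200},
    "scan": {
        "window": 50_000,
        "step": 10_000,
        "min_sites": 10,
        "top_fraction": 0.001,
        "min_windows": 6,
        "merge_distance": 1_000_000,
        "focal": 0,
    },
    "structure": {"K": 3, "n_restarts": 3, "max_iter": 1000, "tol": 1e-6},
}

# fixed stage-seed derivation: child index per stage
_STAGE_SEED = {"simulate": 0, "structure": 1}


def _merge_config(user: dict) -> dict:
    cfg = {}
    for key, default in _DEFAULTS.items():
        if isinstance(default, dict):
            block = dict(default)
            user_block = user.get(key, {}) or {}
            unknown = set(user_block) - set(default)
            if unknown:
                raise ValueError(f"unknown config keys in '{key}': {sorted(unknown)}")
            block.update(user_block)
            cfg[key] = block
        else:
            cfg[key] = user.get(key, default)
    unknown = set(user) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge_config(user)


def _stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(master).spawn(max(_STAGE_SEED.values()) + 1)[
        _STAGE_SEED[stage]
    ]


def run_pipeline(config: dict, outdir) -> Path:
    """Run every stage and persist stage outputs under ``outdir``.

    ``config`` may be a partial dict (merged over defaults) that has already
    passed :func:`_merge_config`, or a raw user dict.
    """
    cfg = _merge_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg["log_level"])
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)

    master_seed = int(cfg["seed"])

    # --- stage 1: data (simulate or ingest) --------------------------------
    if cfg["input"]["beagle"]:
        table = glmod.read_beagle(cfg["input"]["beagle"])
        pops = cfg["input"]["populations"]
        if not pops:
            raise ValueError("ingesting a Beagle file requires input.populations")
        pop_indices = {name: list(idx) for name, idx in pops.items()}
        truth = None
        logger.info("ingested %d sites x %d individuals", table.n_sites, table.n_individuals)
    else:
        sim = dict(cfg["simulate"])
        sweep = sim.pop("sweep")
        sim_cfg = SimulationConfig(
            **sim,
            sweep=Sweep(**sweep) if sweep else None,
            seed=int(np.random.default_rng(_stage_seed(master_seed, "simulate")).integers(2**31)),
        )
        truth, pileup = simulate_dataset(sim_cfg)
        table = glmod.compute_gl_table(pileup, cfg["gl"]["min_base_quality"])
        pop_indices = {
            f"pop{k}": list(range(truth.pop_slice(k).start, truth.pop_slice(k).stop))
            for k in range(sim_cfg.n_pops)
        }
        logger.info("simulated %d sites, %d individuals", table.n_sites, table.n_individuals)

        # --- stage 2: site filters ----------------------------------------
        if cfg["filters"]["enabled"]:
            fcfg = filtmod.FilterConfig(
                min_individuals=cfg["filters"]["min_individuals"],
                min_depth=cfg["filters"]["min_depth"],
                het_p=cfg["filters"]["het_p"],
                strand_p=cfg["filters"]["strand_p"],
                min_base_quality=cfg["gl"]["min_base_quality"],
            )
            report = filtmod.apply_filters(pileup, table, fcfg)
            report.to_csv(out / "site_filters.tsv", sep="\t", index=False)
            keep = report["pass"].to_numpy()
            logger.info(
                "site filters: %d/%d pass (coverage %d, het %d, strand %d removed)",
                keep.sum(), len(keep),
                (~report["pass_coverage"]).sum(),
                (~report["pass_het"]).sum(),
                (~report["pass_strand"]).sum(),
            )
            table = table.subset_sites(keep)
        if truth is not None:
            truth.sites_frame().to_csv(out / "truth_sites.tsv", sep="\t", index=False)
            pd.DataFrame(truth.true_Q).to_csv(out / "truth_Q.tsv", sep="\t", index=False)

    glmod.write_beagle(table, out / "genolike.beagle")

    # --- stage 3: MAF ------------------------------------------------------
    maf = glmod.estimate_maf_table(table)
    pd.DataFrame(
        {"chrom": table.sites["chrom"], "pos": table.sites["pos"], "maf": maf}
    ).to_csv(out / "maf.tsv", sep="\t", index=False)

    # --- stage 4: SAF + 2D-SFS + FST components ---------------------------
    names = list(pop_indices)
    if len(names) < 3:
        raise ValueError("the scan needs three populations")
    focal = int(cfg["scan"]["focal"])
    i, j, k = focal, *(x for x in range(3) if x != focal)
    safs = {n: sfsmod.saf_table(table.subset_individuals(pop_indices[n]).gl) for n in names}
    n_dip = {n: len(pop_indices[n]) for n in names}

    comps = {}
    fst_genome = {}
    for key, (x, y) in {"ij": (i, j), "ik": (i, k), "jk": (j, k)}.items():
        nx, ny = names[x], names[y]
        sfs2 = sfsmod.estimate_sfs_em(
            safs[nx], safs[ny], tol=cfg["sfs"]["tol"], max_iter=cfg["sfs"]["max_iter"]
        )
        a, d = scanmod.fst_site_components(
            safs[nx], safs[ny], sfs2.eta, n_dip[nx], n_dip[ny]
        )
        comps[key] = (a, d)
        fst_genome[f"{nx}-{ny}"] = scanmod.genome_fst(a, d)
        logger.info("2D-SFS %s-%s: %d EM iterations, loglik %.2f", nx, ny, sfs2.n_iter, sfs2.loglik)
    with open(out / "fst_genome.json", "w") as fh:
        json.dump(fst_genome, fh, indent=1)
    logger.info("genome-wide FST: %s", fst_genome)

    # --- stage 5: sliding scan + peaks -------------------------------------
    chrom = str(table.sites["chrom"].iloc[0])
    chrom_length = cfg["simulate"]["chrom_length"] if truth is not None else None
    windows = scanmod.sliding_scan(
        table.sites["pos"].to_numpy(),
        comps,
        window=cfg["scan"]["window"],
        step=cfg["scan"]["step"],
        chrom=chrom,
        chrom_length=chrom_length,
        min_sites=cfg["scan"]["min_sites"],
    )
    windows.to_csv(out / "windows.tsv", sep="\t", index=False, float_format="%.6g")
    peaks = scanmod.call_peaks(
        windows,
        top_fraction=cfg["scan"]["top_fraction"],
        min_windows=cfg["scan"]["min_windows"],
        merge_distance=cfg["scan"]["merge_distance"],
    )
    scanmod.peaks_frame(peaks).to_csv(out / "peaks.tsv", sep="\t", index=False)
    logger.info("%d candidate peaks", len(peaks))

    # --- stage 6: structure -------------------------------------------------
    struct_table = glmod.filter_maf(table, cfg["gl"]["maf_threshold"], maf=maf)
    struct_seed = int(
        np.random.default_rng(_stage_seed(master_seed, "structure")).integers(2**31)
    )
    model = structmod.admixture_em(
        struct_table,
        K=cfg["structure"]["K"],
        max_iter=cfg["structure"]["max_iter"],
        tol=cfg["structure"]["tol"],
        n_restarts=cfg["structure"]["n_restarts"],
        seed=struct_seed,
    )
    pd.DataFrame(model.Q).to_csv(out / "admixture_Q.tsv", sep="\t", index=False, float_format="%.6g")
    pca = structmod.pca_covariance(struct_table, maf=None)
    pd.DataFrame(pca.C).to_csv(out / "pca_covariance.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        pca.eigenvectors[:, :3], columns=["PC1", "PC2", "PC3"]
    ).to_csv(out / "pca_vectors.tsv", sep="\t", index=False, float_format="%.6g")
    logger.info("admixture loglik %.2f (restart %d)", model.loglik, model.restart_id)
    return out
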