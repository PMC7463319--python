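"""Pipeline orchestration: run the full analysis from one configuration.

A run is described by a small key-value configuration (YAML on disk or a
plain dict): input genotype file (or a synthetic demo dataset), stage
toggles, per-stage parameters, a master seed and an output directory.
Stages execute in a fixed order — dedup, stats, fst, ibd, bottleneck,
simulate, niche — each writing delimiter-separated outputs; a manifest
records inputs, parameters, the seed, the package version and a content
digest of every output file.  Per-stage seeds are derived deterministically
from the master seed, so a rerun with the same configuration reproduces
stochastic stages exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bottleneck import MutationModelSpec, het_excess_test
from .diversity import diversity_summary, ibd_test, pairwise_fst, wc_fstatistics
from .drift import SimConfig, found_panmictic, half_life, simulate_constant_n
from .genotypes import dedup_clones, find_clones, read_genepop, read_site_table
from .niche import delta_csi_table, load_site_suitability
from .synthetic import MetapopSpec, generate_metapopulation, study_spectra

log = logging.getLogger("fragdrift.pipeline")

DEFAULTS: dict = {
    "seed": 1,
    "outdir": "fragdrift_run",
    "input": None,  # GenePop path; None -> synthetic demo metapopulation
    "sites": None,  # site table path for IBD
    "stages": {
        "dedup": True,
        "stats": True,
        "fst": True,
        "ibd": False,
        "bottleneck": False,
        "simulate": True,
        "niche": True,
    },
    "fst_permutations": 200,
    "ibd_permutations": 1000,
    "bottleneck_model": "IAM",
    "bottleneck_iterations": 200,
    "simulate_n": [20, 100],
    "generations": 200,
    "replicates": 100,
    "ci": 0.95,
    "demo": {"n_pops": 4, "n_per_pop": 25, "fst": 0.14, "n_loci": 5,
             "mean_alleles": 5.0, "he": 0.6},
}


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULTS))
    for k, v in user.items():
        if k == "stages" and isinstance(v, dict):
            cfg["stages"].update(v)
        else:
            cfg[k] = v
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured stages; returns the manifest (also written).

    Any stage failure halts the run with the stage name in the raised
    error; outputs of completed stages are retained.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else {
        **json.loads(json.dumps(DEFAULTS)),
        **{k: v for k, v in config.items() if k != "stages"},
    }
    if isinstance(config, dict) and "stages" in config:
        cfg["stages"] = {**DEFAULTS["stages"], **config["stages"]}
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "stages": [],
        "outputs": {},
    }

    def emit(name: str, df, **to_csv_kw) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", **to_csv_kw)
        manifest["outputs"][name] = _digest(path)

    def stage(name: str):
        enabled = cfg["stages"].get(name, False)
        if enabled:
            log.info("stage %-10s start seed=%d", name, _stage_seed(seed, name))
        return enabled

    t_start = time.time()
    try:
        if cfg["input"]:
            g = read_genepop(cfg["input"])
        else:
            demo = cfg["demo"]
            spectra = study_spectra(
                demo["n_loci"], demo["mean_alleles"], demo["he"],
                seed=_stage_seed(seed, "demo"),
            )
            g = generate_metapopulation(
                MetapopSpec(
                    n_pops=demo["n_pops"],
                    n_per_pop=demo["n_per_pop"],
                    fst=demo["fst"],
                    spectra=tuple(map(tuple, spectra)),
                    seed=_stage_seed(seed, "demo-geno"),
                )
            )

        if stage("dedup"):
            groups = [grp for grp in find_clones(g) if len(grp) > 1]
            report = [
                {
                    "group": i + 1,
                    "size": len(grp),
                    "members": ";".join(g.ids[j] for j in grp),
                }
                for i, grp in enumerate(groups)
            ]
            g = dedup_clones(g)
            import pandas as pd

            emit("clones.tsv", pd.DataFrame(report, columns=["group", "size", "members"]), index=False)
            manifest["stages"].append("dedup")

        if stage("stats"):
            summ = diversity_summary(g)
            emit("diversity.tsv", summ.table)
            manifest["stages"].append("stats")

        fst_matrix = None
        if stage("fst"):
            res = wc_fstatistics(g, seed=_stage_seed(seed, "fst"))
            import pandas as pd

            emit(
                "fst_global.tsv",
                pd.DataFrame(
                    [{"theta": res.theta, "ci_low": res.ci_low,
                      "ci_high": res.ci_high, "fis": res.fis}]
                ),
                index=False,
            )
            fst_matrix, p_matrix = pairwise_fst(
                g, permutations=int(cfg["fst_permutations"]),
                seed=_stage_seed(seed, "fst-pairs"),
            )
            emit("fst_pairwise.tsv", fst_matrix)
            emit("fst_pairwise_p.tsv", p_matrix)
            manifest["stages"].append("fst")

        if stage("ibd"):
            if fst_matrix is None or not cfg["sites"]:
                raise RuntimeError("ibd stage requires fst stage and a site table")
            sites = read_site_table(cfg["sites"])
            res = ibd_test(
                fst_matrix, sites, permutations=int(cfg["ibd_permutations"]),
                seed=_stage_seed(seed, "ibd"),
            )
            import pandas as pd

            emit("ibd.tsv", pd.DataFrame([res.__dict__]), index=False)
            manifest["stages"].append("ibd")

        if stage("bottleneck"):
            spec = MutationModelSpec(
                model=cfg["bottleneck_model"],
                iterations=int(cfg["bottleneck_iterations"]),
            )
            table, _ = het_excess_test(g, spec, seed=_stage_seed(seed, "bottleneck"))
            emit("bottleneck.tsv", table)
            manifest["stages"].append("bottleneck")

        if stage("simulate"):
            pool = found_panmictic(g, seed=_stage_seed(seed, "found"))
            for n in cfg["simulate_n"]:
                traj = simulate_constant_n(
                    pool,
                    SimConfig(
                        n=int(n),
                        generations=int(cfg["generations"]),
                        replicates=int(cfg["replicates"]),
                        ci=float(cfg["ci"]),
                        seed=_stage_seed(seed, f"sim-{n}"),
                    ),
                )
                summary = traj.summary("he").merge(
                    traj.summary("alleles"),
                    on="generation",
                    suffixes=("_he", "_alleles"),
                )
                summary["half_life_he"] = half_life(traj, "he")
                summary["half_life_alleles"] = half_life(traj, "alleles")
                emit(f"simulation_n{n}.tsv", summary, index=False)
            manifest["stages"].append("simulate")

        if stage("niche"):
            table = load_site_suitability().rename(columns=str)
            emit("delta_csi.tsv", delta_csi_table(table), index=False)
            manifest["stages"].append("niche")
    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline halted: {err}") from err

    manifest["wall_time_s"] = round(time.time() - t_start, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
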