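"""One-shot orchestration: simulate (or load) -> scan -> stability -> epistasis.

A pipeline run is fully described by a config mapping (usually loaded from
YAML) plus a master seed; every output is reproducible bit-identically from
that pair.  Per-stage seeds are fanned out deterministically from the master
seed so stages can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import time
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import dataio, epistasis as epi, pairscan, simdata, stability as stab

__all__ = ["load_config", "validate_config", "run_pipeline", "demo_config_path"]


def demo_config_path() -> Path:
    """Path of the packaged demo configuration."""
    with resources.as_file(
        resources.files("episcan.data").joinpath("demo_config.yaml")
    ) as p:
        return Path(p)


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: Mapping[str, Any]) -> None:
    if "seed" not in cfg:
        raise ValueError("config must set a master 'seed'")
    has_sim = "simulate" in cfg
    has_inputs = "inputs" in cfg
    if has_sim == has_inputs:
        raise ValueError("config must contain exactly one of 'simulate' or 'inputs'")
    if has_sim:
        sim = cfg["simulate"]
        for key in ("n_lines", "map", "environments", "grand_mean"):
            if key not in sim:
                raise ValueError(f"simulate block missing {key!r}")
    else:
        inputs = cfg["inputs"]
        for key in ("genotypes", "phenotypes"):
            if key not in inputs:
                raise ValueError(f"inputs block missing {key!r}")


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    geno, pheno, scan = (int(s) % (2**31) for s in ss.generate_state(3))
    return {"genotypes": geno, "phenotypes": pheno, "scan": scan}


def _config_hash(cfg: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _build_architecture(sim: Mapping[str, Any]) -> simdata.TraitArchitecture:
    return simdata.TraitArchitecture(
        grand_mean=float(sim["grand_mean"]),
        additive_effects=[(d["marker"], float(d["a"])) for d in sim.get("additive", [])],
        epistatic_pairs=[
            (d["marker_a"], d["marker_b"], float(d["w"]))
            for d in sim.get("epistatic", [])
        ],
        environment_effects=list((sim.get("env_shifts") or {}).items()),
        residual_sd=float(sim.get("residual_sd", 0.5)),
        env_residual_sd=sim.get("env_residual_sd"),
        het_rate=float(sim.get("het_rate", 0.002)),
        missing_rate=float(sim.get("missing_rate", 0.0)),
    )


def _simulate_stage(
    sim: Mapping[str, Any], seeds: dict[str, int], out: Path
) -> tuple[simdata.RILPopulation, list[simdata.PhenotypeSet], list[Path]]:
    geom = sim["map"]
    linkage_map = simdata.default_map(
        int(geom["n_markers"]), int(geom["n_groups"]), float(geom["length_cm"])
    )
    arch = _build_architecture(sim)
    pop = simdata.simulate_ril_genotypes(
        linkage_map,
        int(sim["n_lines"]),
        seed=seeds["genotypes"],
        het_rate=arch.het_rate,
        missing_rate=arch.missing_rate,
    )
    phenos = simdata.simulate_phenotypes(
        pop, arch, list(sim["environments"]), seed=seeds["phenotypes"]
    )
    files = []
    dataio.write_map(linkage_map, out / "map.tsv")
    dataio.write_genotypes(pop, out / "genotypes.tsv")
    files += [out / "map.tsv", out / "genotypes.tsv"]
    for p in phenos:
        path = out / f"pheno_{p.env_id}.tsv"
        dataio.write_phenotypes(p, path)
        files.append(path)
    truth = out / "truth.json"
    truth.write_text(
        json.dumps(
            {
                "grand_mean": arch.grand_mean,
                "additive_effects": list(arch.additive_effects),
                "epistatic_pairs": list(arch.epistatic_pairs),
                "environment_effects": list(arch.environment_effects),
                "residual_sd": arch.residual_sd,
                "het_rate": arch.het_rate,
                "missing_rate": arch.missing_rate,
            },
            indent=2,
        )
    )
    files.append(truth)
    return pop, phenos, files


def _load_stage(
    inputs: Mapping[str, Any]
) -> tuple[simdata.RILPopulation, list[simdata.PhenotypeSet]]:
    pop = dataio.read_genotypes(inputs["genotypes"])
    phenos = [dataio.read_phenotypes(p) for p in inputs["phenotypes"]]
    return pop, phenos


def run_pipeline(cfg: Mapping[str, Any], out_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute all stages and return the run manifest.

    The manifest records the seed, a config hash, every file written, the
    per-environment significant-pair counts, and the stability and
    epistasis histograms.
    """
    validate_config(cfg)
    t0 = time.monotonic()
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "episcan_out"))
    out.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    seeds = _stage_seeds(master)
    files: list[Path] = []

    if "simulate" in cfg:
        pop, phenos, sim_files = _simulate_stage(cfg["simulate"], seeds, out)
        files += sim_files
    else:
        pop, phenos = _load_stage(cfg["inputs"])

    scan_cfg_map = dict(cfg.get("scan", {}))
    scan_cfg = pairscan.ScanConfig(seed=seeds["scan"], **scan_cfg_map)
    scan_df, counts = pairscan.scan_all(pop, phenos, scan_cfg)
    for env, group in scan_df.groupby("env_id"):
        path = out / f"scan_{env}.tsv"
        dataio.write_results(group, path)
        files.append(path)
    counts_df = pd.DataFrame(
        {"env_id": list(counts), "n_pairs": [counts[e] for e in counts]}
    )
    dataio.write_results(counts_df, out / "counts.tsv")
    files.append(out / "counts.tsv")

    available = sum(1 for v in counts.values() if v)
    manifest: dict[str, Any] = {
        "seed": master,
        "stage_seeds": seeds,
        "config_hash": _config_hash(cfg),
        "env_counts": counts,
        "n_scan_records": int(len(scan_df)),
    }

    if available == 0:
        manifest.update(
            {
                "stability_histogram": {},
                "n_stable_pairs": 0,
                "epistasis_histogram": {},
                "files": [str(f) for f in files],
            }
        )
    else:
        records = stab.aggregate_stability(scan_df, available)
        stab_block = cfg.get("stability", {})
        stable = stab.select_stable(
            records,
            min_envs=stab_block.get("min_envs"),
            preset=stab_block.get("preset", "half"),
        )
        dataio.write_results(stab.records_to_frame(stable), out / "stability.tsv")
        hist = stab.stability_histogram(records)
        dataio.write_results(
            pd.DataFrame(
                {"env_count": list(hist), "n_pairs": list(hist.values())}
            ),
            out / "stability_histogram.tsv",
        )
        files += [out / "stability.tsv", out / "stability_histogram.tsv"]
        manifest["stability_histogram"] = hist
        manifest["n_stable_pairs"] = len(stable)

        if stable:
            alpha2 = float(cfg.get("epistasis", {}).get("alpha2", 0.01))
            epi_records, epi_hist = epi.epistasis_report(stable, phenos, pop, alpha2)
            dataio.write_results(epi.records_to_frame(epi_records), out / "epistasis.tsv")
            files.append(out / "epistasis.tsv")
            manifest["epistasis_histogram"] = epi_hist
        else:
            manifest["epistasis_histogram"] = {}
        manifest["files"] = [str(f) for f in files]

    manifest["runtime_s"] = round(time.monotonic() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
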