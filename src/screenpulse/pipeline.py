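"""End-to-end workflows wiring the analysis stages together.

``run_genomewide`` executes: control-guide normalization → per-replicate
negative-binomial β fits → per-replicate differential β → replicate
averaging → mean±kσ per-day calling → high-fidelity filtering →
trajectory clustering, writing plain TSV outputs plus a JSON run manifest
(input hashes, parameters, package version, collected warnings).

``run_tiling`` executes the tiling workflow: survival rates plus
domain-as-gene β.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigError, ConsistencyError
from .counts import read_counts, read_library, read_design, size_factors_control
from .beta import BetaTable, cellcycle_normalize, fit_screen
from .domain import domain_beta, survival_rates
from .hits import (average_replicates, cluster_trajectories,
                   differential_beta_from_table, high_fidelity_hits,
                   select_hits)

__all__ = ["RunConfig", "run_genomewide", "run_tiling"]


@dataclass
class RunConfig:
    """Parameters of a pipeline run; defaults match the study design the
    package targets (2σ calling, 2-of-{6,8,10} high fidelity, 6 clusters)."""

    counts: str
    library: str
    outdir: str
    design: str | None = None
    treat: str = "DAC"
    control: str = "DMSO"
    k_sigma: float = 2.0
    hf_days: tuple[int, ...] = (6, 8, 10)
    min_days: int = 2
    n_clusters: int = 6
    cellcycle: bool = False
    cellcycle_reference: str | None = None
    per_replicate: bool = True
    tiling_days: tuple[int, ...] = (2, 4, 6)
    pseudocount: float = 0.5


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, cfg: RunConfig, stages: dict,
                    caught: list[str], outputs: list[str]) -> None:
    manifest = {
        "screenpulse_version": __version__,
        "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(cfg).items()},
        "inputs": {name: _sha256(p) for name, p in
                   (("counts", cfg.counts), ("library", cfg.library),
                    ("design", cfg.design)) if p},
        "outputs": outputs,
        "stage_seconds": stages,
        "warnings": caught,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_genomewide(cfg: RunConfig) -> dict[str, Path]:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        t0 = time.perf_counter()
        library = read_library(cfg.library)
        cm = read_counts(cfg.counts, library)
        design = read_design(cfg.design) if cfg.design else None
        stages["load"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        ntc = [i for i in library.ntc_ids if i in cm.counts.index]
        sf = size_factors_control(cm, ntc if ntc else list(cm.counts.index))
        stages["normalize"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        fits = fit_screen(cm, library, design, per_replicate=cfg.per_replicate,
                          size_factors=sf)
        if not cfg.per_replicate:
            fits = {0: fits}
        if cfg.cellcycle:
            ref = None
            if cfg.cellcycle_reference:
                ref = [l.strip() for l in open(cfg.cellcycle_reference)
                       if l.strip()]
            fits = {r: cellcycle_normalize(bt, ref) for r, bt in fits.items()}
        stages["mle"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        beta_long = pd.concat(
            [bt.table.assign(replicate=r) for r, bt in fits.items()],
            ignore_index=True)
        diffs = {r: differential_beta_from_table(bt, cfg.treat, cfg.control)
                 for r, bt in fits.items()}
        avg = average_replicates(list(diffs.values()))
        hits = high_fidelity_hits(select_hits(avg, cfg.k_sigma),
                                  days=cfg.hf_days, min_days=cfg.min_days)
        stages["hits"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        hf_genes = hits.flags.index[hits.flags["hf_pos"] | hits.flags["hf_neg"]]
        clusters = None
        if len(hf_genes) >= cfg.n_clusters:
            clusters = cluster_trajectories(avg.loc[hf_genes], k=cfg.n_clusters)
        else:
            warnings.warn(f"only {len(hf_genes)} high-fidelity genes; "
                          f"clustering skipped (k={cfg.n_clusters})")
        stages["cluster"] = time.perf_counter() - t0
        caught = [str(w.message) for w in wlist]

    paths = {"beta": outdir / "beta.tsv", "diff": outdir / "diff.tsv",
             "hits": outdir / "hits.tsv", "thresholds": outdir / "thresholds.tsv"}
    beta_long.to_csv(paths["beta"], sep="\t", index=False)
    diff_long = pd.concat(
        [d.rename_axis("gene").reset_index()
          .melt(id_vars="gene", var_name="day", value_name="diff_beta")
          .assign(replicate=r)
         for r, d in diffs.items()] +
        [avg.rename_axis("gene").reset_index()
         .melt(id_vars="gene", var_name="day", value_name="diff_beta")
         .assign(replicate="avg")],
        ignore_index=True)
    diff_long.to_csv(paths["diff"], sep="\t", index=False)
    hits.to_tsv(paths["hits"])
    hits.thresholds_to_tsv(paths["thresholds"])
    if clusters is not None:
        paths["clusters"] = outdir / "clusters.tsv"
        clusters.to_tsv(paths["clusters"])

    _write_manifest(outdir, cfg, stages, caught, [p.name for p in paths.values()])
    return paths


def run_tiling(cfg: RunConfig) -> dict[str, Path]:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        t0 = time.perf_counter()
        library = read_library(cfg.library)
        cm = read_counts(cfg.counts, library)
        design = read_design(cfg.design) if cfg.design else None
        stages["load"] = time.perf_counter() - t0

        if not library.ntc_ids:
            raise ConfigError("tiling workflow requires non-targeting controls "
                              "for survival-rate normalization")
        t0 = time.perf_counter()
        surv = survival_rates(cm, library, days=list(cfg.tiling_days),
                              treat=cfg.treat, control=cfg.control,
                              pseudocount=cfg.pseudocount)
        stages["survival"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        fits = domain_beta(cm, library, design, per_replicate=cfg.per_replicate)
        if not cfg.per_replicate:
            fits = {0: fits}
        beta_long = pd.concat(
            [bt.table.assign(replicate=r) for r, bt in fits.items()],
            ignore_index=True)
        stages["domain_beta"] = time.perf_counter() - t0
        caught = [str(w.message) for w in wlist]

    paths = {"survival": outdir / "surv.tsv",
             "domain_beta": outdir / "domain_beta.tsv"}
    surv.to_csv(paths["survival"], sep="\t", index=False)
    beta_long.to_csv(paths["domain_beta"], sep="\t", index=False)
    _write_manifest(outdir, cfg, stages, caught, [p.name for p in paths.values()])
    return paths
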