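"""End-to-end orchestration: simulate or ingest, then run the analyses.

A RunConfig (typically loaded from YAML) selects the data source
(simulation parameters or file paths), the stages to run, and the
permutation settings.  Every stochastic step derives from the single seed
in the config, so re-running the same config reproduces all outputs
bit-for-bit; a provenance manifest (parameters, seeds, package version,
input digests, output list) is written next to the results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clusters import build_adjacency, cluster_permutation_test
from .experience import (pairwise_contrasts, pc_association, phenomenology_pca,
                         proportion_tests)
from .glme import BRAIN, ModelSpec
from .io import (read_awakening_table, read_band_table, read_coordinates,
                 write_awakening_table, write_band_table, write_cluster_table,
                 write_coordinates)
from .spectral import extract_features
from .synthetic import CohortDataset, SimConfig, generate_cohort
from .timecourse import estimate_peak, fit_trend, measure_by_time_interaction

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger("dreamdepth")

ALL_STAGES = ("features", "clusters", "contrasts", "pca", "timecourse")


@dataclass
class RunConfig:
    """One pipeline run: inputs, stage roster, permutation settings."""

    output_dir: str = "dreamdepth_out"
    seed: int = 0
    # simulate mode (used when no input paths are given)
    sim: dict = field(default_factory=dict)
    # file mode
    awakening_csv: str | None = None
    coordinates_csv: str | None = None
    band_csvs: dict[str, str] = field(default_factory=dict)
    # analysis settings
    stages: tuple[str, ...] = ALL_STAGES
    bands: tuple[str, ...] = ("delta", "gamma", "ratio")
    cluster_outcomes: tuple[str, ...] = ("sleep_depth",)
    n_permutations: int = 5000
    alpha: float = 0.05
    p_thresh: float = 0.005
    min_cluster_size: int = 3
    adjacency_method: str = "delaunay"

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.awakening_csv is not None:
            for p in (self.awakening_csv, self.coordinates_csv,
                      *self.band_csvs.values()):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("stages", "bands", "cluster_outcomes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_or_simulate(cfg: RunConfig):
    if cfg.awakening_csv is not None:
        records = read_awakening_table(cfg.awakening_csv)
        sensors = read_coordinates(cfg.coordinates_csv)
        features = {}
        for band, path in cfg.band_csvs.items():
            features[band], _ = read_band_table(path)
        dataset = CohortDataset(sensors, records, features)
        return dataset, "files"
    sim = SimConfig(**{**cfg.sim, "seed": cfg.seed})
    return generate_cohort(sim), "simulation"


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; returns the result bundle.

    Results are also written under ``cfg.output_dir`` together with a
    ``manifest.json`` from which the run can be reproduced exactly.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    outputs: list[str] = []

    def _save_csv(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, float_format="%.10g", **kw)
        outputs.append(name)

    t0 = _time.perf_counter()
    dataset, source = _load_or_simulate(cfg)
    bundle["dataset"] = dataset
    log.info("stage data (%s): %d records, %d channels [%.1fs]", source,
             len(dataset.records), len(dataset.sensors),
             _time.perf_counter() - t0)
    write_awakening_table(dataset.records, out / "awakenings.csv")
    write_coordinates(dataset.sensors, out / "electrodes.csv")
    outputs += ["awakenings.csv", "electrodes.csv"]
    if source == "simulation" and dataset.truth is not None:
        truth = dataclasses.asdict(dataset.truth.config)
        (out / "truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True,
                       default=lambda o: o.tolist() if hasattr(o, "tolist")
                       else str(o))
        )
        outputs.append("truth.json")

    if "features" in cfg.stages and dataset.segments:
        t0 = _time.perf_counter()
        dataset.features = extract_features(dataset)
        log.info("stage features: extracted from %d segments [%.1fs]",
                 len(dataset.segments), _time.perf_counter() - t0)
    for band in cfg.bands:
        if band in dataset.features:
            write_band_table(
                dataset.features[band], out / f"bandpower_{band}.csv",
                {"band": band, "log": "natural"},
            )
            outputs.append(f"bandpower_{band}.csv")

    records = dataset.records

    if "clusters" in cfg.stages:
        t0 = _time.perf_counter()
        graph = build_adjacency(dataset.sensors, method=cfg.adjacency_method)
        bundle["clusters"] = {}
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC1]))
        for outcome in cfg.cluster_outcomes:
            for band in cfg.bands:
                if band not in dataset.features:
                    continue
                spec = ModelSpec(outcome=outcome, predictors=(BRAIN,))
                sig, annotated, stats, null = cluster_permutation_test(
                    records, dataset.features[band], spec, graph,
                    n_perm=cfg.n_permutations, alpha=cfg.alpha,
                    p_thresh=cfg.p_thresh, min_size=cfg.min_cluster_size,
                    seed=int(rng.integers(2**31 - 1)),
                )
                key = f"{outcome}_{band}"
                bundle["clusters"][key] = {
                    "significant": sig, "candidates": annotated,
                    "channel_stats": stats, "null": null,
                }
                write_cluster_table(annotated, out / f"clusters_{key}.csv")
                _save_csv(stats, f"topography_{key}.csv")
                _save_csv(pd.DataFrame({"max_abs_mass": null.values}),
                          f"null_{key}.csv", index=False)
                outputs.append(f"clusters_{key}.csv")
        log.info("stage clusters [%.1fs]", _time.perf_counter() - t0)

    if "contrasts" in cfg.stages:
        t0 = _time.perf_counter()
        bundle["contrasts"] = {}
        for outcome in ("sleep_depth", "sleepiness"):
            tab = pairwise_contrasts(records, outcome)
            bundle["contrasts"][outcome] = tab
            _save_csv(tab, f"contrasts_{outcome}.csv", index=False)
        bundle["proportions"] = proportion_tests(records)
        _save_csv(bundle["proportions"]["proportions"], "report_proportions.csv")
        log.info("stage contrasts [%.1fs]", _time.perf_counter() - t0)

    if "pca" in cfg.stages:
        t0 = _time.perf_counter()
        pca = phenomenology_pca(records)
        bundle["pca"] = pca
        bundle["pc_fits"] = {}
        _save_csv(pca.loadings, "pca_loadings.csv")
        _save_csv(pca.scores, "pca_scores.csv")
        for outcome in ("sleep_depth", "sleepiness"):
            for comp in ("pc1", "pc2"):
                fit = pc_association(records, pca.scores, outcome, comp)
                bundle["pc_fits"][(outcome, comp)] = fit
                _save_csv(fit.params, f"pcfit_{outcome}_{comp}.csv")
        log.info("stage pca [%.1fs]", _time.perf_counter() - t0)

    if "timecourse" in cfg.stages:
        t0 = _time.perf_counter()
        trends = {}
        trends["sleep_depth"] = fit_trend(records, "sleep_depth",
                                          covariates=("sleepiness",))
        trends["sleepiness"] = fit_trend(records, "sleepiness",
                                         covariates=("sleep_depth",))
        bundle["trends"] = trends
        if trends["sleepiness"].order == 2:
            bundle["sleepiness_peak"] = estimate_peak(trends["sleepiness"])
        bundle["post4_interaction"] = measure_by_time_interaction(records)
        rows = []
        for name, tr in trends.items():
            for order, bic in tr.bic_by_order.items():
                rows.append({"outcome": name, "order": order, "bic": bic,
                             "selected": order == tr.order})
        _save_csv(pd.DataFrame(rows), "trend_bic.csv", index=False)
        _save_csv(bundle["post4_interaction"].params, "post4_interaction.csv")
        log.info("stage timecourse [%.1fs]", _time.perf_counter() - t0)

    manifest = {
        "package_version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "source": source,
        "inputs": {
            p: _digest(p)
            for p in filter(None, [cfg.awakening_csv, cfg.coordinates_csv,
                                   *cfg.band_csvs.values()])
        },
        "outputs": sorted(set(outputs)) + ["manifest.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
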