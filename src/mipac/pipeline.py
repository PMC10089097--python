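"""End-to-end orchestration: recordings -> comodulograms -> ssPAC ->
cluster inference -> gamma power -> cohort table -> group statistics.

Every stage is deterministic given the configuration (which carries all
seeds), and the result bundle can be persisted as TSV/JSON with a
provenance block sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import ClusterResult, permutation_test
from .config import PipelineConfig
from .containers import HEMISPHERES, LANGUAGES, SsPacMap, TimeSeriesRecording
from .group import (
    AnovaResult,
    ContrastResult,
    RegressionResult,
    behavior_regression,
    build_cohort_table,
    default_posthoc_contrasts,
    posthoc_ttests,
    split_plot_anova,
)
from .io import read_cohort
from .pac import comodulogram, sspac
from .spectral import band_power, epoch, power_spectrum
from .synth import generate_behavior, generate_cohort

log = logging.getLogger("mipac")


@dataclass
class PipelineResult:
    sspac_maps: list[SsPacMap]
    cluster_results: dict[tuple[str, str], ClusterResult]
    cohort_table: pd.DataFrame
    anova_sspac: AnovaResult
    anova_sspow: AnovaResult | None
    posthocs: list[ContrastResult]
    regressions: list[RegressionResult] | None
    ground_truth: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.2f s", name, time.perf_counter() - self.t0)
            return False

    return _Timer()


def _sspow_value(rec: TimeSeriesRecording, config: PipelineConfig) -> float:
    """Mean gamma-band power over 2 s sliding epochs of all trials."""
    epochs = []
    for trial in rec.trials:
        t = trial if trial.ndim == 1 else trial.mean(axis=1)
        epochs.extend(epoch(t, rec.fs, config.epoch_window_s, config.epoch_step_s))
    ps = power_spectrum(epochs, rec.fs)
    return band_power(ps, *config.gamma_power_band)


def _group_recordings(
    recordings: list[TimeSeriesRecording],
) -> dict[tuple[str, str, str], dict[str, TimeSeriesRecording]]:
    grouped: dict[tuple[str, str, str], dict[str, TimeSeriesRecording]] = {}
    for rec in recordings:
        key = (rec.subject_id, rec.language, rec.hemisphere)
        grouped.setdefault(key, {})[rec.condition] = rec
    for key, conds in grouped.items():
        missing = {"natural", "rotated"} - set(conds)
        if missing:
            raise ValueError(f"recording set {key} lacks condition(s) {sorted(missing)}")
    return grouped


def run_pipeline(
    config: PipelineConfig,
    input_dir=None,
    out_dir=None,
    compute_sspow: bool = True,
) -> PipelineResult:
    """Run the full analysis; simulate the cohort if ``input_dir`` is None."""
    ground_truth = None
    behavior = None
    with _stage("load"):
        if input_dir is None:
            recordings, ground_truth = generate_cohort(config.synth)
            behavior = generate_behavior(config.synth, ground_truth)
        else:
            recordings = read_cohort(Path(input_dir) / "recordings")
            behavior_path = Path(input_dir) / "behavior.tsv"
            behavior = pd.read_csv(behavior_path, sep="\t") if behavior_path.exists() else None

    spec = config.filter_bank()
    grouped = _group_recordings(recordings)

    sspac_maps: list[SsPacMap] = []
    sspow_values: dict[tuple[str, str, str], float] | None = {} if compute_sspow else None
    with _stage("comodulogram"):
        for key in sorted(grouped):
            conds = grouped[key]
            como = {
                cond: comodulogram(
                    conds[cond], spec, config.n_bins, config.edge_trim_s, seed=config.qe_seed
                )
                for cond in ("natural", "rotated")
            }
            sspac_maps.append(sspac(como["natural"], como["rotated"]))
            if sspow_values is not None:
                sspow_values[key] = _sspow_value(conds["natural"], config) - _sspow_value(
                    conds["rotated"], config
                )

    cluster_results: dict[tuple[str, str], ClusterResult] = {}
    with _stage("cluster"):
        for lang in LANGUAGES:
            for hemi in HEMISPHERES:
                maps = [
                    m
                    for m in sspac_maps
                    if m.meta["language"] == lang and m.meta["hemisphere"] == hemi
                ]
                cluster_results[(lang, hemi)] = permutation_test(
                    maps,
                    n_perm=config.n_perm,
                    alpha=config.alpha,
                    seed=config.synth.seed + 10_000,
                    connectivity=config.connectivity,
                )

    with _stage("groupstats"):
        table = build_cohort_table(
            sspac_maps,
            sspow=sspow_values,
            behavior=behavior,
            phase_band=config.theta_phase_band,
            amp_band=config.gamma_amp_band,
        )
        anova_sspac = split_plot_anova(table, "sspac")
        anova_sspow = (
            split_plot_anova(table, "sspow") if sspow_values is not None else None
        )
        posthocs = posthoc_ttests(table, default_posthoc_contrasts(), "sspac")
        score_cols = [c for c in table.columns if c.endswith("_pct")]
        regressions = (
            behavior_regression(
                table, score_cols, "sspac", alpha_threshold=config.regression_alpha
            )
            if score_cols
            else None
        )

    result = PipelineResult(
        sspac_maps=sspac_maps,
        cluster_results=cluster_results,
        cohort_table=table,
        anova_sspac=anova_sspac,
        anova_sspow=anova_sspow,
        posthocs=posthocs,
        regressions=regressions,
        ground_truth=ground_truth,
        provenance={
            "config_hash": config.content_hash(),
            "config": config.to_dict(),
            "mipac_version": __version__,
            "numpy_version": np.__version__,
        },
    )
    if out_dir is not None:
        with _stage("write"):
            write_results(result, out_dir)
    return result


def _cluster_to_dict(key: tuple[str, str], res: ClusterResult) -> dict:
    return {
        "language": key[0],
        "hemisphere": key[1],
        "threshold_t": res.threshold_t,
        "n_perm": res.n_perm,
        "alpha": res.alpha,
        "clusters": [
            {
                "sign": c.sign,
                "mass": c.mass,
                "p": c.p,
                "size": c.size,
                "cells": [list(map(int, cell)) for cell in c.cells],
            }
            for c in res.clusters
        ],
    }


def write_results(result: PipelineResult, out_dir) -> None:
    """Persist the bundle as TSV/JSON files plus a provenance block."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.cohort_table.to_csv(out / "cohort_table.tsv", sep="\t", index=False)
    result.anova_sspac.table.to_csv(out / "anova_sspac.tsv", sep="\t")
    if result.anova_sspow is not None:
        result.anova_sspow.table.to_csv(out / "anova_sspow.tsv", sep="\t")
    pd.DataFrame([dataclasses.asdict(c) for c in result.posthocs]).to_csv(
        out / "posthocs.tsv", sep="\t", index=False
    )
    if result.regressions is not None:
        pd.DataFrame([dataclasses.asdict(r) for r in result.regressions]).to_csv(
            out / "regressions.tsv", sep="\t", index=False
        )
    clusters = [_cluster_to_dict(k, v) for k, v in sorted(result.cluster_results.items())]
    (out / "clusters.json").write_text(json.dumps(clusters, indent=1))
    maps_dir = out / "sspac_maps"
    maps_dir.mkdir(exist_ok=True)
    for m in result.sspac_maps:
        stem = "_".join(str(m.meta[k]) for k in ("subject_id", "language", "hemisphere"))
        df = pd.DataFrame(m.values, index=m.phase_freqs, columns=m.amp_freqs)
        df.to_csv(maps_dir / f"{stem}.tsv", sep="\t")
    if result.ground_truth is not None:
        result.ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=1, sort_keys=True))
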