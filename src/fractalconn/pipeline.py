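"""End-to-end orchestration: preprocess -> sliding connectivity ->
feature selection -> summaries and brain-behavior correlations.

A :class:`PipelineConfig` gathers every stage's parameters, validates them
before any computation starts, and round-trips losslessly through YAML/JSON
so that a run is fully described by its config and seed. ``run_pipeline``
executes the stages in order, persisting every intermediate artifact
(HDF5 tensors, CSV tables, JSON metrics) plus a machine-readable run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fractal import ScaleSet, WindowPlan, sliding_connectivity
from .io import write_recording_csv, write_tensor_h5
from .preprocess import bandpass_filter, common_average_reference, trim_epoch
from .selection import RFEConfig, build_feature_dataset, run_selection
from .stats_tools import abs_mean_variance_corr, spearman_table, summary_table
from .synthetic import CohortSpec, gen_cohort, gen_scores

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved parameters of every pipeline stage."""

    # preprocessing
    low_hz: float = 0.5
    high_hz: float = 45.0
    filter_order: int = 4
    car: bool = True
    epoch_s: float | None = None
    # connectivity
    scales: tuple[int, ...] = (8, 16, 32, 64, 128)
    win_len: int = 1024
    step: int = 128
    # selection
    C: float = 1.0
    elim_frac: float = 0.5
    corr_threshold: float = 0.9
    one_by_one_below: int = 20
    k_max: int | None = None
    # stats
    adjust_dfa_fdr: bool = True
    adjust_posthoc_fdr: bool = False
    seed: int = 0

    def validate(self) -> None:
        scale_set = ScaleSet(self.scales)
        if self.win_len <= scale_set.scales[-1]:
            raise ValueError("win_len must exceed the largest scale")
        WindowPlan(self.win_len, self.step)
        RFEConfig(self.C, self.elim_frac, self.corr_threshold, self.one_by_one_below)
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "scales" in d:
            d["scales"] = tuple(int(s) for s in d["scales"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _preprocess(rec, cfg: PipelineConfig):
    out = bandpass_filter(rec, cfg.low_hz, cfg.high_hz, cfg.filter_order)
    if cfg.car:
        out = common_average_reference(out)
    if cfg.epoch_s is not None:
        out = trim_epoch(out, cfg.epoch_s)
    return out


def run_pipeline(
    cohort: CohortSpec,
    cfg: PipelineConfig,
    out_dir,
    preprocess: bool = False,
    write_recordings: bool = False,
) -> dict:
    """Run the full analysis on a synthetic cohort and persist artifacts.

    Stages: cohort generation, optional preprocessing, sliding-window
    connectivity, SVM-RFE selection, summaries, cognitive-score generation
    and Spearman brain-behavior correlation. Returns the metrics dict that
    is also written to ``metrics.json``. Deterministic given the seeds in
    ``cohort`` and ``cfg``.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        recordings, truth = gen_cohort(cohort)
        truth.to_csv(out / "ground_truth.csv", index=False)
        pd.DataFrame(
            {"subject_id": [r.subject_id for r in recordings],
             "group": [r.group for r in recordings]}
        ).to_csv(out / "subjects.csv", index=False)
        if write_recordings:
            rec_dir = out / "recordings"
            rec_dir.mkdir(exist_ok=True)
            for r in recordings:
                write_recording_csv(r, rec_dir / f"{r.subject_id}.csv")

        if preprocess:
            stage = "preprocess"
            recordings = [_preprocess(r, cfg) for r in recordings]

        stage = "connect"
        scale_set = ScaleSet(cfg.scales)
        plan = WindowPlan(cfg.win_len, cfg.step)
        tensors, dfas, groups = {}, {}, {}
        tensor_dir = out / "tensors"
        tensor_dir.mkdir(exist_ok=True)
        for r in recordings:
            t, d = sliding_connectivity(r, scale_set, plan)
            tensors[r.subject_id] = t
            dfas[r.subject_id] = d
            groups[r.subject_id] = r.group
            write_tensor_h5(t, d, tensor_dir / f"{r.subject_id}.h5")

        stage = "discriminate"
        ds = build_feature_dataset(tensors, groups)
        rfe_cfg = RFEConfig(cfg.C, cfg.elim_frac, cfg.corr_threshold, cfg.one_by_one_below)
        sel = run_selection(ds, rfe_cfg, k_max=cfg.k_max)
        chosen = pd.DataFrame(
            [ds.feature_names[i] for i in sel.chosen_set],
            columns=["ch1", "ch2", "scale"],
        )
        chosen.to_csv(out / "chosen_features.csv", index=False)
        sel.per_fold.to_csv(out / "per_fold_metrics.csv", index=False)

        stage = "summarize"
        summaries = summary_table(tensors, dfas, groups)
        summaries.to_csv(out / "summaries.csv")
        scores = gen_scores(summaries.drop(columns="group"), cohort)
        scores.to_csv(out / "scores.csv")

        stage = "correlate"
        corr = pd.DataFrame()
        mv = pd.DataFrame()
        if len(scores.columns) and all(
            (summaries["group"] == g).sum() >= 5 for g in ("young", "elderly")
        ):
            feat_cols = [
                f"mu_dccc_{a}_{b}_s{s}" for a, b, s in chosen.itertuples(index=False)
            ] + [
                f"var_dccc_{a}_{b}_s{s}" for a, b, s in chosen.itertuples(index=False)
            ]
            corr = spearman_table(summaries, scores, feat_cols)
            corr.to_csv(out / "correlations.csv", index=False)
        if len(chosen) >= 3:
            pairs = [
                (f"mu_dccc_{a}_{b}_s{s}", f"var_dccc_{a}_{b}_s{s}")
                for a, b, s in chosen.itertuples(index=False)
            ]
            mv = abs_mean_variance_corr(summaries, pairs)
            mv.to_csv(out / "mean_variance_relation.csv", index=False)
    except Exception:
        logger.exception("pipeline failed in stage '%s'; partial outputs kept in %s", stage, out)
        raise

    metrics = {
        "n_subjects": len(recordings),
        "n_windows": int(next(iter(tensors.values())).n_windows),
        "n_features": int(ds.n_features),
        "n_folds": int(len(sel.per_fold)),
        "chosen_k": len(sel.chosen_set),
        "acc_sample_pct": sel.acc_sw,
        "acc_subject_pct": sel.acc_subj,
        "kappa_sample": sel.kappa_sw,
        "kappa_subject": sel.kappa_subj,
        "chance_level_pct": sel.chance_level_pct,
    }
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": cohort.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stages": ["simulate", "connect", "discriminate", "summarize", "correlate"],
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return metrics
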