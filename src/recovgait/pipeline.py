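"""Experiment orchestration: train on complete data, occlude the test
branch, recover with each technique, and tabulate recovery and
classification metrics.

The central design follows the train-on-complete / test-on-occluded
protocol: the gated initialization model and the classifier are fitted
once per seed on the complete training split; occlusion is then simulated
only on copies of the test split, each recovery technique is applied, and
every (technique, group, missing-frames, hidden-units, seed) cell yields a
recovery-error row (vs. the untouched ground truth) and a classification
row.  Four techniques are available:

* ``none``       — zero-filled passthrough (no recovery);
* ``ukf``        — unscented tracking alone, initialized from the last two
                   observed frames, coasting predict-only through gaps;
* ``gated``      — iterative gated-recurrent imputation alone;
* ``recovgait``  — gated initialization + unscented tracking with
                   pseudo-measurement fusion (the combined method).

Models are trained once per seed and shared across occlusion cells; cell
failures are recorded and do not abort the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import gated_init, ukf
from .classifier import ClassifierConfig, evaluate, split_dataset, train_classifier
from .gated_init import GatedInitConfig
from .metrics import error_metrics, sweep_report
from .occlusion import OcclusionSpec, simulate_missing
from .sequences import GaitSequence
from .skeleton import BodyPart
from .synthetic import make_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "recover_with", "run_ablation",
           "run_part_sensitivity", "run_multipart", "TECHNIQUES"]

TECHNIQUES = ("none", "ukf", "gated", "recovgait")


@dataclass
class RunConfig:
    """Configuration of one experiment sweep."""

    n_pd: int = 26
    n_healthy: int = 50
    frames: int = 50
    groups: tuple = (BodyPart.HEAD, BodyPart.BODY, BodyPart.HIPS, BodyPart.LEGS)
    missing_frames: tuple = (40,)
    techniques: tuple = TECHNIQUES
    hidden_units: tuple = (50,)
    seeds: tuple = (0,)
    split_fractions: tuple = (0.7, 0.3)
    init_config: GatedInitConfig = field(default_factory=GatedInitConfig)
    classifier_config: ClassifierConfig = field(default_factory=ClassifierConfig)
    sigma_q: float = 3.0
    sigma_r: float = 2.0
    r_pseudo_scale: float = 10.0
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if not self.techniques:
            raise ValueError("at least one technique required")
        if not self.seeds:
            raise ValueError("at least one seed required")
        unknown = set(self.techniques) - set(TECHNIQUES)
        if unknown:
            raise ValueError(f"unknown techniques {sorted(unknown)}; "
                             f"valid: {TECHNIQUES}")
        self.groups = tuple(
            BodyPart.from_name(g) if isinstance(g, str) else g
            for g in self.groups
        )
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)

    def ukf_params(self) -> ukf.UKFParams:
        return ukf.default_keypoint_params(
            sigma_q=self.sigma_q, sigma_r=self.sigma_r,
            r_pseudo_scale=self.r_pseudo_scale)


def recover_with(technique: str, seqs: list[GaitSequence], init_model=None,
                 params: ukf.UKFParams | None = None) -> list[GaitSequence]:
    """Apply one recovery technique to a list of occluded sequences."""
    if technique == "none":
        return [s.copy() for s in seqs]
    if technique == "ukf":
        return [ukf.ukf_only_recover(s, params) for s in seqs]
    if technique == "gated":
        if init_model is None:
            raise ValueError("technique 'gated' requires an init model")
        return [gated_init.iterative_reconstruct(init_model, s) for s in seqs]
    if technique == "recovgait":
        if init_model is None:
            raise ValueError("technique 'recovgait' requires an init model")
        return [ukf.recover_sequence(s, init_model, params) for s in seqs]
    raise ValueError(f"unknown technique {technique!r}; valid: {TECHNIQUES}")


def _prepare_seed(cfg: RunConfig, seed: int, train_init: bool = True,
                  train_clf: bool = True):
    """Data, split and per-seed models (shared across occlusion cells)."""
    data = make_dataset(cfg.n_pd, cfg.n_healthy, frames=cfg.frames, seed=seed)
    train_seqs, test_seqs = split_dataset(data, cfg.split_fractions, seed=seed)
    init_models = {}
    if train_init:
        for units in cfg.hidden_units:
            icfg = replace(cfg.init_config, hidden_units=units, seed=seed)
            t = time.perf_counter()
            init_models[units] = gated_init.train(train_seqs, icfg)
            logger.info("seed %d: init model (%d units) trained in %.1fs",
                        seed, units, time.perf_counter() - t)
    clf = None
    if train_clf:
        ccfg = replace(cfg.classifier_config, seed=seed)
        t = time.perf_counter()
        clf = train_classifier(train_seqs, ccfg)
        logger.info("seed %d: classifier trained in %.1fs",
                    seed, time.perf_counter() - t)
    return train_seqs, test_seqs, init_models, clf


def _write(cfg: RunConfig, name: str, recovery_rows: list[dict],
           clf_rows: list[dict]) -> tuple[pd.DataFrame, pd.DataFrame]:
    rec = sweep_report(recovery_rows)
    clf = sweep_report(clf_rows)
    if cfg.out_dir is not None:
        cfg.out_dir.mkdir(parents=True, exist_ok=True)
        rec.to_csv(cfg.out_dir / f"{name}_recovery.csv", index=False,
                   float_format="%.4f")
        clf.to_csv(cfg.out_dir / f"{name}_classification.csv", index=False,
                   float_format="%.4f")
        manifest = {
            "run": name,
            "seeds": list(cfg.seeds),
            "techniques": list(cfg.techniques),
            "groups": [g.value for g in cfg.groups],
            "missing_frames": list(cfg.missing_frames),
            "hidden_units": list(cfg.hidden_units),
            "n_pd": cfg.n_pd, "n_healthy": cfg.n_healthy,
            "frames": cfg.frames,
            "sigma_q": cfg.sigma_q, "sigma_r": cfg.sigma_r,
            "r_pseudo_scale": cfg.r_pseudo_scale,
        }
        with (cfg.out_dir / f"{name}_manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=2)
    return rec, clf


def run_ablation(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The four-arm ablation grid.

    Returns (recovery table, classification table); each row is one
    (technique, group, missing_frames, hidden_units, seed) cell.
    """
    params = cfg.ukf_params()
    recovery_rows: list[dict] = []
    clf_rows: list[dict] = []
    for seed in cfg.seeds:
        train_seqs, test_seqs, init_models, clf = _prepare_seed(cfg, seed)
        complete = evaluate(clf, test_seqs)
        clf_rows.append({"technique": "complete", "group": "none",
                         "missing_frames": 0, "hidden_units": "-",
                         "seed": seed, **complete.as_dict()})
        for group in cfg.groups:
            for k in cfg.missing_frames:
                spec = OcclusionSpec(groups=(group,), missing_frames=k)
                occluded = [simulate_missing(s, spec) for s in test_seqs]
                for technique in cfg.techniques:
                    units_list = (cfg.hidden_units
                                  if technique in ("gated", "recovgait")
                                  else ("-",))
                    for units in units_list:
                        key = {"technique": technique, "group": group.value,
                               "missing_frames": k, "hidden_units": units,
                               "seed": seed}
                        try:
                            model = init_models.get(units)
                            recovered = recover_with(technique, occluded,
                                                     model, params)
                            rec = error_metrics(test_seqs, recovered,
                                                scope="all")
                            recovery_rows.append(
                                {**key, "mae": rec.mae, "mse": rec.mse,
                                 "mape": rec.mape, "n_values": rec.n_values})
                            report = evaluate(clf, recovered)
                            clf_rows.append({**key, **report.as_dict()})
                        except Exception as exc:  # cell isolation
                            logger.error("cell %s failed: %s", key, exc)
                            recovery_rows.append({**key, "error": str(exc)})
    return _write(cfg, "ablation", recovery_rows, clf_rows)


def run_part_sensitivity(cfg: RunConfig) -> pd.DataFrame:
    """Classification vs. occluded body part and missing-frame count,
    with no recovery applied (zero-fill), plus the complete baseline."""
    if not cfg.missing_frames:
        raise ValueError("missing_frames list must be non-empty")
    rows: list[dict] = []
    for seed in cfg.seeds:
        _, test_seqs, _, clf = _prepare_seed(cfg, seed, train_init=False)
        baseline = evaluate(clf, test_seqs)
        rows.append({"technique": "none", "group": "none", "missing_frames": 0,
                     "seed": seed, **baseline.as_dict()})
        for group in cfg.groups:
            for k in cfg.missing_frames:
                spec = OcclusionSpec(groups=(group,), missing_frames=k)
                occluded = [simulate_missing(s, spec) for s in test_seqs]
                report = evaluate(clf, occluded)
                rows.append({"technique": "none", "group": group.value,
                             "missing_frames": k, "seed": seed,
                             **report.as_dict()})
    table = sweep_report(rows)
    if cfg.out_dir is not None:
        cfg.out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(cfg.out_dir / "part_sensitivity.csv", index=False,
                     float_format="%.4f")
    return table


MULTIPART_LEVELS = (
    (BodyPart.LEGS,),
    (BodyPart.LEGS, BodyPart.HIPS),
    (BodyPart.BODY, BodyPart.LEGS, BodyPart.HIPS),
    (BodyPart.HEAD, BodyPart.BODY, BodyPart.LEGS, BodyPart.HIPS),
)


def run_multipart(cfg: RunConfig, technique: str = "recovgait") -> pd.DataFrame:
    """Recovery error under nested multi-part occlusion (legs up to whole
    body), one row per nesting level and seed."""
    params = cfg.ukf_params()
    k = cfg.missing_frames[0]
    units = cfg.hidden_units[0]
    rows: list[dict] = []
    for seed in cfg.seeds:
        needs_init = technique in ("gated", "recovgait")
        _, test_seqs, init_models, _ = _prepare_seed(
            cfg, seed, train_init=needs_init, train_clf=False)
        model = init_models.get(units)
        for level in MULTIPART_LEVELS:
            spec = OcclusionSpec(groups=level, missing_frames=k)
            occluded = [simulate_missing(s, spec) for s in test_seqs]
            recovered = recover_with(technique, occluded, model, params)
            rec = error_metrics(test_seqs, recovered, scope="all")
            rows.append({
                "technique": technique,
                "group": "+".join(g.value for g in level),
                "missing_frames": k, "hidden_units": units, "seed": seed,
                "mae": rec.mae, "mse": rec.mse, "mape": rec.mape,
                "n_values": rec.n_values,
            })
    table = sweep_report(rows)
    if cfg.out_dir is not None:
        cfg.out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(cfg.out_dir / "multipart.csv", index=False,
                     float_format="%.4f")
    return table
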