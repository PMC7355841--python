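"""End-to-end experiment orchestration.

Chains the stages: simulate (or load) raw sessions -> impute -> angular
conversion -> error computation -> outlier removal -> 10x augmentation ->
feature assembly -> standardize -> split -> train/evaluate classifiers,
or -> regression model comparison.  Every run writes a manifest recording
the configuration hash and seeds so reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from .augmentation import AugmentationConfig
from .classification import ClassifierSpec, cross_validate, evaluate, train_classifier
from .geometry import ErrorTrace, RawGazeSession, combine_eyes, compute_errors, to_angles
from .preprocessing import CleaningConfig, clean_error_trace, impute_missing
from .regression import (
    REGRESSION_KINDS,
    RegressionSpec,
    build_regression_features,
    fit_error_model,
)
from .simulate import SimulationSpec, default_profiles, make_aoi_grid, simulate_study

__all__ = [
    "PipelineConfig",
    "session_aoi_index",
    "session_to_error_trace",
    "sessions_to_error_traces",
    "run_classification_experiment",
    "run_regression_experiment",
]


@dataclass(frozen=True)
class PipelineConfig:
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    participants: int = 20
    samples_per_aoi: int = 41
    test_fraction: float = 0.30
    folds: int = 10
    seed: int = 0


def session_aoi_index(session: RawGazeSession) -> np.ndarray:
    """Per-sample AOI ids (1..15) from the ground-truth trace.

    Each sample's (aoi_x, aoi_y) is matched to the nearest centre of the
    5x3 stimulus grid of the session's screen.
    """
    grid = make_aoi_grid(session.screen)
    d2 = (
        (np.asarray(session.aoi_x, float)[:, None] - grid.centers_x[None, :]) ** 2
        + (np.asarray(session.aoi_y, float)[:, None] - grid.centers_y[None, :]) ** 2
    )
    return d2.argmin(axis=1) + 1


def session_to_error_trace(
    session: RawGazeSession, cleaning: CleaningConfig | None = None
) -> ErrorTrace:
    """Impute, convert to angles, compute signed errors, remove outliers."""
    imputed = RawGazeSession(
        timestamps_ms=session.timestamps_ms,
        x_left=impute_missing(session.x_left),
        y_left=impute_missing(session.y_left),
        x_right=impute_missing(session.x_right),
        y_right=impute_missing(session.y_right),
        aoi_x=session.aoi_x, aoi_y=session.aoi_y,
        z_mm=session.z_mm, platform=session.platform,
        condition=session.condition, participant=session.participant,
        screen=session.screen,
    )
    gaze = combine_eyes(imputed)
    ang = to_angles(gaze, (session.aoi_x, session.aoi_y),
                    session.screen, session.z_mm)
    trace = compute_errors(
        ang,
        condition=session.condition, participant=session.participant,
        platform=session.platform, aoi_index=session_aoi_index(session),
    )
    if cleaning is None:
        cleaning = CleaningConfig()
    return clean_error_trace(trace, cleaning)


def sessions_to_error_traces(sessions, cleaning: CleaningConfig | None = None):
    return [session_to_error_trace(s, cleaning) for s in sessions]


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_classification_experiment(
    config: PipelineConfig,
    platform: str = "desktop",
    scope: str = "user_distance",
    classifiers: tuple[str, ...] = ("knn", "svm", "mlp"),
    outdir: str | Path | None = None,
    sessions=None,
) -> dict:
    """Full classification run; returns a report bundle (JSON-serializable).

    With ``sessions=None`` a study is simulated with the packaged default
    error profiles.  The bundle holds, per classifier, the stratified CV
    accuracy and the held-out detection-rate report, plus a manifest with
    dataset cardinalities and the configuration hash.
    """
    if sessions is None:
        spec = SimulationSpec(platform=platform,
                              participants=config.participants,
                              samples_per_aoi=config.samples_per_aoi,
                              seed=config.seed)
        sessions = simulate_study(spec, default_profiles(platform))
    traces = sessions_to_error_traces(sessions, config.cleaning)
    dataset = feat.assemble_dataset(traces, scope=scope,
                                    aug_cfg=config.augmentation,
                                    seed=config.seed)
    std = feat.standardize(dataset)
    train, test = feat.split(std, config.test_fraction, seed=config.seed)

    specs = {
        "knn": ClassifierSpec(kind="knn", seed=config.seed),
        "svm": ClassifierSpec(kind="svm", seed=config.seed),
        "mlp": ClassifierSpec(kind="mlp", seed=config.seed),
    }
    reports = {}
    for name in classifiers:
        spec_ = specs[name]
        cv_mean, cv_sd, _ = cross_validate(std, spec_, folds=config.folds,
                                           seed=config.seed)
        model = train_classifier(train, spec_)
        rep = evaluate(model, test, spec_, cv_accuracy=cv_mean, cv_sd=cv_sd)
        reports[name] = rep.to_dict()

    manifest = {
        "platform": platform,
        "scope": scope,
        "n_samples": int(dataset.n_samples),
        "n_classes": len(dataset.class_names),
        "class_names": dataset.class_names,
        "n_train": int(train.n_samples),
        "n_test": int(test.n_samples),
        "seed": config.seed,
        "config_hash": _config_hash({
            "cleaning": asdict(config.cleaning),
            "augmentation": asdict(config.augmentation),
            "participants": config.participants,
            "samples_per_aoi": config.samples_per_aoi,
            "test_fraction": config.test_fraction,
            "folds": config.folds,
            "seed": config.seed,
            "platform": platform, "scope": scope,
        }),
    }
    bundle = {"manifest": manifest, "reports": reports}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"classification_{platform}_{scope}.json").write_text(
            json.dumps(bundle, indent=2)
        )
        for name in classifiers:
            pd.DataFrame(
                reports[name]["confusion"],
                index=manifest["class_names"], columns=manifest["class_names"],
            ).to_csv(outdir / f"confusion_{platform}_{scope}_{name}.csv")
    return bundle


def run_regression_experiment(
    config: PipelineConfig,
    platform: str = "desktop",
    conditions: tuple[str, ...] = ("UD60", "roll20", "pitch20", "yaw20"),
    kinds: tuple[str, ...] = REGRESSION_KINDS,
    outdir: str | Path | None = None,
    sessions=None,
) -> dict:
    """Fit all regression families per condition; RMSE table + coefficients."""
    if sessions is None:
        spec = SimulationSpec(platform=platform,
                              participants=config.participants,
                              samples_per_aoi=config.samples_per_aoi,
                              seed=config.seed)
        profiles = default_profiles(platform)
        profiles = {c: profiles[c] for c in conditions}
        sessions = simulate_study(spec, profiles)

    rmse_table: dict[str, dict[str, float]] = {k: {} for k in kinds}
    coefficients: dict[str, dict] = {}
    for cond in conditions:
        cond_sessions = [s for s in sessions if s.condition == cond]
        if not cond_sessions:
            raise ValueError(f"no sessions for condition {cond!r}")
        traces = sessions_to_error_traces(cond_sessions, config.cleaning)
        angs, errs = [], []
        for s, t in zip(cond_sessions, traces):
            gaze = combine_eyes(RawGazeSession(
                timestamps_ms=s.timestamps_ms,
                x_left=impute_missing(s.x_left), y_left=impute_missing(s.y_left),
                x_right=impute_missing(s.x_right), y_right=impute_missing(s.y_right),
                aoi_x=s.aoi_x, aoi_y=s.aoi_y, z_mm=s.z_mm,
                platform=s.platform, condition=s.condition,
                participant=s.participant, screen=s.screen,
            ))
            angs.append(to_angles(gaze, (s.aoi_x, s.aoi_y), s.screen, s.z_mm))
            errs.append(t)
        ang = _concat_angular(angs)
        err_frontal = np.concatenate([t.err_frontal for t in errs])
        err = ErrorTrace(err_frontal=err_frontal,
                         err_yaw=np.concatenate([t.err_yaw for t in errs]),
                         err_pitch=np.concatenate([t.err_pitch for t in errs]),
                         condition=cond, platform=platform)
        x, y, _ = build_regression_features(ang, err)
        best_kind, best_rmse, best_model = None, np.inf, None
        for kind in kinds:
            rspec = RegressionSpec(kind=kind, seed=config.seed)
            model, report = fit_error_model(x, y, rspec, condition=cond)
            rmse_table[kind][cond] = report.rmse
            if report.rmse < best_rmse and model is not None:
                best_kind, best_rmse, best_model = kind, report.rmse, model
        if best_model is not None:
            coefficients[cond] = {
                "kind": best_kind,
                "b0": best_model.b0,
                "b": best_model.b.tolist(),
                "y_offset": best_model.y_offset,
            }

    bundle = {
        "platform": platform,
        "rmse": rmse_table,
        "best_coefficients": coefficients,
        "seed": config.seed,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rmse_table).T.to_csv(outdir / f"rmse_{platform}.csv")
        (outdir / f"regression_{platform}.json").write_text(
            json.dumps(bundle, indent=2)
        )
    return bundle


def _concat_angular(angs):
    from .geometry import AngularTrace

    return AngularTrace(
        theta_gaze=np.concatenate([a.theta_gaze for a in angs]),
        theta_gt=np.concatenate([a.theta_gt for a in angs]),
        theta_yaw=np.concatenate([a.theta_yaw for a in angs]),
        theta_pitch=np.concatenate([a.theta_pitch for a in angs]),
        aoi_yaw=np.concatenate([a.aoi_yaw for a in angs]),
        aoi_pitch=np.concatenate([a.aoi_pitch for a in angs]),
        osd_mm=np.concatenate([a.osd_mm for a in angs]),
        osd_gt_mm=np.concatenate([a.osd_gt_mm for a in angs]),
    )
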