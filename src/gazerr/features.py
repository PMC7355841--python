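"""Feature construction for gaze-error pattern learning.

Each (participant, condition, error-category, augmentation-variant) trace
is summarised into a 20-element feature vector:

    [err_AOI-1 .. err_AOI-15, mean, sd, IQR, CI95_upper, CI95_lower]

where the first fifteen entries are mean absolute errors at the 15 AOI
stimulus locations (5x3 grid, row-major) and the rest are whole-trace
statistics.  A reduced 5-feature set keeps only the statistics, which
impurity-based ranking identifies as the most discriminative.  Datasets
are assembled per classification scope:

* ``user_distance`` — 4 classes (UD50/UD60/UD70/UD80),
* ``pose``          — 4 classes (neutral + roll/pitch/yaw 20 deg, where
  neutral is the 60-cm user-distance data),
* ``mixed``         — 7 classes (4 distances + 3 non-neutral poses).

With 20 participants and 30 samples per participant-condition (3 error
categories x 10 augmentation variants) this yields 2400/2400/4200 samples.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from .augmentation import AugmentationConfig, augment_10x, flip_aoi
from .geometry import ErrorTrace

__all__ = [
    "FEATURE_NAMES",
    "REDUCED_FEATURE_NAMES",
    "FeatureVector",
    "LabeledDataset",
    "errors_per_aoi",
    "sample_stats",
    "build_feature_vector",
    "trace_features",
    "assemble_dataset",
    "standardize",
    "split",
]

FEATURE_NAMES = tuple(
    [f"err_aoi_{k}" for k in range(1, 16)]
    + ["mean_err", "sd_err", "iqr_err", "ci95_upper", "ci95_lower"]
)
REDUCED_FEATURE_NAMES = ("mean_err", "sd_err", "iqr_err", "ci95_upper", "ci95_lower")
#: column positions of the reduced statistical feature set
REDUCED_COLUMNS = tuple(range(15, 20))


class MissingAOIError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureVector:
    """One labelled training sample (20 features + metadata)."""

    values: np.ndarray                  # length 20, FEATURE_NAMES order
    category: str = "frontal"           # frontal | yaw | pitch
    label: str = ""
    participant: str = ""
    variant: str = "original"

    def __post_init__(self) -> None:
        if len(self.values) != 20:
            raise ValueError(f"expected 20 features, got {len(self.values)}")

    @property
    def reduced(self) -> np.ndarray:
        """The 5-feature statistical subset [mean, sd, IQR, CI bounds]."""
        return self.values[list(REDUCED_COLUMNS)]


def errors_per_aoi(
    err_values: np.ndarray, aoi_index: np.ndarray, n_aoi: int = 15
) -> np.ndarray:
    """Mean absolute error at each AOI (1..n_aoi, row-major)."""
    e = np.abs(np.asarray(err_values, float))
    idx = np.asarray(aoi_index)
    out = np.empty(n_aoi)
    for k in range(1, n_aoi + 1):
        sel = idx == k
        if not sel.any():
            raise MissingAOIError(f"AOI {k} has no samples")
        out[k - 1] = e[sel].mean()
    return out


def sample_stats(err_values: np.ndarray) -> tuple[float, float, float, float, float]:
    """(mean, sample sd, IQR, CI95 upper, CI95 lower) of an error sample.

    The confidence interval is the normal approximation for the mean,
    mean +/- 1.96 * sd / sqrt(n); quartiles use linear interpolation.
    """
    x = np.asarray(err_values, float)
    if x.size < 2:
        raise ValueError("need at least 2 values for sample statistics")
    m = float(x.mean())
    sd = float(x.std(ddof=1))
    q1, q3 = np.percentile(x, [25, 75])
    half = 1.96 * sd / np.sqrt(x.size)
    return m, sd, float(q3 - q1), m + half, m - half


def build_feature_vector(
    per_aoi: np.ndarray,
    stats: Sequence[float],
    *,
    category: str = "frontal",
    label: str = "",
    participant: str = "",
    variant: str = "original",
) -> FeatureVector:
    """Concatenate per-AOI errors and sample statistics into the 20-vector."""
    per_aoi = np.asarray(per_aoi, float)
    if per_aoi.size != 15 or len(stats) != 5:
        raise ValueError("expected 15 AOI entries and 5 statistics")
    return FeatureVector(
        values=np.concatenate([per_aoi, np.asarray(stats, float)]),
        category=category, label=label, participant=participant, variant=variant,
    )


def trace_features(
    err_values: np.ndarray,
    aoi_index: np.ndarray,
    *,
    category: str = "frontal",
    label: str = "",
    participant: str = "",
    variant: str = "original",
) -> FeatureVector:
    """Feature vector of a single (possibly augmented) error trace."""
    return build_feature_vector(
        errors_per_aoi(err_values, aoi_index),
        sample_stats(np.abs(np.asarray(err_values, float))),
        category=category, label=label, participant=participant, variant=variant,
    )


@dataclass
class LabeledDataset:
    """Feature matrix with class labels and per-row provenance."""

    matrix: np.ndarray                    # n_samples x n_features
    labels: np.ndarray                    # class label per row
    feature_names: tuple[str, ...] = FEATURE_NAMES
    provenance: Optional[pd.DataFrame] = None   # participant/category/variant
    scaler: Optional[StandardScaler] = None

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("matrix rows must match number of labels")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def class_names(self) -> list[str]:
        return sorted(set(map(str, self.labels)))

    def reduced(self) -> "LabeledDataset":
        """Project onto the 5 statistical features."""
        cols = [self.feature_names.index(n) for n in REDUCED_FEATURE_NAMES]
        return LabeledDataset(
            matrix=self.matrix[:, cols],
            labels=self.labels,
            feature_names=REDUCED_FEATURE_NAMES,
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(self.feature_names))
        df["label"] = self.labels
        if self.provenance is not None:
            for col in self.provenance.columns:
                df[col] = self.provenance[col].to_numpy()
        return df


# Conditions making up each classification scope.  The neutral pose is the
# 60-cm user-distance recording, stored once under "UD60".
_SCOPE_CONDITIONS = {
    "user_distance": {"UD50": "UD50", "UD60": "UD60", "UD70": "UD70", "UD80": "UD80"},
    "pose": {"UD60": "neutral", "roll20": "roll20",
             "pitch20": "pitch20", "yaw20": "yaw20"},
    "mixed": {"UD50": "UD50", "UD60": "UD60", "UD70": "UD70", "UD80": "UD80",
              "roll20": "roll20", "pitch20": "pitch20", "yaw20": "yaw20"},
}

CATEGORIES = ("frontal", "yaw", "pitch")


def assemble_dataset(
    traces: Iterable[ErrorTrace],
    scope: str = "user_distance",
    aug_cfg: AugmentationConfig | None = None,
    seed: int = 0,
) -> LabeledDataset:
    """Build a labelled feature dataset from cleaned error traces.

    Every trace contributes 3 error categories x 10 augmentation variants
    = 30 feature rows.  ``scope`` selects and relabels conditions; traces
    whose condition is outside the scope are ignored, and a condition
    required by the scope but absent from the input raises.
    """
    if scope not in _SCOPE_CONDITIONS:
        raise ValueError(f"unknown scope {scope!r}")
    if aug_cfg is None:
        aug_cfg = AugmentationConfig()
    cond_map = _SCOPE_CONDITIONS[scope]

    rows, labels, prov = [], [], []
    seen: set[str] = set()
    ss = np.random.SeedSequence(seed)
    for trace in traces:
        if trace.condition not in cond_map:
            continue
        seen.add(trace.condition)
        label = cond_map[trace.condition]
        if trace.aoi_index is None:
            raise ValueError("traces must carry an AOI index for feature assembly")
        for category in CATEGORIES:
            key = zlib.crc32(
                f"{trace.participant}|{trace.condition}|{category}".encode()
            )
            child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(key,))
            var_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
            variants = augment_10x(
                trace.category(category), aug_cfg, var_seed, trace.aoi_index
            )
            for vname, vtrace in variants.items():
                fv = trace_features(
                    vtrace, trace.aoi_index,
                    category=category, label=label,
                    participant=trace.participant, variant=vname,
                )
                rows.append(fv.values)
                labels.append(label)
                prov.append((trace.participant, category, vname))
    missing = set(cond_map) - seen
    if missing:
        raise ValueError(f"scope {scope!r} is missing conditions: {sorted(missing)}")
    return LabeledDataset(
        matrix=np.vstack(rows),
        labels=np.asarray(labels),
        provenance=pd.DataFrame(prov, columns=["participant", "category", "variant"]),
    )


def standardize(dataset: LabeledDataset) -> LabeledDataset:
    """Zero-mean unit-variance columns; constant columns are dropped with a warning."""
    import warnings

    sds = dataset.matrix.std(axis=0)
    keep = sds > 0
    names = tuple(n for n, k in zip(dataset.feature_names, keep) if k)
    if not keep.all():
        dropped = [n for n, k in zip(dataset.feature_names, keep) if not k]
        warnings.warn(f"dropping constant feature columns: {dropped}")
    scaler = StandardScaler()
    mat = scaler.fit_transform(dataset.matrix[:, keep])
    return LabeledDataset(
        matrix=mat, labels=dataset.labels, feature_names=names,
        provenance=dataset.provenance, scaler=scaler,
    )


def split(
    dataset: LabeledDataset, test_fraction: float = 0.30, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified shuffled train/test split."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    idx = np.arange(dataset.n_samples)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed,
        shuffle=True, stratify=dataset.labels,
    )
    def take(ii: np.ndarray) -> LabeledDataset:
        return LabeledDataset(
            matrix=dataset.matrix[ii],
            labels=dataset.labels[ii],
            feature_names=dataset.feature_names,
            provenance=None if dataset.provenance is None
            else dataset.provenance.iloc[ii].reset_index(drop=True),
            scaler=dataset.scaler,
        )
    return take(train_idx), take(test_idx)
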