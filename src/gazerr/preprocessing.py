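"""Missing-value imputation and outlier removal for gaze traces.

Raw fixation data contains dropouts (tracker lost the eyes) and isolated
out-of-range samples.  Three standard outlier rules are provided:

* 1-D median filtering with a centred window (default kernel 41, the mean
  number of samples recorded around each AOI dwell),
* the median-absolute-deviation (MAD) rule, flagging points further than
  ``mad_k`` MADs from the median,
* the IQR fence, flagging points beyond Q3 + 1.5*IQR or below Q1 - 1.5*IQR.

Flagged points are by default replaced with the series median rather than
dropped, so cleaned traces stay aligned with the ground-truth schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "CleaningConfig",
    "impute_missing",
    "median_filter_1d",
    "mad_outliers",
    "iqr_outliers",
    "clean_series",
    "clean_error_trace",
]


class EmptyDataError(ValueError):
    pass


@dataclass(frozen=True)
class CleaningConfig:
    method: str = "median_filter"          # median_filter | mad | iqr
    kernel_size: int = 41
    mad_k: float = 3.0
    iqr_k: float = 1.5                     # conventional fence multiplier
    replace_policy: str = "replace_with_median"   # or "drop"

    def __post_init__(self) -> None:
        if self.method not in ("median_filter", "mad", "iqr"):
            raise ValueError(f"unknown cleaning method {self.method!r}")
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 3")
        if self.mad_k <= 0:
            raise ValueError("mad_k must be positive")


def impute_missing(series: np.ndarray) -> np.ndarray:
    """Mean substitution: NaN entries replaced by the mean of the rest."""
    x = np.asarray(series, dtype=float).copy()
    missing = np.isnan(x)
    if missing.all():
        raise EmptyDataError("cannot impute an all-missing series")
    if missing.any():
        x[missing] = x[~missing].mean()
    return x


def median_filter_1d(series: np.ndarray, kernel_size: int = 41) -> np.ndarray:
    """Centred sliding median with reflect padding; output length = input."""
    if kernel_size % 2 == 0:
        raise ValueError("kernel_size must be odd")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise EmptyDataError("empty series")
    # 'mirror' matches np.pad reflect semantics (edge value not repeated)
    return ndimage.median_filter(x, size=kernel_size, mode="mirror")


def mad_outliers(
    series: np.ndarray, mad_k: float = 3.0, replace_policy: str = "replace_with_median"
) -> tuple[np.ndarray, np.ndarray]:
    """MAD rule: flag |x - median| > mad_k * MAD.

    Returns ``(mask, cleaned)`` where mask is True at flagged points.  A
    zero MAD on nonconstant data (more than half the points identical)
    would flag everything off-median, so that case flags nothing and warns.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for MAD flagging")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        if not np.all(x == x[0]):
            warnings.warn("MAD is zero on nonconstant data; no points flagged")
        mask = np.zeros(x.shape, dtype=bool)
    else:
        mask = np.abs(x - med) > mad_k * mad
    return mask, _apply_mask(x, mask, med, replace_policy)


def iqr_outliers(
    series: np.ndarray, iqr_k: float = 1.5, replace_policy: str = "replace_with_median"
) -> tuple[np.ndarray, np.ndarray]:
    """IQR fence with linear-interpolation quartiles."""
    x = np.asarray(series, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points for IQR flagging")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    mask = (x > q3 + iqr_k * iqr) | (x < q1 - iqr_k * iqr)
    return mask, _apply_mask(x, mask, np.median(x), replace_policy)


def _apply_mask(
    x: np.ndarray, mask: np.ndarray, median: float, replace_policy: str
) -> np.ndarray:
    if replace_policy == "drop":
        return x[~mask]
    if replace_policy == "replace_with_median":
        out = x.copy()
        out[mask] = median
        return out
    raise ValueError(f"unknown replace_policy {replace_policy!r}")


def clean_series(series: np.ndarray, cfg: CleaningConfig) -> np.ndarray:
    """Apply the configured outlier-removal method to one series."""
    if cfg.method == "median_filter":
        return median_filter_1d(series, cfg.kernel_size)
    if cfg.method == "mad":
        return mad_outliers(series, cfg.mad_k, cfg.replace_policy)[1]
    return iqr_outliers(series, cfg.iqr_k, cfg.replace_policy)[1]


def clean_error_trace(trace, cfg: CleaningConfig):
    """Clean all three angular-error components of an ErrorTrace."""
    return replace(
        trace,
        err_frontal=clean_series(trace.err_frontal, cfg),
        err_yaw=clean_series(trace.err_yaw, cfg),
        err_pitch=clean_series(trace.err_pitch, cfg),
    )
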