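"""Ten-fold augmentation of angular gaze-error traces.

Labelled gaze-error data is expensive to collect (20 participants per
operating condition), so each cleaned error trace is expanded into ten
variants before feature construction:

1. the original trace,
2. additive Gaussian noise, N(0, 0.2 deg),
3. additive pink-noise jitter (PSD ~ 1/f^0.8 above a 2 Hz cutoff),
   emulating fixational eye jitter,
4. a linear-interpolation resampled variant (half-sample offset),
5. raised-cosine (Hann, N = 30) smoothing,
6. a circular time shift by 10 samples,
7. interpolation + Gaussian noise,
8. interpolation + pink jitter,
9. horizontal flip (top AOI row swapped with bottom row),
10. vertical flip (AOI columns mirrored left-right).

The flips are defined on the error magnitudes of the 15 AOI dwells of a
5x3 stimulus grid; on a trace they permute whole dwell blocks, which
preserves the sample multiset and therefore all whole-trace statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, ndimage

__all__ = [
    "AugmentationConfig",
    "add_gaussian_noise",
    "add_pink_jitter",
    "pink_noise",
    "interpolate_variant",
    "raised_cosine_smooth",
    "hann_window",
    "time_shift",
    "flip_aoi",
    "aoi_flip_permutation",
    "augment_10x",
    "VARIANT_NAMES",
]

VARIANT_NAMES = (
    "original",
    "gaussian",
    "pink_jitter",
    "interpolated",
    "smoothed",
    "time_shifted",
    "interp_gaussian",
    "interp_jitter",
    "hflip",
    "vflip",
)


@dataclass(frozen=True)
class AugmentationConfig:
    noise_mean: float = 0.0
    noise_sigma: float = 0.2          # degrees
    pink_alpha: float = 0.8           # PSD ~ 1/f^alpha
    pink_cutoff_hz: float = 2.0       # shaping flat below this frequency
    sample_rate_hz: float = 41.0 / 3.0  # 41 samples per 3-s AOI dwell
    hann_N: int = 30
    shift_samples: int = 10
    aoi_rows: int = 3
    aoi_cols: int = 5

    def __post_init__(self) -> None:
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if self.hann_N < 2:
            raise ValueError("hann_N must be >= 2")


def add_gaussian_noise(
    trace: np.ndarray, cfg: AugmentationConfig, seed: int
) -> np.ndarray:
    """Perturb every point with i.i.d. N(noise_mean, noise_sigma^2)."""
    rng = np.random.default_rng(seed)
    x = np.asarray(trace, float)
    return x + rng.normal(cfg.noise_mean, cfg.noise_sigma, size=x.shape)


def pink_noise(
    n: int,
    sigma: float = 0.2,
    alpha: float = 0.8,
    cutoff_hz: float = 2.0,
    sample_rate_hz: float = 41.0 / 3.0,
    seed: int = 0,
) -> np.ndarray:
    """Zero-mean noise with power spectral density ~ 1/f^alpha above a cutoff.

    White Gaussian noise is shaped in the frequency domain: Fourier
    amplitudes are multiplied by (f / cutoff)^(-alpha/2) for f > cutoff and
    left flat below it, the DC bin is zeroed, and the result is rescaled to
    standard deviation ``sigma``.
    """
    if n < 64:
        raise ValueError("need at least 64 samples for spectral shaping")
    rng = np.random.default_rng(seed)
    white = rng.normal(0.0, sigma, size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    gain = np.ones_like(f)
    shaped = f > cutoff_hz
    gain[shaped] = (f[shaped] / cutoff_hz) ** (-alpha / 2.0)
    spec *= gain
    spec[0] = 0.0                       # exact zero mean
    out = np.fft.irfft(spec, n=n)
    sd = out.std()
    if sd > 0:
        out *= sigma / sd
    return out


def add_pink_jitter(
    trace: np.ndarray, cfg: AugmentationConfig, seed: int
) -> np.ndarray:
    """Add spectrally shaped fixational jitter to the trace."""
    x = np.asarray(trace, float)
    jitter = pink_noise(
        x.size,
        sigma=cfg.noise_sigma,
        alpha=cfg.pink_alpha,
        cutoff_hz=cfg.pink_cutoff_hz,
        sample_rate_hz=cfg.sample_rate_hz,
        seed=seed,
    )
    return x + jitter


def interpolate_variant(trace: np.ndarray) -> np.ndarray:
    """Half-sample-offset linear resampling mapped back to the input grid.

    The trace is sampled at midpoints between adjacent samples, then
    linearly interpolated (with extrapolation at the ends) back onto the
    original sample positions.  Linear inputs are reproduced exactly;
    anything else is gently smoothed.
    """
    x = np.asarray(trace, float)
    if x.size < 2:
        raise ValueError("need at least 2 points to interpolate")
    pos = np.arange(x.size, dtype=float)
    mids = pos[:-1] + 0.5
    vals = np.interp(mids, pos, x)
    back = interpolate.interp1d(mids, vals, kind="linear", fill_value="extrapolate")
    return back(pos)


def hann_window(N: int) -> np.ndarray:
    """Raised cosine w(n) = 0.5*(1 - cos(2*pi*n/(N-1))), n = 0..N-1."""
    n = np.arange(N)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * n / (N - 1)))


def raised_cosine_smooth(trace: np.ndarray, hann_N: int = 30) -> np.ndarray:
    """Convolve with a unit-sum raised-cosine kernel (mirror-padded edges)."""
    x = np.asarray(trace, float)
    if x.size < hann_N:
        raise ValueError(f"trace length {x.size} shorter than window {hann_N}")
    w = hann_window(hann_N)
    w = w / w.sum()
    return ndimage.convolve1d(x, w, mode="mirror")


def time_shift(trace: np.ndarray, shift_samples: int = 10) -> np.ndarray:
    """Circular shift; preserves length and the value multiset."""
    x = np.asarray(trace, float)
    if shift_samples >= x.size:
        raise ValueError("shift must be smaller than the trace length")
    return np.roll(x, shift_samples)


def aoi_flip_permutation(axis: str, rows: int = 3, cols: int = 5) -> np.ndarray:
    """Index permutation of the row-major AOI grid under a flip.

    ``horizontal`` swaps the top AOI row with the bottom row (errors at the
    top of the screen replaced by those at the bottom); ``vertical``
    mirrors the columns left-right.
    """
    grid = np.arange(rows * cols).reshape(rows, cols)
    if axis == "horizontal":
        flipped = grid[::-1, :]
    elif axis == "vertical":
        flipped = grid[:, ::-1]
    else:
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    return flipped.ravel()


def flip_aoi(
    per_aoi_errors: np.ndarray, axis: str, rows: int = 3, cols: int = 5
) -> np.ndarray:
    """Flip a per-AOI error vector (row-major AOI-1..AOI-15) on the grid."""
    v = np.asarray(per_aoi_errors, float)
    if v.size != rows * cols:
        raise ValueError(f"expected {rows * cols} AOI entries, got {v.size}")
    return v[aoi_flip_permutation(axis, rows, cols)]


def _flip_trace(
    trace: np.ndarray, aoi_index: np.ndarray, axis: str, rows: int, cols: int
) -> np.ndarray:
    """Permute dwell blocks of a trace according to an AOI flip."""
    perm = aoi_flip_permutation(axis, rows, cols)
    out = np.empty_like(np.asarray(trace, float))
    idx = np.asarray(aoi_index)
    for k in range(rows * cols):
        out[idx == k + 1] = trace[idx == perm[k] + 1]
    return out


def augment_10x(
    trace: np.ndarray,
    cfg: AugmentationConfig,
    seed: int,
    aoi_index: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Produce the fixed ten-variant expansion of one error trace.

    Returns an ordered mapping variant-name -> trace; every variant has the
    input's length.  The two flip variants require ``aoi_index`` (per-sample
    AOI assignment); with balanced dwell blocks they permute whole blocks.
    Deterministic for a fixed seed.
    """
    x = np.asarray(trace, float)
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)
    interp = interpolate_variant(x)
    variants: dict[str, np.ndarray] = {
        "original": x.copy(),
        "gaussian": add_gaussian_noise(x, cfg, int(sub[0])),
        "pink_jitter": add_pink_jitter(x, cfg, int(sub[1])),
        "interpolated": interp,
        "smoothed": raised_cosine_smooth(x, cfg.hann_N),
        "time_shifted": time_shift(x, cfg.shift_samples),
        "interp_gaussian": add_gaussian_noise(interp, cfg, int(sub[2])),
        "interp_jitter": add_pink_jitter(interp, cfg, int(sub[3])),
    }
    if aoi_index is not None:
        variants["hflip"] = _flip_trace(x, aoi_index, "horizontal",
                                        cfg.aoi_rows, cfg.aoi_cols)
        variants["vflip"] = _flip_trace(x, aoi_index, "vertical",
                                        cfg.aoi_rows, cfg.aoi_cols)
    else:
        # Without an AOI schedule the flips degenerate to whole-trace
        # reversal surrogates; feature-level flips still use flip_aoi.
        variants["hflip"] = x[::-1].copy()
        variants["vflip"] = x[::-1].copy()
    return variants
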