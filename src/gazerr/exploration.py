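"""Descriptive analytics for gaze-error data.

Kernel density estimates of error distributions, spatial maps of error
over the visual field, cross-condition correlation, 2-D embedding of the
feature space, and impurity-based feature ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE

from .features import LabeledDataset

__all__ = [
    "KDEConfig",
    "kde_density",
    "spatial_error_map",
    "correlation_matrix",
    "embed_2d",
    "rank_features",
]


@dataclass(frozen=True)
class KDEConfig:
    bandwidth: float = 0.2          # degrees
    grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


def kde_density(values: np.ndarray, cfg: KDEConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate on a grid.

    f(x) = 1/(n*h) * sum_i K((x - x_i)/h) with the standard normal kernel
    K(u) = exp(-u^2/2)/sqrt(2*pi).  The bandwidth is in data units
    (degrees), fixed rather than data-adaptive.  Returns (grid, density).
    """
    if cfg is None:
        cfg = KDEConfig()
    x = np.asarray(values, float)
    if x.size == 0:
        raise ValueError("empty input")
    h = cfg.bandwidth
    if cfg.grid is None:
        lo, hi = x.min() - 4 * h, x.max() + 4 * h
        grid = np.linspace(lo, hi, 512)
    else:
        grid = np.asarray(cfg.grid, float)
    u = (grid[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * u * u).sum(axis=1) / (np.sqrt(2 * np.pi) * x.size * h)
    return grid, dens


def spatial_error_map(
    err_values: np.ndarray,
    yaw_deg: np.ndarray,
    pitch_deg: np.ndarray,
    bins: int | tuple[int, int] = 15,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean |error| binned over the (yaw, pitch) visual field.

    Returns (grid, yaw_edges, pitch_edges); cells without samples are NaN.
    Grid rows index yaw bins, columns pitch bins.
    """
    result = sstats.binned_statistic_2d(
        np.asarray(yaw_deg, float),
        np.asarray(pitch_deg, float),
        np.abs(np.asarray(err_values, float)),
        statistic="mean",
        bins=bins,
    )
    return result.statistic, result.x_edge, result.y_edge


def correlation_matrix(datasets: dict[str, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    """Pearson correlations between error series from different conditions.

    Series are truncated to the shortest length.  A zero-variance series
    yields NaN entries (flagged, not raised).  Returns (matrix, names).
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    names = list(datasets)
    n = min(len(v) for v in datasets.values())
    mat = np.vstack([np.asarray(datasets[k], float)[:n] for k in names])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    np.fill_diagonal(corr, 1.0)
    return corr, names


def embed_2d(
    features: np.ndarray, perplexity: float = 80.0, seed: int = 0
) -> np.ndarray:
    """t-SNE embedding of a standardized feature matrix onto 2 components.

    Visualization-only: the contract is the output shape, determinism
    under a fixed seed, and qualitative cluster preservation.
    """
    x = np.asarray(features, float)
    if x.shape[0] <= 3 * perplexity:
        raise ValueError(
            f"need more than {3 * perplexity:.0f} samples for perplexity {perplexity}"
        )
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(x)


def rank_features(
    dataset: LabeledDataset, n_estimators: int = 200, max_depth: int = 8,
    seed: int = 0,
) -> np.ndarray:
    """Mean impurity-decrease feature importances from a random forest.

    Importances are nonnegative and sum to 1; higher means the feature
    contributes more to separating the condition classes.
    """
    if len(set(map(str, dataset.labels))) < 2:
        raise ValueError("need at least two classes to rank features")
    # max_features=None: every split sees all features, so importances are
    # permutation-equivariant and depend only on the bootstrap draws
    forest = RandomForestClassifier(
        n_estimators=n_estimators, max_depth=max_depth, random_state=seed,
        max_features=None,
    )
    forest.fit(dataset.matrix, dataset.labels)
    return forest.feature_importances_
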