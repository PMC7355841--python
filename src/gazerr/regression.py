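"""Gaze-error prediction models.

Maps standardized gaze angular variables [gaze angle, gaze yaw, gaze
pitch] to the gaze-error magnitude with six regression families: ordinary
least squares, polynomial, Ridge, Lasso, ElasticNet and an MLP.  The
regularized linear fits minimise

    || Xw - y ||^2 + z1 ||w||_1 + z2 ||w||_2^2

with default overall strength 0.001 and, for ElasticNet, an L1 mixing
ratio of 0.5.  The target is centred before fitting (its mean is carried
in the model), so fitted intercepts are numerically zero and the model is
the affine form  Y = B0 + B1*X1 + B2*X2 + B3*X3  on standardized inputs.

``load_reference_models`` bundles pre-fitted ElasticNet coefficients for
eight operating conditions (desktop head poses and tablet platform poses)
so error prediction is available without any training data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

from .geometry import AngularTrace, ErrorTrace

__all__ = [
    "RegressionSpec",
    "ErrorModel",
    "FitReport",
    "build_regression_features",
    "fit_error_model",
    "predict_error",
    "rmse",
    "load_reference_models",
    "REGRESSION_KINDS",
]

REGRESSION_KINDS = ("linear", "polynomial", "ridge", "lasso", "elasticnet", "mlp")


@dataclass(frozen=True)
class RegressionSpec:
    kind: str = "elasticnet"
    penalty: float = 0.001            # overall regularization strength z
    elastic_l1_ratio: float = 0.5     # L1 mixing for elasticnet
    poly_degree: int = 2
    mlp_hidden: tuple[int, ...] = (100,)
    mlp_alpha: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in REGRESSION_KINDS:
            raise ValueError(f"unknown regression kind {self.kind!r}")
        if self.penalty < 0 or self.poly_degree < 1:
            raise ValueError("invalid regression hyperparameters")


@dataclass
class ErrorModel:
    """Affine gaze-error predictor on standardized angular inputs."""

    b0: float
    b: np.ndarray                     # 3 coefficients (gaze, yaw, pitch)
    condition: str = ""
    feature_means: np.ndarray | None = None
    feature_sds: np.ndarray | None = None
    y_offset: float = 0.0             # mean of the (centred) target

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, float)
        if self.b.shape != (3,):
            raise ValueError("expected exactly 3 coefficients")
        if not np.isfinite(self.b).all() or not np.isfinite(self.b0):
            raise ValueError("coefficients must be finite")


@dataclass
class FitReport:
    kind: str
    rmse: float
    estimator: object = None

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse cannot be negative")


def build_regression_features(
    ang: AngularTrace, err: ErrorTrace, signed: bool = False
) -> tuple[np.ndarray, np.ndarray, StandardScaler]:
    """Standardized design matrix (gaze, yaw, pitch angles) and target.

    The target is the frontal error magnitude (or the signed error with
    ``signed=True``).  Returns (X_std, y, fitted scaler); the scaler's
    inverse transform recovers the raw angles.
    """
    if len(ang) != len(err):
        raise ValueError("angular and error traces are misaligned")
    raw = np.column_stack([ang.theta_gaze, ang.theta_yaw, ang.theta_pitch])
    if np.any(raw.std(axis=0) == 0):
        raise ValueError("constant angular column; cannot standardize")
    scaler = StandardScaler()
    x = scaler.fit_transform(raw)
    y = err.err_frontal if signed else np.abs(err.err_frontal)
    return x, np.asarray(y, float), scaler


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared prediction error."""
    yt = np.asarray(y_true, float)
    yp = np.asarray(y_pred, float)
    if yt.shape != yp.shape:
        raise ValueError("length mismatch")
    if yt.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((yp - yt) ** 2)))


def _make_estimator(spec: RegressionSpec):
    if spec.kind == "linear":
        return LinearRegression()
    if spec.kind == "polynomial":
        return make_pipeline(
            PolynomialFeatures(spec.poly_degree, include_bias=False),
            LinearRegression(),
        )
    if spec.kind == "ridge":
        return Ridge(alpha=spec.penalty, random_state=spec.seed)
    if spec.kind == "lasso":
        return Lasso(alpha=spec.penalty, max_iter=50_000)
    if spec.kind == "elasticnet":
        return ElasticNet(alpha=spec.penalty, l1_ratio=spec.elastic_l1_ratio,
                          max_iter=50_000)
    return MLPRegressor(
        hidden_layer_sizes=spec.mlp_hidden, alpha=spec.mlp_alpha,
        activation="relu", solver="adam", learning_rate_init=0.001,
        max_iter=2000, random_state=spec.seed,
    )


def fit_error_model(
    x: np.ndarray, y: np.ndarray, spec: RegressionSpec | None = None,
    condition: str = "",
) -> tuple[ErrorModel | None, FitReport]:
    """Fit one regression family on standardized features.

    The target is centred before fitting so linear-family intercepts are
    ~0; the target mean is stored as ``y_offset`` and added back in
    prediction.  For the polynomial and MLP kinds no 3-coefficient affine
    model exists, so the ErrorModel slot is None and predictions go
    through the FitReport's estimator.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("x must be n x p aligned with y")
    if x.shape[0] <= 3:
        raise ValueError("need more than 3 observations")
    if spec is None:
        spec = RegressionSpec()
    y_mean = float(y.mean())
    yc = y - y_mean
    est = _make_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if spec.kind == "linear" and np.linalg.matrix_rank(x) < x.shape[1]:
            warnings.warn("singular design matrix; OLS fit is not unique")
        est.fit(x, yc)
    pred = est.predict(x) + y_mean
    report = FitReport(kind=spec.kind, rmse=rmse(y, pred), estimator=est)
    model = None
    if spec.kind in ("linear", "ridge", "lasso", "elasticnet") and x.shape[1] == 3:
        model = ErrorModel(
            b0=float(est.intercept_), b=np.asarray(est.coef_, float),
            condition=condition, y_offset=y_mean,
        )
    return model, report


def predict_error(model: ErrorModel, x_std: np.ndarray) -> np.ndarray:
    """Affine evaluation Y = B0 + B1*X1 + B2*X2 + B3*X3 (+ target offset)."""
    x = np.atleast_2d(np.asarray(x_std, float))
    if x.shape[1] != 3:
        raise ValueError(f"expected 3 columns, got {x.shape[1]}")
    return model.b0 + model.y_offset + x @ model.b


# Pre-fitted ElasticNet coefficients (B1, B2, B3; intercept B0) of the
# best error model per operating condition, on standardized
# (gaze angle, gaze yaw, gaze pitch) inputs with a centred target.
_REFERENCE_COEFFICIENTS = {
    "desktop_neutral": ([0.09336917, 0.19406989, -0.00279198], -1.99912371e-16),
    "desktop_roll20": ([0.0, 0.65189252, 0.07303053], 3.23942926e-16),
    "desktop_pitch20": ([0.22606558, 0.11028886, 0.05731872], -9.55229176e-17),
    "desktop_yaw20": ([0.0, 0.51352565, 0.08149052], 8.94037155e-17),
    "tablet_neutral": ([0.07333954, 0.0, -0.17956056], 1.76076146e-16),
    "tablet_roll20": ([0.0, -0.31460996, -0.23620848], -2.87637414e-16),
    "tablet_pitch20": ([0.0, -0.05682588, -0.20804325], 2.34007877e-16),
    "tablet_yaw20": ([0.0, -0.01596391, -0.06346607], -2.41027682e-17),
}


def load_reference_models() -> dict[str, ErrorModel]:
    """The eight bundled pose error models (desktop head poses, tablet
    platform poses), keyed ``<platform>_<condition>``."""
    return {
        name: ErrorModel(b0=b0, b=np.array(coefs), condition=name)
        for name, (coefs, b0) in _REFERENCE_COEFFICIENTS.items()
    }
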