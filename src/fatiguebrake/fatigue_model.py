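"""Ridge regression of subjective fatigue on spectral EEG features.

The model is ordinary L2-penalized linear regression solved analytically
through its normal equations, appropriate for the very small designs this
package targets (n in the tens, p = 3). Two conventions are supported,
selected by two orthogonal switches:

``standardize``
    z-score the feature columns and the response before solving (the
    textbook presentation for comparable coefficients).
``loss``
    ``"sum"`` penalizes the summed squared error, i.e. solves
    ``(X'X + alpha I) beta = X'y``;
    ``"mean"`` penalizes the mean squared error, i.e. solves
    ``(X'X/n + alpha I) beta = X'y/n``. The two differ only by rescaling
    alpha by n, but published alphas are meaningless without knowing which
    was used. The mean-loss form on raw features is the convention under
    which this package reproduces the printed study model (see the study
    reproduction report); it is therefore the default.

The intercept is never penalized: it is recovered from the training means
after solving on centered data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DesignMatrix",
    "FatigueModel",
    "ridge_fit",
    "ridge_predict",
    "kfold_cv",
    "cv_predictions",
    "select_alpha",
]

_METRICS = ("mae", "rmse", "mse")


@dataclass
class DesignMatrix:
    """An ``n x p`` feature matrix with aligned responses and session keys."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    keys: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y row counts differ")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match X columns")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("design matrix must not contain missing values")
        if not self.keys:
            self.keys = list(range(self.y.size))

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "DesignMatrix":
        idx = np.asarray(idx)
        return DesignMatrix(self.X[idx], self.y[idx], list(self.feature_names),
                            [self.keys[i] for i in idx])


@dataclass
class FatigueModel:
    """A fitted ridge model with its scaling frozen at training time.

    ``beta`` holds the coefficients on the model's working scale (the scale
    the normal equations were solved on: z-scores if ``standardize``,
    original units otherwise); ``beta0`` is the intercept on the original
    response scale, so ``predict`` always maps original-scale features to
    original-scale fatigue scores.
    """

    beta: np.ndarray
    alpha: float
    feature_names: list[str]
    feature_means: np.ndarray
    feature_scales: np.ndarray
    y_mean: float
    y_scale: float
    standardize: bool
    loss: str

    @property
    def coefficients_raw(self) -> np.ndarray:
        """Slopes in original units (response units per feature unit)."""
        return self.beta * self.y_scale / self.feature_scales

    @property
    def beta0(self) -> float:
        """Intercept on the original response scale."""
        return float(self.y_mean - self.feature_means @ self.coefficients_raw)

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features "
                f"({self.feature_names}), got {X.shape[1]}"
            )
        return X @ self.coefficients_raw + self.beta0

    # ------------------------------------------------------------- serialization
    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "alpha": self.alpha,
            "standardize": self.standardize,
            "loss": self.loss,
            "beta": self.beta.tolist(),
            "beta0": self.beta0,
            "feature_means": self.feature_means.tolist(),
            "feature_scales": self.feature_scales.tolist(),
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FatigueModel":
        d = json.loads(Path(path).read_text())
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            alpha=float(d["alpha"]),
            feature_names=list(d["feature_names"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_scales=np.asarray(d["feature_scales"], dtype=float),
            y_mean=float(d["y_mean"]),
            y_scale=float(d["y_scale"]),
            standardize=bool(d["standardize"]),
            loss=str(d["loss"]),
        )


def ridge_fit(
    dm: DesignMatrix,
    alpha: float = 0.1,
    standardize: bool = False,
    loss: str = "mean",
) -> FatigueModel:
    """Solve the ridge normal equations analytically.

    With ``alpha = 0`` this is exactly least squares (and raises a
    diagnostic if the design is rank deficient, suggesting ``alpha > 0``).
    As ``alpha`` grows all slopes shrink toward zero; the unpenalized
    intercept then approaches the training response mean.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if loss not in ("sum", "mean"):
        raise ValueError(f"loss must be 'sum' or 'mean', got {loss!r}")

    mx = dm.X.mean(axis=0)
    my = float(dm.y.mean())
    if standardize:
        sx = dm.X.std(axis=0, ddof=1)
        if np.any(sx == 0):
            dead = [n for n, s in zip(dm.feature_names, sx) if s == 0]
            raise ValueError(f"cannot standardize constant features {dead}")
        sy = float(dm.y.std(ddof=1))
        if sy == 0:
            raise ValueError("cannot standardize a constant response")
    else:
        sx = np.ones(dm.p)
        sy = 1.0

    Z = (dm.X - mx) / sx
    yc = (dm.y - my) / sy
    gram = Z.T @ Z
    rhs = Z.T @ yc
    if loss == "mean":
        gram = gram / dm.n
        rhs = rhs / dm.n

    system = gram + alpha * np.eye(dm.p)
    if alpha == 0:
        rank = np.linalg.matrix_rank(gram)
        if rank < dm.p:
            raise np.linalg.LinAlgError(
                f"normal equations are singular at alpha=0 (rank {rank} < {dm.p}); "
                "use alpha > 0"
            )
    beta = np.linalg.solve(system, rhs)
    return FatigueModel(
        beta=beta, alpha=float(alpha), feature_names=list(dm.feature_names),
        feature_means=mx, feature_scales=sx, y_mean=my, y_scale=sy,
        standardize=standardize, loss=loss,
    )


def ridge_predict(model: FatigueModel, x) -> np.ndarray:
    """Predicted fatigue score(s) for original-scale feature vector(s)."""
    return model.predict(x)


def _metric(err: np.ndarray, metric: str) -> float:
    if metric == "mae":
        return float(np.mean(np.abs(err)))
    if metric == "rmse":
        return float(np.sqrt(np.mean(err**2)))
    if metric == "mse":
        return float(np.mean(err**2))
    raise ValueError(f"metric must be one of {_METRICS}, got {metric!r}")


def _folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} folds cannot exceed n={n} rows")
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(n), k)


def kfold_cv(
    dm: DesignMatrix,
    alpha: float = 0.1,
    k: int = 5,
    metric: str = "mae",
    seed: int | None = None,
    standardize: bool = False,
    loss: str = "mean",
) -> float:
    """Mean held-out error over a random k-fold partition.

    Rows are shuffled with ``seed`` and split into ``k`` near-equal folds;
    each fold is scored by a model fit on the remaining folds (all scaling
    parameters re-estimated on the training folds only), and the fold errors
    are averaged.
    """
    if seed is None:
        raise ValueError("an explicit fold-shuffle seed is required")
    errors = []
    for fold in _folds(dm.n, k, seed):
        train = np.setdiff1d(np.arange(dm.n), fold)
        model = ridge_fit(dm.subset(train), alpha, standardize=standardize, loss=loss)
        err = model.predict(dm.X[fold]) - dm.y[fold]
        errors.append(_metric(err, metric))
    return float(np.mean(errors))


def cv_predictions(
    dm: DesignMatrix,
    alpha: float = 0.1,
    k: int = 5,
    seed: int | None = None,
    standardize: bool = False,
    loss: str = "mean",
) -> np.ndarray:
    """Pooled out-of-fold predictions for every row (for CV fit diagnostics)."""
    if seed is None:
        raise ValueError("an explicit fold-shuffle seed is required")
    pred = np.empty(dm.n)
    for fold in _folds(dm.n, k, seed):
        train = np.setdiff1d(np.arange(dm.n), fold)
        model = ridge_fit(dm.subset(train), alpha, standardize=standardize, loss=loss)
        pred[fold] = model.predict(dm.X[fold])
    return pred


def select_alpha(
    dm: DesignMatrix,
    grid,
    k: int = 5,
    seed: int | None = None,
    standardize: bool = False,
    loss: str = "mean",
) -> float:
    """Grid value minimizing mean CV MSE; ties resolve to the smaller alpha.

    The same fold assignment (from ``seed``) is reused for every candidate
    so the comparison is paired.
    """
    grid = sorted(float(a) for a in grid)
    if not grid:
        raise ValueError("alpha grid must be non-empty")
    if len(set(grid)) != len(grid):
        raise ValueError("alpha grid values must be distinct")
    scores = [
        kfold_cv(dm, a, k=k, metric="mse", seed=seed, standardize=standardize, loss=loss)
        for a in grid
    ]
    return grid[int(np.argmin(scores))]  # argmin takes the first = smallest alpha
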