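"""Regression of spirometry from regional PRM features.

Two model families map the 76-feature vector (72 regional PRM parameters
plus age, sex, height, weight) to a spirometry target, either FEV1/FVC or
FEV1% predicted, both as fractions:

* ``random_forest`` - a random forest with 500 trees, unlimited depth and
  ceil(p/3) candidate features per split;
* ``mlp`` - a two-hidden-layer (64, 32) ReLU perceptron on standardized
  inputs with early stopping on 10% of the training data.

Both are wrapped in a single scikit-learn estimator, :class:`PFTRegressor`,
so they compose with pipelines and model selection.  Predictions are clipped
to the physiologically valid domain (0, 1.6].
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .prm import feature_names

__all__ = ["PFTRegressor", "split_train_validation", "train_regressor",
           "FEATURE_COLUMNS", "TARGETS", "PFT_DOMAIN"]

#: the 76 model inputs, in order
FEATURE_COLUMNS: list[str] = feature_names() + ["age", "sex", "height", "weight"]
TARGETS = ("fev1_fvc", "fev1_pct")
#: valid half-open prediction domain (0, 1.6]
PFT_DOMAIN = (1e-3, 1.6)


class PFTRegressor(RegressorMixin, BaseEstimator):
    """Spirometry regressor over PRM + clinical features.

    Parameters
    ----------
    family : {"random_forest", "mlp"}
    n_estimators : int
        Trees in the forest (random_forest only).
    max_depth : int or None
        Tree depth limit (random_forest only; None = grow fully).
    max_features : int, float, str or None
        Features per split; None picks ceil(p / 3) at fit time.
    hidden_layer_sizes, max_iter : MLP architecture / iteration cap.
    clip : (low, high)
        Predictions are clipped into this interval.
    random_state : int or None

    Attributes
    ----------
    model_ : the fitted underlying scikit-learn estimator
    feature_names_in_ : column names seen at fit (DataFrame input only)
    feature_importances_ : impurity importances (random_forest)
    loss_curve_ : training loss per epoch (mlp)
    """

    def __init__(
        self,
        family: str = "random_forest",
        n_estimators: int = 500,
        max_depth: int | None = None,
        max_features: int | float | str | None = None,
        bootstrap: bool = True,
        hidden_layer_sizes: tuple[int, ...] = (64, 32),
        max_iter: int = 2000,
        clip: tuple[float, float] = PFT_DOMAIN,
        random_state: int | None = None,
    ):
        self.family = family
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.bootstrap = bootstrap
        self.hidden_layer_sizes = hidden_layer_sizes
        self.max_iter = max_iter
        self.clip = clip
        self.random_state = random_state

    def _validate_X(self, X, reset: bool):
        if isinstance(X, pd.DataFrame):
            if reset:
                self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            elif hasattr(self, "feature_names_in_"):
                seen = list(X.columns)
                expected = list(self.feature_names_in_)
                if seen != expected:
                    missing = sorted(set(expected) - set(seen))
                    extra = sorted(set(seen) - set(expected))
                    raise ValueError(
                        "feature columns do not match training layout: "
                        f"missing {missing}, unexpected {extra}"
                    )
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_samples, n_features)")
        if reset:
            self.n_features_in_ = X.shape[1]
        elif X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values; drop or impute rows first")
        return X

    def fit(self, X, y):
        """Fit the chosen family to features X and a spirometry target y."""
        X = self._validate_X(X, reset=True)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y lengths differ")
        if not np.isfinite(y).all():
            raise ValueError("targets contain non-finite values")
        if self.family == "random_forest":
            max_features = self.max_features
            if max_features is None:
                max_features = max(1, math.ceil(X.shape[1] / 3))
            self.model_ = RandomForestRegressor(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                max_features=max_features,
                bootstrap=self.bootstrap,
                random_state=self.random_state,
                n_jobs=1,
            )
        elif self.family == "mlp":
            self.model_ = make_pipeline(
                StandardScaler(),
                MLPRegressor(
                    hidden_layer_sizes=self.hidden_layer_sizes,
                    activation="relu",
                    early_stopping=True,
                    validation_fraction=0.1,
                    max_iter=self.max_iter,
                    random_state=self.random_state,
                ),
            )
        else:
            raise ValueError(f"unknown model family {self.family!r}")
        self.model_.fit(X, y)
        if self.family == "random_forest":
            self.feature_importances_ = self.model_.feature_importances_
        else:
            self.loss_curve_ = np.asarray(self.model_[-1].loss_curve_)
        return self

    def predict(self, X):
        """Predict the target, clipped to the valid spirometry domain."""
        check_is_fitted(self, "model_")
        X = self._validate_X(X, reset=False)
        lo, hi = self.clip
        return np.clip(self.model_.predict(X), lo, hi)


def split_train_validation(
    cohort: pd.DataFrame,
    seed: int = 0,
    sizes: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded disjoint, exhaustive train/validation split of a cohort table.

    By default the validation set holds ``round(n / 5)`` subjects (a 4:1
    split).  ``sizes=(n_train, n_val)`` overrides the rule exactly - studies
    sometimes report splits that are not exactly 4:1 (e.g. 494/121 of 615) -
    and must sum to ``len(cohort)``.
    """
    n = len(cohort)
    if n < 5:
        raise ValueError("need at least 5 rows to split 4:1")
    if sizes is not None:
        n_train, n_val = sizes
        if n_train + n_val != n:
            raise ValueError(f"explicit sizes {sizes} do not sum to n={n}")
    else:
        n_val = int(round(n / 5))
        n_train = n - n_val
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx, val_idx = np.sort(order[:n_train]), np.sort(order[n_train:])
    return cohort.iloc[train_idx], cohort.iloc[val_idx]


def train_regressor(
    cohort: pd.DataFrame,
    target: str,
    family: str = "random_forest",
    seed: int = 0,
    **params,
) -> PFTRegressor:
    """Fit a :class:`PFTRegressor` on a cohort table's feature columns."""
    if target not in TARGETS:
        raise ValueError(f"target must be one of {TARGETS}")
    model = PFTRegressor(family=family, random_state=seed, **params)
    return model.fit(cohort[FEATURE_COLUMNS], cohort[target])
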