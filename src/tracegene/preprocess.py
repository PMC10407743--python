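"""Feature preprocessing: iterative imputation, symmetrizing power transform,
and per-feature scaling to [-1, 1].

The imputer follows the chained-equations recipe: initialize every missing
cell with the feature median, then revisit each incomplete feature — in a
deterministic order of ascending missingness — and re-predict its originally
missing cells with a Bayesian ridge regression on its 100 most correlated
features, repeating for a fixed number of sweeps. Observed cells never
change. The fitted state (medians, neighbor lists, ridge coefficients, power
-transform lambdas, min/max) transforms held-out genes with training-time
parameters only, which is what keeps patient candidates leakage-free.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import PowerTransformer

from .feature_table import FeatureTable

logger = logging.getLogger(__name__)

DEFAULT_TRANSFORM_FAMILIES = ("expression", "preferential_expression")


def bayesian_ridge(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-3,
    eps: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Evidence-maximization Bayesian ridge (coef, intercept).

    Same model and hyperpriors as the scikit-learn estimator (alpha_1 =
    alpha_2 = lambda_1 = lambda_2 = 1e-6), implemented through the
    eigendecomposition of the Gram matrix so repeated fits inside the
    imputation sweeps stay cheap.
    """
    n, d = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    G = Xc.T @ Xc
    s, V = np.linalg.eigh(G)
    s = np.maximum(s, 0.0)
    b = V.T @ (Xc.T @ yc)
    yty = float(yc @ yc)

    alpha = 1.0 / (np.var(y) + 1e-12)
    lam = 1.0
    coef_old = None
    coef = np.zeros(d)
    for _ in range(max_iter):
        c = b / (s + lam / alpha)
        coef = V @ c
        rmse = yty - 2.0 * float(b @ c) + float(s @ (c * c))
        rmse = max(rmse, 0.0)
        gamma = float(np.sum(alpha * s / (lam + alpha * s)))
        lam = (gamma + 2.0 * eps) / (float(coef @ coef) + 2.0 * eps)
        alpha = (n - gamma + 2.0 * eps) / (rmse + 2.0 * eps)
        if coef_old is not None and np.sum(np.abs(coef - coef_old)) < tol:
            break
        coef_old = coef.copy()
    c = b / (s + lam / alpha)
    coef = V @ c
    intercept = y_mean - float(x_mean @ coef)
    return coef, intercept


class TracePreprocessor(BaseEstimator, TransformerMixin):
    """Impute, power-transform and scale a feature table.

    Parameters
    ----------
    n_iterations : sweeps of the chained-equation imputer (default 10).
    n_neighbors : predictor features per imputed feature (default 100),
        chosen by largest absolute Pearson correlation on the
        median-initialized matrix.
    transform_families : feature families passed through a per-feature
        Yeo-Johnson transform (maximum-likelihood lambda).

    Fitted attributes end with an underscore; ``fit_transform`` returns the
    training table processed with the training-time loop, while ``transform``
    applies the frozen state to new (held-out) genes.
    """

    def __init__(
        self,
        n_iterations: int = 10,
        n_neighbors: int = 100,
        transform_families: tuple[str, ...] = DEFAULT_TRANSFORM_FAMILIES,
        seed: int = 0,
    ) -> None:
        self.n_iterations = n_iterations
        self.n_neighbors = n_neighbors
        self.transform_families = transform_families
        self.seed = seed

    # -- imputation ---------------------------------------------------------

    def _fit_impute(self, values: pd.DataFrame) -> np.ndarray:
        M = values.values.astype(float).copy()
        n, d = M.shape
        self.medians_ = np.nanmedian(M, axis=0)
        miss = np.isnan(M)
        for j in range(d):
            M[miss[:, j], j] = self.medians_[j]

        frac_missing = miss.mean(axis=0)
        targets = [j for j in range(d) if miss[:, j].any()]
        if targets and d > 1:
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.atleast_2d(np.corrcoef(M, rowvar=False))
            np.fill_diagonal(corr, 0.0)
            corr = np.nan_to_num(corr, nan=0.0)
        else:
            corr = np.zeros((d, d))
        targets.sort(key=lambda j: (frac_missing[j], values.columns[j]))
        self.visit_order_ = [values.columns[j] for j in targets]

        self.neighbors_: dict[str, np.ndarray] = {}
        self.models_: dict[str, tuple[np.ndarray, float] | None] = {}
        k = min(self.n_neighbors, d - 1)
        for j in targets:
            name = values.columns[j]
            a = np.abs(corr[:, j])
            order = np.lexsort((np.arange(d), -a))
            self.neighbors_[name] = order[:k]

        self.iteration_deltas_: list[float] = []
        for it in range(self.n_iterations):
            deltas = []
            for j in targets:
                name = values.columns[j]
                obs = ~miss[:, j]
                y = M[obs, j]
                if np.ptp(y) == 0:  # constant feature: median fill only
                    self.models_[name] = None
                    continue
                nb = self.neighbors_[name]
                coef, intercept = bayesian_ridge(M[obs][:, nb], y)
                self.models_[name] = (coef, intercept)
                new = M[miss[:, j]][:, nb] @ coef + intercept
                deltas.append(float(np.mean(np.abs(new - M[miss[:, j], j]))))
                M[miss[:, j], j] = new
            self.iteration_deltas_.append(float(np.mean(deltas)) if deltas else 0.0)
        return M

    def _apply_impute(self, values: pd.DataFrame) -> np.ndarray:
        M = values.values.astype(float).copy()
        miss = np.isnan(M)
        cols = list(values.columns)
        col_pos = {c: i for i, c in enumerate(cols)}
        for i, c in enumerate(cols):
            M[miss[:, i], i] = self.medians_[i]
        for _ in range(self.n_iterations):
            for name in self.visit_order_:
                j = col_pos[name]
                if not miss[:, j].any():
                    continue
                model = self.models_.get(name)
                if model is None:
                    continue
                coef, intercept = model
                nb = self.neighbors_[name]
                M[miss[:, j], j] = M[miss[:, j]][:, nb] @ coef + intercept
        return M

    # -- transform + scale --------------------------------------------------

    def _fit_power(self, M: np.ndarray, table: FeatureTable) -> np.ndarray:
        fam = table.meta["family"].values
        self.power_columns_ = np.where(np.isin(fam, self.transform_families))[0]
        self.power_ok_: list[int] = []
        self.lambdas_: dict[int, float] = {}
        out = M.copy()
        for j in self.power_columns_:
            pt = PowerTransformer(method="yeo-johnson", standardize=False)
            try:
                col = pt.fit_transform(M[:, j : j + 1])
                lam = float(pt.lambdas_[0])
                if not np.isfinite(col).all() or not np.isfinite(lam):
                    raise ValueError("non-finite transform")
            except Exception:  # noqa: BLE001 - lambda fit failure leaves feature as-is
                logger.warning(
                    "Yeo-Johnson fit failed for feature %s; left untransformed",
                    table.features[j],
                )
                continue
            out[:, j] = col[:, 0]
            self.power_ok_.append(int(j))
            self.lambdas_[int(j)] = lam
        return out

    @staticmethod
    def _yeo_johnson(x: np.ndarray, lam: float) -> np.ndarray:
        out = np.empty_like(x, dtype=float)
        pos = x >= 0
        if abs(lam) < 1e-12:
            out[pos] = np.log1p(x[pos])
        else:
            out[pos] = (np.power(x[pos] + 1.0, lam) - 1.0) / lam
        if abs(lam - 2.0) < 1e-12:
            out[~pos] = -np.log1p(-x[~pos])
        else:
            out[~pos] = -(np.power(-x[~pos] + 1.0, 2.0 - lam) - 1.0) / (2.0 - lam)
        return out

    def _apply_power(self, M: np.ndarray) -> np.ndarray:
        out = M.copy()
        for j in self.power_ok_:
            out[:, j] = self._yeo_johnson(M[:, j], self.lambdas_[j])
        return out

    def _fit_scale(self, M: np.ndarray) -> np.ndarray:
        self.min_ = M.min(axis=0)
        self.max_ = M.max(axis=0)
        return self._apply_scale(M, clip=False)

    def _apply_scale(self, M: np.ndarray, clip: bool = True) -> np.ndarray:
        span = self.max_ - self.min_
        constant = span == 0
        safe = np.where(constant, 1.0, span)
        out = 2.0 * (M - self.min_) / safe - 1.0
        out[:, constant] = 0.0
        if clip:
            out = np.clip(out, -1.0, 1.0)
        return out

    # -- public API ---------------------------------------------------------

    def fit(self, table: FeatureTable, y=None) -> "TracePreprocessor":
        self.fit_transform(table)
        return self

    def fit_transform(self, table: FeatureTable, y=None) -> FeatureTable:
        all_missing = table.values.isna().all(axis=0)
        if all_missing.any():
            dropped = list(table.values.columns[all_missing])
            logger.warning("dropping %d fully missing feature(s)", len(dropped))
            table = FeatureTable(
                table.values.loc[:, ~all_missing], table.meta.loc[~all_missing]
            )
        self.dropped_features_ = list(all_missing.index[all_missing])
        self.feature_names_ = list(table.features)
        self.meta_ = table.meta.copy()
        M = self._fit_impute(table.values)
        M = self._fit_power(M, table)
        M = self._fit_scale(M)
        self.n_features_in_ = M.shape[1]
        return FeatureTable(
            pd.DataFrame(M, index=table.genes, columns=table.features), table.meta
        )

    def transform(self, table: FeatureTable) -> FeatureTable:
        values = table.values.reindex(columns=self.feature_names_)
        M = self._apply_impute(values)
        M = self._apply_power(M)
        M = self._apply_scale(M, clip=True)
        return FeatureTable(
            pd.DataFrame(M, index=table.genes, columns=self.feature_names_), self.meta_
        )

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        state = {
            "medians": self.medians_.tolist(),
            "feature_names": self.feature_names_,
            "dropped_features": self.dropped_features_,
            "visit_order": self.visit_order_,
            "neighbors": {k: v.tolist() for k, v in self.neighbors_.items()},
            "models": {
                k: (None if v is None else [v[0].tolist(), v[1]])
                for k, v in self.models_.items()
            },
            "power_ok": self.power_ok_,
            "lambdas": {str(k): v for k, v in self.lambdas_.items()},
            "min": self.min_.tolist(),
            "max": self.max_.tolist(),
            "meta": self.meta_.reset_index().to_dict(orient="list"),
            "params": self.get_params(),
        }
        Path(path).write_text(json.dumps(state))

    @classmethod
    def load(cls, path: str | Path) -> "TracePreprocessor":
        state = json.loads(Path(path).read_text())
        obj = cls(**{k: v for k, v in state["params"].items() if k != "transform_families"})
        obj.transform_families = tuple(state["params"]["transform_families"])
        obj.medians_ = np.array(state["medians"])
        obj.feature_names_ = state["feature_names"]
        obj.dropped_features_ = state["dropped_features"]
        obj.visit_order_ = state["visit_order"]
        obj.neighbors_ = {k: np.array(v) for k, v in state["neighbors"].items()}
        obj.models_ = {
            k: (None if v is None else (np.array(v[0]), float(v[1])))
            for k, v in state["models"].items()
        }
        obj.power_ok_ = state["power_ok"]
        obj.lambdas_ = {int(k): float(v) for k, v in state["lambdas"].items()}
        obj.min_ = np.array(state["min"])
        obj.max_ = np.array(state["max"])
        meta = pd.DataFrame(state["meta"]).set_index("feature_id")
        obj.meta_ = meta
        return obj
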