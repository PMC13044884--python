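"""Non-graph baseline regressors on molecular descriptor tables.

Three model families, with the canonical hyperparameters used throughout:

* MLP — hidden layers (500, 400, 300, 200, 100), ReLU, Adam, MSE loss,
  inputs standardized to zero mean / unit variance with statistics from the
  training rows only;
* Decision tree — squared-error criterion, max depth 4, min samples split 2;
* Random forest — 500 estimators of max depth 4.

Trees and forests consume raw descriptor values; targets are never
standardized (β is already on a log scale). The ``feature_set`` field selects
between all descriptors and a reduced list of "main" descriptors chosen by
random-forest impurity importance (see ``featurize.select_main_features``);
by default that selection is re-run inside each cross-validation training
fold so no test information leaks into it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeRegressor

from .errors import ConfigurationError, SchemaError
from .featurize import DescriptorTable

MODEL_KINDS = ("mlp", "decision_tree", "random_forest")


@dataclass(frozen=True)
class BaselineConfig:
    model: str = "random_forest"
    feature_set: str = "all"  # "all" | "main"
    seed: int = 0
    # mlp
    hidden_layer_sizes: tuple[int, ...] = (500, 400, 300, 200, 100)
    mlp_activation: str = "relu"
    mlp_solver: str = "adam"
    mlp_max_iter: int = 2000
    # tree / forest
    max_depth: int = 4
    min_samples_split: int = 2
    n_estimators: int = 500
    # feature selection
    n_main_features: int = 11
    reselect_per_fold: bool = True
    selected_features: tuple[str, ...] | None = None  # global list when reselect_per_fold=False

    def __post_init__(self):
        if self.model not in MODEL_KINDS:
            raise ConfigurationError(f"model must be one of {MODEL_KINDS}")
        if self.feature_set not in ("all", "main"):
            raise ConfigurationError("feature_set must be 'all' or 'main'")


def make_estimator(config: BaselineConfig):
    if config.model == "mlp":
        return MLPRegressor(
            hidden_layer_sizes=config.hidden_layer_sizes,
            activation=config.mlp_activation,
            solver=config.mlp_solver,
            max_iter=config.mlp_max_iter,
            random_state=config.seed,
        )
    if config.model == "decision_tree":
        return DecisionTreeRegressor(
            criterion="squared_error",
            max_depth=config.max_depth,
            min_samples_split=config.min_samples_split,
            random_state=config.seed,
        )
    return RandomForestRegressor(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        min_samples_split=config.min_samples_split,
        criterion="squared_error",
        random_state=config.seed,
    )


class BaselineRegressor:
    """Model object pairing a descriptor table with targets and a config."""

    def __init__(
        self,
        table: DescriptorTable,
        targets,
        config: BaselineConfig | None = None,
        selected_features: list[str] | None = None,
    ):
        self.config = config or BaselineConfig()
        y = np.asarray(targets, dtype=float)
        if len(y) != table.n_molecules:
            raise ConfigurationError("targets must align with descriptor table rows")
        if not np.all(np.isfinite(table.values)):
            raise ConfigurationError("descriptor table contains non-finite values")
        if not np.all(np.isfinite(y)):
            raise ConfigurationError("targets must be finite")
        if self.config.feature_set == "main":
            if selected_features is None:
                from .featurize import select_main_features

                selected_features = select_main_features(
                    table, y, k=self.config.n_main_features, seed=self.config.seed
                )
            table = table.subset_columns(selected_features)
        self.table = table
        self.endog = y
        self.selected_features = selected_features

    def fit(self) -> "BaselineResults":
        y = self.endog
        if np.ptp(y) == 0:
            warnings.warn("constant target vector; the fitted model is degenerate", stacklevel=2)
        X = self.table.values
        scaler = None
        if self.config.model == "mlp":
            scaler = StandardScaler().fit(X)
            X = scaler.transform(X)
        est = make_estimator(self.config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter on tiny folds
            est.fit(X, y)
        return BaselineResults(
            model=self,
            config=self.config,
            estimator=est,
            scaler=scaler,
            feature_names=list(self.table.descriptor_names),
        )


@dataclass
class BaselineResults:
    model: BaselineRegressor
    config: BaselineConfig
    estimator: object
    scaler: StandardScaler | None
    feature_names: list[str] = field(default_factory=list)

    def predict(self, table: DescriptorTable) -> np.ndarray:
        if table.n_molecules == 0:
            return np.array([])
        if table.descriptor_names != self.feature_names:
            try:
                table = table.subset_columns(self.feature_names)
            except SchemaError as exc:
                raise SchemaError(f"descriptor columns do not match training: {exc}") from exc
        X = table.values
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return np.asarray(self.estimator.predict(X), dtype=float)

    @property
    def feature_importances_(self) -> np.ndarray:
        imp = getattr(self.estimator, "feature_importances_", None)
        if imp is None:
            raise AttributeError(f"{self.config.model} exposes no impurity importances")
        return np.asarray(imp)

    def summary(self) -> str:
        lines = [
            "Baseline Regression Results",
            "=" * 40,
            f"Model:         {self.config.model}",
            f"Feature set:   {self.config.feature_set} ({len(self.feature_names)} descriptors)",
            f"No. molecules: {self.model.table.n_molecules}",
            f"Seed:          {self.config.seed}",
            "=" * 40,
        ]
        return "\n".join(lines)


def fit_baseline(
    table: DescriptorTable,
    targets,
    config: BaselineConfig,
    selected_features: list[str] | None = None,
) -> BaselineResults:
    return BaselineRegressor(table, targets, config, selected_features).fit()


def predict_baseline(results: BaselineResults, table: DescriptorTable) -> np.ndarray:
    return results.predict(table)
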