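"""Shallow-network regression of per-SE mean community size on features.

One hidden layer of 10 logistic units trained with L-BFGS; per
replicate a fresh random 75/25 split is drawn, standardization is fit
on the training rows only, and held-out Pearson r and RMSE are
recorded.  Feature-subset ablation reruns the identical protocol per
subset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)


class PredictorError(ValueError):
    pass


@dataclass
class PredictorConfig:
    hidden_nodes: int = 10
    n_replicates: int = 100
    holdout_fraction: float = 0.25
    standardize: bool = True
    seed: int = 0
    alpha: float = 1e-4
    max_iter: int = 2000
    feature_subsets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.holdout_fraction < 1:
            raise PredictorError("holdout_fraction must lie in (0, 1)")
        if self.hidden_nodes < 1:
            raise PredictorError("hidden_nodes must be >= 1")


@dataclass
class PredictionReport:
    """Replicate-averaged held-out performance per feature subset."""

    per_subset: pd.DataFrame  # subset, mean_r, std_r, mean_rmse, std_rmse, n_replicates

    def subset(self, name: str) -> pd.Series:
        return self.per_subset.set_index("subset").loc[name]


def _one_replicate(
    x: np.ndarray, y: np.ndarray, config: PredictorConfig, rng: np.random.Generator
) -> tuple[float, float]:
    n = len(y)
    n_test = max(1, int(round(n * config.holdout_fraction)))
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    x_train, x_test = x[train_idx], x[test_idx]
    y_train, y_test = y[train_idx], y[test_idx]
    if config.standardize:
        scaler = StandardScaler().fit(x_train)  # training rows only: no leakage
        x_train = scaler.transform(x_train)
        x_test = scaler.transform(x_test)
    model = MLPRegressor(
        hidden_layer_sizes=(config.hidden_nodes,),
        activation="logistic",
        solver="lbfgs",
        alpha=config.alpha,
        max_iter=config.max_iter,
        random_state=int(rng.integers(2**31 - 1)),
    )
    with warnings.catch_warnings():
        # lbfgs hitting max_iter is routine for this tiny architecture
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(x_train, y_train)
    pred = model.predict(x_test)
    rmse = float(np.sqrt(np.mean((pred - y_test) ** 2)))
    if np.std(pred) == 0 or np.std(y_test) == 0:
        r = 0.0
    else:
        r = float(pearsonr(y_test, pred).statistic)
    return r, rmse


def train_predictor(
    features: pd.DataFrame,
    target: pd.Series,
    config: PredictorConfig,
    columns: list[str] | None = None,
    subset_name: str = "all",
) -> PredictionReport:
    """Replicate-train the shallow network and report held-out metrics."""
    cols = columns or [
        c for c in features.columns if c not in {"se_id", "chrom"}
        and pd.api.types.is_numeric_dtype(features[c])
    ]
    missing = [c for c in (columns or []) if c not in features.columns]
    if missing:
        raise PredictorError(f"unknown feature column(s): {missing}")
    x = features[cols].to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    if len(x) != len(y):
        raise PredictorError("features and target length mismatch")
    if len(y) < 40:
        raise PredictorError("need >= 40 rows to train")
    if np.isnan(x).any():
        raise PredictorError("feature table contains missing values")
    if np.std(y) == 0:
        raise PredictorError("constant target; correlation undefined")
    rng = np.random.default_rng(config.seed)
    rs, rmses = [], []
    for _ in range(config.n_replicates):
        r, rmse = _one_replicate(x, y, config, rng)
        rs.append(r)
        rmses.append(rmse)
    report = pd.DataFrame(
        [
            {
                "subset": subset_name,
                "mean_r": float(np.mean(rs)),
                "std_r": float(np.std(rs)),
                "mean_rmse": float(np.mean(rmses)),
                "std_rmse": float(np.std(rmses)),
                "n_replicates": config.n_replicates,
                "n_features": len(cols),
            }
        ]
    )
    return PredictionReport(per_subset=report)


def ablation(
    features: pd.DataFrame, target: pd.Series, config: PredictorConfig
) -> PredictionReport:
    """Run the identical training protocol for each named feature subset."""
    if not config.feature_subsets:
        raise PredictorError("config.feature_subsets is empty")
    frames = []
    for name, cols in config.feature_subsets.items():
        if not cols:
            raise PredictorError(f"subset {name!r} is empty")
        rep = train_predictor(features, target, config, columns=cols, subset_name=name)
        frames.append(rep.per_subset)
    return PredictionReport(per_subset=pd.concat(frames, ignore_index=True))


#: paper-named ablation subsets over the default feature-table columns
DEFAULT_SUBSETS: dict[str, list[str]] = {
    "pol2_med1": ["pol2", "med1"],
    "osn": ["oct4", "sox2", "nanog"],
    "speckle_lad": ["speckle_score", "lad_score"],
    "linear_separation": ["n_se_1mb", "inv_dist_sum"],
    "all": [
        "pol2", "med1", "oct4", "sox2", "nanog", "k27ac",
        "lad_score", "speckle_score", "n_se_1mb", "inv_dist_sum",
    ],
}
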