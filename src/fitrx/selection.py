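"""Dataset partitioning, grid search and nested cross-validation.

The dataset is shuffled once (seeded) and cut into 10 near-equal
segments; in any round, 8 segments update weights, 1 drives
hyperparameter tuning and early stopping, and 1 is held out for final
evaluation.  Hyperparameters (learning rate eta, momentum beta, L2
coefficient alpha) are chosen by exhaustive grid search minimizing the
mean inner-validation RMSE.  Nested cross-validation wraps this: the
outer 10-fold loop estimates generalization, the inner loop (on the
outer-training portion only) selects hyperparameters, and weights are
reinitialized for every outer fold so no information crosses folds.

Metrics (RMSE, MAE, R^2) are computed on the encoded 4-dimensional
outputs with all residuals pooled, giving one number per round.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .corpus import Corpus
from .network import (
    LayerSpec,
    NetworkState,
    TrainConfig,
    forward_batch,
    init_network,
    train,
)

logger = logging.getLogger("fitrx")

__all__ = [
    "SplitPlan",
    "GridSpec",
    "CVResult",
    "paper_split_sizes",
    "make_splits",
    "grid_search",
    "nested_cv",
]


def paper_split_sizes(n_total: int) -> tuple[int, int, int]:
    """(train, validation, test) counts under the floor(80/10/10) convention.

    Note floor can drop up to two samples (e.g. 1,594 -> 1,275 + 159 +
    159 = 1,593); the operational splitter below assigns remainders to
    training instead, so no sample is silently lost there.
    """
    if n_total < 10:
        raise ValueError("need at least 10 samples for an 80/10/10 split")
    return (
        int(np.floor(0.8 * n_total)),
        int(np.floor(0.1 * n_total)),
        int(np.floor(0.1 * n_total)),
    )


@dataclass(frozen=True)
class SplitPlan:
    """Fold assignment per sample: ``folds[i]`` in [0, n_folds)."""

    folds: np.ndarray
    n_folds: int = 10

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds == fold)

    def roles(self, test_fold: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(train, validation, test) index arrays: the test fold is held
        out, the next fold (cyclically) validates, the rest train."""
        val_fold = (test_fold + 1) % self.n_folds
        test = self.indices(test_fold)
        val = self.indices(val_fold)
        train_idx = np.flatnonzero(
            (self.folds != test_fold) & (self.folds != val_fold)
        )
        return train_idx, val, test


def make_splits(n_or_corpus, seed: int, n_folds: int = 10) -> SplitPlan:
    """Seeded shuffle then contiguous segmentation into near-equal folds."""
    n = len(n_or_corpus) if isinstance(n_or_corpus, Corpus) else int(n_or_corpus)
    if n < n_folds:
        raise ValueError(f"cannot cut {n} samples into {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for k, seg in enumerate(np.array_split(perm, n_folds)):
        folds[seg] = k
    return SplitPlan(folds=folds, n_folds=n_folds)


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter candidate sets; defaults are the standard sweep."""

    eta: tuple[float, ...] = (0.001, 0.01, 0.1)
    beta: tuple[float, ...] = (0.5, 0.7, 0.9)
    alpha: tuple[float, ...] = (0.0, 0.001, 0.01)

    def __post_init__(self) -> None:
        if not (self.eta and self.beta and self.alpha):
            raise ValueError("grid axes must be nonempty")

    def configs(self, base: TrainConfig) -> list[TrainConfig]:
        out = []
        for eta, beta, alpha in itertools.product(self.eta, self.beta, self.alpha):
            out.append(replace(base, eta=eta, beta=beta, alpha=alpha))
        return out

    def __len__(self) -> int:
        return len(self.eta) * len(self.beta) * len(self.alpha)


def _pooled_metrics(pred: np.ndarray, target: np.ndarray) -> dict[str, float]:
    r = (pred - target).ravel()
    t = target.ravel()
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    return {
        "rmse": float(np.sqrt(np.mean(r ** 2))),
        "mae": float(np.mean(np.abs(r))),
        "r2": 1.0 - float(np.sum(r ** 2)) / ss_tot if ss_tot > 0 else np.nan,
    }


def _fit_eval(X, Y, train_idx, val_idx, eval_idx, cfg, spec, rng, input_scaling=False):
    net = init_network(spec, rng)
    if input_scaling:
        net.set_input_scaling(X[train_idx])
    result = train(net, X[train_idx], Y[train_idx], X[val_idx], Y[val_idx], cfg)
    pred = forward_batch(result.state, X[eval_idx])
    return result.state, _pooled_metrics(pred, Y[eval_idx])


def grid_search(
    X: np.ndarray,
    Y: np.ndarray,
    grid: GridSpec,
    base_cfg: TrainConfig,
    seed: int,
    n_folds: int = 10,
    spec: LayerSpec = LayerSpec(),
    input_scaling: bool = False,
) -> tuple[TrainConfig, pd.DataFrame]:
    """Exhaustive grid search minimizing mean inner-validation RMSE.

    Every configuration is trained on each inner fold's training portion
    and scored on its validation fold.  Exact RMSE ties break toward
    smaller alpha, then smaller eta, then smaller beta.  A single-config
    grid short-circuits without training.
    """
    configs = grid.configs(base_cfg)
    if len(configs) == 1:
        return configs[0], pd.DataFrame(
            [{"eta": configs[0].eta, "beta": configs[0].beta,
              "alpha": configs[0].alpha, "mean_rmse": np.nan}]
        )
    plan = make_splits(len(X), seed=seed, n_folds=n_folds)
    rows = []
    for cfg in configs:
        fold_rmse = []
        for k in range(n_folds):
            val_idx = plan.indices(k)
            train_idx = np.flatnonzero(plan.folds != k)
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, k, hash((cfg.eta, cfg.beta, cfg.alpha)) & 0x7FFFFFFF])
            )
            _, metrics = _fit_eval(
                X, Y, train_idx, val_idx, val_idx, cfg, spec, rng, input_scaling
            )
            fold_rmse.append(metrics["rmse"])
        rows.append(
            {"eta": cfg.eta, "beta": cfg.beta, "alpha": cfg.alpha,
             "mean_rmse": float(np.mean(fold_rmse))}
        )
        logger.info(
            "grid eta=%g beta=%g alpha=%g -> mean inner RMSE %.4f",
            cfg.eta, cfg.beta, cfg.alpha, rows[-1]["mean_rmse"],
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["mean_rmse", "alpha", "eta", "beta"], kind="stable"
    )
    best = order.iloc[0]
    winner = replace(
        base_cfg, eta=float(best["eta"]), beta=float(best["beta"]), alpha=float(best["alpha"])
    )
    logger.info("grid search evaluated %d configurations", len(configs))
    return winner, table


@dataclass
class CVResult:
    """Per-round and aggregate nested-CV metrics (Table-style report)."""

    rounds: pd.DataFrame  # columns: round, rmse, mae, r2
    chosen: list[TrainConfig]
    fold_bookkeeping: list[dict]

    @property
    def mean(self) -> dict[str, float]:
        return {c: float(self.rounds[c].mean()) for c in ("rmse", "mae", "r2")}

    @property
    def best(self) -> dict[str, float]:
        """Row of the best (minimum-RMSE) round."""
        row = self.rounds.loc[self.rounds["rmse"].idxmin()]
        return {c: float(row[c]) for c in ("rmse", "mae", "r2")}

    def table(self) -> pd.DataFrame:
        """Rounds plus Mean and Best summary rows."""
        extra = pd.DataFrame(
            [
                {"round": "Mean", **self.mean},
                {"round": "Best", **self.best},
            ]
        )
        return pd.concat([self.rounds, extra], ignore_index=True)


def nested_cv(
    X: np.ndarray,
    Y: np.ndarray,
    grid: GridSpec,
    base_cfg: TrainConfig,
    seed: int,
    n_outer: int = 10,
    n_inner: int = 10,
    inner_cfg: TrainConfig | None = None,
    spec: LayerSpec = LayerSpec(),
    input_scaling: bool = False,
) -> CVResult:
    """Nested cross-validation with per-fold weight reinitialization.

    Outer folds estimate generalization; the inner grid search sees only
    the outer-training portion, so held-out indices never leak into
    hyperparameter selection (asserted structurally).  ``inner_cfg``
    lets the inner loop run with a reduced epoch cap; the winning
    hyperparameters are then applied to ``base_cfg`` for the final fit
    of each outer fold.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if len(X) < 10 * n_outer:
        raise ValueError("corpus too small for nested cross-validation")
    inner_base = inner_cfg if inner_cfg is not None else base_cfg
    outer = make_splits(len(X), seed=seed, n_folds=n_outer)
    rows, chosen, bookkeeping = [], [], []
    for k in range(n_outer):
        test_idx = outer.indices(k)
        pool = np.flatnonzero(outer.folds != k)
        winner, _ = grid_search(
            X[pool], Y[pool], grid, inner_base,
            seed=int(np.random.SeedSequence([seed, 1000 + k]).generate_state(1)[0] % (2**31)),
            n_folds=n_inner, spec=spec, input_scaling=input_scaling,
        )
        final_cfg = replace(
            base_cfg, eta=winner.eta, beta=winner.beta, alpha=winner.alpha
        )
        # fresh weights per fold; carve a validation slice out of the pool
        # for early stopping (last tenth of the shuffled pool)
        inner_plan = make_splits(len(pool), seed=seed + k, n_folds=10)
        val_local = inner_plan.indices(9)
        train_local = np.flatnonzero(inner_plan.folds != 9)
        train_idx = pool[train_local]
        val_idx = pool[val_local]
        assert not np.intersect1d(test_idx, pool).size, "fold leakage"
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2000 + k]))
        net = init_network(spec, rng)
        if input_scaling:
            net.set_input_scaling(X[train_idx])
        result = train(net, X[train_idx], Y[train_idx], X[val_idx], Y[val_idx], final_cfg)
        pred = forward_batch(result.state, X[test_idx])
        metrics = _pooled_metrics(pred, Y[test_idx])
        rows.append({"round": k + 1, **metrics})
        chosen.append(final_cfg)
        bookkeeping.append(
            {"round": k + 1, "test_idx": test_idx, "train_idx": train_idx,
             "val_idx": val_idx, "pool_idx": pool}
        )
        logger.info(
            "outer fold %d: RMSE %.4f MAE %.4f R2 %.4f (alpha=%g)",
            k + 1, metrics["rmse"], metrics["mae"], metrics["r2"], final_cfg.alpha,
        )
    return CVResult(
        rounds=pd.DataFrame(rows), chosen=chosen, fold_bookkeeping=bookkeeping
    )
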