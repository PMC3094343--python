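"""Random-Forest regression marker scan with a per-marker permutation null.

mtry is tuned by out-of-bag variance explained (1 - MSE_OOB / Var(y)) over a
fixed grid, importance is the unscaled mean increase in OOB MSE when a
marker's values are shuffled (IncMSE), and significance compares each
marker's observed IncMSE against the empirical distribution of its own IncMSE
across forests refit on response permutations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .simdata import MarkerMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RFConfig",
    "RFScanResult",
    "tune_mtry",
    "rf_importance",
    "rf_permutation_scan",
    "compare_selections",
]

DEFAULT_MTRY_GRID = (3, 6, 12, 24, 48, 96)


@dataclass
class RFConfig:
    n_trees: int = 5000
    mtry_grid: tuple[int, ...] = DEFAULT_MTRY_GRID
    n_perm: int = 1000
    alpha: float = 0.05
    perm_trees: int | None = None  # defaults to n_trees
    scale_importance: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.perm_trees is None:
            self.perm_trees = self.n_trees
        if self.perm_trees < 100:
            warnings.warn("perm_trees < 100: per-marker null distributions will be noisy")


@dataclass
class RFScanResult:
    marker_names: list[str]
    inc_mse: np.ndarray
    null_quantile: np.ndarray
    p_perm: np.ndarray
    significant: np.ndarray
    mtry: int
    oob_variance_explained: float
    null_distributions: np.ndarray | None = None  # n_perm x m
    trait: str = "trait"

    def significant_set(self) -> set[str]:
        return {n for n, s in zip(self.marker_names, self.significant) if s}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker": self.marker_names,
            "inc_mse": self.inc_mse,
            "null_q": self.null_quantile,
            "p_perm": self.p_perm,
            "significant": self.significant,
        })


def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, mtry: int,
                seed: int, oob: bool = False) -> RandomForestRegressor:
    rf = RandomForestRegressor(
        n_estimators=n_trees, max_features=mtry, bootstrap=True,
        oob_score=oob, random_state=int(seed), n_jobs=1, min_samples_leaf=5)
    rf.fit(X, y)
    return rf


def _oob_mask(tree_random_state: int, n: int) -> np.ndarray:
    """Out-of-bag mask for one tree, reproducing scikit-learn's bootstrap draw."""
    rs = np.random.RandomState(tree_random_state)
    sampled = rs.randint(0, n, n)
    mask = np.ones(n, dtype=bool)
    mask[sampled] = False
    return mask


def oob_variance_explained(rf: RandomForestRegressor, y: np.ndarray) -> float:
    """1 - MSE_OOB / Var(y), the forest's OOB fraction of variance explained."""
    pred = rf.oob_prediction_
    mse = float(np.mean((y - pred) ** 2))
    return 1.0 - mse / float(np.var(y))


def tune_mtry(markers: MarkerMatrix, y, cfg: RFConfig
              ) -> tuple[int, pd.DataFrame]:
    """Pick mtry maximizing OOB variance explained over the grid.

    Grid values exceeding the marker count are skipped with a warning; ties
    resolve toward the smaller mtry.
    """
    X = markers.scores.astype(np.float32)
    yv = np.asarray(y, dtype=float).ravel()
    m = X.shape[1]
    rows = []
    best_mtry, best_ve = None, -np.inf
    rng = np.random.default_rng(cfg.seed)
    for mtry in cfg.mtry_grid:
        if mtry > m:
            warnings.warn(f"mtry={mtry} exceeds marker count {m}; skipped")
            continue
        rf = _fit_forest(X, yv, cfg.n_trees, mtry, rng.integers(2 ** 31), oob=True)
        ve = oob_variance_explained(rf, yv)
        rows.append({"mtry": mtry, "variance_explained": ve})
        if ve > best_ve:  # strict: ties keep the smaller, earlier mtry
            best_mtry, best_ve = mtry, ve
    if best_mtry is None:
        raise ValueError("no grid value is <= the marker count")
    return best_mtry, pd.DataFrame(rows)


def rf_importance(markers: MarkerMatrix, y, mtry: int, cfg: RFConfig,
                  n_trees: int | None = None, seed: int | None = None
                  ) -> np.ndarray:
    """Unscaled IncMSE: per-tree OOB increase in MSE under within-OOB
    shuffling of one marker column, averaged over all trees."""
    X = markers.scores.astype(np.float32)
    yv = np.asarray(y, dtype=float).ravel()
    if np.ptp(yv) == 0:
        warnings.warn("constant response: all importances are 0")
        return np.zeros(X.shape[1])
    rf = _fit_forest(X, yv, n_trees or cfg.perm_trees, mtry,
                     cfg.seed if seed is None else seed)
    return _forest_inc_mse(rf, X, yv, cfg)


def _forest_inc_mse(rf: RandomForestRegressor, X: np.ndarray, yv: np.ndarray,
                    cfg: RFConfig) -> np.ndarray:
    """Batched IncMSE: for each tree, one predict call over stacked copies of
    its OOB block, each copy with one used feature permuted.  Features a tree
    never splits on contribute exactly 0 for that tree."""
    n, m = X.shape
    total = np.zeros(m)
    sd_acc = np.zeros(m)
    n_trees = len(rf.estimators_)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    for tree in rf.estimators_:
        oob = _oob_mask(tree.random_state, n)
        n_oob = int(oob.sum())
        if n_oob == 0:
            continue
        Xo = X32[oob]
        yo = yv[oob]
        # tree_.predict skips per-call input validation (hot loop)
        base_pred = tree.tree_.predict(Xo).ravel()
        base_mse = float(np.mean((yo - base_pred) ** 2))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        if used.size == 0:
            continue
        rs = np.random.RandomState(tree.random_state)
        stack = np.repeat(Xo[None, :, :], used.size, axis=0)
        for u, j in enumerate(used):
            stack[u, :, j] = Xo[rs.permutation(n_oob), j]
        preds = tree.tree_.predict(
            np.ascontiguousarray(stack.reshape(-1, m))).reshape(used.size, n_oob)
        mse_perm = np.mean((yo[None, :] - preds) ** 2, axis=1)
        delta = mse_perm - base_mse
        total[used] += delta
        sd_acc[used] += delta ** 2
    inc = total / n_trees
    if cfg.scale_importance:
        var = sd_acc / n_trees - inc ** 2
        se = np.sqrt(np.clip(var, 0, None) / n_trees)
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = np.where(se > 0, inc / se, inc)
    return inc


def rf_permutation_scan(markers: MarkerMatrix, y, cfg: RFConfig,
                        trait: str = "trait", keep_null: bool = False
                        ) -> RFScanResult:
    """Full RF scan: tune mtry once, compute observed IncMSE, then build each
    marker's null from forests refit on permuted responses.

    A marker is significant iff its observed IncMSE strictly exceeds the
    (1 - alpha) empirical quantile of its own null; the permutation p-value is
    (1 + #{null >= observed}) / (1 + n_perm).
    """
    yv = np.asarray(y, dtype=float).ravel()
    X = markers.scores.astype(np.float32)
    n, m = X.shape
    mtry, grid_tbl = tune_mtry(markers, yv, cfg)
    logger.info("tuned mtry=%d: %s", mtry,
                grid_tbl.to_string(index=False).replace("\n", " | "))

    rng = np.random.default_rng(cfg.seed + 1)
    rf_obs = _fit_forest(X, yv, cfg.perm_trees, mtry, rng.integers(2 ** 31), oob=True)
    obs = _forest_inc_mse(rf_obs, X, yv, cfg)
    ve = oob_variance_explained(rf_obs, yv)

    null = np.empty((cfg.n_perm, m))
    for b in range(cfg.n_perm):
        yp = yv[rng.permutation(n)]
        rf_b = _fit_forest(X, yp, cfg.perm_trees, mtry, rng.integers(2 ** 31))
        null[b] = _forest_inc_mse(rf_b, X, yp, cfg)

    q = np.quantile(null, 1.0 - cfg.alpha, axis=0)
    sig = obs > q
    p_perm = (1.0 + (null >= obs[None, :]).sum(axis=0)) / (1.0 + cfg.n_perm)
    return RFScanResult(marker_names=list(markers.marker_names), inc_mse=obs,
                        null_quantile=q, p_perm=p_perm, significant=sig,
                        mtry=mtry, oob_variance_explained=ve,
                        null_distributions=null if keep_null else None,
                        trait=trait)


def compare_selections(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Pairwise intersection counts and Jaccard overlap of named marker sets."""
    names = list(sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = len(sets[a] & sets[b])
            union = len(sets[a] | sets[b])
            rows.append({
                "set_a": a, "set_b": b,
                "size_a": len(sets[a]), "size_b": len(sets[b]),
                "intersection": inter,
                "jaccard": inter / union if union else np.nan,
            })
    return pd.DataFrame(rows)
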