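"""Stage-one screening: boosted regression trees over categorical predictors.

Stagewise least-squares boosting of depth-limited regression trees on the
three categorical predictors (age group, gender, collection period), with the
classic ensemble summaries used to screen for influential interactions:

* relative variable importance — per-predictor split-improvement totals
  rescaled to sum to 100;
* pairwise interaction strength — residual variance of an additive
  main-effects linear model fitted to the ensemble's two-way
  partial-dependence grid (exactly zero for additive, e.g. stump, ensembles);
* partial dependence — per-level marginal effects, centred at zero.

Because every predictor is categorical with at most five levels, trees split
on exact level subsets (all 2^(k-1)-1 bipartitions are enumerated) and the
fitted ensemble is piecewise constant on the 50-cell design grid; predictions
are therefore cached per cell, which makes the marginalizations exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .synthetic import AGE_GROUPS, GENDERS, PERIODS, PooledObservation, ValidationError

PREDICTORS: tuple[str, ...] = ("age_group", "gender", "period")
_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": AGE_GROUPS,
    "gender": GENDERS,
    "period": PERIODS,
}
_N_LEVELS = tuple(len(_LEVELS[p]) for p in PREDICTORS)


class UndefinedImportanceError(ValueError):
    """Importance is undefined for an ensemble that never split."""


@dataclass
class _Node:
    # leaf: value set, var is None; internal: var/mask/children set
    value: float = 0.0
    var: Optional[int] = None
    mask: int = 0  # bitmask over levels of `var`; set bit -> go left
    improvement: float = 0.0
    left: Optional["_Node"] = None
    right: Optional["_Node"] = None


@dataclass
class BRTFit:
    """A fitted boosted tree ensemble plus its train/test partition."""

    trees: list[_Node]
    f0: float
    shrinkage: float
    train_indices: np.ndarray
    test_indices: np.ndarray
    loss_trace: np.ndarray  # training SSE after each accepted tree
    X: np.ndarray  # (n, 3) integer-coded predictors, full data
    y: np.ndarray  # (n,) log-concentrations, full data

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    _cell_table_cache: Optional[np.ndarray] = field(default=None, repr=False)

    def cell_table(self) -> np.ndarray:
        """Ensemble prediction on the full (5, 2, 5) design grid."""
        if self._cell_table_cache is None:
            A, G, T = _N_LEVELS
            grid = np.stack(
                np.meshgrid(np.arange(A), np.arange(G), np.arange(T), indexing="ij"), axis=-1
            ).reshape(-1, 3)
            pred = np.full(len(grid), self.f0)
            for tree in self.trees:
                pred += self.shrinkage * _predict_tree(tree, grid)
            self._cell_table_cache = pred.reshape(A, G, T)
        return self._cell_table_cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        tab = self.cell_table()
        X = np.asarray(X)
        return tab[X[:, 0], X[:, 1], X[:, 2]]


def encode(data: Sequence[PooledObservation]) -> tuple[np.ndarray, np.ndarray]:
    """Integer-code observations to (X, y) with y = log-concentration."""
    X = np.array(
        [
            [
                AGE_GROUPS.index(o.age_group),
                GENDERS.index(o.gender),
                PERIODS.index(o.period),
            ]
            for o in data
        ],
        dtype=np.intp,
    ).reshape(-1, 3)
    y = np.array([o.log_concentration for o in data], dtype=float)
    return X, y


def _predict_tree(node: _Node, X: np.ndarray) -> np.ndarray:
    out = np.empty(len(X))
    stack = [(node, np.arange(len(X)))]
    while stack:
        nd, idx = stack.pop()
        if nd.var is None:
            out[idx] = nd.value
        else:
            go_left = (np.right_shift(nd.mask, X[idx, nd.var]) & 1).astype(bool)
            stack.append((nd.left, idx[go_left]))
            stack.append((nd.right, idx[~go_left]))
    return out


def _best_split(Xn: np.ndarray, r: np.ndarray) -> Optional[tuple[int, int, float]]:
    """Best (var, mask, improvement) by exhaustive level-subset search."""
    n = len(r)
    tot = r.sum()
    base = tot * tot / n
    best = None
    best_imp = 1e-12  # require strictly positive improvement
    for j, k in enumerate(_N_LEVELS):
        cnt = np.bincount(Xn[:, j], minlength=k).astype(float)
        sums = np.bincount(Xn[:, j], weights=r, minlength=k)
        # enumerate proper subsets; fix level 0 to the left to kill mirror duplicates
        for mask in range(1, 1 << k, 2):
            bits = [(mask >> b) & 1 for b in range(k)]
            nl = sum(c for c, b in zip(cnt, bits) if b)
            if nl == 0 or nl == n:
                continue
            sl = sum(s for s, b in zip(sums, bits) if b)
            imp = sl * sl / nl + (tot - sl) ** 2 / (n - nl) - base
            if imp > best_imp:
                best_imp = imp
                best = (j, mask, imp)
    return best


def _grow_tree(Xn: np.ndarray, r: np.ndarray, depth: int) -> _Node:
    node = _Node(value=float(r.mean()))
    if depth <= 0 or len(r) < 2:
        return node
    found = _best_split(Xn, r)
    if found is None:
        return node
    j, mask, imp = found
    node.var, node.mask, node.improvement = j, mask, imp
    go_left = (np.right_shift(mask, Xn[:, j]) & 1).astype(bool)
    node.left = _grow_tree(Xn[go_left], r[go_left], depth - 1)
    node.right = _grow_tree(Xn[~go_left], r[~go_left], depth - 1)
    return node


def _stratified_half_split(X: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """50/50 split stratified by design cell; global sizes differ by <= 1."""
    cell = X[:, 0] * 100 + X[:, 1] * 10 + X[:, 2]
    train, test = [], []
    balance = 0  # len(train) - len(test)
    for c in np.unique(cell):
        idx = np.flatnonzero(cell == c)
        idx = rng.permutation(idx)
        k = len(idx) // 2
        if len(idx) % 2 == 1:
            if balance <= 0:
                k += 1
        train.extend(idx[:k])
        test.extend(idx[k:])
        balance = len(train) - len(test)
    return np.sort(np.array(train, dtype=np.intp)), np.sort(np.array(test, dtype=np.intp))


def fit_brt(
    data: Sequence[PooledObservation],
    shrinkage: float = 0.01,
    max_trees: int = 5000,
    tree_depth: int = 3,
    split_seed: int = 0,
    patience: int = 50,
) -> BRTFit:
    """Fit a stagewise least-squares boosted tree ensemble.

    Half the data (stratified by design cell, seed-controlled) trains the
    ensemble; the other half drives early stopping: boosting halts once the
    held-out deviance has not improved for ``patience`` rounds (or a tree can
    find no improving split), and the ensemble is truncated at the best
    held-out iteration.
    """
    if len(data) < 2:
        raise ValidationError("need at least 2 observations")
    if not (0 < shrinkage <= 1):
        raise ValidationError("shrinkage must be in (0, 1]")
    X, y = encode(data)
    rng = np.random.default_rng(split_seed)
    train_idx, test_idx = _stratified_half_split(X, rng)
    Xtr, ytr = X[train_idx], y[train_idx]
    Xte, yte = X[test_idx], y[test_idx]

    f0 = float(ytr.mean())
    Ftr = np.full(len(ytr), f0)
    Fte = np.full(len(yte), f0)
    trees: list[_Node] = []
    loss: list[float] = []
    best_test = float(((yte - Fte) ** 2).sum()) if len(yte) else 0.0
    best_m = 0
    since_best = 0
    for _ in range(max_trees):
        r = ytr - Ftr
        tree = _grow_tree(Xtr, r, tree_depth)
        if tree.var is None:
            break  # no improving split: predictive performance cannot improve
        trees.append(tree)
        Ftr += shrinkage * _predict_tree(tree, Xtr)
        loss.append(float(((ytr - Ftr) ** 2).sum()))
        if len(yte):
            Fte += shrinkage * _predict_tree(tree, Xte)
            test_sse = float(((yte - Fte) ** 2).sum())
            if test_sse < best_test - 1e-12:
                best_test = test_sse
                best_m = len(trees)
                since_best = 0
            else:
                since_best += 1
                if since_best >= patience:
                    break
        else:
            best_m = len(trees)
    trees = trees[:best_m]
    loss = loss[:best_m]
    return BRTFit(
        trees=trees,
        f0=f0,
        shrinkage=shrinkage,
        train_indices=train_idx,
        test_indices=test_idx,
        loss_trace=np.asarray(loss),
        X=X,
        y=y,
    )


def _collect_importance(node: _Node, acc: np.ndarray) -> None:
    if node.var is not None:
        acc[node.var] += node.improvement
        _collect_importance(node.left, acc)
        _collect_importance(node.right, acc)


def relative_importance(fit: BRTFit) -> dict[str, float]:
    """Per-predictor relative importance, rescaled to sum to 100.

    Sums the squared-error improvement of every split made on each predictor
    across the ensemble (the least-squares improvement criterion), then
    rescales so the three importances add to 100.
    """
    acc = np.zeros(3)
    for tree in fit.trees:
        _collect_importance(tree, acc)
    total = acc.sum()
    if total <= 0:
        raise UndefinedImportanceError("ensemble contains no splits")
    acc = 100.0 * acc / total
    return dict(zip(PREDICTORS, acc.tolist()))


def _train_freqs(fit: BRTFit) -> list[np.ndarray]:
    Xtr = fit.X[fit.train_indices]
    return [
        np.bincount(Xtr[:, j], minlength=k).astype(float) / len(Xtr)
        for j, k in enumerate(_N_LEVELS)
    ]


def interaction_strength(fit: BRTFit, pair: tuple[str, str]) -> float:
    """Interaction strength of an unordered predictor pair.

    The ensemble's two-way partial-dependence grid (the third predictor
    marginalized over its empirical training distribution) is fitted with an
    additive main-effects linear model; the mean squared residual of that fit
    is returned.  Purely additive ensembles — in particular any ensemble of
    stumps — score exactly zero.
    """
    try:
        j1, j2 = (PREDICTORS.index(p) for p in pair)
    except ValueError as e:
        raise ValidationError(f"unknown predictor in pair {pair!r}") from e
    if j1 == j2:
        raise ValidationError("pair must contain two distinct predictors")
    j3 = 3 - j1 - j2
    tab = fit.cell_table()
    w3 = _train_freqs(fit)[j3]
    grid = np.tensordot(np.moveaxis(tab, j3, -1), w3, axes=([-1], [0]))
    if j1 > j2:  # grid axes follow predictor order
        grid = grid.T
    k1, k2 = grid.shape
    # additive main-effects design on the grid cells
    u, v = np.meshgrid(np.arange(k1), np.arange(k2), indexing="ij")
    D = np.column_stack(
        [np.ones(grid.size)]
        + [(u.ravel() == i).astype(float) for i in range(1, k1)]
        + [(v.ravel() == i).astype(float) for i in range(1, k2)]
    )
    coef, *_ = np.linalg.lstsq(D, grid.ravel(), rcond=None)
    resid = grid.ravel() - D @ coef
    return float(np.mean(resid**2))


def interaction_table(fit: BRTFit) -> dict[tuple[str, str], float]:
    """Interaction strength for all three unordered predictor pairs."""
    pairs = [("age_group", "gender"), ("age_group", "period"), ("gender", "period")]
    return {p: interaction_strength(fit, p) for p in pairs}


def partial_dependence(fit: BRTFit, predictor: str) -> dict[str, float]:
    """Per-level marginal effect of one predictor, centred at zero.

    Each level's effect is the ensemble prediction averaged over the joint
    empirical training distribution of the other two predictors, minus the
    training-frequency-weighted mean effect (so effects above zero mark
    levels with higher-than-expected concentrations).
    """
    try:
        j = PREDICTORS.index(predictor)
    except ValueError as e:
        raise ValidationError(f"unknown predictor {predictor!r}") from e
    others = [k for k in range(3) if k != j]
    Xtr = fit.X[fit.train_indices]
    # joint empirical distribution of the two other predictors
    k1, k2 = _N_LEVELS[others[0]], _N_LEVELS[others[1]]
    joint = np.zeros((k1, k2))
    np.add.at(joint, (Xtr[:, others[0]], Xtr[:, others[1]]), 1.0)
    joint /= joint.sum()
    tab = np.moveaxis(fit.cell_table(), j, 0)  # (levels_j, k1, k2)
    pd_vals = np.tensordot(tab, joint, axes=([1, 2], [0, 1]))
    wj = _train_freqs(fit)[j]
    pd_vals = pd_vals - float(pd_vals @ wj)
    return dict(zip(_LEVELS[predictor], pd_vals.tolist()))


def brt_rmse(fit: BRTFit, subset: str = "test") -> float:
    """Root mean squared prediction error on the train or test half."""
    if subset == "train":
        idx = fit.train_indices
    elif subset == "test":
        idx = fit.test_indices
    else:
        raise ValidationError("subset must be 'train' or 'test'")
    if len(idx) == 0:
        raise ValidationError(f"{subset} subset is empty")
    resid = fit.y[idx] - fit.predict(fit.X[idx])
    return float(np.sqrt(np.mean(resid**2)))
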