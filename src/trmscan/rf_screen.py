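"""Stage 1 of TRM: Random-Forests variable screening.

Variables are ranked once by unscaled OOB permutation importance on an
initial forest, then backward-eliminated (dropping a fixed fraction of the
least important per round, refitting, and tracking the OOB error), and the
final set is the smallest one whose OOB error is within one standard error
of the minimum across the elimination path.

SNPs enter the forest as ordinal dosages 0/1/2; trees can realize dominant
or recessive splits internally, so no model coding is imposed here.  The
forest itself is a CART ensemble specialized to 3-valued ordinal predictors
(the only candidate split points are dosage <= 0 and dosage <= 1), with
Gini split selection, bootstrap resampling, and mtry random candidate
features per node — the classic random-forest recipe, compiled with numba
so that the bootstrap-heavy calibration stages stay tractable on one CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)


def mtry_default(p: int) -> int:
    """Number of predictors tried per split: round-half-up of sqrt(p)
    (e.g. p = 2177 -> 47)."""
    return int(np.floor(np.sqrt(p) + 0.5))


@dataclass
class ForestConfig:
    """Settings for the screening forests.

    The defaults (5000 trees for the initial forest, 2000 per elimination
    refit, mtry = round(sqrt(p)), drop 20% of remaining variables per
    round) match the varSelRF-style procedure at full study scale; tests
    and quick runs pass smaller tree counts.
    """

    n_trees_first: int = 5000
    n_trees_iter: int = 2000
    mtry: int | None = None
    drop_fraction: float = 0.2
    min_leaf: int = 1
    seed: int = 0
    recompute_importance: bool = False

    def __post_init__(self) -> None:
        if self.n_trees_first < 1 or self.n_trees_iter < 1:
            raise ValueError("tree counts must be >= 1")
        if not 0.0 < self.drop_fraction < 1.0:
            raise ValueError("drop_fraction must lie in (0, 1)")

    def resolved_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else mtry_default(p)
        return max(1, min(m, p))


@dataclass
class ScreenTrace:
    """Elimination path: (variable set, OOB error, binomial SE) per step,
    plus the 1-SE-rule selection."""

    steps: list[tuple[tuple[str, ...], float, float]]
    selected: list[str]
    importance: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Compiled CART-on-dosage kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nb_build_tree(XbT, yb, mtry, min_leaf, seed,
                   feature, thr, left, right, node_cls):
    """Grow one classification tree on bootstrap rows (XbT: features x rows,
    int8 dosages, transposed for cache locality).

    Split candidates per feature are dosage <= 0 and dosage <= 1; the best
    Gini-gain split over ``mtry`` features drawn without replacement is
    taken.  Returns the number of nodes used.
    """
    np.random.seed(seed)
    p, m = XbT.shape
    idx = np.arange(m)
    # explicit stack of (node, lo, hi)
    cap = 2 * m + 2
    st_node = np.empty(cap, np.int32)
    st_lo = np.empty(cap, np.int32)
    st_hi = np.empty(cap, np.int32)
    top = 0
    st_node[0] = 0
    st_lo[0] = 0
    st_hi[0] = m
    top = 1
    node_count = 1
    featbuf = np.arange(p)
    while top > 0:
        top -= 1
        node = st_node[top]
        lo = st_lo[top]
        hi = st_hi[top]
        size = hi - lo
        n1 = 0
        for i in range(lo, hi):
            n1 += yb[idx[i]]
        n0 = size - n1
        node_cls[node] = 1 if n1 > n0 else 0
        feature[node] = -1
        if n1 == 0 or n0 == 0 or size < 2 * min_leaf:
            continue
        parent_imp = size - (n1 * n1 + n0 * n0) / size
        best_gain = 1e-12
        best_f = -1
        best_t = np.int8(0)
        # partial Fisher-Yates: mtry distinct candidate features
        for t in range(mtry):
            r = t + np.random.randint(0, p - t)
            tmp = featbuf[t]
            featbuf[t] = featbuf[r]
            featbuf[r] = tmp
            f = featbuf[t]
            c00 = 0; c01 = 0; c02 = 0
            c10 = 0; c11 = 0; c12 = 0
            for i in range(lo, hi):
                d = XbT[f, idx[i]]
                if yb[idx[i]] == 1:
                    if d == 0:
                        c10 += 1
                    elif d == 1:
                        c11 += 1
                    else:
                        c12 += 1
                else:
                    if d == 0:
                        c00 += 1
                    elif d == 1:
                        c01 += 1
                    else:
                        c02 += 1
            for cut in range(2):
                if cut == 0:
                    l1 = c10; l0 = c00
                else:
                    l1 = c10 + c11; l0 = c00 + c01
                ls = l1 + l0
                rs = size - ls
                if ls < min_leaf or rs < min_leaf or ls == 0 or rs == 0:
                    continue
                r1 = n1 - l1
                r0 = n0 - l0
                child_imp = (ls - (l1 * l1 + l0 * l0) / ls
                             + rs - (r1 * r1 + r0 * r0) / rs)
                gain = parent_imp - child_imp
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                    best_t = np.int8(cut)
        if best_f < 0:
            continue
        # partition idx[lo:hi]: <= thr to the left
        i = lo
        j = hi - 1
        while i <= j:
            if XbT[best_f, idx[i]] <= best_t:
                i += 1
            else:
                tmp = idx[i]
                idx[i] = idx[j]
                idx[j] = tmp
                j -= 1
        mid = i
        feature[node] = best_f
        thr[node] = best_t
        lchild = node_count
        rchild = node_count + 1
        node_count += 2
        left[node] = lchild
        right[node] = rchild
        st_node[top] = lchild; st_lo[top] = lo; st_hi[top] = mid; top += 1
        st_node[top] = rchild; st_lo[top] = mid; st_hi[top] = hi; top += 1
    return node_count


@njit(cache=True)
def _nb_predict(feature, thr, left, right, node_cls, X, out):
    m = X.shape[0]
    for i in range(m):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= thr[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = node_cls[node]


@njit(cache=True)
def _nb_perm_importance_tree(feature, thr, left, right, node_cls,
                             XoT, yo, wo, used, perm):
    """Per-tree permutation importance on its OOB rows (XoT: features x
    rows; wo: per-row subject weights): weighted error after permuting each
    used feature (one shared permutation per tree) minus the unpermuted
    weighted error."""
    m = XoT.shape[1]
    base = 0.0
    for i in range(m):
        node = 0
        while feature[node] >= 0:
            if XoT[feature[node], i] <= thr[node]:
                node = left[node]
            else:
                node = right[node]
        if node_cls[node] != yo[i]:
            base += wo[i]
    diffs = np.zeros(used.size, dtype=np.float64)
    col = np.empty(m, dtype=np.int8)
    for k in range(used.size):
        f = used[k]
        for i in range(m):
            col[i] = XoT[f, i]
        for i in range(m):
            XoT[f, i] = col[perm[i]]
        e = 0.0
        for i in range(m):
            node = 0
            while feature[node] >= 0:
                if XoT[feature[node], i] <= thr[node]:
                    node = left[node]
                else:
                    node = right[node]
            if node_cls[node] != yo[i]:
                e += wo[i]
        diffs[k] = e - base
        for i in range(m):
            XoT[f, i] = col[i]
    return diffs


class DosageForest:
    """Random forest of dosage-specialized CART trees with OOB bookkeeping.

    ``weights`` carries subject multiplicities from an outer bootstrap: each
    tree then resamples subjects proportionally to their multiplicity, and a
    subject is out-of-bag for a tree only when none of its copies are in the
    tree's sample.  This keeps OOB estimates honest when the whole dataset
    has been resampled with replacement (a duplicated subject can otherwise
    sit on both sides of a tree's bag and leak).
    """

    def __init__(self, n_trees: int, mtry: int, min_leaf: int, seed: int):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_leaf = min_leaf
        self.seed = seed
        self.trees: list[tuple] = []
        self.oob_rows: list[np.ndarray] = []
        self.weights: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray,
            weights: np.ndarray | None = None) -> "DosageForest":
        X = np.ascontiguousarray(X, dtype=np.int8)
        y = np.ascontiguousarray(y, dtype=np.int8)
        n = X.shape[0]
        if weights is None:
            weights = np.ones(n)
        weights = np.asarray(weights, dtype=float)
        self.weights = weights
        total = weights.sum()
        n_draw = int(round(total))
        cum = np.cumsum(weights) / total
        alive = weights > 0
        rng = np.random.default_rng(self.seed)
        tree_seeds = rng.integers(0, 2**31 - 1, size=self.n_trees)
        for k in range(self.n_trees):
            rows = np.searchsorted(cum, rng.random(n_draw), side="right")
            inbag = np.zeros(n, dtype=np.bool_)
            inbag[rows] = True
            XbT = np.ascontiguousarray(X[rows].T)
            yb = y[rows]
            cap = 2 * n_draw + 2
            feature = np.full(cap, -1, np.int32)
            thr = np.zeros(cap, np.int8)
            left = np.full(cap, -1, np.int32)
            right = np.full(cap, -1, np.int32)
            node_cls = np.zeros(cap, np.int8)
            used_n = _nb_build_tree(XbT, yb, self.mtry, self.min_leaf,
                                    int(tree_seeds[k]), feature, thr, left,
                                    right, node_cls)
            self.trees.append((feature[:used_n].copy(), thr[:used_n].copy(),
                               left[:used_n].copy(), right[:used_n].copy(),
                               node_cls[:used_n].copy()))
            self.oob_rows.append(np.flatnonzero(alive & ~inbag))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.int8)
        votes = np.zeros(X.shape[0], dtype=np.int32)
        out = np.empty(X.shape[0], dtype=np.int8)
        for tree in self.trees:
            _nb_predict(*tree, X, out)
            votes += out
        return (votes * 2 > len(self.trees)).astype(np.int8)


def oob_error(forest: DosageForest, X: np.ndarray,
              y: np.ndarray) -> tuple[float, float]:
    """Aggregated OOB error (majority vote over the trees in which a subject
    is out-of-bag, weighted by subject multiplicity) and its binomial
    standard error over the effective OOB-covered n."""
    X = np.ascontiguousarray(X, dtype=np.int8)
    n = X.shape[0]
    w = forest.weights if forest.weights is not None else np.ones(n)
    votes1 = np.zeros(n, dtype=np.int32)
    total = np.zeros(n, dtype=np.int32)
    for tree, rows in zip(forest.trees, forest.oob_rows):
        if rows.size == 0:
            continue
        out = np.empty(rows.size, dtype=np.int8)
        _nb_predict(*tree, np.ascontiguousarray(X[rows]), out)
        votes1[rows] += out
        total[rows] += 1
    covered = total > 0
    n_oob = float(w[covered].sum())
    if n_oob <= 0:
        raise RuntimeError("no OOB predictions: increase the tree count")
    pred = (votes1[covered] * 2 > total[covered]).astype(np.int8)
    miss = (pred != y[covered]).astype(float)
    err = float((w[covered] * miss).sum() / n_oob)
    se = float(np.sqrt(err * (1.0 - err) / n_oob))
    return err, se


def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, mtry: int,
                seed: int, min_leaf: int = 1,
                weights: np.ndarray | None = None) -> DosageForest:
    return DosageForest(n_trees, mtry, min_leaf, seed).fit(X, y, weights)


def oob_importance(X: np.ndarray, y: np.ndarray, cfg: ForestConfig,
                   forest: DosageForest | None = None,
                   weights: np.ndarray | None = None) -> np.ndarray:
    """Unscaled OOB permutation importance.

    Per tree: classification error on its OOB subjects after permuting one
    variable, minus the unpermuted OOB error; averaged over all trees
    without dividing by the standard error.  Variables a tree never splits
    on contribute exactly zero for that tree; one random permutation per
    tree is shared across its variables.
    """
    X = np.ascontiguousarray(X, dtype=np.int8)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be a 2-D matrix with at least one variable")
    y = np.ascontiguousarray(y, dtype=np.int8)
    p = X.shape[1]
    if forest is None:
        forest = _fit_forest(X, y, cfg.n_trees_first, cfg.resolved_mtry(p),
                             cfg.seed, cfg.min_leaf, weights)
    w = forest.weights if forest.weights is not None else np.ones(X.shape[0])
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    imp = np.zeros(p)
    for tree, rows in zip(forest.trees, forest.oob_rows):
        m = rows.size
        if m == 0:
            continue
        feature = tree[0]
        used = np.unique(feature[feature >= 0]).astype(np.int64)
        if used.size == 0:
            continue
        XoT = np.ascontiguousarray(X[rows].T)
        yo = y[rows]
        wo = w[rows]
        perm = rng.permutation(m)
        diffs = _nb_perm_importance_tree(*tree, XoT, yo, wo, used, perm)
        imp[used] += diffs / wo.sum()
    return imp / len(forest.trees)


def backward_eliminate(X: np.ndarray, y: np.ndarray, snp_ids: list[str],
                       cfg: ForestConfig,
                       row_weights: np.ndarray | None = None) -> ScreenTrace:
    """varSelRF-style backward elimination with the 1-SE stopping rule.

    The importance ranking is computed once, on the initial forest, and kept
    fixed across rounds (set ``cfg.recompute_importance`` to re-rank after
    each refit).  Each round drops ``drop_fraction`` of the least important
    remaining variables and refits with ``n_trees_iter`` trees, down to two
    variables.  The returned selection is the smallest variable set whose
    OOB error is at most min(OOB error) + SE(at the minimizing step).
    """
    X = np.ascontiguousarray(X, dtype=np.int8)
    y = np.ascontiguousarray(y, dtype=np.int8)
    p = X.shape[1]
    if p < 1:
        raise ValueError("need at least one variable")
    if len(snp_ids) != p:
        raise ValueError("snp_ids must match the number of columns")
    seeds = np.random.SeedSequence(cfg.seed).generate_state(64) % (2**31)
    forest = _fit_forest(X, y, cfg.n_trees_first, cfg.resolved_mtry(p),
                         int(seeds[0]), cfg.min_leaf, row_weights)
    imp = oob_importance(X, y, cfg, forest=forest)
    err, se = oob_error(forest, X, y)
    current = list(np.argsort(-imp, kind="stable"))  # descending importance
    steps: list[tuple[tuple[str, ...], float, float]] = [
        (tuple(snp_ids[j] for j in sorted(current)), err, se)
    ]
    importance = {snp_ids[j]: float(imp[j]) for j in range(p)}
    round_no = 0
    while len(current) > 2:
        round_no += 1
        n_keep = max(2, len(current) - max(1, int(np.floor(
            cfg.drop_fraction * len(current)))))
        current = current[:n_keep]
        Xs = np.ascontiguousarray(X[:, current])
        forest = _fit_forest(Xs, y, cfg.n_trees_iter,
                             cfg.resolved_mtry(n_keep), int(seeds[round_no]),
                             cfg.min_leaf, row_weights)
        err, se = oob_error(forest, Xs, y)
        steps.append((tuple(snp_ids[j] for j in sorted(current)), err, se))
        if cfg.recompute_importance and n_keep > 2:
            sub_cfg = ForestConfig(cfg.n_trees_iter, cfg.n_trees_iter,
                                   cfg.mtry, cfg.drop_fraction, cfg.min_leaf,
                                   int(seeds[round_no]))
            sub_imp = oob_importance(Xs, y, sub_cfg, forest=forest)
            current = [current[k] for k in np.argsort(-sub_imp, kind="stable")]
    selected = one_se_selection(steps)
    logger.info("screen: %d steps, selected %d vars", len(steps),
                len(selected))
    return ScreenTrace(steps=steps, selected=selected, importance=importance)


def one_se_selection(steps: list[tuple[tuple[str, ...], float, float]]
                     ) -> list[str]:
    """The 1-SE rule over an elimination trace: the smallest variable set
    whose OOB error does not exceed the minimum OOB error plus the standard
    error at the minimizing step."""
    if not steps:
        raise ValueError("empty elimination trace")
    errors = np.array([s[1] for s in steps])
    k_min = int(np.argmin(errors))
    bound = errors[k_min] + steps[k_min][2]
    eligible = [s for s in steps if s[1] <= bound]
    selected_step = min(eligible, key=lambda s: len(s[0]))
    return list(selected_step[0])
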