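"""Stage 2 of TRM: a MARS-style regression engine over genotype indicators.

On ordinal dosage input (0/1/2) the classical hinge functions at knots 0.5
and 1.5 generate exactly four indicators per SNP — carrier (dosage >= 1),
homozygous minor (dosage == 2), and their mirrors — so basis functions are
products of up to two such indicators from distinct SNPs.  The forward pass
greedily adds mirror-pair bases that most reduce the least-squares RSS of
the 0/1 response; the backward pass deletes bases to minimize the GCV
criterion with a per-basis-function penalty d, itself selected by 10-fold
cross-validation.  The binary response is fitted by least squares (classic
MARS classification mode); odds ratios are re-estimated downstream by
logistic regression.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class Ind(enum.Enum):
    """Genotype indicator kinds: the four dosage dichotomies."""

    GE1 = "ge1"  # dosage >= 1  (minor-allele carrier; dominant coding)
    EQ0 = "eq0"  # dosage == 0  (mirror of GE1)
    EQ2 = "eq2"  # dosage == 2  (homozygous minor; recessive coding)
    LE1 = "le1"  # dosage <= 1  (mirror of EQ2)


#: Hinge-style mirror pairs added jointly in the forward pass.
MIRROR_PAIRS: tuple[tuple[Ind, Ind], ...] = ((Ind.GE1, Ind.EQ0),
                                             (Ind.EQ2, Ind.LE1))

#: Dosage values for which each indicator is 1.
IND_DOSAGES: dict[Ind, frozenset[int]] = {
    Ind.GE1: frozenset({1, 2}),
    Ind.EQ0: frozenset({0}),
    Ind.EQ2: frozenset({2}),
    Ind.LE1: frozenset({0, 1}),
}


def indicator_column(dosage: np.ndarray, kind: Ind) -> np.ndarray:
    d = np.asarray(dosage)
    if kind is Ind.GE1:
        return (d >= 1).astype(float)
    if kind is Ind.EQ0:
        return (d == 0).astype(float)
    if kind is Ind.EQ2:
        return (d == 2).astype(float)
    return (d <= 1).astype(float)


@dataclass(frozen=True)
class BasisFunction:
    """Product of 0-2 genotype indicators; the empty product is the intercept."""

    terms: tuple[tuple[str, Ind], ...] = ()

    def __post_init__(self) -> None:
        snps = [s for s, _ in self.terms]
        if len(self.terms) > 2:
            raise ValueError("basis functions are limited to two-way products")
        if len(set(snps)) != len(snps):
            raise ValueError("a basis function may not use the same SNP twice")

    @property
    def degree(self) -> int:
        return len(self.terms)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.terms)

    def key(self) -> frozenset:
        return frozenset(self.terms)

    def evaluate(self, columns: dict[str, np.ndarray]) -> np.ndarray:
        if not self.terms:
            first = next(iter(columns.values()))
            return np.ones(first.shape[0])
        out = None
        for snp, kind in self.terms:
            col = indicator_column(columns[snp], kind)
            out = col if out is None else out * col
        return out

    def describe(self) -> str:
        if not self.terms:
            return "(intercept)"
        return " * ".join(f"I({s} {k.value})" for s, k in self.terms)


@dataclass
class MarsModel:
    basis: list[BasisFunction]
    coefficients: np.ndarray
    gcv: float
    penalty_d: float
    _design: np.ndarray | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_basis(self) -> int:
        return len(self.basis)

    def predict(self, columns: dict[str, np.ndarray]) -> np.ndarray:
        cols = [bf.evaluate(columns) for bf in self.basis]
        return np.column_stack(cols) @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "penalty_d": self.penalty_d,
            "gcv": self.gcv,
            "basis": [
                {"terms": [[s, k.value] for s, k in bf.terms],
                 "coefficient": float(c)}
                for bf, c in zip(self.basis, self.coefficients)
            ],
        }


@dataclass
class MarsConfig:
    max_bf: int = 30
    max_degree: int = 2
    penalty_grid: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    cv_folds: int = 10
    penalty_d: float | None = None  # None -> select by CV
    forward_tol: float = 1e-8
    seed: int = 0


def gcv_score(rss: float, n: int, M: int, d: float) -> float:
    """Generalized cross-validation: (RSS/n) / (1 - C/n)^2 with effective
    parameter count C = M + d*(M-1)/2 (M basis functions incl. intercept)."""
    C = M + d * (M - 1) / 2.0
    if C >= n:
        raise ValueError(f"effective parameters C={C} >= n={n}: model too large")
    return (rss / n) / (1.0 - C / n) ** 2


def _lstsq_rss(D: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    return coef, float(resid @ resid)


def forward_pass(X: np.ndarray, snp_ids: list[str], y: np.ndarray,
                 max_bf: int = 30, max_degree: int = 2,
                 forward_tol: float = 1e-8) -> MarsModel:
    """Greedy forward addition of mirror-pair bases.

    At each step, for every current basis (the parent) of degree below
    ``max_degree`` and every SNP not already in the parent, the two mirror
    indicator products are evaluated jointly; the pair giving the largest
    RSS reduction is added.  The pass stops at ``max_bf`` basis functions
    (including the intercept) or when the best reduction falls below
    ``forward_tol * n * var(y)``.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p < 1:
        raise ValueError("at least one candidate SNP required")
    columns = {sid: X[:, j] for j, sid in enumerate(snp_ids)}
    ind_cols = {(sid, kind): indicator_column(columns[sid], kind)
                for sid in snp_ids for kind in Ind}

    basis: list[BasisFunction] = [BasisFunction()]
    D = np.ones((n, 1))
    tol_rss = forward_tol * n * float(np.var(y)) if np.var(y) > 0 else np.inf
    tol_col = 1e-9 * n

    # candidate indicator block, ordered so mirror pairs are adjacent:
    # for each SNP, (GE1, EQ0) then (EQ2, LE1)
    pair_snp: list[str] = []
    pair_kinds: list[tuple[Ind, Ind]] = []
    cand_cols = []
    for sid in snp_ids:
        for pair in MIRROR_PAIRS:
            pair_snp.append(sid)
            pair_kinds.append(pair)
            cand_cols.append(ind_cols[(sid, pair[0])])
            cand_cols.append(ind_cols[(sid, pair[1])])
    C = np.column_stack(cand_cols)  # n x (4p), 0/1 indicators
    P12 = C[:, 0::2] * C[:, 1::2]   # per-pair product column (n x 2p)
    snp_of_pair = np.array([snp_ids.index(s) for s in pair_snp])
    K = len(pair_snp)

    # orthonormal basis of the current design, grown by Gram-Schmidt
    Q = np.ones((n, 1)) / np.sqrt(n)
    qy = [float(Q[:, 0] @ y)]

    class _Parent:
        """Incremental per-parent candidate state.

        For candidate columns z_i = parent * c_i the RSS reduction of adding
        a mirror pair only needs the Gram and response terms of z projected
        off the current orthonormal basis; those are maintained as running
        sums over the orthonormal columns q_k:
        g_ij = z_i'z_j - sum_k (q_k'z_i)(q_k'z_j), b_i = z_i'y - sum v_i qy_k.
        """

        __slots__ = ("idx", "col", "g11", "g22", "g12", "b1", "b2", "blocked")

        def __init__(self, parent_idx: int):
            self.idx = parent_idx
            pc = D[:, parent_idx]
            self.col = pc
            diag = pc @ C          # z_i'z_i (indicator columns: c*c = c)
            self.g11 = diag[0::2].copy()
            self.g22 = diag[1::2].copy()
            self.g12 = (pc @ P12).astype(float)
            zy = (pc * y) @ C
            self.b1 = zy[0::2].copy()
            self.b2 = zy[1::2].copy()
            # project off all existing orthonormal columns
            V = ((Q * pc[:, None]).T @ C)  # (M x 4p)
            v1, v2 = V[:, 0::2], V[:, 1::2]
            self.g11 -= (v1 * v1).sum(axis=0)
            self.g22 -= (v2 * v2).sum(axis=0)
            self.g12 -= (v1 * v2).sum(axis=0)
            w = np.asarray(qy)
            self.b1 -= w @ v1
            self.b2 -= w @ v2
            parent = basis[parent_idx]
            self.blocked = np.isin(snp_of_pair,
                                   [snp_ids.index(s) for s in parent.snp_ids])

        def update(self, q: np.ndarray, qy_new: float) -> None:
            v = (self.col * q) @ C
            v1, v2 = v[0::2], v[1::2]
            self.g11 -= v1 * v1
            self.g22 -= v2 * v2
            self.g12 -= v1 * v2
            self.b1 -= qy_new * v1
            self.b2 -= qy_new * v2

        def reductions(self) -> np.ndarray:
            g11 = np.maximum(self.g11, 0.0)
            g22 = np.maximum(self.g22, 0.0)
            g12, b1, b2 = self.g12, self.b1, self.b2
            ok1 = g11 > tol_col
            ok2 = g22 > tol_col
            det = g11 * g22 - g12 * g12
            with np.errstate(divide="ignore", invalid="ignore"):
                red_both = np.where(
                    det > tol_col * np.maximum(g11, g22),
                    (b1 * b1 * g22 - 2 * b1 * b2 * g12 + b2 * b2 * g11)
                    / np.where(det > 0, det, 1.0),
                    -np.inf)
                red_1 = np.where(ok1, b1 * b1 / np.where(ok1, g11, 1.0),
                                 -np.inf)
                red_2 = np.where(ok2, b2 * b2 / np.where(ok2, g22, 1.0),
                                 -np.inf)
            red = np.maximum(red_both, np.maximum(red_1, red_2))
            red[self.blocked] = -np.inf
            return red

    parents: list[_Parent] = [_Parent(0)]
    existing_keys = {basis[0].key()}

    def _orthonormalize(col: np.ndarray) -> np.ndarray | None:
        u = col - Q @ (Q.T @ col)
        u -= Q @ (Q.T @ u)  # second pass for numerical stability
        nrm2 = float(u @ u)
        if nrm2 < tol_col:
            return None
        return u / np.sqrt(nrm2)

    while len(basis) + 2 <= max_bf:
        best: tuple[float, _Parent, int] | None = None
        for ps in parents:
            red = ps.reductions()
            k = int(np.argmax(red))
            while red[k] > (best[0] if best else -np.inf):
                keys = [frozenset(basis[ps.idx].terms + ((pair_snp[k], kind),))
                        for kind in pair_kinds[k]]
                if all(key in existing_keys for key in keys):
                    ps.blocked[k] = True
                    red[k] = -np.inf
                    k = int(np.argmax(red))
                    continue
                best = (float(red[k]), ps, k)
                break
        if best is None or best[0] < tol_rss:
            break
        _, ps, k = best
        parent = basis[ps.idx]
        sid = pair_snp[k]
        new_q: list[np.ndarray] = []
        added_idx: list[int] = []
        for kind in pair_kinds[k]:
            bf = BasisFunction(parent.terms + ((sid, kind),))
            if bf.key() in existing_keys:
                continue
            existing_keys.add(bf.key())
            col = bf.evaluate(columns)
            q = _orthonormalize(col)
            if q is None:
                continue  # numerically collinear with the current basis
            basis.append(bf)
            D = np.column_stack([D, col])
            added_idx.append(len(basis) - 1)
            Q = np.column_stack([Q, q])
            qy_new = float(q @ y)
            qy.append(qy_new)
            new_q.append(q)
            for other in parents:
                other.update(q, qy_new)
        if not new_q:
            ps.blocked[k] = True
            continue
        for bidx in added_idx:
            if basis[bidx].degree < max_degree:
                parents.append(_Parent(bidx))

    coef, rss = _lstsq_rss(D, y)
    model = MarsModel(basis=basis, coefficients=coef,
                      gcv=gcv_score(rss, n, len(basis), 0.0), penalty_d=0.0,
                      _design=D, _y=y)
    return model


def backward_prune(model: MarsModel, d: float) -> MarsModel:
    """Backward deletion: repeatedly remove the basis function whose removal
    minimizes GCV (intercept never deleted); return the GCV-minimal model
    along the deletion path, including the unpruned start."""
    if model._design is None or model._y is None:
        raise ValueError("model must come from forward_pass (design retained)")
    D, y = model._design, model._y
    n = D.shape[0]
    active = list(range(len(model.basis)))
    # subset refits via the precomputed Gram: RSS = y'y - b_S' G_S^{-1} b_S
    G = D.T @ D
    bv = D.T @ y
    yy = float(y @ y)

    def fit(idx: list[int]) -> tuple[np.ndarray, float, float]:
        Gs = G[np.ix_(idx, idx)]
        bs = bv[idx]
        coef, _, _, _ = np.linalg.lstsq(Gs, bs, rcond=None)
        rss = max(yy - float(bs @ coef), 0.0)
        try:
            g = gcv_score(rss, n, len(idx), d)
        except ValueError:
            g = np.inf  # C >= n: effectively infinite penalty, keep deleting
        return coef, rss, g

    coef, rss, g = fit(active)
    best = (g, list(active), coef)
    while len(active) > 1:
        step_best: tuple[float, list[int], np.ndarray] | None = None
        for k in active:
            if k == 0:  # intercept
                continue
            trial = [i for i in active if i != k]
            coef_t, _, g_t = fit(trial)
            if step_best is None or g_t < step_best[0]:
                step_best = (g_t, trial, coef_t)
        if step_best is None:
            break
        active = step_best[1]
        if step_best[0] < best[0]:
            best = step_best
    g_best, idx_best, coef_best = best
    return MarsModel(basis=[model.basis[i] for i in idx_best],
                     coefficients=coef_best, gcv=g_best, penalty_d=d,
                     _design=D[:, idx_best], _y=y)


def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    assignment = np.empty(y.shape[0], dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % folds
    return assignment


def cv_select_penalty(X: np.ndarray, snp_ids: list[str], y: np.ndarray,
                      folds: int = 10,
                      grid: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0),
                      seed: int = 0, max_bf: int = 30,
                      max_degree: int = 2) -> float:
    """Pick the per-basis penalty d by stratified k-fold CV on held-out
    squared error; ties go to the largest (most conservative) d."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] < folds:
        raise ValueError("need n >= folds")
    if len(grid) == 1:
        return float(grid[0])
    fold_of = _stratified_folds(y, folds, seed)
    errors = np.zeros(len(grid))
    counts = np.zeros(len(grid))
    for f in range(folds):
        test = fold_of == f
        train = ~test
        if np.unique(y[train]).size < 2 or test.sum() == 0:
            continue
        fwd = forward_pass(X[train], snp_ids, y[train], max_bf=max_bf,
                           max_degree=max_degree)
        test_cols = {sid: X[test, j] for j, sid in enumerate(snp_ids)}
        for gi, d in enumerate(grid):
            pruned = backward_prune(fwd, d)
            pred = pruned.predict(test_cols)
            errors[gi] += float(((y[test] - pred) ** 2).sum())
            counts[gi] += test.sum()
        del fwd
    mse = errors / np.maximum(counts, 1)
    best = mse.min()
    # largest d within numerical tie of the minimum
    eligible = [d for d, m in zip(grid, mse) if m <= best + 1e-12]
    return float(max(eligible))


def fit_mars(X: np.ndarray, snp_ids: list[str], y: np.ndarray,
             cfg: MarsConfig | None = None) -> MarsModel:
    """Forward + backward MARS fit, selecting the penalty by CV when
    ``cfg.penalty_d`` is unset."""
    cfg = cfg or MarsConfig()
    d = cfg.penalty_d
    if d is None:
        d = cv_select_penalty(X, snp_ids, y, folds=cfg.cv_folds,
                              grid=cfg.penalty_grid, seed=cfg.seed,
                              max_bf=cfg.max_bf, max_degree=cfg.max_degree)
    fwd = forward_pass(X, snp_ids, y, max_bf=cfg.max_bf,
                       max_degree=cfg.max_degree, forward_tol=cfg.forward_tol)
    return backward_prune(fwd, d)


def model_to_factors(model: MarsModel) -> list:
    """Map each non-intercept basis to a selected factor.

    Degree-1 bases become main-effect factors with their genotype dichotomy;
    degree-2 bases become SNP-pair factors with their 3x3 cell set (cells
    keyed by the pair's sorted snp_ids).  Duplicates are merged.
    """
    from .trm_pipeline import Factor

    out: list = []
    seen = set()
    for bf in model.basis:
        if bf.degree == 0:
            continue
        if bf.degree == 1:
            (sid, kind), = bf.terms
            factor = Factor(kind="main", snp_ids=(sid,),
                            dichotomy=IND_DOSAGES[kind])
        else:
            (s1, k1), (s2, k2) = bf.terms
            if s2 < s1:
                (s1, k1), (s2, k2) = (s2, k2), (s1, k1)
            cells = frozenset(
                (a, b) for a in IND_DOSAGES[k1] for b in IND_DOSAGES[k2]
            )
            factor = Factor(kind="pair", snp_ids=(s1, s2), dichotomy=cells)
        key = (factor.kind, factor.snp_ids, factor.dichotomy)
        if key in seen:
            continue
        seen.add(key)
        out.append(factor)
    return out
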