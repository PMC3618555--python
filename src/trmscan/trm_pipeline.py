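"""End-to-end TRM: forest screening, MARS interaction search, bootstrap
selection frequencies, null-model calibration, and the multivariable
logistic summary of retained factors.

The TRM search itself carries no p-values, so factor selection is stabilized
by bootstrap: the pipeline is re-run on B resamples of the data and each
factor's selection frequency is recorded.  A null calibration — the same
procedure on an outcome drawn independently of the genotypes with the
study's class sizes — yields the false-positive frequency distribution whose
95th percentile motivates the retention cutoff (default: keep factors with
frequency strictly above 5%).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .geno_data import GenotypeMatrix, Phenotype
from .mars_engine import MarsConfig, cv_select_penalty, fit_mars, model_to_factors
from .rf_screen import ForestConfig, backward_eliminate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Factor:
    """A selected main effect or SNP-pair interaction.

    ``dichotomy`` is the indicator definition: a frozenset of dosages for a
    main effect, or of (dosage_a, dosage_b) cells — keyed by the sorted SNP
    pair — for an interaction.
    """

    kind: str  # "main" | "pair"
    snp_ids: tuple[str, ...]
    dichotomy: frozenset
    bootstrap_freq: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("main", "pair"):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if self.kind == "pair" and tuple(sorted(self.snp_ids)) != self.snp_ids:
            raise ValueError("pair snp_ids must be stored sorted")
        object.__setattr__(self, "dichotomy", frozenset(self.dichotomy))

    def key(self) -> tuple:
        """Identity used to match factors across bootstrap resamples: the
        SNP (pair) only — mirror dichotomies flip freely between resamples."""
        return (self.kind, self.snp_ids)

    def strict_key(self) -> tuple:
        return (self.kind, self.snp_ids, self.dichotomy)

    def indicator(self, gm: GenotypeMatrix) -> np.ndarray:
        if self.kind == "main":
            d = gm.column(self.snp_ids[0])
            return np.isin(d, list(self.dichotomy)).astype(float)
        da = gm.column(self.snp_ids[0])
        db = gm.column(self.snp_ids[1])
        out = np.zeros(gm.n_subjects)
        for (a, b) in self.dichotomy:
            out += (da == a) & (db == b)
        return (out > 0).astype(float)

    def label(self, gm: GenotypeMatrix | None = None) -> str:
        if gm is None:
            if self.kind == "main":
                return f"{self.snp_ids[0]} (dosage in {sorted(self.dichotomy)})"
            return (f"{self.snp_ids[0]}+ {self.snp_ids[1]} "
                    f"(cells {sorted(self.dichotomy)})")
        if self.kind == "main":
            rec = gm.record(self.snp_ids[0])
            inside = "/".join(rec.genotype_label(d) for d in sorted(self.dichotomy))
            outside = "/".join(rec.genotype_label(d)
                               for d in sorted({0, 1, 2} - self.dichotomy))
            return f"{self.snp_ids[0]} ({inside} vs. {outside})"
        rec_a = gm.record(self.snp_ids[0])
        rec_b = gm.record(self.snp_ids[1])
        set_a = sorted({c[0] for c in self.dichotomy})
        set_b = sorted({c[1] for c in self.dichotomy})
        if {(a, b) for a in set_a for b in set_b} == set(self.dichotomy):
            ga = "/".join(rec_a.genotype_label(d) for d in set_a)
            gb = "/".join(rec_b.genotype_label(d) for d in set_b)
            return f"{self.snp_ids[0]}+ {self.snp_ids[1]} ({ga}+ {gb} vs. others)"
        cells = ", ".join(
            rec_a.genotype_label(a) + "+" + rec_b.genotype_label(b)
            for a, b in sorted(self.dichotomy))
        return f"{self.snp_ids[0]}+ {self.snp_ids[1]} ({{{cells}}} vs. others)"


@dataclass
class TrmConfig:
    forest: ForestConfig = field(default_factory=ForestConfig)
    mars: MarsConfig = field(default_factory=MarsConfig)
    B: int = 500
    cutoff: float = 0.05
    seed: int = 0
    match_dichotomy: bool = False  # strict factor identity across resamples
    regenerate_null: bool = True   # fresh null outcome per null resample

    def with_seed(self, seed: int) -> "TrmConfig":
        return replace(self, seed=seed,
                       forest=replace(self.forest, seed=seed),
                       mars=replace(self.mars, seed=seed))


@dataclass
class CalibrationResult:
    B: int
    null_freqs: dict[tuple, float]
    percentile95: float
    cutoff: float


def run_trm(gm: GenotypeMatrix, phen: Phenotype,
            cfg: TrmConfig | None = None,
            row_weights: np.ndarray | None = None) -> list[Factor]:
    """Forest screen then MARS on the surviving SNPs; returns uncalibrated
    factors.  Deterministic given the data and ``cfg.seed``.

    ``row_weights`` carries subject multiplicities from an outer bootstrap
    resample: forests then resample subjects at the subject level (no
    duplicate-row OOB leakage) and the MARS stage fits the correspondingly
    re-weighted least-squares problem.
    """
    factors, _, _ = _run_trm_detail(gm, phen, cfg or TrmConfig(), row_weights)
    return factors


def _run_trm_detail(gm: GenotypeMatrix, phen: Phenotype, cfg: TrmConfig,
                    row_weights: np.ndarray | None = None
                    ) -> tuple[list[Factor], list[str], float]:
    if gm.has_missing():
        raise ValueError("TRM requires a complete matrix: impute first")
    X = gm.dosage
    trace = backward_eliminate(X, phen.y, gm.snp_ids, cfg.forest,
                               row_weights=row_weights)
    selected = trace.selected
    if not selected:
        return [], [], float(cfg.mars.penalty_d or 0.0)
    idx = [gm.snp_index(s) for s in selected]
    if row_weights is not None:
        rows = np.repeat(np.arange(gm.n_subjects),
                         np.asarray(row_weights, dtype=int))
        Xs = X[rows][:, idx].astype(float)
        y_fit = phen.y[rows].astype(float)
    else:
        Xs = X[:, idx].astype(float)
        y_fit = phen.y.astype(float)
    d = cfg.mars.penalty_d
    if d is None:
        d = cv_select_penalty(Xs, selected, y_fit,
                              folds=cfg.mars.cv_folds,
                              grid=cfg.mars.penalty_grid, seed=cfg.mars.seed,
                              max_bf=cfg.mars.max_bf,
                              max_degree=cfg.mars.max_degree)
    model = fit_mars(Xs, selected, y_fit, replace(cfg.mars, penalty_d=d))
    return model_to_factors(model), selected, float(d)


def _bootstrap_keys(gm: GenotypeMatrix, phen: Phenotype, cfg: TrmConfig,
                    B: int, seed: int) -> tuple[Counter, dict[tuple, Counter]]:
    """Run TRM on B with-replacement resamples (expressed as subject
    multiplicity weights); count factor keys and track the dichotomies
    observed per key."""
    n = gm.n_subjects
    seeds = np.random.SeedSequence(seed).generate_state(2 * B + 2) % (2**31)
    rng = np.random.default_rng(int(seeds[0]))
    counts: Counter = Counter()
    dichotomies: dict[tuple, Counter] = {}
    y = phen.y
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        if y[idx].min() == y[idx].max():
            continue  # degenerate resample: nothing selectable
        w = np.bincount(idx, minlength=n).astype(float)
        cfg_b = cfg.with_seed(int(seeds[b + 1]))
        factors = run_trm(gm, phen, cfg_b, row_weights=w)
        for f in factors:
            key = f.strict_key() if cfg.match_dichotomy else f.key()
            counts[key] += 1
            dichotomies.setdefault(key, Counter())[f.dichotomy] += 1
    return counts, dichotomies


def _fix_penalty(gm: GenotypeMatrix, phen: Phenotype, cfg: TrmConfig
                 ) -> tuple[list[Factor], TrmConfig]:
    """Run TRM once on the full data; freeze the CV-selected penalty so the
    B resample runs do not re-tune it."""
    base_cfg = cfg.with_seed(cfg.seed)
    base_factors, _, d = _run_trm_detail(gm, phen, base_cfg)
    fixed = replace(cfg, mars=replace(cfg.mars, penalty_d=d))
    return base_factors, fixed


def bootstrap_frequencies(gm: GenotypeMatrix, phen: Phenotype,
                          cfg: TrmConfig | None = None,
                          B: int | None = None,
                          seed: int | None = None) -> list[Factor]:
    """Selection frequency of each factor over B bootstrap resamples of the
    observed data, ranked by descending frequency.

    The MARS penalty is cross-validated once on the full data and held fixed
    across resamples.  Factors are matched across resamples by SNP (pair)
    identity; the reported dichotomy comes from the full-data run when the
    factor was selected there, otherwise it is the modal dichotomy across
    resamples.
    """
    cfg = cfg or TrmConfig()
    B = B if B is not None else cfg.B
    seed = seed if seed is not None else cfg.seed
    base_factors, cfg_fixed = _fix_penalty(gm, phen, cfg)
    counts, dichotomies = _bootstrap_keys(gm, phen, cfg_fixed, B, seed)
    base_by_key = {}
    for f in base_factors:
        key = f.strict_key() if cfg.match_dichotomy else f.key()
        base_by_key.setdefault(key, f)
    out: list[Factor] = []
    all_keys = set(counts) | set(base_by_key)
    for key in all_keys:
        freq = counts.get(key, 0) / B
        if key in base_by_key:
            f = base_by_key[key]
        else:
            kind, snp_ids = key[0], key[1]
            dich = dichotomies[key].most_common(1)[0][0]
            f = Factor(kind=kind, snp_ids=snp_ids, dichotomy=dich)
        out.append(replace(f, bootstrap_freq=freq))
    out.sort(key=lambda f: (-f.bootstrap_freq, f.kind, f.snp_ids))
    return out


def null_calibration(gm: GenotypeMatrix, n1: int = 659, n0: int = 492,
                     B: int = 500, seed: int = 0,
                     cfg: TrmConfig | None = None) -> CalibrationResult:
    """Calibrate the retention cutoff on a genotype-independent outcome.

    A binary outcome with class sizes n1/n0 is generated independently of
    the genotypes; TRM runs on B bootstrap resamples of the null model and
    every selected factor's frequency is a false-positive frequency.  The
    95th percentile of those frequencies is reported; the suggested cutoff
    is the config cutoff raised to that percentile if necessary.

    By default the null outcome is regenerated for each resample, so the
    frequencies measure how often a factor is re-selected under outcomes
    carrying no signal at all.  With ``cfg.regenerate_null = False`` a single
    null outcome is drawn once and only the subjects are resampled; the
    frequencies then also absorb the chance associations realized in that
    one outcome draw and run far higher — useful for studying the stability
    of in-sample noise, but not a false-positive calibration.
    """
    cfg = cfg or TrmConfig()
    if B < 50:
        warnings.warn(f"B={B} null resamples give an unstable 95th percentile",
                      RuntimeWarning, stacklevel=2)
    n = gm.n_subjects
    if n != n1 + n0:
        scale = n / (n1 + n0)
        n1, n0 = int(round(n1 * scale)), 0
        n0 = n - n1
        warnings.warn(f"matrix has {n} subjects: null class sizes rescaled to "
                      f"{n1}/{n0}", RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    base = np.zeros(n, dtype=np.int8)
    base[:n1] = 1

    if cfg.regenerate_null:
        # a fresh null outcome per resample
        counts: Counter = Counter()
        seeds = np.random.SeedSequence(seed).generate_state(2 * B + 2) % (2**31)
        idx_rng = np.random.default_rng(int(seeds[0]))
        _, cfg_fixed = _ensure_fixed_penalty(cfg)
        for b in range(B):
            y_null = rng.permutation(base)
            idx = idx_rng.integers(0, n, size=n)
            if y_null[idx].min() == y_null[idx].max():
                continue
            w = np.bincount(idx, minlength=n).astype(float)
            phen_b = Phenotype(list(gm.subject_ids), y_null)
            factors = run_trm(gm, phen_b, cfg_fixed.with_seed(int(seeds[b + 1])),
                              row_weights=w)
            for f in factors:
                key = f.strict_key() if cfg.match_dichotomy else f.key()
                counts[key] += 1
    else:
        y_null = rng.permutation(base)
        phen_null = Phenotype(list(gm.subject_ids), y_null)
        _, cfg_fixed = _fix_penalty(gm, phen_null, cfg)
        counts, _ = _bootstrap_keys(gm, phen_null, cfg_fixed, B, seed)

    freqs = {k: c / B for k, c in counts.items()}
    pct95 = float(np.percentile(list(freqs.values()), 95)) if freqs else 0.0
    cutoff = max(cfg.cutoff, pct95)
    return CalibrationResult(B=B, null_freqs=freqs, percentile95=pct95,
                             cutoff=cutoff)


def _ensure_fixed_penalty(cfg: TrmConfig) -> tuple[None, TrmConfig]:
    if cfg.mars.penalty_d is None:
        # regenerate-per-replicate mode has no single full-data fit to tune
        # on; default to the middle of the grid
        mid = sorted(cfg.mars.penalty_grid)[len(cfg.mars.penalty_grid) // 2]
        return None, replace(cfg, mars=replace(cfg.mars, penalty_d=float(mid)))
    return None, cfg


def select_factors(factors: list[Factor], cutoff: float = 0.05) -> list[Factor]:
    """Retain factors with bootstrap frequency strictly above the cutoff,
    ordered by descending frequency."""
    kept = [f for f in factors
            if f.bootstrap_freq is not None and f.bootstrap_freq > cutoff]
    kept.sort(key=lambda f: (-f.bootstrap_freq, f.kind, f.snp_ids))
    return kept


def multivariable_model(factors: list[Factor], gm: GenotypeMatrix,
                        phen: Phenotype) -> pd.DataFrame:
    """Joint logistic fit of the outcome on all factor indicators.

    Constant or collinear indicators are dropped with a log entry.  Returns
    one row per retained factor: coefficient, SE, Wald p, OR, 95% CI.
    """
    if not factors:
        raise ValueError("at least one factor required")
    cols, used = [], []
    for f in factors:
        x = f.indicator(gm)
        if np.ptp(x) == 0:
            logger.info("factor %s: constant indicator dropped", f.label())
            continue
        if cols:
            Q, _ = np.linalg.qr(np.column_stack(cols + [np.ones(len(x))]))
            resid = x - Q @ (Q.T @ x)
            if float(resid @ resid) < 1e-8 * len(x):
                logger.info("factor %s: collinear indicator dropped", f.label())
                continue
        cols.append(x)
        used.append(f)
    if not cols:
        raise ValueError("all factor indicators constant or collinear")
    X = sm.add_constant(np.column_stack(cols), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(phen.y.astype(float), X).fit(disp=0, maxiter=200)
    rows = []
    for i, f in enumerate(used, start=1):
        beta, se = float(res.params[i]), float(res.bse[i])
        rows.append({
            "factor": f.label(gm), "kind": f.kind,
            "snp_ids": "+".join(f.snp_ids),
            "bootstrap_freq": f.bootstrap_freq,
            "coef": beta, "se": se, "p": float(res.pvalues[i]),
            "OR": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - 1.96 * se)),
            "ci_high": float(np.exp(beta + 1.96 * se)),
        })
    return pd.DataFrame(rows)


@dataclass
class MainEffectsComparison:
    factor: Factor
    lrt_p: float | None
    aic_delta: float | None  # AIC(interaction model) - AIC(mains only)
    skipped: bool = False
    reason: str | None = None


def compare_vs_main_effects(pair: Factor, gm: GenotypeMatrix,
                            phen: Phenotype) -> MainEffectsComparison:
    """Likelihood-ratio test of {both SNPs' genotype main effects +
    interaction indicator} against {main effects only} (1 df).

    Main effects enter as dominant + recessive indicators per SNP, which
    together span arbitrary single-SNP genotype effects.
    """
    if pair.kind != "pair":
        raise ValueError("compare_vs_main_effects expects a pair factor")
    y = phen.y.astype(float)
    main_cols = []
    for sid in pair.snp_ids:
        d = gm.column(sid)
        for col in ((d >= 1).astype(float), (d == 2).astype(float)):
            if np.ptp(col) > 0:
                main_cols.append(col)
    inter = pair.indicator(gm)
    if np.ptp(inter) == 0:
        return MainEffectsComparison(pair, None, None, skipped=True,
                                     reason="interaction indicator constant")
    base = np.column_stack(main_cols) if main_cols else np.empty((len(y), 0))
    Qb, _ = np.linalg.qr(sm.add_constant(base, has_constant="add"))
    resid = inter - Qb @ (Qb.T @ inter)
    if float(resid @ resid) < 1e-8 * len(y):
        return MainEffectsComparison(
            pair, None, None, skipped=True,
            reason="interaction indicator collinear with main codings")
    X0 = sm.add_constant(base, has_constant="add")
    X1 = sm.add_constant(np.column_stack([base, inter]), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit0 = sm.Logit(y, X0).fit(disp=0, maxiter=200)
        fit1 = sm.Logit(y, X1).fit(disp=0, maxiter=200)
    lrt = 2.0 * (fit1.llf - fit0.llf)
    p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    return MainEffectsComparison(pair, p, float(fit1.aic - fit0.aic))
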