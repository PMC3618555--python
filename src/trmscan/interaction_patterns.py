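"""Two-SNP genotype-combination pattern models and cross-cohort evaluation.

A pattern partitions the 3x3 grid of genotype combinations of a SNP pair
into a reference group plus risk (OR > 1) and protective (OR < 1) groups,
fitted by logistic regression.  Cross-evaluation re-assesses training-cohort
patterns in a test cohort (Step 1), searches de novo for pair patterns
within the implicated gene pairs in the test cohort (Step 2), re-fits those
findings in the training cohort (Step 3), and flags pattern pairs whose
like-direction cell sets overlap ("similar" patterns).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import statsmodels.api as sm

from .geno_data import GenotypeMatrix, Phenotype
from .mars_engine import IND_DOSAGES, MarsConfig, fit_mars
from .trm_pipeline import Factor

logger = logging.getLogger(__name__)

ALL_CELLS = frozenset((a, b) for a in range(3) for b in range(3))


@dataclass
class PatternGroup:
    cells: frozenset
    or_: float
    ci95: tuple[float, float]
    p: float

    @property
    def direction(self) -> str:
        return "risk" if self.or_ > 1.0 else "protective"


@dataclass
class InteractionPattern:
    """Fitted 3x3 pattern for an (unordered) SNP pair.

    Cells are (dosage_a, dosage_b) with snp_a < snp_b lexicographically.
    """

    snp_a: str
    snp_b: str
    reference: frozenset
    groups: list[PatternGroup]
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.snp_b < self.snp_a:
            raise ValueError("snp pair must be stored sorted (snp_a < snp_b)")
        covered = set(self.reference)
        for g in self.groups:
            if covered & set(g.cells):
                raise ValueError("pattern groups must be disjoint")
            covered |= set(g.cells)
        if covered != set(ALL_CELLS):
            raise ValueError("pattern groups + reference must cover all 9 cells")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.snp_a, self.snp_b)

    @property
    def risk_cells(self) -> frozenset:
        out: set = set()
        for g in self.groups:
            if g.or_ > 1.0:
                out |= set(g.cells)
        return frozenset(out)

    @property
    def protective_cells(self) -> frozenset:
        out: set = set()
        for g in self.groups:
            if g.or_ < 1.0:
                out |= set(g.cells)
        return frozenset(out)

    @property
    def min_p(self) -> float:
        return min((g.p for g in self.groups), default=np.nan)


def pattern_table(snp_a: str, snp_b: str, gm: GenotypeMatrix,
                  phen: Phenotype) -> np.ndarray:
    """3x3x2 counts: cell (i, j, k) holds the number of subjects with
    dosage_a = i, dosage_b = j and outcome k."""
    da = gm.column(snp_a)
    db = gm.column(snp_b)
    y = phen.y
    counts = np.zeros((3, 3, 2), dtype=int)
    for i in range(3):
        for j in range(3):
            cell = (da == i) & (db == j)
            counts[i, j, 1] = int((cell & (y == 1)).sum())
            counts[i, j, 0] = int((cell & (y == 0)).sum())
    return counts


def fit_pattern(snp_a: str, snp_b: str, group_cells: list[frozenset],
                gm: GenotypeMatrix, phen: Phenotype,
                reference: frozenset | None = None,
                cohort: str = "") -> InteractionPattern:
    """Logistic fit of the outcome on disjoint cell-group indicators.

    ``reference`` defaults to the cells not in any group ("others").  A
    group empty in either outcome class is merged into the reference with a
    log entry.  Returns Wald OR/CI/p per non-reference group.
    """
    if snp_b < snp_a:
        snp_a, snp_b = snp_b, snp_a
        group_cells = [frozenset((b, a) for a, b in g) for g in group_cells]
        if reference is not None:
            reference = frozenset((b, a) for a, b in reference)
    da = gm.column(snp_a)
    db = gm.column(snp_b)
    y = phen.y.astype(float)

    def indicator(cells: frozenset) -> np.ndarray:
        out = np.zeros(len(y), dtype=bool)
        for (a, b) in cells:
            out |= (da == a) & (db == b)
        return out

    used = set().union(*group_cells) if group_cells else set()
    if reference is None:
        reference = frozenset(ALL_CELLS - used)
    kept_cells: list[frozenset] = []
    for cells in group_cells:
        ind = indicator(cells)
        if ind.sum() == 0 or (y[ind] == 1).sum() == 0 or (y[ind] == 0).sum() == 0:
            logger.info("pattern %s+%s: group %s empty in an outcome class; "
                        "merged into reference", snp_a, snp_b, sorted(cells))
            reference = frozenset(reference | cells)
            continue
        kept_cells.append(cells)
    if not kept_cells:
        raise ValueError(f"no fittable groups for {snp_a}+{snp_b}")
    X = sm.add_constant(
        np.column_stack([indicator(c).astype(float) for c in kept_cells]),
        has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    groups = []
    for i, cells in enumerate(kept_cells, start=1):
        beta, se = float(res.params[i]), float(res.bse[i])
        groups.append(PatternGroup(
            cells=cells, or_=float(np.exp(beta)),
            ci95=(float(np.exp(beta - 1.96 * se)),
                  float(np.exp(beta + 1.96 * se))),
            p=float(res.pvalues[i])))
    return InteractionPattern(snp_a=snp_a, snp_b=snp_b, reference=reference,
                              groups=groups, cohort=cohort)


def pattern_from_factor(factor: Factor, gm: GenotypeMatrix, phen: Phenotype,
                        cohort: str = "") -> InteractionPattern:
    """Fit a pair factor's dichotomy as a one-group pattern ("X vs. others")."""
    if factor.kind != "pair":
        raise ValueError("pattern_from_factor expects a pair factor")
    a, b = factor.snp_ids
    return fit_pattern(a, b, [frozenset(factor.dichotomy)], gm, phen,
                       cohort=cohort)


def derive_pattern(snp_a: str, snp_b: str, gm: GenotypeMatrix,
                   phen: Phenotype, mars_cfg: MarsConfig | None = None,
                   cohort: str = "") -> InteractionPattern | None:
    """Detect the best genotype-combination pattern for one SNP pair with
    the MARS engine, then re-fit the implied cell groups by logistic
    regression.  Returns None when MARS keeps no basis for the pair
    (intercept-only model)."""
    if snp_b < snp_a:
        snp_a, snp_b = snp_b, snp_a
    mars_cfg = mars_cfg or MarsConfig(penalty_d=3.0)
    idx = [gm.snp_index(snp_a), gm.snp_index(snp_b)]
    X = gm.dosage[:, idx].astype(float)
    model = fit_mars(X, [snp_a, snp_b], phen.y.astype(float), mars_cfg)
    # map each basis to its 3x3 cell set; disjointify in model order
    group_cells: list[frozenset] = []
    covered: set = set()
    for bf in model.basis:
        if bf.degree == 0:
            continue
        sets = {snp_a: set(range(3)), snp_b: set(range(3))}
        for sid, kind in bf.terms:
            sets[sid] = set(IND_DOSAGES[kind])
        cells = {(a, b) for a in sets[snp_a] for b in sets[snp_b]} - covered
        if cells:
            group_cells.append(frozenset(cells))
            covered |= cells
    if not group_cells or len(covered) == 9:
        # no structure, or no reference cell left to anchor the ORs
        if not group_cells:
            return None
        # release the last group's cells into the reference
        covered -= set(group_cells[-1])
        group_cells = group_cells[:-1]
        if not group_cells:
            return None
    try:
        return fit_pattern(snp_a, snp_b, group_cells, gm, phen, cohort=cohort)
    except ValueError:
        return None


@dataclass
class SimilarityReport:
    similar: bool
    risk_overlap: frozenset
    protective_overlap: frozenset
    overlap_fraction: float  # |overlap| / |smaller like-direction set|
    subset: bool  # one like-direction set contained in the other


def similar_pattern(a: InteractionPattern, b: InteractionPattern
                    ) -> SimilarityReport:
    """Two patterns on the same SNP pair are similar when their risk (or
    protective) cell sets intersect and point the same direction."""
    if a.pair != b.pair:
        raise ValueError(f"patterns are for different SNP pairs: "
                         f"{a.pair} vs {b.pair}")
    risk_ov = a.risk_cells & b.risk_cells
    prot_ov = a.protective_cells & b.protective_cells
    frac = 0.0
    subset = False
    for ov, sa, sb in ((risk_ov, a.risk_cells, b.risk_cells),
                       (prot_ov, a.protective_cells, b.protective_cells)):
        if ov:
            small = min(len(sa), len(sb))
            frac = max(frac, len(ov) / small)
            subset = subset or sa <= sb or sb <= sa
    return SimilarityReport(similar=bool(risk_ov or prot_ov),
                            risk_overlap=frozenset(risk_ov),
                            protective_overlap=frozenset(prot_ov),
                            overlap_fraction=frac, subset=subset)


@dataclass
class Step1Result:
    factor: Factor
    available: bool
    train_pattern: InteractionPattern | None = None
    test_refit: InteractionPattern | None = None
    test_pattern: InteractionPattern | None = None
    similarity: SimilarityReport | None = None


@dataclass
class Step2Result:
    gene_pair: tuple[str, str]
    pattern: InteractionPattern
    significant: bool


@dataclass
class Step3Result:
    gene_pair: tuple[str, str]
    test_pattern: InteractionPattern
    train_refit: InteractionPattern | None
    train_pattern: InteractionPattern | None
    similarity: SimilarityReport | None


@dataclass
class CrossEvalReport:
    step1: list[Step1Result]
    step2: list[Step2Result]
    step3: list[Step3Result]


def _gene_pair(gm: GenotypeMatrix, pair: tuple[str, str]) -> tuple[str, str]:
    genes = tuple(sorted(gm.record(s).gene_symbol or "?" for s in pair))
    return genes  # type: ignore[return-value]


def cross_evaluate(train_gm: GenotypeMatrix, train_phen: Phenotype,
                   test_gm: GenotypeMatrix, test_phen: Phenotype,
                   trained_factors: list[Factor],
                   alpha: float = 0.05,
                   mars_cfg: MarsConfig | None = None) -> CrossEvalReport:
    """Three-step cross-cohort evaluation of trained pair factors.

    Step 1: each trained SNP-pair pattern is re-assessed in the test cohort
    (pairs with a SNP absent from the test panel are recorded as not
    available).  Step 2: all SNP pairs within the trained gene pairs are
    searched de novo in the test cohort; patterns with any group p < alpha
    are retained.  Step 3: Step-2 findings are re-fitted in the training
    cohort.  Similarity flags compare like-direction cell sets of the
    patterns detected independently in the two cohorts.
    """
    mars_cfg = mars_cfg or MarsConfig(penalty_d=3.0)
    test_snps = set(test_gm.snp_ids)
    pair_factors = [f for f in trained_factors if f.kind == "pair"]

    step1: list[Step1Result] = []
    for f in pair_factors:
        if not set(f.snp_ids) <= test_snps:
            logger.info("pair %s: SNP absent from test panel (N/A)",
                        "+".join(f.snp_ids))
            step1.append(Step1Result(factor=f, available=False))
            continue
        train_pat = derive_pattern(*f.snp_ids, train_gm, train_phen,
                                   mars_cfg, cohort="train")
        if train_pat is None:
            train_pat = pattern_from_factor(f, train_gm, train_phen,
                                            cohort="train")
        try:
            refit = fit_pattern(train_pat.snp_a, train_pat.snp_b,
                                [g.cells for g in train_pat.groups],
                                test_gm, test_phen,
                                reference=train_pat.reference, cohort="test")
        except ValueError:
            logger.info("pair %s: trained grouping not fittable in test "
                        "cohort", "+".join(f.snp_ids))
            refit = None
        test_pat = derive_pattern(*f.snp_ids, test_gm, test_phen,
                                  mars_cfg, cohort="test")
        sim = (similar_pattern(train_pat, test_pat)
               if test_pat is not None else None)
        step1.append(Step1Result(factor=f, available=True,
                                 train_pattern=train_pat, test_refit=refit,
                                 test_pattern=test_pat, similarity=sim))

    # Step 2: de-novo pair search inside the trained gene pairs, in test
    gene_pairs = sorted({_gene_pair(train_gm, f.snp_ids)
                         for f in pair_factors})
    gene_to_test_snps: dict[str, list[str]] = {}
    for s in test_gm.snps:
        gene_to_test_snps.setdefault(s.gene_symbol or "?", []).append(s.snp_id)
    step2: list[Step2Result] = []
    for ga, gb in gene_pairs:
        snps_a = gene_to_test_snps.get(ga, [])
        snps_b = gene_to_test_snps.get(gb, [])
        for sa in snps_a:
            for sb in snps_b:
                if sa == sb:
                    continue
                pat = derive_pattern(sa, sb, test_gm, test_phen, mars_cfg,
                                     cohort="test")
                if pat is None:
                    continue
                sig = pat.min_p < alpha
                if sig:
                    step2.append(Step2Result(gene_pair=(ga, gb), pattern=pat,
                                             significant=True))

    # Step 3: re-fit Step-2 findings in the training cohort
    train_snps = set(train_gm.snp_ids)
    step3: list[Step3Result] = []
    for res in step2:
        pat = res.pattern
        if not {pat.snp_a, pat.snp_b} <= train_snps:
            step3.append(Step3Result(res.gene_pair, pat, None, None, None))
            continue
        try:
            refit = fit_pattern(pat.snp_a, pat.snp_b,
                                [g.cells for g in pat.groups], train_gm,
                                train_phen, reference=pat.reference,
                                cohort="train")
        except ValueError:
            refit = None
        train_pat = derive_pattern(pat.snp_a, pat.snp_b, train_gm,
                                   train_phen, mars_cfg, cohort="train")
        sim = similar_pattern(pat, train_pat) if train_pat is not None else None
        step3.append(Step3Result(res.gene_pair, pat, refit, train_pat, sim))
    return CrossEvalReport(step1=step1, step2=step2, step3=step3)


def pattern_report_frame(report: CrossEvalReport, train_gm: GenotypeMatrix,
                         test_gm: GenotypeMatrix):
    """Flatten a CrossEvalReport into a tidy DataFrame of fitted groups."""
    import pandas as pd

    rows = []

    def add(pat: InteractionPattern | None, gm: GenotypeMatrix, step: str,
            pair: tuple[str, str], note: str = "") -> None:
        if pat is None:
            rows.append({"step": step, "snp_pair": "+".join(pair),
                         "cohort": "", "cells": "N/A", "OR": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                         "note": note or "N/A"})
            return
        for g in pat.groups:
            ra, rb = gm.record(pat.snp_a), gm.record(pat.snp_b)
            label = ", ".join(ra.genotype_label(a) + "+" + rb.genotype_label(b)
                              for a, b in sorted(g.cells))
            rows.append({"step": step, "snp_pair": f"{pat.snp_a}+{pat.snp_b}",
                         "cohort": pat.cohort, "cells": label, "OR": g.or_,
                         "ci_low": g.ci95[0], "ci_high": g.ci95[1], "p": g.p,
                         "note": note})

    for r in report.step1:
        pair = r.factor.snp_ids
        if not r.available:
            add(None, train_gm, "step1", pair, note="N/A")
            continue
        add(r.train_pattern, train_gm, "step1", pair)
        add(r.test_refit, test_gm, "step1", pair, note="refit")
        add(r.test_pattern, test_gm, "step1", pair,
            note=f"similar={r.similarity.similar}" if r.similarity else "")
    for r in report.step2:
        add(r.pattern, test_gm, "step2", (r.pattern.snp_a, r.pattern.snp_b))
    for r in report.step3:
        add(r.train_refit, train_gm, "step3",
            (r.test_pattern.snp_a, r.test_pattern.snp_b),
            note=f"similar={r.similarity.similar}" if r.similarity else "")
    return pd.DataFrame(rows)
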