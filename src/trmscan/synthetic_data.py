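"""Synthetic case-control cohorts with planted single-SNP and two-locus effects.

The generator emulates the data structure the analysis assumes: ~1,151
subjects split 659/492 by outcome, a panel of a few hundred to a few
thousand biallelic SNPs with Hardy-Weinberg genotype frequencies, optional
LD blocks built by copy-with-mutation, sporadic completely-at-random
missingness (median-scale rate 2.6%), and planted effects — single SNPs
under a named inheritance model and two-locus genotype-combination patterns
— with odds ratios in the 1.4-2.5 range typical of reported interaction
effect sizes.  Outcomes follow a logistic disease model whose intercept is
solved for a target baseline prevalence; case-control ascertainment is by
rejection sampling from that population model, which preserves the odds-
ratio interpretation of downstream logistic fits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .geno_data import MISSING, GenotypeMatrix, ModelCode, Phenotype, SnpRecord, encode_snp

logger = logging.getLogger(__name__)

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
                 ("A", "C"), ("G", "T")]


@dataclass
class MainEffect:
    snp: int  # panel index
    model: ModelCode
    or_: float


@dataclass
class InteractionEffect:
    snp_a: int
    snp_b: int
    cells: frozenset  # (dosage_a, dosage_b) combinations carrying the effect
    or_: float


@dataclass
class CohortSpec:
    """Generator settings; the defaults mirror the emulated study structure."""

    n_cases: int = 659
    n_controls: int = 492
    n_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)  # (size, r2)
    missing_rate: float = 0.026
    main_effects: list[MainEffect] = field(default_factory=list)
    interactions: list[InteractionEffect] = field(default_factory=list)
    hwe_violators: list[int] = field(default_factory=list)  # F = 0.5 inflation
    baseline_prevalence: float = 0.3
    effect_maf: float = 0.3  # planted-effect SNPs are common variants
    snps_per_gene: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for e in self.main_effects:
            if e.or_ <= 0 or not 0 <= e.snp < self.n_snps:
                raise ValueError(f"invalid main effect {e}")
        for e in self.interactions:
            if e.or_ <= 0 or not (0 <= e.snp_a < self.n_snps
                                  and 0 <= e.snp_b < self.n_snps):
                raise ValueError(f"invalid interaction effect {e}")
        for size, r2 in self.ld_blocks:
            if r2 > 1.0:
                raise ValueError(f"unattainable LD target r2={r2} > 1")

    @property
    def n_subjects(self) -> int:
        return self.n_cases + self.n_controls


def _draw_mafs(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.maf_range
    mafs = rng.uniform(lo, hi, size=spec.n_snps)
    # SNPs in tight LD share the block anchor's allele frequency
    start = 0
    for size, _ in spec.ld_blocks:
        stop = min(start + size, spec.n_snps)
        mafs[start:stop] = mafs[start]
        start = stop
    # planted effects emulate the reported interactions, which involve common
    # variants with sizeable genotype-combination groups
    for e in spec.main_effects:
        mafs[e.snp] = spec.effect_maf
    for e in spec.interactions:
        mafs[e.snp_a] = spec.effect_maf
        mafs[e.snp_b] = spec.effect_maf
    return mafs


def _panel(spec: CohortSpec, rng: np.random.Generator) -> list[SnpRecord]:
    recs = []
    for j in range(spec.n_snps):
        major, minor = _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
        gene = f"GENE{j // max(1, spec.snps_per_gene) + 1}"
        recs.append(SnpRecord(snp_id=f"rs{100001 + j}", chromosome=str(j % 22 + 1),
                              gene_symbol=gene, major_allele=major,
                              minor_allele=minor))
    return recs


def _draw_dosages(spec: CohortSpec, mafs: np.ndarray, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Raw genotype draw: HWE per SNP, then LD blocks and HWE violators."""
    p = spec.n_snps
    dosage = rng.binomial(2, mafs[None, :].repeat(n, axis=0)).astype(np.int8)
    # LD blocks: consecutive runs; members copy the block anchor and are
    # re-drawn independently with probability m, giving r ~ (1 - m)
    start = 0
    for size, r2 in spec.ld_blocks:
        stop = min(start + size, p)
        m = 1.0 - np.sqrt(r2)
        anchor = dosage[:, start]
        for j in range(start + 1, stop):
            redraw = rng.random(n) < m
            col = anchor.copy()
            col[redraw] = rng.binomial(2, mafs[j], size=int(redraw.sum()))
            dosage[:, j] = col
        start = stop
    for j in spec.hwe_violators:
        q = mafs[j]
        f = 0.5  # inbreeding-style homozygote inflation
        probs = np.array([(1 - q) ** 2 + f * q * (1 - q),
                          2 * q * (1 - q) * (1 - f),
                          q ** 2 + f * q * (1 - q)])
        dosage[:, j] = rng.choice(3, size=n, p=probs).astype(np.int8)
    return dosage


def _linear_predictor(dosage: np.ndarray, spec: CohortSpec) -> np.ndarray:
    eta = np.zeros(dosage.shape[0])
    for e in spec.main_effects:
        eta += np.log(e.or_) * encode_snp(dosage[:, e.snp], e.model)
    for e in spec.interactions:
        da, db = dosage[:, e.snp_a], dosage[:, e.snp_b]
        ind = np.zeros(dosage.shape[0], dtype=bool)
        for (a, b) in e.cells:
            ind |= (da == a) & (db == b)
        eta += np.log(e.or_) * ind
    return eta


def _solve_intercept(spec: CohortSpec, mafs: np.ndarray,
                     rng: np.random.Generator, mc: int = 20000) -> float:
    """Intercept beta0 such that the population prevalence matches the spec."""
    if not spec.main_effects and not spec.interactions:
        pr = spec.baseline_prevalence
        return float(np.log(pr / (1 - pr)))
    pool = _draw_dosages(spec, mafs, mc, rng)
    eta = _linear_predictor(pool, spec)

    def f(b0: float) -> float:
        return float(expit(b0 + eta).mean()) - spec.baseline_prevalence

    lo, hi = -20.0, 20.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("target prevalence unachievable with the planted "
                         f"effects (prevalence={spec.baseline_prevalence})")
    return float(brentq(f, lo, hi, xtol=1e-8))


def _apply_missingness(dosage: np.ndarray, rate: float,
                       rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return dosage
    mask = rng.random(dosage.shape) < rate
    # never blank out an entire SNP
    for j in np.flatnonzero(mask.all(axis=0)):
        mask[rng.integers(dosage.shape[0]), j] = False
    out = dosage.copy()
    out[mask] = MISSING
    return out


def simulate_genotypes(spec: CohortSpec, n_subjects: int | None = None,
                       seed: int | None = None) -> GenotypeMatrix:
    """Genotype matrix alone (no outcome model): HWE draws, LD blocks,
    planted HWE violators, and MCAR missingness at the spec's rate."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mafs = _draw_mafs(spec, rng)
    n = n_subjects if n_subjects is not None else spec.n_subjects
    dosage = _draw_dosages(spec, mafs, n, rng)
    dosage = _apply_missingness(dosage, spec.missing_rate, rng)
    recs = _panel(spec, rng)
    ids = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(ids, recs, dosage)


def simulate_phenotype(gm: GenotypeMatrix, spec: CohortSpec,
                       seed: int | None = None) -> Phenotype:
    """Population (unascertained) outcome draw from the logistic model; the
    intercept is solved for the spec's baseline prevalence on these
    genotypes.  Missing calls count as dosage 0 for planted-effect terms."""
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 1)
    dosage = np.where(gm.dosage == MISSING, 0, gm.dosage)
    eta = _linear_predictor(dosage, spec)

    def f(b0: float) -> float:
        return float(expit(b0 + eta).mean()) - spec.baseline_prevalence

    b0 = float(brentq(f, -20, 20, xtol=1e-8))
    y = (rng.random(gm.n_subjects) < expit(b0 + eta)).astype(np.int8)
    if y.min() == y.max():  # tiny-n degenerate draw
        y[0] = 1 - y[0]
    return Phenotype(list(gm.subject_ids), y)


def simulate_cohort(spec: CohortSpec, seed: int | None = None,
                    mafs: np.ndarray | None = None,
                    recs: list[SnpRecord] | None = None
                    ) -> tuple[GenotypeMatrix, Phenotype]:
    """Case-control cohort with exactly n_cases/n_controls subjects.

    Rejection sampling from the population model: genotype batches are drawn
    under HWE/LD, outcomes follow the logistic model, and subjects are kept
    until both quotas are filled.  ``mafs``/``recs`` allow two cohorts to
    share one SNP panel.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if mafs is None:
        mafs = _draw_mafs(spec, rng)
    if recs is None:
        recs = _panel(spec, rng)
    b0 = _solve_intercept(spec, mafs, rng)
    need = {1: spec.n_cases, 0: spec.n_controls}
    got: dict[int, list[np.ndarray]] = {1: [], 0: []}
    have = {1: 0, 0: 0}
    batch = max(1000, spec.n_subjects)
    guard = 0
    while have[1] < need[1] or have[0] < need[0]:
        guard += 1
        if guard > 2000:  # pragma: no cover
            raise RuntimeError("case-control sampler failed to fill quotas")
        dosage = _draw_dosages(spec, mafs, batch, rng)
        prob = expit(b0 + _linear_predictor(dosage, spec))
        y = rng.random(batch) < prob
        for cls in (1, 0):
            short = need[cls] - have[cls]
            if short > 0:
                rows = np.flatnonzero(y == cls)[:short]
                if rows.size:
                    got[cls].append(dosage[rows])
                    have[cls] += rows.size
    dosage = np.vstack([np.vstack(got[1]), np.vstack(got[0])])
    y = np.concatenate([np.ones(spec.n_cases, dtype=np.int8),
                        np.zeros(spec.n_controls, dtype=np.int8)])
    # shuffle subject order so case status is not positional
    order = rng.permutation(spec.n_subjects)
    dosage, y = dosage[order], y[order]
    dosage = _apply_missingness(dosage, spec.missing_rate, rng)
    ids = [f"S{i + 1:05d}" for i in range(spec.n_subjects)]
    return GenotypeMatrix(ids, recs, dosage), Phenotype(ids, y)


def make_cohort_pair(spec: CohortSpec, panel_overlap: float = 1.0,
                     test_spec: CohortSpec | None = None,
                     seed: int | None = None
                     ) -> tuple[tuple[GenotypeMatrix, Phenotype],
                                tuple[GenotypeMatrix, Phenotype]]:
    """Two independent cohorts sharing the SNP panel and planted effects.

    The test cohort keeps a random fraction ``panel_overlap`` of the SNPs
    (planted-effect SNPs are always retained so shared effects stay
    evaluable at the genotype level; whole-pair absence is exercised by
    lowering overlap until partner genes drop out).
    """
    if not 0.0 < panel_overlap <= 1.0:
        raise ValueError("panel_overlap must lie in (0, 1]")
    seed = spec.seed if seed is None else seed
    panel_rng = np.random.default_rng(seed)
    mafs = _draw_mafs(spec, panel_rng)
    recs = _panel(spec, panel_rng)
    train = simulate_cohort(spec, seed=seed, mafs=mafs, recs=recs)
    t_spec = test_spec or spec
    test_gm, test_phen = simulate_cohort(t_spec, seed=seed + 10_000,
                                         mafs=mafs, recs=recs)
    if panel_overlap < 1.0:
        rng = np.random.default_rng(seed + 20_000)
        keep_mask = rng.random(spec.n_snps) < panel_overlap
        for e in t_spec.main_effects:
            keep_mask[e.snp] = True
        for e in t_spec.interactions:
            keep_mask[e.snp_a] = True
            keep_mask[e.snp_b] = True
        keep_ids = [test_gm.snp_ids[j] for j in np.flatnonzero(keep_mask)]
        test_gm = test_gm.subset_snps(keep_ids)
    return train, (test_gm, test_phen)


def truth_dict(spec: CohortSpec) -> dict:
    """JSON-serializable record of the planted effects (for test harnesses)."""
    return {
        "n_cases": spec.n_cases, "n_controls": spec.n_controls,
        "n_snps": spec.n_snps, "baseline_prevalence": spec.baseline_prevalence,
        "main_effects": [
            {"snp_index": e.snp, "model": e.model.value, "or": e.or_}
            for e in spec.main_effects],
        "interactions": [
            {"snp_a": e.snp_a, "snp_b": e.snp_b,
             "cells": sorted(map(list, e.cells)), "or": e.or_}
            for e in spec.interactions],
        "hwe_violators": list(spec.hwe_violators),
        "seed": spec.seed,
    }


def write_truth(spec: CohortSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth_dict(spec), indent=1))
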