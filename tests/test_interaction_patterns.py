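import numpy as np
import pytest

import trmscan as t
from trmscan.geno_data import GenotypeMatrix, Phenotype, SnpRecord
from trmscan.interaction_patterns import (ALL_CELLS, InteractionPattern,
                                          PatternGroup, cross_evaluate,
                                          derive_pattern, fit_pattern,
                                          pattern_from_factor, pattern_table,
                                          similar_pattern)
from trmscan.synthetic_data import InteractionEffect
from trmscan.trm_pipeline import Factor

from conftest import DOM_DOM_CELLS


def _gm(grid, ids=("rsA", "rsB")):
    grid = np.asarray(grid, dtype=np.int8)
    return GenotypeMatrix([f"S{i}" for i in range(grid.shape[0])],
                          [SnpRecord(s) for s in ids], grid)


class TestPatternTable:
    def test_counts_conserve_n(self):
        rng = np.random.default_rng(0)
        grid = rng.integers(0, 3, size=(300, 2))
        y = rng.integers(0, 2, 300).astype(np.int8)
        gm = _gm(grid)
        counts = pattern_table("rsA", "rsB", gm, Phenotype(gm.subject_ids, y))
        assert counts.sum() == 300
        assert counts[:, :, 1].sum() == y.sum()

    def test_monomorphic_mass_in_origin_cell(self):
        gm = _gm(np.zeros((50, 2)))
        y = np.tile([0, 1], 25).astype(np.int8)
        counts = pattern_table("rsA", "rsB", gm, Phenotype(gm.subject_ids, y))
        assert counts[0, 0].sum() == 50
        assert counts.sum() - counts[0, 0].sum() == 0

    def test_hwe_margins_for_maf_half(self):
        rng = np.random.default_rng(1)
        grid = rng.binomial(2, 0.5, size=(100_000, 2))
        gm = _gm(grid)
        y = rng.integers(0, 2, 100_000).astype(np.int8)
        counts = pattern_table("rsA", "rsB", gm, Phenotype(gm.subject_ids, y))
        marg_a = counts.sum(axis=(1, 2)) / 100_000
        np.testing.assert_allclose(marg_a, [0.25, 0.5, 0.25], atol=0.01)


class TestFitPattern:
    def test_vs_others_equals_cross_product_or(self):
        rng = np.random.default_rng(2)
        grid = rng.integers(0, 3, size=(800, 2))
        ind = (grid[:, 0] >= 1) & (grid[:, 1] >= 1)
        pr = np.where(ind, 0.55, 0.35)
        y = (rng.random(800) < pr).astype(np.int8)
        gm = _gm(grid)
        phen = Phenotype(gm.subject_ids, y)
        pat = fit_pattern("rsA", "rsB", [frozenset(DOM_DOM_CELLS)], gm, phen)
        a = ((ind) & (y == 1)).sum()
        b = ((ind) & (y == 0)).sum()
        c = ((~ind) & (y == 1)).sum()
        d = ((~ind) & (y == 0)).sum()
        assert pat.groups[0].or_ == pytest.approx(a * d / (b * c), abs=1e-6)

    def test_null_pattern_or_near_one(self):
        rng = np.random.default_rng(3)
        grid = rng.integers(0, 3, size=(5000, 2))
        y = rng.integers(0, 2, 5000).astype(np.int8)
        gm = _gm(grid)
        pat = fit_pattern("rsA", "rsB", [frozenset(DOM_DOM_CELLS)], gm,
                          Phenotype(gm.subject_ids, y))
        assert pat.groups[0].or_ == pytest.approx(1.0, abs=0.15)

    def test_empty_group_merged_into_reference(self):
        rng = np.random.default_rng(4)
        grid = np.column_stack([rng.integers(0, 2, 300),
                                rng.integers(0, 2, 300)])  # no dosage-2 cells
        gm = _gm(grid)
        y = rng.integers(0, 2, 300).astype(np.int8)
        pat = fit_pattern("rsA", "rsB",
                          [frozenset({(2, 2)}), frozenset({(1, 1)})], gm,
                          Phenotype(gm.subject_ids, y))
        assert len(pat.groups) == 1
        assert (2, 2) in pat.reference

    def test_groups_partition_grid(self):
        rng = np.random.default_rng(5)
        grid = rng.integers(0, 3, size=(400, 2))
        gm = _gm(grid)
        y = rng.integers(0, 2, 400).astype(np.int8)
        pat = fit_pattern("rsA", "rsB", [frozenset({(0, 0)})], gm,
                          Phenotype(gm.subject_ids, y))
        covered = set(pat.reference) | {c for g in pat.groups for c in g.cells}
        assert covered == set(ALL_CELLS)


def _pattern(risk_cells, or_=1.5, pair=("rsA", "rsB")):
    ref = frozenset(ALL_CELLS - set(risk_cells))
    return InteractionPattern(
        snp_a=pair[0], snp_b=pair[1], reference=ref,
        groups=[PatternGroup(cells=frozenset(risk_cells), or_=or_,
                             ci95=(or_ * 0.7, or_ * 1.4), p=0.01)])


class TestSimilarPattern:
    def test_subset_overlap_same_direction(self):
        # training risk cells {0}x{1,2} (OR 1.83) vs test risk {0}x{2}
        # (OR 1.39): overlapping like-direction cells -> similar
        a = _pattern({(0, 1), (0, 2)}, or_=1.83)
        b = _pattern({(0, 2)}, or_=1.39)
        rep = similar_pattern(a, b)
        assert rep.similar and rep.subset and rep.overlap_fraction == 1.0

    def test_direction_mismatch(self):
        a = _pattern({(0, 1), (0, 2)}, or_=1.8)
        b = _pattern({(0, 1), (0, 2)}, or_=0.6)
        assert not similar_pattern(a, b).similar

    def test_disjoint_cells(self):
        a = _pattern({(0, 1)}, or_=1.8)
        b = _pattern({(2, 2)}, or_=1.5)
        assert not similar_pattern(a, b).similar

    def test_symmetric_and_reflexive(self):
        a = _pattern({(0, 1), (1, 1)}, or_=1.4)
        b = _pattern({(1, 1)}, or_=2.0)
        assert similar_pattern(a, b).similar == similar_pattern(b, a).similar
        assert similar_pattern(a, a).similar

    def test_different_pairs_rejected(self):
        a = _pattern({(0, 1)})
        b = _pattern({(0, 1)}, pair=("rsA", "rsC"))
        with pytest.raises(ValueError):
            similar_pattern(a, b)


class TestCrossEvaluate:
    @pytest.fixture(scope="class")
    def cohort_pair(self):
        spec = t.CohortSpec(
            n_snps=40, missing_rate=0.0, seed=29, snps_per_gene=4,
            interactions=[InteractionEffect(snp_a=8, snp_b=20,
                                            cells=DOM_DOM_CELLS, or_=2.2)])
        return spec, *t.make_cohort_pair(spec, panel_overlap=1.0, seed=29)

    def test_shared_pattern_found_similar(self, cohort_pair):
        spec, (gm, y), (gm2, y2) = cohort_pair
        pair = tuple(sorted((gm.snp_ids[8], gm.snp_ids[20])))
        factor = Factor(kind="pair", snp_ids=pair, dichotomy=DOM_DOM_CELLS)
        report = cross_evaluate(gm, y, gm2, y2, [factor])
        r = report.step1[0]
        assert r.available
        assert r.similarity is not None and r.similarity.similar
        assert any(res.pattern.pair == pair for res in report.step2)

    def test_absent_snp_reported_na(self, cohort_pair):
        spec, (gm, y), (gm2, y2) = cohort_pair
        pair = tuple(sorted((gm.snp_ids[8], gm.snp_ids[20])))
        keep = [s for s in gm2.snp_ids if s != pair[0]]
        gm2_sub = gm2.subset_snps(keep)
        factor = Factor(kind="pair", snp_ids=pair, dichotomy=DOM_DOM_CELLS)
        report = cross_evaluate(gm, y, gm2_sub, y2, [factor])
        assert not report.step1[0].available

    def test_step3_refit_on_train_matches_train_fit(self, cohort_pair):
        # re-fitting a step-2 pattern on the training cohort must reproduce a
        # direct training-cohort fit of the same grouping exactly
        spec, (gm, y), (gm2, y2) = cohort_pair
        pair = tuple(sorted((gm.snp_ids[8], gm.snp_ids[20])))
        factor = Factor(kind="pair", snp_ids=pair, dichotomy=DOM_DOM_CELLS)
        report = cross_evaluate(gm, y, gm2, y2, [factor])
        for res in report.step3:
            if res.train_refit is None:
                continue
            direct = fit_pattern(res.test_pattern.snp_a,
                                 res.test_pattern.snp_b,
                                 [g.cells for g in res.test_pattern.groups],
                                 gm, y, reference=res.test_pattern.reference)
            for g1, g2 in zip(res.train_refit.groups, direct.groups):
                assert g1.or_ == pytest.approx(g2.or_, abs=1e-10)


def test_pattern_from_factor_matches_fit_pattern(planted_pair_cohort):
    _, gm, phen = planted_pair_cohort
    pair = tuple(sorted((gm.snp_ids[20], gm.snp_ids[40])))
    f = Factor(kind="pair", snp_ids=pair, dichotomy=DOM_DOM_CELLS)
    pat = pattern_from_factor(f, gm, phen)
    assert pat.groups[0].or_ > 1.5  # planted OR 2.2, sampled estimate
    assert pat.groups[0].p < 1e-3
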