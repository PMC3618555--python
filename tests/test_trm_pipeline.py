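import numpy as np
import pytest

import trmscan as t
from trmscan.geno_data import GenotypeMatrix, ModelCode, Phenotype, SnpRecord
from trmscan.synthetic_data import InteractionEffect, MainEffect
from trmscan.trm_pipeline import (Factor, bootstrap_frequencies,
                                  compare_vs_main_effects, multivariable_model,
                                  null_calibration, run_trm, select_factors)

from conftest import DOM_DOM_CELLS, scaled_trm


def _factor_main(snp="rs1", dosages=(1, 2), freq=None):
    return Factor(kind="main", snp_ids=(snp,), dichotomy=frozenset(dosages),
                  bootstrap_freq=freq)


class TestFactor:
    def test_pair_key_is_order_independent(self):
        f = Factor(kind="pair", snp_ids=("rsA", "rsB"),
                   dichotomy=frozenset({(1, 1)}))
        assert f.key() == ("pair", ("rsA", "rsB"))
        with pytest.raises(ValueError, match="sorted"):
            Factor(kind="pair", snp_ids=("rsB", "rsA"),
                   dichotomy=frozenset({(1, 1)}))

    def test_indicator_main_and_pair(self):
        gm = GenotypeMatrix(
            ["a", "b", "c"],
            [SnpRecord("rs1"), SnpRecord("rs2")],
            np.array([[0, 0], [1, 2], [2, 1]], dtype=np.int8))
        np.testing.assert_array_equal(
            _factor_main("rs1").indicator(gm), [0, 1, 1])
        pair = Factor(kind="pair", snp_ids=("rs1", "rs2"),
                      dichotomy=frozenset({(1, 2), (2, 2)}))
        np.testing.assert_array_equal(pair.indicator(gm), [0, 1, 0])


class TestSelectFactors:
    def test_strict_cutoff(self):
        freqs = (0.30, 0.06, 0.05, 0.042)
        factors = [_factor_main(f"rs{i}", freq=f) for i, f in enumerate(freqs)]
        kept = select_factors(factors, 0.05)
        assert [f.bootstrap_freq for f in kept] == [0.30, 0.06]

    def test_empty(self):
        assert select_factors([], 0.05) == []

    def test_ordering_by_descending_frequency(self):
        factors = [_factor_main(f"rs{i}", freq=f)
                   for i, f in enumerate((0.1, 0.5, 0.3))]
        kept = select_factors(factors, 0.05)
        assert [f.bootstrap_freq for f in kept] == [0.5, 0.3, 0.1]


class TestRunTrm:
    def test_planted_main_effect_recovered_as_degree_one(self,
                                                         planted_main_cohort):
        spec, gm, phen = planted_main_cohort
        planted = gm.snp_ids[30]
        hits = pair_hits = 0
        for seed in range(5):
            factors = run_trm(gm, phen, scaled_trm(seed=100 + seed))
            keys = {f.key() for f in factors}
            hits += ("main", (planted,)) in keys
            pair_hits += any(k[0] == "pair" and planted in k[1] for k in keys)
        assert hits >= 4

    def test_deterministic_given_seed(self, planted_pair_cohort):
        _, gm, phen = planted_pair_cohort
        cfg = scaled_trm(seed=77)
        f1 = run_trm(gm, phen, cfg)
        f2 = run_trm(gm, phen, cfg)
        assert [(f.key(), f.dichotomy) for f in f1] == \
            [(f.key(), f.dichotomy) for f in f2]

    def test_missing_matrix_rejected(self):
        gm = GenotypeMatrix(["a", "b"], [SnpRecord("rs1")],
                            np.array([[0], [-1]], dtype=np.int8))
        phen = Phenotype(["a", "b"], np.array([0, 1], dtype=np.int8))
        with pytest.raises(ValueError, match="impute"):
            run_trm(gm, phen, scaled_trm())


class TestBootstrapFrequencies:
    def test_single_resample_gives_binary_frequencies(self,
                                                      planted_pair_cohort):
        _, gm, phen = planted_pair_cohort
        factors = bootstrap_frequencies(gm, phen, scaled_trm(seed=31), B=1,
                                        seed=8)
        assert all(f.bootstrap_freq in (0.0, 1.0) for f in factors)

    def test_reproducible_frequency_table(self, planted_pair_cohort):
        _, gm, phen = planted_pair_cohort
        cfg = scaled_trm(seed=32)
        t1 = bootstrap_frequencies(gm, phen, cfg, B=5, seed=9)
        t2 = bootstrap_frequencies(gm, phen, cfg, B=5, seed=9)
        assert [(f.key(), f.bootstrap_freq) for f in t1] == \
            [(f.key(), f.bootstrap_freq) for f in t2]

    def test_planted_pair_outranks_null_factors(self, planted_pair_cohort):
        spec, gm, phen = planted_pair_cohort
        pair = tuple(sorted((gm.snp_ids[20], gm.snp_ids[40])))
        factors = bootstrap_frequencies(gm, phen, scaled_trm(seed=33), B=25,
                                        seed=10)
        freq = {f.key(): f.bootstrap_freq for f in factors}
        planted_freq = freq.get(("pair", pair), 0.0)
        others = [v for k, v in freq.items()
                  if not set(k[1]) & set(pair)]
        assert planted_freq > 0.05
        assert planted_freq >= max(others, default=0.0)


class TestNullCalibration:
    def test_frequency_arithmetic(self):
        # selected 30 of 500 resamples -> 6%; 21 of 500 -> 4.2%, which falls
        # below the conservative 5% retention cutoff
        assert 30 / 500 == pytest.approx(0.060)
        assert 21 / 500 == pytest.approx(0.042)
        f = _factor_main(freq=21 / 500)
        assert select_factors([f], cutoff=0.05) == []

    def test_scaled_null_percentile_small(self, null_cohort):
        _, gm, phen = null_cohort
        cal = null_calibration(gm, n1=659, n0=492, B=50, seed=3,
                               cfg=scaled_trm(seed=21))
        assert cal.B == 50
        assert cal.percentile95 < 0.10
        assert cal.cutoff >= cal.percentile95

    def test_small_b_warns(self, null_cohort):
        _, gm, phen = null_cohort
        with pytest.warns(RuntimeWarning):
            null_calibration(gm, n1=659, n0=492, B=2, seed=4,
                             cfg=scaled_trm(seed=22))


class TestMultivariableModel:
    def _cohort_with_two_factors(self, seed=0, n=2500, beta2=-0.6):
        rng = np.random.default_rng(seed)
        grid = rng.binomial(2, 0.3, size=(n, 2)).astype(np.int8)
        x1 = (grid[:, 0] >= 1).astype(float)
        x2 = (grid[:, 1] == 2).astype(float)
        pr = 1 / (1 + np.exp(-(-0.8 + 0.7 * x1 + beta2 * x2)))
        y = (rng.random(n) < pr).astype(np.int8)
        gm = GenotypeMatrix([f"S{i}" for i in range(n)],
                            [SnpRecord("rs1"), SnpRecord("rs2")], grid)
        return gm, Phenotype(gm.subject_ids, y)

    def test_orthogonal_null_covariate_leaves_estimate_unchanged(self):
        # adding an independent null factor must not move the other factor's
        # log-OR (odds ratios are non-collapsible, so this only holds exactly
        # when the added factor carries no effect)
        gm, phen = self._cohort_with_two_factors(n=30_000, beta2=0.0)
        f1 = _factor_main("rs1", (1, 2))
        f2 = Factor(kind="main", snp_ids=("rs2",), dichotomy=frozenset({2}))
        joint = multivariable_model([f1, f2], gm, phen)
        from trmscan.single_snp_assoc import fit_logistic

        sep1 = fit_logistic(f1.indicator(gm), phen.y.astype(float))
        assert joint["coef"][0] == pytest.approx(sep1.beta, abs=1e-3)

    def test_constant_indicator_dropped(self):
        gm, phen = self._cohort_with_two_factors(seed=1)
        f1 = _factor_main("rs1", (1, 2))
        f_const = Factor(kind="main", snp_ids=("rs2",),
                         dichotomy=frozenset({0, 1, 2}))
        table = multivariable_model([f1, f_const], gm, phen)
        assert len(table) == 1

    def test_collinear_duplicate_dropped(self):
        gm, phen = self._cohort_with_two_factors(seed=2)
        f1 = _factor_main("rs1", (1, 2))
        table = multivariable_model([f1, f1], gm, phen)
        assert len(table) == 1

    def test_requires_factors(self):
        gm, phen = self._cohort_with_two_factors(seed=3)
        with pytest.raises(ValueError):
            multivariable_model([], gm, phen)


class TestCompareVsMainEffects:
    def _pure_interaction_cohort(self, seed, n=2000, gamma=np.log(2.5)):
        rng = np.random.default_rng(seed)
        grid = rng.binomial(2, 0.3, size=(n, 2)).astype(np.int8)
        ind = ((grid[:, 0] >= 1) & (grid[:, 1] >= 1)).astype(float)
        pr = 1 / (1 + np.exp(-(-0.8 + gamma * ind)))
        y = (rng.random(n) < pr).astype(np.int8)
        gm = GenotypeMatrix([f"S{i}" for i in range(n)],
                            [SnpRecord("rsA"), SnpRecord("rsB")], grid)
        return gm, Phenotype(gm.subject_ids, y)

    def test_pure_interaction_detected(self):
        pair = Factor(kind="pair", snp_ids=("rsA", "rsB"),
                      dichotomy=DOM_DOM_CELLS)
        hits = 0
        for seed in range(20):
            gm, phen = self._pure_interaction_cohort(seed)
            rec = compare_vs_main_effects(pair, gm, phen)
            hits += (not rec.skipped) and rec.lrt_p < 0.01
        assert hits >= 18

    def test_collinear_interaction_skipped(self):
        # recessive-cell "interaction" of one SNP with itself-like partner:
        # a cell set reproducible from main codings is reported as skipped
        rng = np.random.default_rng(5)
        grid = np.column_stack([rng.binomial(2, 0.3, 500),
                                np.zeros(500)]).astype(np.int8)
        y = rng.integers(0, 2, 500).astype(np.int8)
        gm = GenotypeMatrix([f"S{i}" for i in range(500)],
                            [SnpRecord("rsA"), SnpRecord("rsB")], grid)
        pair = Factor(kind="pair", snp_ids=("rsA", "rsB"),
                      dichotomy=frozenset({(1, 0), (2, 0)}))
        rec = compare_vs_main_effects(pair, gm,
                                      Phenotype(gm.subject_ids, y))
        assert rec.skipped

    def test_main_factor_rejected(self):
        with pytest.raises(ValueError):
            compare_vs_main_effects(_factor_main(), None, None)
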