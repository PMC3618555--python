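import itertools

import numpy as np
import pytest

from trmscan.geno_data import SnpRecord
from trmscan.mars_engine import (BasisFunction, Ind, MarsConfig, backward_prune,
                                 cv_select_penalty, fit_mars, forward_pass,
                                 gcv_score, model_to_factors)


class TestGcv:
    def test_hand_computation(self):
        # intercept-only: C = 1, GCV = (10/100) / (1 - 1/100)^2
        assert gcv_score(10.0, 100, 1, 3.0) == pytest.approx(0.1 / 0.99 ** 2)

    def test_perfect_fit(self):
        assert gcv_score(0.0, 100, 5, 2.0) == 0.0

    def test_strictly_increasing_in_m_for_positive_d(self):
        vals = [gcv_score(50.0, 200, m, 2.0) for m in range(1, 10)]
        assert np.all(np.diff(vals) > 0)

    def test_oversized_model_rejected(self):
        with pytest.raises(ValueError):
            gcv_score(1.0, 10, 8, 3.0)


class TestBasisFunction:
    def test_degree_limit(self):
        with pytest.raises(ValueError):
            BasisFunction((("a", Ind.GE1), ("b", Ind.EQ2), ("c", Ind.GE1)))

    def test_same_snp_twice_rejected(self):
        with pytest.raises(ValueError):
            BasisFunction((("a", Ind.GE1), ("a", Ind.EQ2)))

    def test_intercept_evaluates_to_ones(self):
        cols = {"a": np.array([0, 1, 2])}
        np.testing.assert_array_equal(BasisFunction().evaluate(cols), [1, 1, 1])


class TestForwardPass:
    def test_noiseless_product_target_reaches_zero_rss(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, size=(200, 5))
        y = ((X[:, 0] >= 1) & (X[:, 1] == 2)).astype(float)
        model = forward_pass(X, [f"s{i}" for i in range(5)], y)
        rss = float(((y - model._design @ model.coefficients) ** 2).sum())
        assert rss == pytest.approx(0.0, abs=1e-10)
        assert any(b.degree == 2 and set(b.snp_ids) == {"s0", "s1"}
                   for b in model.basis)

    def test_constant_response_keeps_intercept_only(self):
        X = np.tile([0, 1, 2], (30, 1))
        model = forward_pass(X, ["a", "b", "c"], np.ones(30))
        assert model.n_basis == 1

    def test_single_candidate_has_no_degree_two(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, size=(100, 1))
        y = rng.integers(0, 2, 100).astype(float)
        model = forward_pass(X, ["only"], y)
        assert all(b.degree <= 1 for b in model.basis)

    def test_respects_max_bf(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(300, 10))
        y = rng.random(300)
        model = forward_pass(X, [f"s{i}" for i in range(10)], y, max_bf=6)
        assert model.n_basis <= 6

    def test_rss_never_increases_along_path(self):
        # adding basis functions can only reduce the least-squares RSS
        rng = np.random.default_rng(4)
        X = rng.integers(0, 3, size=(250, 6))
        y = rng.integers(0, 2, 250).astype(float)
        model = forward_pass(X, [f"s{i}" for i in range(6)], y)
        D = model._design
        prev = np.inf
        for m in range(1, D.shape[1] + 1):
            coef, *_ = np.linalg.lstsq(D[:, :m], y, rcond=None)
            rss = float(((y - D[:, :m] @ coef) ** 2).sum())
            assert rss <= prev + 1e-9
            prev = rss


class TestBackwardPrune:
    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0])
    def test_matches_exhaustive_subset_oracle(self, seed, d):
        # with <= 4 non-intercept bases the greedy deletion path attains the
        # best GCV over every subset reachable by nested deletion
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 3, size=(300, 5))
        eta = (0.5 * (X[:, 0] >= 1) - 0.4 * (X[:, 1] == 2)
               + 0.3 * ((X[:, 2] >= 1) & (X[:, 3] >= 1)))
        y = (eta + rng.normal(0, 0.6, 300) > 0.2).astype(float)
        fwd = forward_pass(X, list("abcde"), y, max_bf=5)
        pruned = backward_prune(fwd, d)
        D, yv = fwd._design, fwd._y
        n, m = D.shape[0], len(fwd.basis)
        best = np.inf
        for r in range(1, m + 1):
            for sub in itertools.combinations(range(m), r):
                if 0 not in sub:
                    continue
                Ds = D[:, list(sub)]
                coef, *_ = np.linalg.lstsq(Ds, yv, rcond=None)
                rss = float(((yv - Ds @ coef) ** 2).sum())
                best = min(best, gcv_score(rss, n, r, d))
        assert pruned.gcv == pytest.approx(best, abs=1e-12)

    def test_huge_penalty_gives_intercept_only(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, size=(200, 4))
        y = rng.integers(0, 2, 200).astype(float)
        fwd = forward_pass(X, list("abcd"), y)
        assert backward_prune(fwd, 1e6).n_basis == 1

    def test_zero_penalty_never_worsens_gcv(self):
        # at d = 0 the criterion still charges one df per basis (C = M), so
        # pruning may trim near-useless bases but can only improve GCV
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, size=(400, 4))
        x0 = (X[:, 0] >= 1).astype(float)
        y = (0.8 * x0 + rng.normal(0, 0.5, 400) > 0.4).astype(float)
        fwd = forward_pass(X, list("abcd"), y, max_bf=7)
        pruned = backward_prune(fwd, 0.0)
        full_gcv = gcv_score(
            float(((y - fwd._design @ fwd.coefficients) ** 2).sum()),
            400, fwd.n_basis, 0.0)
        assert pruned.gcv <= full_gcv + 1e-12
        assert set(pruned.basis) <= set(fwd.basis)

    def test_null_response_prunes_to_intercept(self):
        # single-SNP null fixture: d = 3 removes chance bases almost always
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(50):
            X = rng.integers(0, 3, size=(300, 1))
            y = rng.integers(0, 2, 300).astype(float)
            model = backward_prune(forward_pass(X, ["s"], y), 3.0)
            hits += model.n_basis == 1
        assert hits >= 45

    def test_saturated_two_snp_basis_reproduces_cell_means(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, size=(600, 2))
        y = rng.random(600)
        fwd = forward_pass(X, ["a", "b"], y, max_bf=30)
        cols = {"a": X[:, 0], "b": X[:, 1]}
        pred = fwd.predict(cols)
        for i in range(3):
            for j in range(3):
                cell = (X[:, 0] == i) & (X[:, 1] == j)
                if cell.sum() == 0:
                    continue
                np.testing.assert_allclose(pred[cell], y[cell].mean(),
                                           atol=1e-8)


class TestCvPenalty:
    def test_degenerate_grid(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 3, size=(100, 2))
        y = rng.integers(0, 2, 100).astype(float)
        assert cv_select_penalty(X, ["a", "b"], y, grid=(2.5,)) == 2.5

    def test_noise_ties_break_to_largest(self):
        # penalties large enough that every fold prunes to the intercept give
        # identical CV error; the tie resolves to the most conservative d
        rng = np.random.default_rng(7)
        X = rng.integers(0, 3, size=(300, 3))
        y = rng.integers(0, 2, 300).astype(float)
        assert cv_select_penalty(X, list("abc"), y, grid=(50.0, 100.0, 200.0),
                                 seed=1) == 200.0

    def test_planted_signal_survives_cv_choice(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 3, size=(2000, 5))
        ind = ((X[:, 0] >= 1) & (X[:, 1] >= 1)).astype(float)
        pr = 1 / (1 + np.exp(-(-0.8 + 1.1 * ind)))
        y = (rng.random(2000) < pr).astype(float)
        ids = [f"s{i}" for i in range(5)]
        model = fit_mars(X, ids, y, MarsConfig(seed=2))
        factors = model_to_factors(model)
        assert any(f.kind == "pair" and set(f.snp_ids) == {"s0", "s1"}
                   for f in factors)


class TestModelToFactors:
    def _model(self, bases):
        return type("M", (), {"basis": [BasisFunction()] + bases})()

    def test_main_effect_label(self):
        from trmscan.geno_data import GenotypeMatrix

        model = self._model([BasisFunction((("rs1477908", Ind.GE1),))])
        factors = model_to_factors(model)
        assert len(factors) == 1
        f = factors[0]
        assert f.kind == "main" and f.dichotomy == frozenset({1, 2})
        gm = GenotypeMatrix(
            ["s1"], [SnpRecord("rs1477908", major_allele="A",
                               minor_allele="G")],
            np.array([[0]], dtype=np.int8))
        assert f.label(gm) == "rs1477908 (AG/GG vs. AA)"

    def test_pair_complement_form(self):
        from trmscan.geno_data import GenotypeMatrix

        bf = BasisFunction((("rs1477908", Ind.EQ0), ("rs1387665", Ind.EQ0)))
        f = model_to_factors(self._model([bf]))[0]
        assert f.kind == "pair"
        assert f.snp_ids == ("rs1387665", "rs1477908")  # stored sorted
        assert f.dichotomy == frozenset({(0, 0)})
        gm = GenotypeMatrix(
            ["s1"],
            [SnpRecord("rs1387665", major_allele="A", minor_allele="G"),
             SnpRecord("rs1477908", major_allele="A", minor_allele="G")],
            np.array([[0, 0]], dtype=np.int8))
        assert f.label(gm) == "rs1387665+ rs1477908 (AA+ AA vs. others)"

    def test_intercept_only_gives_empty_list(self):
        assert model_to_factors(self._model([])) == []

    def test_duplicates_merged(self):
        bf = BasisFunction((("a", Ind.GE1),))
        factors = model_to_factors(self._model([bf, bf]))
        assert len(factors) == 1
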