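"""Block permutation, importance terms, the Z-test and cross-fitting."""

import itertools
import math

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold

from permfit import PermFITConfig, crossfit_importance, significant_features
from permfit.cohort_io import DesignMatrix
from permfit.importance import (
    ImportanceRecord,
    derive_seed,
    importance_terms,
    importance_test,
    permute_feature_block,
    records_table,
)
from permfit.model_zoo import EstimatorFactory


def _design(matrix, blocks, cont=()):
    return DesignMatrix(
        matrix=np.asarray(matrix, dtype=float),
        column_blocks=dict(blocks),
        encoding="test",
        feature_order=tuple(blocks),
        continuous_columns=tuple(cont),
    )


class FixedLogitEstimator:
    """π̂(x) = sigmoid(w·x): deterministic, ignores fitting entirely."""

    def __init__(self, weights):
        self.w = np.asarray(weights, dtype=float)

    def fit(self, design, z):
        return self

    def predict_probability(self, design):
        return 1 / (1 + np.exp(-(design @ self.w)))


class FakeFactory:
    """Duck-typed factory wrapping a fixed estimator (crossfit contract)."""

    def __init__(self, estimator, seed=0):
        self.estimator = estimator
        self.seed = seed

    def with_seed(self, seed):
        return FakeFactory(self.estimator, seed)

    def make(self):
        return self.estimator


class TestPermuteBlock:
    def _toy(self):
        rng = np.random.default_rng(0)
        return _design(rng.normal(size=(10, 4)),
                       {"a": (0, 1), "b": (1, 3), "c": (3, 4)})

    def test_identity_permutation_is_noop(self):
        d = self._toy()
        out = permute_feature_block(d, "b", rng=None, permutation=np.arange(10))
        np.testing.assert_array_equal(out.matrix, d.matrix)

    def test_single_row_design(self):
        d = _design([[1.0, 2.0]], {"a": (0, 1), "b": (1, 2)})
        out = permute_feature_block(d, "a", np.random.default_rng(0))
        np.testing.assert_array_equal(out.matrix, d.matrix)

    def test_multiset_preserved_and_other_columns_bit_identical(self):
        d = self._toy()
        out = permute_feature_block(d, "b", np.random.default_rng(5))
        block = slice(1, 3)
        orig_rows = sorted(map(tuple, d.matrix[:, block]))
        perm_rows = sorted(map(tuple, out.matrix[:, block]))
        assert orig_rows == perm_rows
        np.testing.assert_array_equal(out.matrix[:, 0], d.matrix[:, 0])
        np.testing.assert_array_equal(out.matrix[:, 3], d.matrix[:, 3])

    def test_block_rows_move_together(self):
        d = self._toy()
        out = permute_feature_block(d, "b", np.random.default_rng(5))
        np.testing.assert_array_equal(
            out.matrix[:, 1:3], d.matrix[out.permutation, 1:3]
        )

    def test_unknown_feature_lists_names(self):
        with pytest.raises(KeyError, match="valid"):
            permute_feature_block(self._toy(), "ghost", np.random.default_rng(0))


class TestImportanceTerms:
    def test_unchanged_predictions_give_zero(self):
        p = np.array([0.2, 0.7, 0.5])
        terms = importance_terms(np.array([1, 0, 1]), p, p)
        np.testing.assert_allclose(terms, 0.0, atol=1e-15)

    def test_hand_computed_values(self):
        t = importance_terms(np.array([1]), np.array([0.8]), np.array([0.4]))
        assert t[0] == pytest.approx(math.log(2), abs=1e-12)
        t = importance_terms(np.array([0]), np.array([0.2]), np.array([0.6]))
        assert t[0] == pytest.approx(math.log(2), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            importance_terms(np.array([1, 0]), np.array([0.5]), np.array([0.5, 0.5]))


class TestImportanceTest:
    def test_all_zero_terms_center_the_null(self):
        delta, var, stat, p = importance_test(np.zeros(10))
        assert (delta, var, stat, p) == (0.0, 0.0, 0.0, 0.5)

    def test_hand_computed_statistic(self):
        delta, var, stat, p = importance_test(np.array([1.0, 0.0, 1.0, 0.0]))
        assert delta == pytest.approx(0.5, abs=1e-15)
        assert var == pytest.approx(0.0625, abs=1e-15)
        assert stat == pytest.approx(2.0, abs=1e-12)
        assert p == pytest.approx(0.0227501, abs=1e-6)

    def test_invariant_to_term_order(self):
        rng = np.random.default_rng(1)
        terms = rng.normal(size=40)
        a = importance_test(terms)
        b = importance_test(rng.permutation(terms))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_degenerate_variance_branches(self):
        with pytest.warns(UserWarning, match="positive"):
            assert importance_test(np.full(5, 2.0))[3] == 0.0
        with pytest.warns(UserWarning, match="negative"):
            assert importance_test(np.full(5, -2.0))[3] == 1.0

    def test_too_few_terms_rejected(self):
        with pytest.raises(ValueError):
            importance_test(np.array([1.0]))


class TestCrossfit:
    def _setup(self, n=8):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(n, 2))
        z = np.tile([0, 1], n // 2)
        design = _design(mat, {"a": (0, 1), "b": (1, 2)})
        factory = FakeFactory(FixedLogitEstimator([1.0, -0.7]))
        return design, z, factory

    def test_identity_permutations_null_everything(self):
        design, z, factory = self._setup()
        cfg = PermFITConfig(n_folds=2, n_permutations=3, seed=5)
        records = crossfit_importance(
            design, z, factory, cfg, perm_sampler=lambda rng, n: np.arange(n)
        )
        for r in records:
            assert r.delta_hat == 0.0
            assert r.p_value == 0.5
            np.testing.assert_allclose(r.terms, 0.0, atol=1e-15)

    def test_brute_force_enumeration_oracle(self):
        """Averaging terms over every n_V! enumerated permutation equals a
        direct closed-form enumeration of the importance terms."""
        design, z, factory = self._setup(n=8)
        all_perms = list(itertools.permutations(range(4)))  # n_V = 4 per fold
        stream = itertools.cycle(all_perms)
        cfg = PermFITConfig(n_folds=2, n_permutations=len(all_perms), seed=11)
        records = crossfit_importance(
            design, z, factory, cfg,
            perm_sampler=lambda rng, n: np.array(next(stream)),
        )
        # independent oracle: same folds, direct formula, explicit enumeration
        est = factory.estimator
        splitter = StratifiedKFold(n_splits=2, shuffle=True,
                                   random_state=derive_seed(11, "folds"))
        expected = {name: [] for name in design.feature_order}
        for _, val in splitter.split(design.matrix, z):
            sub = design.matrix[val]
            zv = z[val]
            p0 = 1 / (1 + np.exp(-(sub @ est.w)))
            for name in design.feature_order:
                s, e = design.column_blocks[name]
                acc = np.zeros(len(val))
                for perm in all_perms:
                    m = sub.copy()
                    m[:, s:e] = sub[list(perm), s:e]
                    pp = 1 / (1 + np.exp(-(m @ est.w)))
                    acc += zv * np.log(p0 / pp) + (1 - zv) * np.log((1 - p0) / (1 - pp))
                expected[name].append(acc / len(all_perms))
        for r in records:
            np.testing.assert_allclose(
                r.terms, np.concatenate(expected[r.feature]), atol=1e-12
            )

    def test_no_leakage_between_folds(self):
        design, z, _ = self._setup(n=40)

        seen = []

        class Probe(FixedLogitEstimator):
            def fit(self, mat, zz):
                seen.append(np.asarray(mat).copy())
                return self

        factory = FakeFactory(Probe([0.5, 0.5]))
        cfg = PermFITConfig(n_folds=4, n_permutations=1, seed=0)
        records = crossfit_importance(design, z, factory, cfg)
        assert len(seen) == 4
        # every row appears in exactly 3 of 4 training sets
        total_rows = sum(len(m) for m in seen)
        assert total_rows == 3 * 40
        assert all(r.n_V == 40 for r in records)

    def test_constant_feature_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        mat = np.column_stack([rng.normal(size=30), np.zeros(30)])
        z = np.tile([0, 1], 15)
        design = _design(mat, {"a": (0, 1), "const": (1, 2)})
        factory = FakeFactory(FixedLogitEstimator([1.0, 1.0]))
        cfg = PermFITConfig(n_folds=3, n_permutations=2, seed=0)
        rec = {r.feature: r for r in crossfit_importance(design, z, factory, cfg)}
        assert rec["const"].degenerate
        assert rec["const"].p_value == 1.0
        assert rec["const"].delta_hat == 0.0
        assert not rec["a"].degenerate

    def test_deterministic_under_master_seed(self, sim_design, sim_cohort):
        cfg = PermFITConfig(n_folds=3, n_permutations=3, seed=21)
        f = EstimatorFactory("logistic")
        a = crossfit_importance(sim_design, sim_cohort.outcome, f, cfg)
        b = crossfit_importance(sim_design, sim_cohort.outcome, f, cfg)
        for ra, rb in zip(a, b):
            assert ra.p_value == rb.p_value
            np.testing.assert_array_equal(ra.terms, rb.terms)

    def test_signal_feature_detected_null_spared(self, sim_design, sim_cohort):
        cfg = PermFITConfig(n_folds=5, n_permutations=10, seed=2)
        recs = {r.feature: r for r in crossfit_importance(
            sim_design, sim_cohort.outcome, EstimatorFactory("logistic"), cfg
        )}
        assert recs["signal_flag"].p_value < 0.001
        assert recs["signal_flag"].delta_statistic > recs["null_even"].delta_statistic

    def test_duplicated_signal_shrinks_conditional_importance(self, sim_cohort):
        """A perfect copy of the signal feature absorbs its conditional
        importance: Δ̂ with the twin present is much smaller."""
        from permfit import encode_design_matrix

        design = encode_design_matrix(sim_cohort.table)
        s, e = design.column_blocks["signal_flag"]
        twin_mat = np.column_stack([design.matrix, design.matrix[:, s:e]])
        blocks = dict(design.column_blocks)
        blocks["signal_twin"] = (design.q, design.q + (e - s))
        twin = _design(twin_mat, blocks, cont=design.continuous_columns)
        cfg = PermFITConfig(n_folds=4, n_permutations=5, seed=9)
        fac = EstimatorFactory("logistic", {"C": 1e6})
        base = {r.feature: r for r in crossfit_importance(
            design, sim_cohort.outcome, fac, cfg)}
        dup = {r.feature: r for r in crossfit_importance(
            twin, sim_cohort.outcome, fac, cfg)}
        assert dup["signal_flag"].delta_hat < 0.5 * base["signal_flag"].delta_hat


class TestKLNonnegativity:
    def test_expected_term_is_kl_divergence(self):
        """With the true π plugged in, E_Z[Δ_ij] is the KL divergence between
        Bernoulli(π(X_i)) and Bernoulli(π(X_i^(j))) — nonnegative, zero iff
        the permutation leaves π unchanged.  Verified by enumeration."""
        x = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        w = np.array([1.2, -0.8])
        pi = 1 / (1 + np.exp(-(0.5 + x @ w)))
        for perm in itertools.permutations(range(4)):
            xp = x.copy()
            xp[:, 0] = x[list(perm), 0]
            pip = 1 / (1 + np.exp(-(0.5 + xp @ w)))
            expected_terms = pi * np.log(pi / pip) + (1 - pi) * np.log(
                (1 - pi) / (1 - pip)
            )
            assert np.all(expected_terms >= -1e-15)
            if np.allclose(pip, pi):
                np.testing.assert_allclose(expected_terms, 0.0, atol=1e-15)


class TestReporting:
    def _records(self, pvals):
        return [
            ImportanceRecord(
                feature=f"f{i}", delta_hat=0.1, terms=np.zeros(4), var_hat=0.01,
                delta_statistic=1.0, p_value=p, n_V=4, n_permutations=1,
            )
            for i, p in enumerate(pvals)
        ]

    def test_all_insignificant_gives_empty_list(self):
        cfg = PermFITConfig(alpha=0.05)
        out = significant_features(self._records([1.0, 1.0, 1.0]), cfg)
        assert len(out) == 0

    def test_alpha_one_returns_everything(self):
        cfg = PermFITConfig(alpha=1.0)
        out = significant_features(self._records([0.3, 1.0, 0.7]), cfg)
        assert len(out) == 3

    def test_ordering_p_then_schema(self):
        cfg = PermFITConfig(alpha=0.05)
        out = significant_features(self._records([0.03, 0.01, 0.03]), cfg)
        assert list(out["feature"]) == ["f1", "f0", "f2"]

    def test_benjamini_hochberg_adjustment_monotone(self):
        cfg = PermFITConfig(alpha=0.05, multiplicity_adjustment="benjamini_hochberg")
        table = records_table(self._records([0.01, 0.02, 0.04, 0.5]), cfg)
        assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()


def test_derive_seed_properties():
    assert derive_seed(3, "perm", 0, "age") == derive_seed(3, "perm", 0, "age")
    assert derive_seed(3, "perm", 0, "age") != derive_seed(3, "perm", 0, "gender")
    assert derive_seed(3, "a") != derive_seed(4, "a")
    assert 0 <= derive_seed(2**30, "x", 99) < 2**31
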