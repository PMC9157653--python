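"""Tests of the cross-validation engine, metrics and transfer scenarios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solgs import evaluate as ev
from solgs import gs_class, simdata
from solgs.evaluate import (ScenarioSpec, build_scenarios, make_cv_folds,
                            map_regression_to_categories, metric_accuracy,
                            metric_auc, metric_pearson, metric_spearman,
                            metric_top_match, paired_t_test)


class TestMakeCvFolds:
    def test_fold_sizes(self):
        scheme = make_cv_folds([f"a{i}" for i in range(10)], 5, 1, seed=0)
        sizes = np.bincount(scheme.assignments[0])
        assert sizes.tolist() == [2, 2, 2, 2, 2]

    def test_sizes_differ_by_at_most_one(self):
        scheme = make_cv_folds([f"a{i}" for i in range(23)], 5, 3, seed=1)
        for r in range(3):
            sizes = np.bincount(scheme.assignments[r])
            assert sizes.max() - sizes.min() <= 1

    def test_each_accession_tested_once_per_repetition(self):
        scheme = make_cv_folds([f"a{i}" for i in range(17)], 5, 30, seed=2)
        counts = np.zeros(17, dtype=int)
        for _, _, _, test in ev.iter_splits(scheme):
            counts[test] += 1
        assert np.all(counts == 30)

    def test_deterministic(self):
        a = make_cv_folds(list("abcdefghij"), 5, 4, seed=3)
        b = make_cv_folds(list("abcdefghij"), 5, 4, seed=3)
        np.testing.assert_array_equal(a.assignments, b.assignments)


class TestRegressionMetrics:
    def test_pearson_trivial(self):
        y = np.array([1.0, 2.0, 4.0, 3.0])
        assert metric_pearson(y, y) == pytest.approx(1.0)
        assert metric_pearson(-y, y) == pytest.approx(-1.0)
        assert metric_pearson(2 * y + 3, y) == pytest.approx(1.0)

    def test_spearman_trivial(self):
        y = np.array([1.0, 2.0, 4.0, 3.0])
        assert metric_spearman(y**3, y) == pytest.approx(1.0)
        assert metric_spearman(-y, y) == pytest.approx(-1.0)

    def test_constant_is_missing(self):
        assert np.isnan(metric_pearson(np.ones(5), np.arange(5.0)))
        assert np.isnan(metric_spearman(np.arange(5.0), np.ones(5)))

    def test_top_match_enumerations(self):
        y = np.arange(10.0)
        assert metric_top_match(y, y, 0.3) == pytest.approx(1.0)
        assert metric_top_match(-y, y, 0.3) == pytest.approx(0.0)
        # overlap of exactly 2 in the top-3 sets
        yhat = y.copy()
        yhat[9] = -5  # drop the top item out of the predicted top-3
        assert metric_top_match(yhat, y, 0.3) == pytest.approx(2 / 3)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([0.15, 0.3]))
    def test_top_match_range(self, seed, frac):
        rng = np.random.default_rng(seed)
        yhat, y = rng.standard_normal(20), rng.standard_normal(20)
        assert 0.0 <= metric_top_match(yhat, y, frac) <= 1.0


class TestClassificationMetrics:
    def test_accuracy(self):
        assert metric_accuracy(list("AAB"), list("ABB")) == pytest.approx(2 / 3)
        assert metric_accuracy([1, 2], [1, 2]) == 1.0
        assert metric_accuracy([1, 2], [2, 1]) == 0.0

    def test_auc_perfect_and_invariance(self):
        truth = np.array([0, 0, 1, 1])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        assert metric_auc(scores, truth, classes=[0, 1]) == pytest.approx(1.0)
        # strictly increasing transform leaves the rank statistic unchanged
        assert metric_auc(scores**3, truth, classes=[0, 1]) == pytest.approx(1.0)

    def test_auc_null(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 500)
        s = rng.random(500)
        scores = np.column_stack([1 - s, s])
        assert abs(metric_auc(scores, truth, classes=[0, 1]) - 0.5) < 0.05

    def test_auc_multiclass_macro(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 3, 300)
        scores = np.eye(3)[truth] * 0.8 + 0.1
        assert metric_auc(scores, truth, classes=[0, 1, 2]) == pytest.approx(1.0)

    def test_auc_single_class_rejected(self):
        with pytest.raises(ValueError):
            metric_auc(np.ones((4, 2)) / 2, np.zeros(4))


class TestRegressionToCategories:
    def test_counts_follow_proportions(self):
        labels = map_regression_to_categories(np.arange(10.0), (0.2, 0.2, 0.6))
        assert np.bincount(labels).tolist() == [2, 2, 6]

    def test_perfect_order_gives_perfect_accuracy(self):
        y = np.random.default_rng(2).standard_normal(20)
        truth = simdata.derive_categorical_trait(y, (0.25, 0.5, 0.25))
        mapped = map_regression_to_categories(y, (0.25, 0.5, 0.25))
        assert metric_accuracy(mapped, truth) == 1.0

    def test_monotone_invariance(self):
        y = np.random.default_rng(3).standard_normal(15)
        a = map_regression_to_categories(y, (0.4, 0.6))
        b = map_regression_to_categories(3 * y + 7, (0.4, 0.6))
        np.testing.assert_array_equal(a, b)


class TestPairedTTest:
    def test_equal_samples(self):
        a = np.arange(10.0)
        t, p = paired_t_test(a, a)
        assert t == 0.0 and p == 1.0

    def test_swap_negates_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal(30), rng.standard_normal(30)
        t1, p1 = paired_t_test(a, b)
        t2, p2 = paired_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_shift_becomes_significant(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal(150)
        _, p_small = paired_t_test(base + 0.05, base + rng.standard_normal(150) * 0.5)
        _, p_big = paired_t_test(base + 5.0, base + rng.standard_normal(150) * 0.5)
        assert p_big < 1e-10
        assert p_big < p_small


@pytest.fixture(scope="module")
def linear_panel():
    rng = np.random.default_rng(6)
    # fewer markers than any training fold so a noiseless linear trait is
    # exactly interpolable by the kernel model
    Z = rng.binomial(2, 0.5, size=(60, 30)).astype(float)
    return Z


class TestRunCv:
    def test_perfect_signal(self, linear_panel):
        y = 2.0 * linear_panel[:, 0] + 1.0
        scheme = make_cv_folds([f"a{i}" for i in range(60)], 5, 2, seed=7)
        rep = ev.run_cv_regression(linear_panel, y, scheme)
        assert rep.records["pearson"].mean() >= 0.99

    def test_record_count(self, linear_panel):
        y = np.random.default_rng(8).standard_normal(60)
        scheme = make_cv_folds([f"a{i}" for i in range(60)], 5, 6, seed=9)
        rep = ev.run_cv_regression(linear_panel, y, scheme)
        assert len(rep.records) == 30

    def test_null_trait_near_zero(self, linear_panel):
        y = np.random.default_rng(10).standard_normal(60)
        scheme = make_cv_folds([f"a{i}" for i in range(60)], 5, 6, seed=11)
        rep = ev.run_cv_regression(linear_panel, y, scheme)
        assert -0.1 < rep.records["pearson"].mean() < 0.1

    def test_no_test_fold_leakage(self, linear_panel):
        """Every fit sees only its training fold (sentinel accession check)."""
        y = np.random.default_rng(12).standard_normal(60)
        scheme = make_cv_folds([f"a{i}" for i in range(60)], 5, 2, seed=13)
        seen = []
        ev.run_cv_regression(linear_panel, y, scheme,
                             fold_callback=lambda tr: seen.append(set(tr)))
        for (r, f, train, test), s in zip(ev.iter_splits(scheme), seen):
            assert s == set(train)
            assert s.isdisjoint(test)

    def test_classification_cv_smote_in_training_only(self, linear_panel):
        labels = (linear_panel[:, 0] + linear_panel[:, 1] > 1.8).astype(int)
        spec = gs_class.ClassifierSpec(family="tree_ensemble", n_trees=50, seed=0)
        scheme = make_cv_folds([f"a{i}" for i in range(60)], 5, 1, seed=14)
        rep = ev.run_cv_classification(linear_panel, labels, spec, scheme)
        assert {"accuracy", "auc"} <= set(rep.records.columns)
        assert rep.records["accuracy"].between(0, 1).all()

    def test_summary_shape(self, linear_panel):
        y = np.random.default_rng(15).standard_normal(60)
        scheme = make_cv_folds([f"a{i}" for i in range(60)], 5, 2, seed=16)
        summary = ev.run_cv_regression(linear_panel, y, scheme).summary()
        assert list(summary.columns) == ["mean", "sd"]
        assert "pearson" in summary.index


@pytest.fixture(scope="module")
def meta():
    species = (["cultivated"] * 20
               + ["w1"] * 4 + ["w2"] * 3 + ["w3"] * 2 + ["w4"] * 2
               + ["w5"] * 1 + ["w6"] * 1 + ["w7"] * 1)
    ids = [f"a{i}" for i in range(len(species))]
    return pd.DataFrame({"species": species,
                         "is_wild": [s != "cultivated" for s in species]},
                        index=pd.Index(ids, name="accession"))


class TestBuildScenarios:
    def test_baseline_single_split(self, meta):
        splits = build_scenarios(meta, ScenarioSpec(mode="baseline_transfer"))
        assert len(splits) == 1
        train, test = splits[0]
        assert len(train) == 20 and len(test) == 14

    def test_wild_augment_stratified(self, meta):
        spec = ScenarioSpec(mode="wild_augment", n_wild=7, n_draws=20, seed=1)
        for train, test in build_scenarios(meta, spec):
            wild_train = meta.loc[train][meta.loc[train, "is_wild"]]
            assert sorted(wild_train["species"].unique()) == [f"w{i}" for i in
                                                              range(1, 8)]
            assert len(wild_train) == 7
            assert set(train).isdisjoint(test)
            assert set(train) | set(test) == set(meta.index)

    def test_wild_balanced_counts(self, meta):
        spec = ScenarioSpec(mode="wild_balanced", n_wild=8, n_draws=10, seed=2)
        for train, test in build_scenarios(meta, spec):
            sub = meta.loc[train]
            assert sub["is_wild"].sum() == 8
            assert (~sub["is_wild"]).sum() == 8
            assert set(train).isdisjoint(test)

    def test_too_few_wild_rejected(self, meta):
        spec = ScenarioSpec(mode="wild_augment", n_wild=3, n_draws=2, seed=3)
        with pytest.raises(ValueError):
            build_scenarios(meta, spec)

    def test_deterministic(self, meta):
        spec = ScenarioSpec(mode="wild_augment", n_wild=7, n_draws=5, seed=4)
        a = build_scenarios(meta, spec)
        b = build_scenarios(meta, spec)
        for (ta, sa), (tb, sb) in zip(a, b):
            np.testing.assert_array_equal(np.sort(ta), np.sort(tb))


def test_transfer_gain_saturates():
    """Most of the transfer gain comes from the first stratified wild
    sample: the 7 -> 30 increase is smaller than the 0 -> 7 jump."""
    import warnings

    from solgs.simdata import PopulationSpec, TraitSpec

    spec = PopulationSpec(n_cultivated=146,
                          wild_group_sizes=simdata.DEFAULT_WILD_SIZES,
                          n_snps=4000, n_chromosomes=12, ld_rho=0.9,
                          fst_wild=0.7, missing_rate=0.0, seed=7000)
    G = simdata.simulate_genotypes(spec)
    G_causal = G.take_variants(np.arange(0, G.n_variants, 2))
    G_marker = G.take_variants(np.arange(1, G.n_variants, 2))
    tbl, _ = simdata.simulate_trait(
        G_causal, TraitSpec(n_qtl=300, h2=0.8, n_trials=1, n_reps=1,
                            trial_var_frac=0.0, seed=7001))
    y = (tbl.set_index("accession")["value"]
         .loc[list(G.accession_ids)].to_numpy())
    Z = G_marker.dosage.astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = ev.evaluate_transfer(Z, y, G.accession_ids, build_scenarios(
            G.meta, ScenarioSpec(mode="baseline_transfer")))
        means = {}
        for n_wild in (7, 30):
            splits = build_scenarios(G.meta, ScenarioSpec(
                mode="wild_augment", n_wild=n_wild, n_draws=60, seed=7002))
            means[n_wild] = float(ev.evaluate_transfer(
                Z, y, G.accession_ids, splits)["pearson"].mean())
    jump = means[7] - float(base["pearson"].mean())
    assert jump > 0
    assert means[30] - means[7] < jump
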