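"""Tests for splitters, metrics, cross-validation and the tuning grid."""

import itertools
import warnings

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression

import synpair as sp
from synpair.nn import TrainingDiverged

from conftest import make_toy_samples


def _brute_force_auroc(labels, scores):
    """Concordant-pair count over all positive-negative pairs (ties = 1/2)."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = concordant = 0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                concordant += 1
            elif p == n:
                concordant += 0.5
    return concordant / total


class TestSplitters:
    @pytest.mark.parametrize("splitter", [sp.split_leave_triple_out, sp.split_leave_pair_out])
    def test_partition_and_determinism(self, splitter):
        samples = sp.augment_order_swap(make_toy_samples(n_drugs=6, n_ccls=4))
        a = splitter(samples, k=5, seed=11)
        b = splitter(samples, k=5, seed=11)
        assert a.assignment == b.assignment
        assert sorted(a.assignment) == list(range(len(samples)))
        assert set(a.assignment.values()) == set(range(5))

    def test_mirrors_share_fold_in_leave_triple_out(self):
        samples = sp.augment_order_swap(make_toy_samples(n_drugs=6, n_ccls=4))
        fold = sp.split_leave_triple_out(samples, k=5, seed=2)
        by_triple = {}
        for i, s in enumerate(samples):
            by_triple.setdefault((s.pair_key, s.ccl_id), set()).add(fold.assignment[i])
        assert all(len(folds) == 1 for folds in by_triple.values())

    def test_leave_pair_out_no_leakage_random_fixtures(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n_drugs = int(rng.integers(5, 9))
            n_ccls = int(rng.integers(2, 5))
            k = int(rng.integers(2, 5))
            samples = sp.augment_order_swap(
                make_toy_samples(n_drugs=n_drugs, n_ccls=n_ccls, seed=trial)
            )
            fold = sp.split_leave_pair_out(samples, k=k, seed=trial)
            for f in range(k):
                train_pairs = {samples[i].pair_key for i in fold.train_indices(f)}
                test_pairs = {samples[i].pair_key for i in fold.test_indices(f)}
                assert train_pairs & test_pairs == set()

    def test_fold_sizes_differ_by_at_most_one_group(self):
        samples = make_toy_samples(n_drugs=7, n_ccls=3)  # 21 pairs
        fold = sp.split_leave_pair_out(samples, k=5, seed=1)
        pair_counts = [
            len({samples[i].pair_key for i in fold.test_indices(f)}) for f in range(5)
        ]
        assert max(pair_counts) - min(pair_counts) <= 1

    def test_five_pairs_k5_exact_membership(self):
        # 5 pairs x 3 CCLs x 2 orders = 30 samples, k=5 -> 6 samples per fold
        all_samples = make_toy_samples(n_drugs=5, n_ccls=3)
        pairs = sorted({s.pair_key for s in all_samples})[:5]
        subset = [s for s in all_samples if s.pair_key in pairs]
        samples = sp.augment_order_swap(subset)
        fold = sp.split_leave_pair_out(samples, k=5, seed=3)
        for f in range(5):
            te = fold.test_indices(f)
            assert len(te) == 6
            assert len({samples[i].pair_key for i in te}) == 1

    def test_k_exceeding_groups_is_error(self):
        samples = make_toy_samples(n_drugs=3, n_ccls=1)  # 3 pairs
        with pytest.raises(sp.ValidationError, match="exceeds"):
            sp.split_leave_pair_out(samples, k=4)


class TestRegressionMetrics:
    def test_identity(self):
        m = sp.regression_metrics([1, 2, 3], [1, 2, 3])
        assert m["rmse"] == 0.0
        assert m["scc"] == pytest.approx(1.0)
        assert m["pcc"] == pytest.approx(1.0)

    def test_reversed_order(self):
        m = sp.regression_metrics([0, 1, 2, 3], [3, 2, 1, 0])
        assert m["scc"] == pytest.approx(-1.0)
        assert m["pcc"] == pytest.approx(-1.0)
        assert m["rmse"] == pytest.approx(np.sqrt(5.0))

    def test_constant_offset(self):
        m = sp.regression_metrics([1, 2, 3], [2, 3, 4])
        assert m["rmse"] == pytest.approx(1.0)
        assert m["pcc"] == pytest.approx(1.0)

    def test_scale_invariance_of_correlations(self):
        rng = np.random.default_rng(4)
        y, p = rng.normal(size=50), rng.normal(size=50)
        base = sp.regression_metrics(y, p)
        scaled = sp.regression_metrics(y, 3.7 * p + 11.0)
        assert scaled["pcc"] == pytest.approx(base["pcc"])
        assert scaled["scc"] == pytest.approx(base["scc"])
        assert scaled["rmse"] != pytest.approx(base["rmse"])

    def test_constant_input_warns_nan(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            m = sp.regression_metrics([1, 1, 1], [1, 2, 3])
        assert np.isnan(m["pcc"]) and np.isnan(m["scc"])
        assert m["rmse"] >= 0


class TestBinarize:
    def test_band_discard(self):
        labels, retained = sp.binarize_scores([-6, -0.5, 0.2, 7], t=1)
        np.testing.assert_array_equal(retained, [0, 3])
        np.testing.assert_array_equal(labels, [0, 1])

    def test_zero_threshold_discards_exact_zeros(self):
        labels, retained = sp.binarize_scores([-1, 0, 2], t=0)
        np.testing.assert_array_equal(retained, [0, 2])
        np.testing.assert_array_equal(labels, [0, 1])

    def test_retained_set_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(scale=10, size=200)
        sizes = [sp.binarize_scores(scores, t)[1].size for t in (0, 1, 5, 10, 20)]
        assert sizes == sorted(sizes, reverse=True)

    def test_degenerate_threshold_empties_the_set(self):
        labels, retained = sp.binarize_scores([-19, 3, 15], t=20)
        assert retained.size == 0

    def test_negative_threshold_rejected(self):
        with pytest.raises(sp.ValidationError):
            sp.binarize_scores([1.0], t=-1)


class TestAuroc:
    def test_examples(self):
        assert sp.auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert sp.auroc([1, 0], [0.3, 0.3]) == 0.5
        assert sp.auroc([1, 1, 0, 0], [4, 2, 3, 1]) == pytest.approx(0.75)

    def test_one_class_warns_nan(self):
        with pytest.warns(RuntimeWarning, match="class"):
            assert np.isnan(sp.auroc([1, 1], [0.2, 0.3]))

    def test_exhaustive_small_sets_match_pair_counting(self):
        rng = np.random.default_rng(9)
        for n in range(2, 9):
            scores = rng.integers(0, 4, size=n).astype(float)  # force ties
            for labels in itertools.product([0, 1], repeat=n):
                if len(set(labels)) < 2:
                    continue
                assert sp.auroc(labels, scores) == pytest.approx(
                    _brute_force_auroc(labels, scores)
                )

    def test_random_larger_sets_match_pair_counting(self):
        rng = np.random.default_rng(10)
        for _ in range(1000):
            n = int(rng.integers(9, 40))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.normal(size=n), 1)  # occasional ties
            assert sp.auroc(labels, scores) == pytest.approx(
                _brute_force_auroc(labels, scores)
            )


class TestCrossValidate:
    def test_shapes_and_shared_folds(self, tiny_dataset):
        samples, _, _ = tiny_dataset
        report = sp.cross_validate(samples, LinearRegression(), k=4, seed=0)
        assert len(report.per_fold) == 4
        assert np.isfinite(report.per_fold["rmse"]).all()
        assert {"rmse", "scc", "pcc", "auroc_t0"} <= set(report.per_fold.columns)

    def test_identical_memberships_across_variants(self, tiny_dataset):
        samples, _, _ = tiny_dataset
        fold = sp.split_leave_pair_out(samples, k=3, seed=5)
        r1 = sp.cross_validate(samples, LinearRegression(), fold_assignment=fold)
        from sklearn.linear_model import Ridge

        r2 = sp.cross_validate(samples, Ridge(), fold_assignment=fold)
        assert r1.strategy == r2.strategy == "leave_pair_out"
        # same memberships -> identical true-score layout, metrics comparable
        assert len(r1.per_fold) == len(r2.per_fold) == 3

    def test_k_of_one_is_error(self, tiny_dataset):
        samples, _, _ = tiny_dataset
        with pytest.raises(sp.ValidationError):
            sp.cross_validate(samples, LinearRegression(), k=1)

    def test_mean_std_aggregation(self, tiny_dataset):
        samples, _, _ = tiny_dataset
        report = sp.cross_validate(samples, LinearRegression(), k=3, seed=1)
        summary = report.summary()
        assert summary.loc["rmse", "mean"] == pytest.approx(report.per_fold["rmse"].mean())
        assert summary.loc["rmse", "std"] == pytest.approx(report.per_fold["rmse"].std(ddof=1))


class _Diverging(sp.SynergyRegressor):
    def fit(self, X, y):
        raise TrainingDiverged("synthetic divergence")


class TestGrid:
    def test_default_grid_enumerates_576_combinations(self):
        combos = sp.enumerate_grid(sp.default_hyperparameter_grid())
        assert len(combos) == 576
        assert all("learning_rate" in c and "width_scale" in c for c in combos)

    def test_two_by_two_grid(self, tiny_dataset):
        samples, _, _ = tiny_dataset
        grid = {
            "learning_rate": [0.01, 0.001],
            "optimizer": ["adam", "adamax"],
        }
        base = sp.SynergyRegressor(
            drug_dim=samples[0].drug_dim, width_scale=0.02, max_epochs=2, batch_size=32
        )
        table = sp.grid_search(samples, grid=grid, seed=0, base_estimator=base)
        assert len(table) == 4
        assert table["converged"].all()
        assert table["rank"].notna().all()

    def test_diverged_runs_flagged_and_unranked(self, tiny_dataset):
        samples, _, _ = tiny_dataset
        base = _Diverging(drug_dim=samples[0].drug_dim)
        table = sp.grid_search(samples, grid={"learning_rate": [0.01]}, base_estimator=base)
        assert not table["converged"].iloc[0]
        assert table["rank"].isna().all()

    def test_empty_grid_rejected(self, tiny_dataset):
        samples, _, _ = tiny_dataset
        with pytest.raises(sp.ValidationError):
            sp.grid_search(samples, grid={"learning_rate": []})


class TestSignatureCorrelation:
    def test_constructed_identity_gives_unit_pcc(self, tiny_world):
        sig_ccl = tiny_world.signatures.signature_ccl_order[0]
        drugs = tiny_world.drug_ids
        records = []
        from scipy.stats import pearsonr

        for i in range(len(drugs) - 1):
            d1, d2 = drugs[i], drugs[i + 1]
            sim = pearsonr(
                tiny_world.signatures.consensus(d1, sig_ccl),
                tiny_world.signatures.consensus(d2, sig_ccl),
            ).statistic
            records.append(sp.SynergyRecord(d1, d2, "CCL000", "ZIP", float(sim), 0.0, 0.0, "c"))
        out = sp.signature_correlation_vs_synergy(tiny_world.signatures, records, sig_ccl)
        assert out["pcc"] == pytest.approx(1.0)
        assert out["scc"] == pytest.approx(1.0)

    def test_independent_synergy_gives_small_correlation(self):
        # a null world: synergy drawn independently of signature similarity
        rng = np.random.default_rng(6)
        n_drugs, dim = 40, 30
        entries = {
            (f"d{i}", "S0", "r0"): rng.normal(size=dim) for i in range(n_drugs)
        }
        sigs = sp.DrugSignatureSet(entries, landmark_dim=dim, signature_ccl_order=("S0",))
        records = []
        for _ in range(600):
            i, j = rng.choice(n_drugs, size=2, replace=False)
            records.append(
                sp.SynergyRecord(f"d{i}", f"d{j}", "c0", "ZIP", float(rng.normal()), 0.0, 0.0, "r")
            )
        out = sp.signature_correlation_vs_synergy(sigs, records, "S0")
        assert abs(out["pcc"]) < 0.1

    def test_too_few_triples_is_error(self, tiny_world):
        sig_ccl = tiny_world.signatures.signature_ccl_order[0]
        d1, d2 = tiny_world.drug_ids[:2]
        recs = [sp.SynergyRecord(d1, d2, "c", "ZIP", 1.0, 0.0, 0.0, "r")] * 2
        with pytest.raises(sp.ValidationError):
            sp.signature_correlation_vs_synergy(tiny_world.signatures, recs, sig_ccl)
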