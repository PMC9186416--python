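"""SVM classification, the ROA score, and the component-level analyses."""

import numpy as np
import pytest
from scipy import stats

from htssr.blocks import TASKS, BlockIndex
from htssr.classify import (
    SampleFeatures,
    ablation_experiment,
    build_samples,
    capacity_vs_overlap,
    compute_roa,
    evaluate_accuracy,
    roa_incremental_classification,
    train_svm,
)
from htssr.features import ReferenceTemplate
from htssr.sparse import SparseCodes


def _codes(rng, k2, k1, subjects, scale=1.0):
    idx = BlockIndex(subjects=subjects, tasks=TASKS, n_inner=k1)
    return SparseCodes(scale * rng.standard_normal((k2, idx.n_columns)), lam=0.1), idx


class TestBuildSamples:
    def test_sample_and_feature_counts(self, rng):
        codes, idx = _codes(rng, k2=5, k1=6, subjects=("a", "b", "c"))
        samples = build_samples(codes, idx)
        assert len(samples) == 3 * 7
        assert all(s.features.size == 5 * 6 for s in samples)

    def test_single_subject_gives_seven_samples(self, rng):
        codes, idx = _codes(rng, k2=4, k1=3, subjects=("only",))
        assert len(build_samples(codes, idx)) == 7

    def test_flatten_unflatten_roundtrip(self, rng):
        """Component-major flattening is invertible entry by entry."""
        codes, idx = _codes(rng, k2=3, k1=4, subjects=("a", "b"))
        samples = build_samples(codes, idx)
        for s in samples:
            block = codes.coefficients[:, idx.block(s.subject_id, s.task_label)]
            back = s.features.reshape(3, 4)
            np.testing.assert_array_equal(back, block)
            for c in range(3):
                for j in range(4):
                    assert s.features[c * 4 + j] == block[c, j]


class TestSvm:
    def test_separable_toy_is_memorized(self, rng):
        X = np.vstack([rng.normal(-5, 0.1, (10, 3)), rng.normal(5, 0.1, (10, 3))])
        samples = [
            SampleFeatures("s", "emotion" if i < 10 else "motor", X[i])
            for i in range(20)
        ]
        clf = train_svm(samples)
        acc, _ = evaluate_accuracy(clf, samples)
        assert acc == 1.0

    def test_retraining_is_deterministic(self, rng):
        codes, idx = _codes(rng, k2=4, k1=5, subjects=("a", "b", "c"))
        samples = build_samples(codes, idx)
        a = train_svm(samples)
        b = train_svm(samples)
        X = np.stack([s.features for s in samples])
        np.testing.assert_array_equal(a.model.predict(X), b.model.predict(X))

    def test_permuted_labels_score_near_chance(self, rng):
        """Training on permuted labels yields held-out accuracy compatible
        with 1/7 guessing (binomial tolerance)."""
        n_train, n_test = 10, 30
        train_codes, idx_tr = _codes(
            rng, 6, 5, tuple(f"tr{i}" for i in range(n_train))
        )
        test_codes, idx_te = _codes(rng, 6, 5, tuple(f"te{i}" for i in range(n_test)))
        train = build_samples(train_codes, idx_tr)
        test = build_samples(test_codes, idx_te)
        perm = rng.permutation(len(train))
        shuffled = [
            SampleFeatures(s.subject_id, train[j].task_label, s.features)
            for s, j in zip(train, perm)
        ]
        clf = train_svm(shuffled)
        acc, _ = evaluate_accuracy(clf, test)
        n = len(test)
        se = np.sqrt((1 / 7) * (6 / 7) / n)
        assert abs(acc - 1 / 7) < 5 * se

    def test_single_class_rejected(self, rng):
        samples = [SampleFeatures("s", "wm", rng.standard_normal(4)) for _ in range(5)]
        with pytest.raises(ValueError, match="two classes"):
            train_svm(samples)

    def test_accuracy_equals_confusion_trace(self, rng):
        codes, idx = _codes(rng, 4, 5, ("a", "b", "c", "d"))
        samples = build_samples(codes, idx)
        clf = train_svm(samples[:21])
        acc, confusion = evaluate_accuracy(clf, samples[21:])
        assert acc == pytest.approx(np.trace(confusion) / confusion.sum())

    def test_feature_length_mismatch_rejected(self, rng):
        codes, idx = _codes(rng, 4, 5, ("a", "b"))
        clf = train_svm(build_samples(codes, idx))
        bad = [SampleFeatures("x", "wm", np.zeros(3))]
        with pytest.raises(ValueError, match="feature length"):
            evaluate_accuracy(clf, bad)


class TestComputeRoa:
    @staticmethod
    def _codes_from_counts(counts, k1, p=1):
        """Codes whose per-task support counts match ``counts`` exactly."""
        k2, T = counts.shape
        idx = BlockIndex(subjects=tuple(f"s{i}" for i in range(p)), tasks=TASKS[:T],
                         n_inner=k1)
        coeffs = np.zeros((k2, idx.n_columns))
        for i in range(k2):
            for t in range(T):
                cols = idx.task_columns(t)[: counts[i, t]]
                coeffs[i, cols] = 1.0
        return SparseCodes(coeffs, lam=0.1), idx

    def test_equal_counts_give_zero(self):
        counts = np.full((3, 7), 4)
        codes, idx = self._codes_from_counts(counts, k1=5)
        roa = compute_roa(codes, idx)
        np.testing.assert_allclose(roa.values, 0.0, atol=1e-12)

    def test_all_zero_row_gives_zero(self, rng):
        codes, idx = _codes(rng, 3, 4, ("a",))
        coeffs = codes.coefficients.copy()
        coeffs[1] = 0.0
        roa = compute_roa(SparseCodes(coeffs, lam=0.1), idx)
        assert roa.values[1] == 0.0

    def test_two_task_pair_is_log_count_ratio(self):
        """T=2, counts (4, 1), no pseudocount: the only pair gives |log 4|,
        enumerated by hand."""
        idx = BlockIndex(subjects=("s0",), tasks=("a", "b"), n_inner=8)
        coeffs = np.zeros((1, idx.n_columns))
        coeffs[0, idx.task_columns(0)[:4]] = 1.0
        coeffs[0, idx.task_columns(1)[:1]] = 1.0
        roa = compute_roa(SparseCodes(coeffs, lam=0.1), idx, pseudocount=0.0)
        assert roa.values[0] == pytest.approx(np.log(4.0), abs=1e-12)

    def test_scale_invariance_of_supports(self, rng):
        codes, idx = _codes(rng, 4, 5, ("a", "b"))
        roa1 = compute_roa(codes, idx)
        roa2 = compute_roa(SparseCodes(37.0 * codes.coefficients, lam=0.1), idx)
        np.testing.assert_array_equal(roa1.values, roa2.values)

    def test_uniform_random_support_converges_to_zero(self, rng):
        """Rows supported i.i.d. uniformly over task columns have ROA -> 0
        as counts grow."""
        idx = BlockIndex(subjects=tuple(f"s{i}" for i in range(8)), tasks=TASKS,
                         n_inner=400)
        coeffs = (rng.random((2, idx.n_columns)) < 0.5).astype(float)
        roa = compute_roa(SparseCodes(coeffs, lam=0.1), idx)
        assert np.all(roa.values < 0.05)

    def test_tie_break_ascending_index(self):
        counts = np.full((4, 7), 3)
        codes, idx = self._codes_from_counts(counts, k1=5)
        roa = compute_roa(codes, idx)
        np.testing.assert_array_equal(roa.rank_order, np.arange(4))

    def test_literal_convention_scales_by_task_count(self):
        idx = BlockIndex(subjects=("s0",), tasks=("a", "b"), n_inner=8)
        coeffs = np.zeros((1, idx.n_columns))
        coeffs[0, idx.task_columns(0)[:4]] = 1.0
        coeffs[0, idx.task_columns(1)[:1]] = 1.0
        pair = compute_roa(SparseCodes(coeffs, lam=0.1), idx, pseudocount=0.0)
        lit = compute_roa(SparseCodes(coeffs, lam=0.1), idx, pseudocount=0.0,
                          convention="literal")
        assert lit.values[0] == pytest.approx(pair.values[0] / 2, abs=1e-12)


class TestIncrementalAndAblation:
    @staticmethod
    def _planted_split(rng, k2=6, k1=4, n_train=8, n_test=6):
        """Task-specific rows carry the label; others are noise."""
        def make(subjects):
            idx = BlockIndex(subjects=subjects, tasks=TASKS, n_inner=k1)
            coeffs = 0.1 * rng.standard_normal((k2, idx.n_columns))
            for ti in range(7):
                row = ti % k2
                for sub in subjects:
                    coeffs[row, idx.block(sub, ti)] += 3.0
            return build_samples(SparseCodes(coeffs, lam=0.1), idx)

        train = make(tuple(f"tr{i}" for i in range(n_train)))
        test = make(tuple(f"te{i}" for i in range(n_test)))
        return train, test

    def test_endpoint_equals_full_model_exactly(self, desk_run):
        curve = dict(desk_run.roa_curve)
        assert curve[max(curve)] == desk_run.accuracy

    def test_noop_ablation_matches_all_components(self, rng):
        train, test = self._planted_split(rng)
        cats = ["task-evoked"] * 6
        res = ablation_experiment(train, test, cats)
        assert res["all"] == res["excl_artifact"] == res["excl_both"]

    def test_excluding_everything_refused(self, rng):
        train, test = self._planted_split(rng)
        with pytest.raises(ValueError, match="excludes every component"):
            ablation_experiment(train, test, ["artifact"] * 6)

    def test_task_rows_carry_the_signal(self, rng):
        """Dropping the planted task rows collapses accuracy; dropping the
        noise rows barely moves it."""
        train, test = self._planted_split(rng, k2=9)
        cats = ["task-evoked"] * 7 + ["resting-state", "artifact"]
        res = ablation_experiment(train, test, cats)
        assert res["all"] - res["excl_both"] < 0.05
        # invert the roles: treat task rows as the excluded group
        cats_flip = ["artifact"] * 7 + ["task-evoked", "task-evoked"]
        res_flip = ablation_experiment(train, test, cats_flip)
        assert res_flip["all"] - res_flip["excl_artifact"] > 0.30


class TestRoaOrderingQuality:
    @staticmethod
    def _components_to_reach(curve, level):
        for m, acc in curve:
            if acc >= level:
                return m
        return curve[-1][0] + 1

    def test_roa_ordering_beats_random_orderings(self, desk_run, desk_samples):
        """The ROA-sorted incremental curve reaches 90% accuracy with no
        more components than the average of 10 seeded random orderings."""
        from htssr.classify import RoaVector

        train, test = desk_samples
        k2 = desk_run.roa_values.size
        roa = compute_roa(
            desk_run.model.ssr.alpha2, desk_run.model.ssr.index
        )
        roa_curve = roa_incremental_classification(train, test, roa)
        m_roa = self._components_to_reach(roa_curve, 0.9)
        rng = np.random.default_rng(99)
        m_random = []
        for _ in range(10):
            perm = rng.permutation(k2)
            fake = RoaVector(values=np.zeros(k2), counts=np.ones((k2, 7)),
                             pseudocount=1.0, rank_order=perm)
            curve = roa_incremental_classification(train, test, fake)
            m_random.append(self._components_to_reach(curve, 0.9))
        assert m_roa <= np.mean(m_random)

    def test_single_task_specific_component_beats_chance(self, rng):
        """With a perfectly task-specific top component, the one-component
        classifier is significantly above 1/7 (binomial p < 0.01)."""
        train, test = TestIncrementalAndAblation._planted_split(
            rng, k2=7, n_train=10, n_test=10
        )
        # ROA computed on the training codes alone
        idx = BlockIndex(subjects=tuple(f"tr{i}" for i in range(10)),
                         tasks=TASKS, n_inner=4)
        coeffs = np.stack([s.features.reshape(7, 4) for s in train], axis=-1)
        # rebuild a k2 x columns matrix in block order
        flat = np.concatenate(
            [coeffs[:, :, i] for i in range(coeffs.shape[2])], axis=1
        )
        roa = compute_roa(SparseCodes(flat, lam=0.1), idx, support_tolerance=1.0)
        curve = roa_incremental_classification(train, test, roa, ms=[1])
        n = len(test)
        successes = int(round(curve[0][1] * n))
        p = stats.binomtest(successes, n, 1 / 7, alternative="greater").pvalue
        assert p < 0.01


class TestCapacityVsOverlap:
    def test_closed_form_regression_oracle(self, rng):
        train, test = TestIncrementalAndAblation._planted_split(rng, k2=5)
        masks = [rng.random(20) > 0.5 for _ in range(5)]
        templates = [ReferenceTemplate("t", rng.random(20) > 0.5)]
        res = capacity_vs_overlap(train, test, masks, templates)
        x, y = res.overlap, res.accuracy
        xc = x - x.mean()
        slope = (xc @ (y - y.mean())) / (xc @ xc)
        intercept = y.mean() - slope * x.mean()
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_constant_overlap_reported_undefined(self, rng):
        train, test = TestIncrementalAndAblation._planted_split(rng, k2=5)
        masks = [np.ones(10, dtype=bool)] * 5
        templates = [ReferenceTemplate("t", np.ones(10, dtype=bool))]
        res = capacity_vs_overlap(train, test, masks, templates)
        assert np.isnan(res.r_squared) and np.isnan(res.p_value)

    def test_too_few_components_rejected(self, rng):
        train, test = TestIncrementalAndAblation._planted_split(rng, k2=5)
        with pytest.raises(ValueError, match="three components"):
            capacity_vs_overlap(train, test, [np.ones(4, dtype=bool)] * 2,
                                [], k2=2)
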