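"""Temporal courses, spectra, spatial maps, GLM templates, categorization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from htssr.blocks import TASKS, BlockIndex
from htssr.dataio import sample_voxels
from htssr.features import (
    ReferenceTemplate,
    categorize_components,
    component_spectrum,
    extract_spatial_map,
    glm_reference_maps,
    overlap_rate,
    paradigm_correlation,
    task_temporal_courses,
)
from htssr.sparse import Dictionary, SparseCodes
from htssr.synthetic import synthesize_dataset


def _unit_dictionary(atoms, tag="temporal"):
    return Dictionary(atoms=atoms, domain_tag=tag, lambda_used=0.1, seed=0,
                      n_iterations=1)


class TestTaskTemporalCourses:
    @staticmethod
    def _setup(rng, p, k1, k2, t):
        idx = BlockIndex(subjects=tuple(f"s{i}" for i in range(p)),
                         tasks=TASKS, n_inner=k1)
        atoms = rng.standard_normal((t, k1))
        atoms /= np.linalg.norm(atoms, axis=0) * 1.0001
        D1 = _unit_dictionary(atoms)
        a2 = SparseCodes(rng.standard_normal((k2, idx.n_columns)), lam=0.1)
        return idx, D1, a2

    def test_single_subject_average_is_the_block(self, rng):
        idx, D1, a2 = self._setup(rng, p=1, k1=4, k2=3, t=20)
        tc = task_temporal_courses(D1, a2, idx, "motor")
        block = a2.coefficients[:, idx.block("s0", "motor")]
        np.testing.assert_allclose(tc.courses, D1.atoms @ block.T, atol=1e-12)

    def test_identity_weights_reproduce_dictionary(self, rng):
        p, k = 3, 4
        idx = BlockIndex(subjects=("a", "b", "c"), tasks=TASKS, n_inner=k)
        atoms = rng.standard_normal((15, k))
        atoms /= np.linalg.norm(atoms, axis=0) * 1.0001
        D1 = _unit_dictionary(atoms)
        coeffs = np.zeros((k, idx.n_columns))
        for sub in idx.subjects:
            for task in idx.tasks:
                coeffs[:, idx.block(sub, task)] = np.eye(k)
        tc = task_temporal_courses(D1, SparseCodes(coeffs, lam=0.1), idx, "wm")
        np.testing.assert_allclose(tc.courses, D1.atoms, atol=1e-12)

    def test_linearity_in_loadings(self, rng):
        idx, D1, a2 = self._setup(rng, p=2, k1=4, k2=3, t=20)
        doubled = SparseCodes(2.0 * a2.coefficients, lam=0.1)
        tc1 = task_temporal_courses(D1, a2, idx, "social")
        tc2 = task_temporal_courses(D1, doubled, idx, "social")
        np.testing.assert_allclose(tc2.courses, 2.0 * tc1.courses, atol=1e-12)


class TestParadigmCorrelation:
    def test_self_and_sign_flip(self, rng):
        x = rng.standard_normal(50)
        assert paradigm_correlation(x, x) == pytest.approx(1.0)
        assert paradigm_correlation(x, -x) == pytest.approx(-1.0)

    def test_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 5.0, 9.0])
        n = 4
        r_hand = (n * (x * y).sum() - x.sum() * y.sum()) / np.sqrt(
            (n * (x**2).sum() - x.sum() ** 2) * (n * (y**2).sum() - y.sum() ** 2)
        )
        assert paradigm_correlation(x, y) == pytest.approx(r_hand, abs=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5), seed=st.integers(0, 2**16))
    def test_invariant_to_affine_rescaling(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        assert paradigm_correlation(a * x + b, y) == pytest.approx(
            paradigm_correlation(x, y), abs=1e-9
        )

    def test_constant_input_reported_undefined(self):
        assert np.isnan(paradigm_correlation(np.ones(10), np.arange(10.0)))


class TestComponentSpectrum:
    def test_sinusoid_peak_at_frequency(self):
        tr, t, f = 0.72, 256, 0.1
        x = np.sin(2 * np.pi * f * np.arange(t) * tr)
        freqs, mag = component_spectrum(x, tr)
        peak = freqs[np.argmax(mag[1:]) + 1]
        assert abs(peak - f) <= freqs[1]

    def test_constant_series_all_power_in_dc(self):
        freqs, mag = component_spectrum(np.full(64, 3.0), 0.72)
        assert np.argmax(mag) == 0
        assert mag[1:].max() < 1e-12

    def test_block_design_fundamental(self):
        """A 40 s-period block design concentrates power near 0.025 Hz."""
        tr = 0.72
        t = 400
        times = np.arange(t) * tr
        box = ((times % 40) < 20).astype(float)
        freqs, mag = component_spectrum(box, tr)
        peak = freqs[np.argmax(mag[1:]) + 1]
        assert abs(peak - 0.025) <= 2 * freqs[1]


class TestExtractSpatialMap:
    def test_values_placed_verbatim_at_sampled_voxels(self, rng):
        sampling = sample_voxels(np.ones((4, 4, 4), dtype=bool), 0.5, seed=1)
        atoms = rng.standard_normal((sampling.n_sampled, 3))
        atoms /= np.linalg.norm(atoms, axis=0) * 1.0001
        D2 = _unit_dictionary(atoms, tag="spatial")
        m = extract_spatial_map(D2, 1, sampling, threshold=1.0)
        np.testing.assert_array_equal(
            m.volume.ravel()[sampling.sampled_indices], atoms[:, 1]
        )
        assert np.all(m.binary_mask.ravel()[~m.sampled_mask.ravel()] == 0)

    def test_infinite_threshold_empty_mask(self, rng):
        sampling = sample_voxels(np.ones((4, 4, 4), dtype=bool), 0.5, seed=1)
        atoms = rng.standard_normal((sampling.n_sampled, 2))
        atoms /= np.linalg.norm(atoms, axis=0) * 1.0001
        m = extract_spatial_map(_unit_dictionary(atoms, "spatial"), 0, sampling,
                                threshold=np.inf)
        assert m.binary_mask.sum() == 0

    def test_invalid_component_rejected(self, rng):
        sampling = sample_voxels(np.ones((4, 4, 4), dtype=bool), 0.5, seed=1)
        atoms = rng.standard_normal((sampling.n_sampled, 2))
        atoms /= np.linalg.norm(atoms, axis=0) * 1.0001
        with pytest.raises(IndexError):
            extract_spatial_map(_unit_dictionary(atoms, "spatial"), 5, sampling)


class TestGlmReferenceMaps:
    def test_noise_free_effect_recovered_exactly(self, rng):
        x = rng.standard_normal(40)
        Y = (2.0 * x + 5.0)[:, None] * np.ones((1, 6))
        templates_in = {"ev": x}
        # effect size check via the per-subject OLS inside the group map
        X = np.column_stack([x, np.ones(40)])
        beta = np.linalg.lstsq(X, Y, rcond=None)[0]
        np.testing.assert_allclose(beta[0], 2.0, atol=1e-10)

    def test_orthogonal_regressor_zero_effect(self, rng):
        x = np.sin(np.linspace(0, 8 * np.pi, 64))
        y = np.cos(np.linspace(0, 8 * np.pi, 64))
        X = np.column_stack([x, np.ones(64)])
        beta = np.linalg.lstsq(X, y[:, None], rcond=None)[0]
        assert abs(beta[0, 0]) < 1e-10

    def test_rank_deficient_design_rejected(self, rng):
        Y = [rng.standard_normal((20, 5))]
        with pytest.raises(ValueError, match="rank-deficient"):
            glm_reference_maps(Y, {"const": np.ones(20)})

    def test_planted_activation_recovered(self, tiny_gt):
        """With low noise the group template at z > 2.3 covers >= 90% of
        the planted task-active voxels."""
        ds = synthesize_dataset(tiny_gt, n_subjects=4, noise_sigma=0.01,
                                jitter_sd=0.0, seed=21)
        task = "motor"
        length = ds.task_lengths[task]
        runs = [ds.signals[(sub, task)] for sub in ds.subjects]
        reg = tiny_gt.paradigms[task].truncated(length).regressor
        templates = glm_reference_maps(runs, {task: reg}, threshold=2.3)
        assert templates, "no voxels survived thresholding"
        tpl = templates[0]
        j = next(
            j for j in tiny_gt.atoms_in_group("task")
            if tiny_gt.atom_labels[j] == f"task:{task}"
        )
        planted = tiny_gt.map_mask(j)
        coverage = (tpl.binary_mask & planted).sum() / planted.sum()
        assert coverage >= 0.9


class TestOverlapRate:
    def test_identity_disjoint_and_fraction(self):
        a = np.array([1, 1, 1, 0, 0], dtype=bool)
        assert overlap_rate(a, a) == 1.0
        assert overlap_rate(a, ~a) == 0.0
        X = np.array([1, 1, 1, 0], dtype=bool)
        T = np.array([1, 1, 1, 1], dtype=bool)
        assert overlap_rate(X, T) == 0.75

    def test_full_overlap_iff_template_subset(self, rng):
        X = rng.random(30) > 0.4
        T = X & (rng.random(30) > 0.3)
        if T.sum():
            assert overlap_rate(X, T) == 1.0

    def test_monotone_as_x_grows(self, rng):
        T = rng.random(40) > 0.5
        X = np.zeros(40, dtype=bool)
        prev = 0.0
        order = rng.permutation(40)
        for i in order[:20]:
            X[i] = True
            cur = overlap_rate(X, T)
            assert cur >= prev
            prev = cur

    def test_empty_template_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_rate(np.ones(5, dtype=bool), np.zeros(5, dtype=bool))


class TestCategorizeComponents:
    def test_paradigm_tracking_component_is_task_evoked(self):
        corrs = np.array([[1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]])
        masks = [np.ones(10, dtype=bool)]
        assert categorize_components(masks, corrs, []) == ["task-evoked"]

    def test_single_template_match_is_resting_state(self):
        tpl = ReferenceTemplate("rsn", np.array([1, 1, 0, 0], dtype=bool))
        corrs = np.zeros((1, 7))
        masks = [np.array([1, 1, 0, 0], dtype=bool)]
        assert categorize_components(masks, corrs, [tpl]) == ["resting-state"]

    def test_no_match_is_artifact(self):
        tpl = ReferenceTemplate("rsn", np.array([1, 1, 0, 0], dtype=bool))
        corrs = np.zeros((1, 7))
        masks = [np.array([0, 0, 1, 1], dtype=bool)]
        assert categorize_components(masks, corrs, [tpl]) == ["artifact"]

    def test_planted_categories_recovered_on_fixture(self, desk_run, desk_dataset,
                                                     desk_sampling):
        """Matching each planted atom to its best spatial component, the
        assigned category agrees with the planted group for >= 80% of atoms."""
        gt = desk_dataset.gt
        D2 = desk_run.model.ssr.D2.atoms
        flat = desk_sampling.sampled_indices
        expected = {"task": "task-evoked", "resting": "resting-state",
                    "artifact": "artifact"}
        hits = total = 0
        for j, label in enumerate(gt.atom_labels):
            planted = gt.spatial_maps[j][flat]
            cors = [
                abs(np.corrcoef(planted, D2[:, c])[0, 1]) for c in range(D2.shape[1])
            ]
            best = int(np.nanargmax(cors))
            total += 1
            if desk_run.categories[best] == expected[gt.atom_group(j)]:
                hits += 1
        assert hits / total >= 0.8
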