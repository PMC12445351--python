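import numpy as np
import pytest

from kscore.core import (
    AlignedScores,
    ControlReference,
    aggregate_repetitions,
    align_subject,
    build_control_reference,
    calibrate_alpha,
    compute_kprofile,
    deviation_factor,
    kscore,
    score_subject,
    subject_pca,
)
from kscore.errors import ParameterError
from kscore.preprocess import MotionMatrix, standardize
from kscore.procrustes import generalized_procrustes, procrustes_fit


def _std_matrix(values, subject_id="s", duration=1.0):
    values = np.asarray(values, dtype=float)
    m = MotionMatrix(
        subject_id=subject_id,
        values=values,
        time_grid=np.linspace(0, 100, values.shape[0]),
        column_labels=[f"c{i}" for i in range(values.shape[1])],
        transition_duration=duration,
    )
    return standardize(m)


def _random_pca(seed, t=30, j=4, subject_id="s", duration=1.0):
    rng = np.random.default_rng(seed)
    base = np.cumsum(rng.normal(size=(t, j)), axis=0)
    return subject_pca(_std_matrix(base, subject_id=subject_id, duration=duration))


class TestSubjectPCA:
    def test_eigenvalue_sum_equals_channel_count(self):
        p = _random_pca(0, t=50, j=7)
        assert np.sum(p.eigenvalues) == pytest.approx(7.0, abs=1e-6)

    def test_two_channel_closed_form(self):
        """Eigenvalues of standardized 2-column data are {1+rho, 1-rho}."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = 0.6 * x + 0.8 * rng.normal(size=40)
        m = _std_matrix(np.column_stack([x, y]))
        rho = np.corrcoef(m.values.T)[0, 1]
        p = subject_pca(m)
        np.testing.assert_allclose(
            p.eigenvalues, [1 + abs(rho), 1 - abs(rho)], atol=1e-9
        )

    def test_full_reconstruction(self):
        p = _random_pca(2, t=60, j=9)
        m = p.scores @ p.loadings.T
        base = _random_pca(2, t=60, j=9)  # same standardized matrix
        assert np.max(np.abs(m - base.scores @ base.loadings.T)) < 1e-12
        # P W^T reproduces X exactly with the complete basis
        x = _std_matrix(np.cumsum(np.random.default_rng(2).normal(size=(60, 9)), axis=0))
        p2 = subject_pca(x)
        assert np.max(np.abs(x.values - p2.scores @ p2.loadings.T)) < 1e-8

    def test_rejects_non_standardized_input(self):
        m = MotionMatrix(
            subject_id="s",
            values=np.random.default_rng(0).normal(3, 2, size=(20, 3)),
            time_grid=np.linspace(0, 100, 20),
            column_labels=["a", "b", "c"],
        )
        with pytest.raises(ParameterError, match="standardized"):
            subject_pca(m)

    def test_orientation_canonical(self):
        p = _random_pca(3, t=40, j=6)
        # orthonormal loadings, proper orientation, descending eigenvalues
        np.testing.assert_allclose(p.loadings.T @ p.loadings, np.eye(6), atol=1e-10)
        assert np.linalg.det(p.loadings) == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(p.eigenvalues) <= 1e-12)


class TestProcrustes:
    def test_similarity_copies_collapse_to_consensus(self):
        rng = np.random.default_rng(4)
        base = np.cumsum(rng.normal(size=(20, 3)), axis=0)
        configs = []
        for _ in range(4):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            configs.append(1.7 * (base @ q.T) + rng.normal(size=3))
        consensus, tfs, residuals = generalized_procrustes(configs)
        assert max(residuals) < 1e-9

    def test_gpa_deterministic(self):
        rng = np.random.default_rng(5)
        configs = [np.cumsum(rng.normal(size=(15, 3)), axis=0) for _ in range(5)]
        c1, _, r1 = generalized_procrustes([c.copy() for c in configs])
        c2, _, r2 = generalized_procrustes([c.copy() for c in configs])
        np.testing.assert_array_equal(c1, c2)
        assert r1 == r2

    def test_consensus_beats_any_single_reference(self):
        """GPA consensus residual sum <= residual sum against each individual
        configuration used as the (unit-normalized) reference."""
        rng = np.random.default_rng(6)
        base = np.cumsum(rng.normal(size=(18, 3)), axis=0)
        configs = [base + 0.3 * rng.normal(size=base.shape) for _ in range(5)]

        def canon(x):
            xc = x - x.mean(axis=0)
            return xc / np.linalg.norm(xc)

        def total_residual(ref):
            return sum(procrustes_fit(c, canon(ref))[1] ** 2 for c in configs)

        consensus, _, _ = generalized_procrustes(configs)
        gpa_res = total_residual(consensus)
        singles = [total_residual(c) for c in configs]
        assert gpa_res <= min(singles) + 1e-12

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(12, 4))
        b = rng.normal(size=(12, 4))
        tf, _ = procrustes_fit(a, b)
        np.testing.assert_allclose(tf.rotation.T @ tf.rotation, np.eye(4), atol=1e-9)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)
        assert tf.scale > 0


def _reference_from(pcas_per_subject, alpha_target=94.0):
    return build_control_reference(pcas_per_subject, alpha_target=alpha_target)


class TestAlignment:
    def _ref(self):
        controls = [[_random_pca(10 + i, subject_id=f"c{i}", duration=1.0 + 0.1 * i)]
                    for i in range(4)]
        return _reference_from(controls)

    def test_subject_equal_to_consensus_has_zero_residual(self):
        ref = self._ref()
        p = _random_pca(10)
        p.scores = ref.consensus_scores.copy()
        aligned = align_subject(p, ref)
        assert aligned.residual < 1e-9
        np.testing.assert_allclose(aligned.values, ref.consensus_scores, atol=1e-9)

    def test_similarity_transformed_subject_recovers_consensus(self):
        ref = self._ref()
        rng = np.random.default_rng(8)
        q, _ = np.linalg.qr(rng.normal(size=(ref.k, ref.k)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        p = _random_pca(11)
        p.scores = 2.0 * (ref.consensus_scores @ q.T) + 0.7
        aligned = align_subject(p, ref)
        np.testing.assert_allclose(aligned.values, ref.consensus_scores, atol=1e-6)

    def test_alignment_idempotent(self):
        ref = self._ref()
        p = _random_pca(12)
        once = align_subject(p, ref)
        p.scores = once.values
        twice = align_subject(p, ref)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        ref = self._ref()
        with pytest.raises(ParameterError):
            align_subject(_random_pca(13, j=3), ref)


class TestProfilesAndScore:
    def _aligned(self, values):
        values = np.asarray(values, dtype=float)
        return AlignedScores(
            subject_id="s",
            values=values,
            transform=None,
            residual=0.0,
            time_grid=np.linspace(0, 100, values.shape[0]),
        )

    def test_kprofile_hand_example(self):
        aligned = self._aligned([[1.0, -1.0], [2.0, 0.0]])
        prof = compute_kprofile(aligned, [1.5, 0.5])
        np.testing.assert_allclose(prof.values, [1.0, 3.0])

    def test_kprofile_single_component_weighting(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(10, 4))
        prof = compute_kprofile(self._aligned(vals), [4.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(prof.values, 4.0 * vals[:, 0])

    def test_kprofile_zeros(self):
        prof = compute_kprofile(self._aligned(np.zeros((7, 3))), [1, 1, 1])
        assert not prof.values.any()

    def test_aggregate_identity_and_mean(self):
        p1 = compute_kprofile(self._aligned(np.zeros((5, 1))), [1.0])
        p2 = compute_kprofile(self._aligned(np.full((5, 1), 2.0)), [1.0])
        mean, t = aggregate_repetitions([p1, p2], [1.0, 2.0])
        np.testing.assert_allclose(mean.values, np.ones(5))
        assert t == pytest.approx(1.5)
        same, _ = aggregate_repetitions([p2, p2], [1.0, 1.0])
        np.testing.assert_array_equal(same.values, p2.values)
        assert mean.n_reps_averaged == 2

    def _ref_for_df(self, grid_n=101, mean=None, alpha=1.0):
        grid = np.linspace(0, 100, grid_n)
        return ControlReference(
            consensus_scores=np.zeros((grid_n, 2)),
            mean_profile=np.zeros(grid_n) if mean is None else mean,
            time_grid=grid,
            mean_transition_time=1.0,
            alpha=alpha,
            n_controls=2,
            column_labels=["a", "b"],
        )

    def test_deviation_factor_zero_and_constant_offset(self):
        from kscore.core import KProfile

        ref = self._ref_for_df()
        equal = KProfile("s", ref.time_grid.copy(), np.zeros(101))
        assert deviation_factor(equal, ref) == 0.0
        const = KProfile("s", ref.time_grid.copy(), np.full(101, 0.5))
        assert deviation_factor(const, ref) == pytest.approx(50.0, abs=1e-12)

    def test_deviation_factor_symmetric(self):
        from kscore.core import KProfile

        rng = np.random.default_rng(10)
        a, b = rng.normal(size=101), rng.normal(size=101)
        ref_b = self._ref_for_df(mean=b)
        ref_a = self._ref_for_df(mean=a)
        pa = KProfile("s", ref_b.time_grid.copy(), a)
        pb = KProfile("s", ref_a.time_grid.copy(), b)
        assert deviation_factor(pa, ref_b) == pytest.approx(deviation_factor(pb, ref_a))

    def test_kscore_identities(self):
        ref = self._ref_for_df(alpha=2.5)
        assert kscore(0.0, 1.0, ref).k_score == 100.0
        assert kscore(2.5, 1.0, ref).k_score == pytest.approx(99.0)
        deficit_1 = 100.0 - kscore(4.0, 1.0, ref).k_score
        deficit_2 = 100.0 - kscore(4.0, 2.0, ref).k_score
        assert deficit_2 == pytest.approx(2 * deficit_1)

    def test_kscore_parameter_errors(self):
        ref = self._ref_for_df(alpha=-1.0)
        with pytest.raises(ParameterError):
            kscore(1.0, 1.0, ref)
        ref2 = self._ref_for_df()
        with pytest.raises(ParameterError):
            kscore(1.0, -1.0, ref2)


class TestCalibrateAlpha:
    def test_closed_form_example(self):
        # time-weighted DFs {2, 4}, target 97 -> alpha = mean/3 = 1
        alpha = calibrate_alpha([2.0, 4.0], [1.0, 1.0], 1.0, target_mean_score=97.0)
        assert alpha == pytest.approx(1.0)

    def test_target_100_rejected(self):
        with pytest.raises(ParameterError):
            calibrate_alpha([1.0], [1.0], 1.0, target_mean_score=100.0)

    def test_all_zero_df_rejected(self):
        with pytest.raises(ParameterError, match="no deviation"):
            calibrate_alpha([0.0, 0.0], [1.0, 1.0], 1.0)

    def test_control_mean_hits_target_by_construction(self):
        rng = np.random.default_rng(11)
        dfs = rng.uniform(1, 10, size=6)
        times = rng.uniform(0.8, 1.4, size=6)
        t_mean = float(np.mean(times))
        alpha = calibrate_alpha(dfs, times, t_mean, target_mean_score=94.0)
        scores = 100.0 - (1.0 / alpha) * (times / t_mean) * dfs
        assert np.mean(scores) == pytest.approx(94.0, abs=1e-9)


class TestControlReference:
    def test_build_and_json_round_trip(self, tmp_path):
        controls = [[_random_pca(20 + i, subject_id=f"c{i}", duration=1.0 + 0.05 * i)]
                    for i in range(5)]
        ref = build_control_reference(controls)
        assert ref.alpha > 0
        assert ref.n_controls == 5
        # resting-position anchor: t=0 row at the origin
        np.testing.assert_allclose(ref.consensus_scores[0], 0.0, atol=1e-12)
        path = tmp_path / "ref.json"
        ref.to_json(path)
        back = ControlReference.from_json(path)
        np.testing.assert_array_equal(back.consensus_scores, ref.consensus_scores)
        np.testing.assert_array_equal(back.mean_profile, ref.mean_profile)
        assert back.alpha == ref.alpha

    def test_rebuild_bit_identical(self):
        controls = [[_random_pca(30 + i, subject_id=f"c{i}")] for i in range(4)]
        r1 = build_control_reference([list(c) for c in controls])
        r2 = build_control_reference([list(c) for c in controls])
        np.testing.assert_array_equal(r1.consensus_scores, r2.consensus_scores)
        assert r1.alpha == r2.alpha

    def test_too_few_controls_rejected(self):
        with pytest.raises(ParameterError):
            build_control_reference([[_random_pca(1)]])

    def test_control_cohort_mean_score_equals_target(self):
        controls = [[_random_pca(40 + i, subject_id=f"c{i}", duration=1.0 + 0.1 * i)]
                    for i in range(5)]
        ref = build_control_reference(controls, alpha_target=94.0)
        scores = [score_subject(c, ref).k_score for c in controls]
        assert np.mean(scores) == pytest.approx(94.0, abs=1e-9)
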