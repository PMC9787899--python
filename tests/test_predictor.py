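import dataclasses

import numpy as np
import pytest

from sonogait.fourier import FourierCoefficients, eval_fourier, fit_fourier
from sonogait.predictor import (
    DEFAULT_GRID,
    MIC_COMBINATIONS,
    ConditionalModel,
    TrialRecord,
    assemble_predictor_vector,
    fit_joint_gaussian,
    fit_model,
    loso_evaluate,
    predict,
    predict_curve,
)
from sonogait.signal_processing import MicId


def make_trial(subject, trial, rng, k=15, duration=0.25):
    coeffs = lambda: FourierCoefficients(
        a0=rng.normal(), a=rng.normal(size=k) * 0.3, b=rng.normal(size=k) * 0.3, duration_s=duration
    )
    return TrialRecord(
        subject_id=subject,
        trial_id=trial,
        mass_kg=75.0 + rng.normal(),
        speed_mps=2.7 + 0.1 * rng.normal(),
        stance_time_s=duration,
        envelope_coeffs={m: coeffs() for m in MicId},
        grf_coeffs=coeffs(),
    )


class TestCombinations:
    def test_exactly_nine_with_documented_membership(self):
        assert len(MIC_COMBINATIONS) == 9
        assert MIC_COMBINATIONS["Mic14"].members == (MicId.MIC1, MicId.MIC4)  # posterior
        assert MIC_COMBINATIONS["Mic23"].members == (MicId.MIC2, MicId.MIC3)  # anterior
        assert MIC_COMBINATIONS["Mic12"].members == (MicId.MIC1, MicId.MIC2)  # medial
        assert MIC_COMBINATIONS["Mic34"].members == (MicId.MIC3, MicId.MIC4)  # lateral
        assert MIC_COMBINATIONS["Mic1234"].members == tuple(MicId)
        singles = [MIC_COMBINATIONS[f"Mic{i}"].members for i in range(1, 5)]
        assert singles == [(m,) for m in MicId]


class TestAssemble:
    def test_vector_lengths(self):
        rng = np.random.default_rng(0)
        trial = make_trial("A", "A_0", rng)
        assert assemble_predictor_vector(trial, MIC_COMBINATIONS["Mic1234"]).shape == (127,)
        assert assemble_predictor_vector(trial, MIC_COMBINATIONS["Mic1"]).shape == (34,)

    def test_scalars_appended_last(self):
        rng = np.random.default_rng(1)
        trial = make_trial("A", "A_0", rng)
        vec = assemble_predictor_vector(trial, MIC_COMBINATIONS["Mic2"])
        assert np.array_equal(vec[-3:], [trial.mass_kg, trial.speed_mps, trial.stance_time_s])
        assert np.array_equal(vec[:31], trial.envelope_coeffs[MicId.MIC2].to_vector())


class TestFitModel:
    def test_identical_training_vectors_collapse_to_mean(self):
        rng = np.random.default_rng(2)
        base = make_trial("A", "A_0", rng)
        clone = dataclasses.replace(base, subject_id="B", trial_id="B_0")
        model = fit_model([base, clone], "Mic1234")
        joint = np.concatenate(
            [assemble_predictor_vector(base, MIC_COMBINATIONS["Mic1234"]), base.grf_coeffs.to_vector()]
        )
        assert np.allclose(model.mean, joint)
        assert model.variances.max() < 1e-10  # nothing but the floor

    def test_two_point_pca_axis_along_difference(self):
        # two joint samples: the single principal axis of the standardized
        # cloud must align with the (normalized) difference vector
        X = np.array([[0.0, 0.0, 0.0, 0.0], [1.0, 2.0, -1.0, 0.5]])
        model = fit_joint_gaussian(X, predictor_len=2, explained_variance=1.0)
        z_diff = (X[1] - X[0]) / model.scale
        z_diff /= np.linalg.norm(z_diff)
        assert np.allclose(np.abs(model.basis[0] @ z_diff), 1.0, atol=1e-9)

    def test_requires_two_trials(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="2 training trials"):
            fit_model([make_trial("A", "A_0", rng)], "Mic1")

    def test_single_subject_training_allowed_for_two_subject_loso(self):
        rng = np.random.default_rng(13)
        trials = [make_trial(s, f"{s}_{i}", rng) for s in "AB" for i in range(4)]
        res = loso_evaluate(trials, "Mic1")  # each fold trains on one subject
        assert set(res["subject_id"]) == {"A", "B"}


class TestPredict:
    def test_mean_predictor_returns_mean_target(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 7))
        model = fit_joint_gaussian(X, predictor_len=4)
        out = predict(model, model.mean[:4])
        assert np.allclose(out, model.mean[4:], atol=1e-10)

    def test_2d_gaussian_closed_form(self):
        # joint covariance [[1, .8], [.8, 1]], zero means: E[y | x=1] = 0.8
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        model = ConditionalModel(
            mean=np.zeros(2),
            scale=np.ones(2),
            basis=evecs[:, order].T,
            variances=evals[order],
            predictor_len=1,
            target_len=1,
            n_harmonics=0,
            combo="",
        )
        assert predict(model, np.array([1.0])) == pytest.approx(0.8, abs=1e-12)

    @pytest.mark.parametrize("method", ["subspace", "gaussian"])
    def test_matches_sample_conditional_mean(self, method):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = rng.integers(3, 11)
            p = rng.integers(1, d)
            A = rng.normal(size=(d, d))
            X = rng.multivariate_normal(rng.normal(size=d), A @ A.T + 0.1 * np.eye(d), size=200)
            model = fit_joint_gaussian(X, predictor_len=int(p), explained_variance=1.0, method=method)
            x = rng.normal(size=int(p))
            S, mu = np.cov(X.T), X.mean(axis=0)
            oracle = mu[p:] + S[p:, :p] @ np.linalg.solve(S[:p, :p], x - mu[:p])
            assert np.allclose(predict(model, x), oracle, atol=1e-6)

    def test_affine_in_the_predictor(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 6))
        model = fit_joint_gaussian(X, predictor_len=3)
        x1, x2 = rng.normal(size=3), rng.normal(size=3)
        lhs = predict(model, 0.3 * x1 + 0.7 * x2)
        rhs = 0.3 * predict(model, x1) + 0.7 * predict(model, x2)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        model = fit_joint_gaussian(rng.normal(size=(20, 5)), predictor_len=2)
        with pytest.raises(ValueError, match="length"):
            predict(model, np.zeros(3))


class TestPredictCurve:
    def test_duplicated_trial_reproduces_training_curve(self):
        rng = np.random.default_rng(8)
        base = make_trial("A", "A_0", rng)
        clone = dataclasses.replace(base, subject_id="B", trial_id="B_0")
        model = fit_model([base, clone], "Mic1234")
        pred = predict_curve(model, base)
        real = eval_fourier(base.grf_coeffs, DEFAULT_GRID)
        assert np.abs(pred.values - real).max() < 1e-6
        assert pred.times[-1] == pytest.approx(base.stance_time_s)


class TestLoso:
    def test_each_fold_excludes_held_out_subject(self, small_cohort):
        trials, _ = small_cohort
        res = loso_evaluate(trials[:60], "Mic1")
        assert set(res["subject_id"]) == {t.subject_id for t in trials[:60]}

    def test_leakage_invariance_under_target_perturbation(self, small_cohort):
        trials, _ = small_cohort
        subset = trials[:80]
        held_out = subset[0].subject_id
        res1 = loso_evaluate(subset, "Mic34")

        def corrupt(t):
            if t.subject_id != held_out:
                return t
            bad = FourierCoefficients(
                a0=t.grf_coeffs.a0 + 100.0,
                a=t.grf_coeffs.a * -3.0,
                b=t.grf_coeffs.b + 5.0,
                duration_s=t.grf_coeffs.duration_s,
            )
            return dataclasses.replace(t, grf_coeffs=bad)

        res2 = loso_evaluate([corrupt(t) for t in subset], "Mic34")
        for r1, r2 in zip(
            res1[res1.subject_id == held_out].itertuples(),
            res2[res2.subject_id == held_out].itertuples(),
        ):
            assert np.array_equal(r1.pred_curve, r2.pred_curve)  # bit-identical

    def test_single_subject_rejected(self, small_cohort):
        trials, _ = small_cohort
        only = [t for t in trials if t.subject_id == trials[0].subject_id]
        with pytest.raises(ValueError, match="2 subjects"):
            loso_evaluate(only, "Mic1")
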