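import numpy as np
import pytest

from bfndecode import decoder as dec
from bfndecode import evaluation as ev
from bfndecode import io as bio
from bfndecode import pipeline as pl
from bfndecode import synthetic as syn
from bfndecode.bfn import NetworkFeatures

ELS = ("C3", "CZ", "C4", "CP4")


def spiral_cfg(seed, **kw):
    defaults = dict(
        seed=seed, electrodes=ELS, rate=250.0, analysis_rate=50.0,
        spiral_duration_s=8.2, unit_s=2.0, noise_sd=0.0, eeg_gain=2.0,
    )
    defaults.update(kw)
    return syn.SyntheticConfig(**defaults)


def attach_constant_features(trial, bands=("theta",), cluster=0.4, vpl=1.5):
    n_el = trial.eeg.n_channels
    trial.features = {
        ep: {
            b: NetworkFeatures(
                DVector=np.zeros(n_el), VDegree=0.0, VPLength=vpl,
                Cluster=cluster, Pbar=0.0,
            )
            for b in bands
        }
        for ep in range(trial.n_epochs)
    }
    return trial


def featured_trials(seed, n, **cfg_kw):
    cfg = spiral_cfg(seed, **cfg_kw)
    trials = [syn.generate_spiral_trial("SPIRAL1", cfg, trial_index=i) for i in range(n)]
    for t in trials:
        pl.compute_trial_features(t, bands=["theta"], target_cost=0.3)
    return trials


class TestDesign:
    def test_width_minimal(self):
        assert dec.design_width(1, 0, 1, 0) == 6

    def test_width_full(self):
        assert dec.design_width(8, 10, 3, 3) == 2209

    def test_build_design_shape(self):
        trials = featured_trials(0, 1)
        l1 = dec.Level1Spec(electrodes=ELS, n_lags=3, analysis_rate=50.0)
        l2 = dec.Level2Spec(("theta",), 1)
        X, y = dec.build_design(trials[0], l1, l2)
        assert X.shape[1] == dec.design_width(4, 3, 1, 1)
        assert y.shape[1] == 3

    def test_too_short_trial_warns(self):
        trials = featured_trials(0, 1)
        l1 = dec.Level1Spec(electrodes=ELS, n_lags=3, analysis_rate=50.0)
        l2 = dec.Level2Spec(("theta",), 10)  # more history than epochs exist
        with pytest.warns(UserWarning, match="too short"):
            X, y = dec.build_design(trials[0], l1, l2)
        assert X.shape[0] == 0

    def test_missing_band_features_named(self):
        trials = featured_trials(0, 1)
        del trials[0].features[1]["theta"]
        l1 = dec.Level1Spec(electrodes=ELS, n_lags=3, analysis_rate=50.0)
        with pytest.raises(ValueError, match=r"epoch 1, band theta"):
            dec.build_design(trials[0], l1, dec.Level2Spec(("theta",), 1))


class TestRidge:
    def test_constant_target_intercept_only(self, rng):
        X = np.hstack([np.ones((200, 1)), rng.standard_normal((200, 5))])
        Y = np.full((200, 3), 4.2)
        beta = dec.ridge_solve(X, Y, 1e-10)
        np.testing.assert_allclose(beta[0], 4.2, atol=1e-6)
        np.testing.assert_allclose(beta[1:], 0.0, atol=1e-6)

    def test_coefficient_recovery(self, rng):
        # well-conditioned wide design: 20x samples, noise sd 0.1
        p, n = 200, 4000
        X = np.hstack([np.ones((n, 1)), rng.standard_normal((n, p - 1))])
        beta_true = rng.standard_normal((p, 3))
        Y = X @ beta_true + 0.1 * rng.standard_normal((n, 3))
        beta = dec.ridge_solve(X, Y, 1e-6)
        rel = np.linalg.norm(beta - beta_true) / np.linalg.norm(beta_true)
        assert rel < 0.1

    def test_rank_deficient_errors_at_zero(self, rng):
        x = rng.standard_normal((50, 1))
        X = np.hstack([np.ones((50, 1)), x, x])  # duplicated column
        with pytest.raises(np.linalg.LinAlgError, match="lambda > 0"):
            dec.ridge_solve(X, rng.standard_normal((50, 1)), 0.0)


class TestFitPredict:
    def test_mlr_recovers_line(self):
        # y = 2*S + 3, single electrode, zero lag
        rng = np.random.default_rng(0)
        eeg = bio.EEGRecording(rng.standard_normal((2, 1000)), 100.0, ["C3", "C4"])
        t = np.arange(1000) / 100.0
        S = eeg.samples[0]
        traj = bio.TrajectoryRecording(t, 2 * S + 3, 2 * S + 3, 2 * S + 3, rate=100.0)
        trial = bio.epoch(bio.synchronize(eeg, traj, analysis_rate=100.0, mode="UD"), 2.0)
        l1 = dec.Level1Spec(electrodes=("C3",), n_lags=0, analysis_rate=100.0)
        model = dec.fit_mlr([trial], l1, lam=1e-8)
        intercept, slopes = model.raw_coefficients(0)
        assert intercept == pytest.approx(3.0, abs=1e-3)
        assert slopes[0] == pytest.approx(2.0, abs=1e-3)

    def test_noiseless_memorization(self):
        trials = featured_trials(3, 1)
        l1 = dec.Level1Spec(electrodes=ELS, n_lags=3, analysis_rate=50.0)
        model = dec.fit_mlr(trials, l1, lam=1e-8)
        scores = ev.axis_pcc(trials[0].trajectory, dec.predict(model, trials[0]))
        assert min(scores.as_tuple()) > 0.999

    def test_nesting_constant_covariates(self):
        # identical lam: HLM with constant level-2 covariates == MLR
        trials = featured_trials(1, 3, noise_sd=0.4)
        for t in trials:
            attach_constant_features(t)
        l1 = dec.Level1Spec(electrodes=ELS, n_lags=3, analysis_rate=50.0)
        # zero epoch history so both models see the identical training rows
        l2 = dec.Level2Spec(("theta",), 0)
        h = dec.fit_hlm(trials[:2], l1, l2, lam=1.0)
        m = dec.fit_mlr(trials[:2], l1, lam=1.0)
        dh = dec.predict(h, trials[2])
        dm = dec.predict(m, trials[2])
        ok = np.isfinite(dh.x) & np.isfinite(dm.x)
        assert ok.sum() > 100
        np.testing.assert_allclose(dh.xyz[:, ok], dm.xyz[:, ok], atol=1e-8)

    def test_zero_eeg_gives_intercept_path(self):
        trials = featured_trials(2, 2, noise_sd=0.2)
        l1 = dec.Level1Spec(electrodes=ELS, n_lags=2, analysis_rate=50.0)
        model = dec.fit_mlr(trials, l1, lam=1.0)
        flat = trials[0]
        flat.eeg_analysis = np.zeros_like(flat.eeg_analysis)
        out = dec.predict(model, flat)
        ok = np.isfinite(out.x)
        intercept, _ = model.raw_coefficients(0)
        np.testing.assert_allclose(out.x[ok], intercept, atol=1e-8)

    def test_electrode_permutation_invariance(self):
        trials = featured_trials(4, 1, noise_sd=0.1)
        l1 = dec.Level1Spec(electrodes=ELS, n_lags=2, analysis_rate=50.0)
        model = dec.fit_mlr(trials, l1, lam=0.5)
        base = dec.predict(model, trials[0])

        perm = [2, 0, 3, 1]
        shuffled = featured_trials(4, 1, noise_sd=0.1)[0]
        shuffled.eeg.samples = shuffled.eeg.samples[perm]
        shuffled.eeg.channel_labels = [trials[0].eeg.channel_labels[i] for i in perm]
        shuffled.eeg_analysis = shuffled.eeg_analysis[perm]
        out = dec.predict(model, shuffled)
        np.testing.assert_allclose(out.xyz, base.xyz, atol=1e-10)

    def test_target_scaling_equivariance(self):
        trials = featured_trials(5, 2, noise_sd=0.2)
        l1 = dec.Level1Spec(electrodes=ELS, n_lags=2, analysis_rate=50.0)
        m1 = dec.fit_mlr(trials, l1, lam=1.0)
        scaled = featured_trials(5, 2, noise_sd=0.2)
        for t in scaled:
            t.trajectory.x *= 3.0
            t.trajectory.y *= 3.0
            t.trajectory.z *= 3.0
        m2 = dec.fit_mlr(scaled, l1, lam=1.0)
        p1 = dec.predict(m1, trials[0])
        p2 = dec.predict(m2, scaled[0])
        np.testing.assert_allclose(p2.xyz, 3.0 * p1.xyz, rtol=1e-8)

    def test_shuffled_targets_no_skill(self):
        rs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            trials = featured_trials(seed, 3, noise_sd=0.5)
            for t in trials[:2]:  # shuffle training targets only
                k = rng.permutation(len(t.trajectory.x))
                t.trajectory.x = t.trajectory.x[k]
                t.trajectory.y = t.trajectory.y[k]
                t.trajectory.z = t.trajectory.z[k]
            l1 = dec.Level1Spec(electrodes=ELS, n_lags=2, analysis_rate=50.0)
            model = dec.fit_mlr(trials[:2], l1, lam=10.0)
            out = dec.predict(model, trials[2])
            scores = ev.axis_pcc(trials[2].trajectory, out)
            rs.extend(scores.as_tuple())
        assert abs(np.mean(rs)) < 0.1

    def test_hlm_json_round_trip(self):
        trials = featured_trials(6, 2, noise_sd=0.2)
        l1 = dec.Level1Spec(electrodes=ELS, n_lags=2, analysis_rate=50.0)
        l2 = dec.Level2Spec(("theta",), 1)
        model = dec.fit_hlm(trials, l1, l2, lam=1.0)
        back = dec._LinearDecoder.from_json(model.to_json())
        assert isinstance(back, dec.HLMModel)
        p1 = dec.predict(model, trials[0])
        p2 = dec.predict(back, trials[0])
        np.testing.assert_allclose(p1.xyz, p2.xyz, atol=1e-12)

    def test_structure_mismatch_raises(self):
        trials = featured_trials(7, 1)
        l1 = dec.Level1Spec(electrodes=ELS, n_lags=2, analysis_rate=50.0)
        model = dec.fit_mlr(trials, l1, lam=1.0)
        other = featured_trials(7, 1)[0]
        with pytest.raises((ValueError, KeyError)):
            dec.predict(
                dec.MLRModel(
                    l1spec=dec.Level1Spec(electrodes=("C3",), n_lags=5, analysis_rate=50.0),
                    l2spec=None,
                    betas=model.betas,
                    stats=model.stats,
                    lam=1.0,
                ),
                other,
            )


class TestSpecDefaults:
    def test_characteristic_defaults(self):
        l1 = dec.Level1Spec()
        assert l1.electrodes == ("F4", "F8", "C3", "CZ", "C4", "CP4", "T3", "T4")
        assert l1.n_lags == 10
        l2 = dec.Level2Spec()
        assert l2.bands == ("delta", "theta", "gamma1")
        assert l2.n_history == 3

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            dec.Level1Spec(n_lags=-1)
        with pytest.raises(ValueError):
            dec.Level1Spec(electrodes=())
        with pytest.raises(ValueError):
            dec.Level2Spec(n_history=-1)
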