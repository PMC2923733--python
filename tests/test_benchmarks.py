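import numpy as np
import pytest

from scdeconv.benchmarks import (
    build_glm_design,
    fit_glm,
    kernel_with_partials,
    peak_score,
    peak_scores,
    reconstruct_trial_peak,
)
from scdeconv.design import Trial, TrialDesign
from scdeconv.model_core import (
    GaussianBump,
    NeuralInputSet,
    SCTimeSeries,
    TimeGrid,
    ValidationError,
    forward_model,
)


def flat_series(n=800, rate=10.0, value=0.0):
    grid = TimeGrid(sampling_rate=rate, n_samples=n)
    return SCTimeSeries(grid=grid, values=np.full(n, float(value)), units="z-units")


class TestPeakScore:
    def test_flat_series_zero(self, small_design):
        s = flat_series()
        for mode in ("EIR", "FIR", "SIR"):
            assert peak_score(s, small_design.trials[0], mode) == 0.0

    def test_short_soa_extends_eir_window_to_5s(self):
        # SOA 3.5 s: the EIR window runs to CS onset + 5 s
        trial = Trial(index=0, cs_onset=10.0, soa=3.5, cs_type="CS-")
        grid = TimeGrid(10.0, 300)
        values = np.zeros(300)
        values[grid.index_at(14.5)] = 2.0  # after US time but inside 5 s window
        s = SCTimeSeries(grid=grid, values=values, units="z-units")
        assert peak_score(s, trial, "EIR") == pytest.approx(2.0)
        long_trial = Trial(index=1, cs_onset=10.0, soa=6.0, cs_type="CS-")
        values2 = np.zeros(300)
        values2[grid.index_at(16.5)] = 2.0  # outside [10, 16) window
        s2 = SCTimeSeries(grid=grid, values=values2, units="z-units")
        assert peak_score(s2, long_trial, "EIR") == pytest.approx(0.0)

    def test_triangular_pulse_and_half_windows(self):
        trial = Trial(index=0, cs_onset=10.0, soa=8.0, cs_type="CS-")
        grid = TimeGrid(10.0, 400)
        t = grid.times()
        h = 1.7
        center, width = 14.0, 2.0
        values = np.clip(h * (1 - np.abs(t - center) / width), 0.0, None)
        s = SCTimeSeries(grid=grid, values=values, units="z-units")
        assert peak_score(s, trial, "EIR") == pytest.approx(h)
        # index-arithmetic oracle for the halves
        fir_sl = grid.window_slice(10.0, 14.0)
        sir_sl = grid.window_slice(14.0, 18.0)
        assert peak_score(s, trial, "FIR") == pytest.approx(values[fir_sl].max())
        assert peak_score(s, trial, "SIR") == pytest.approx(values[sir_sl].max())

    def test_translation_equivariance(self, small_design, rng):
        grid = TimeGrid(10.0, 800)
        base = SCTimeSeries(grid=grid, values=rng.normal(size=800), units="z-units")
        shifted = SCTimeSeries(grid=grid, values=base.values + 4.2, units="z-units")
        np.testing.assert_allclose(peak_scores(base, small_design),
                                   peak_scores(shifted, small_design), atol=1e-12)

    def test_baseline_before_start_errors(self):
        trial = Trial(index=0, cs_onset=0.5, soa=3.5, cs_type="CS-")
        with pytest.raises(ValidationError):
            peak_score(flat_series(), trial)


class TestBuildGlmDesign:
    def test_conditions_mode_k4(self, small_design, rf_scr):
        grid = TimeGrid(10.0, 800)
        dm = build_glm_design(small_design, rf_scr, grid, mode="conditions")
        assert dm.k == 4
        labels = {lab for lab, _, _ in dm.labels}
        assert labels == {"CS-", "CS+noUS", "CS+US", "US"}

    def test_trials_mode_with_derivatives_counting(self, small_design, rf_scr):
        grid = TimeGrid(10.0, 800)
        dm = build_glm_design(small_design, rf_scr, grid, mode="trials",
                              basis="canonical+derivatives")
        # 4 CS events + 2 US events = 6 events x 3 basis kernels
        assert dm.k == 18

    def test_eight_events_three_basis(self, rf_scr):
        trials = [Trial(index=i, cs_onset=10.0 + 15.0 * i, soa=3.5,
                        cs_type="CS+", reinforced=True) for i in range(4)]
        design = TrialDesign(trials=trials, session_end=100.0)
        grid = TimeGrid(10.0, 1000)
        dm = build_glm_design(design, rf_scr, grid, mode="trials",
                              basis="canonical+derivatives")
        assert dm.k == 8 * 3 == 24

    def test_stick_regressor_is_shifted_kernel(self, rf_scr):
        trials = [Trial(index=0, cs_onset=5.0, soa=3.5, cs_type="CS-")]
        design = TrialDesign(trials=trials, session_end=60.0)
        grid = TimeGrid(10.0, 600)
        dm = build_glm_design(design, rf_scr, grid, mode="trials")
        col = dm.X[:, 0]
        expected = np.zeros(600)
        expected[50:50 + len(rf_scr.samples)] = rf_scr.samples
        np.testing.assert_allclose(col, expected)

    def test_duplicate_onsets_rejected(self, rf_scr):
        trials = [Trial(index=0, cs_onset=5.0, soa=3.5, cs_type="CS-"),
                  Trial(index=1, cs_onset=8.5, soa=3.5, cs_type="CS-")]
        # second CS collides with first trial's US time only if reinforced;
        # force a collision with identical CS onsets instead
        with pytest.raises(ValidationError):
            design = TrialDesign(trials=[trials[0], Trial(index=1, cs_onset=5.0,
                                                          soa=3.5, cs_type="CS+")],
                                 session_end=60.0)
            build_glm_design(design, rf_scr, TimeGrid(10.0, 600), mode="trials")


class TestFitGlm:
    def test_exact_recovery(self, small_design, rf_scr, rng):
        grid = TimeGrid(10.0, 800)
        dm = build_glm_design(small_design, rf_scr, grid, mode="trials")
        beta = rng.uniform(0.5, 2.0, dm.k)
        fit = fit_glm(dm.X @ beta, dm)
        np.testing.assert_allclose(fit.betas, beta, atol=1e-8)
        assert fit.sigma_e2 == pytest.approx(0.0, abs=1e-16)

    def test_orthogonal_data(self, rf_scr, rng):
        grid = TimeGrid(10.0, 500)
        trials = [Trial(index=0, cs_onset=5.0, soa=3.5, cs_type="CS-")]
        design = TrialDesign(trials=trials, session_end=50.0)
        dm = build_glm_design(design, rf_scr, grid, mode="trials")
        col = dm.X[:, 0]
        noise = rng.normal(size=500)
        y = noise - col * (col @ noise) / (col @ col)
        fit = fit_glm(y, dm)
        assert abs(fit.betas[0]) < 1e-10
        assert fit.sigma_e2 == pytest.approx(np.mean(y**2))

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(500, 6))
        y = rng.normal(size=500)
        from scdeconv.benchmarks import DesignMatrix

        grid = TimeGrid(10.0, 500)
        dm = DesignMatrix(X=X, labels=[("c", i, "canonical") for i in range(6)],
                          grid=grid, basis_names=("canonical",))
        fit = fit_glm(y, dm)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.betas, oracle, atol=1e-10)

    def test_rank_deficiency_reported(self, rng):
        from scdeconv.benchmarks import DesignMatrix

        base = rng.normal(size=(100, 2))
        X = np.column_stack([base, base[:, 0] + base[:, 1]])
        grid = TimeGrid(10.0, 100)
        dm = DesignMatrix(X=X, labels=[("a", 0, "canonical"), ("b", 1, "canonical"),
                                       ("c", 2, "canonical")],
                          grid=grid, basis_names=("canonical",))
        with pytest.raises(ValidationError, match="rank"):
            fit_glm(rng.normal(size=100), dm)


class TestReconstructTrialPeak:
    @pytest.fixture
    def setup(self, rf_scr):
        trials = [Trial(index=0, cs_onset=5.0, soa=6.0, cs_type="CS-"),
                  Trial(index=1, cs_onset=30.0, soa=6.0, cs_type="CS-")]
        design = TrialDesign(trials=trials, session_end=70.0)
        grid = TimeGrid(10.0, 700)
        dm = build_glm_design(design, rf_scr, grid, mode="trials",
                              basis="canonical+derivatives")
        return design, grid, dm

    def test_zero_derivatives_equals_canonical_peak(self, setup, rf_scr):
        design, grid, dm = setup
        y = dm.X[:, 0] * 1.5  # canonical column of trial 0 only
        fit = fit_glm(y, dm)
        peak = reconstruct_trial_peak(fit, 0)
        assert peak == pytest.approx(1.5 * rf_scr.samples.max(), rel=1e-6)

    def test_all_zero_betas(self, setup):
        design, grid, dm = setup
        fit = fit_glm(np.zeros(dm.n), dm)
        assert reconstruct_trial_peak(fit, 0) == pytest.approx(0.0, abs=1e-10)

    def test_latency_shift_bias_suppression(self, rf_scr):
        # response arrives 1 s late: canonical-only beta underestimates the
        # peak, the derivative reconstruction recovers it
        trials = [Trial(index=0, cs_onset=5.0, soa=6.0, cs_type="CS-")]
        design = TrialDesign(trials=trials, session_end=60.0)
        grid = TimeGrid(10.0, 600)
        true_peak = 1.0 * rf_scr.samples.max()
        shifted = np.zeros(600)
        idx = 50 + 10  # onset + 1 s shift
        shifted[idx:idx + len(rf_scr.samples)] = rf_scr.samples
        dm_c = build_glm_design(design, rf_scr, grid, mode="trials")
        fit_c = fit_glm(shifted, dm_c)
        canonical_peak = fit_c.betas[0] * rf_scr.samples.max()
        dm_d = build_glm_design(design, rf_scr, grid, mode="trials",
                                basis="canonical+derivatives")
        fit_d = fit_glm(shifted, dm_d)
        recon_peak = reconstruct_trial_peak(fit_d, 0)
        assert canonical_peak < 0.9 * true_peak
        assert abs(recon_peak - true_peak) / true_peak < 0.35
        assert abs(recon_peak - true_peak) < abs(canonical_peak - true_peak)

    def test_requires_derivative_basis(self, small_design, rf_scr):
        grid = TimeGrid(10.0, 800)
        dm = build_glm_design(small_design, rf_scr, grid, mode="trials")
        fit = fit_glm(np.zeros(800), dm)
        with pytest.raises(ValidationError):
            reconstruct_trial_peak(fit, 0)


class TestDerivativeBasisRecovery:
    def test_reconstruction_not_worse_than_canonical_on_jitter(self, rf_scr, rng):
        # latency-jittered noiseless responses: derivative reconstruction
        # recovers true peaks at least as well as canonical-only betas
        trials = [Trial(index=i, cs_onset=10.0 + 40.0 * i, soa=6.0, cs_type="CS-")
                  for i in range(6)]
        design = TrialDesign(trials=trials, session_end=260.0)
        grid = TimeGrid(10.0, 2600)
        r2_canon, r2_recon = [], []
        for _ in range(5):
            amps = rng.uniform(0.5, 2.0, len(trials))
            shifts = rng.integers(-8, 9, len(trials))  # up to 0.8 s jitter
            y = np.zeros(grid.n_samples)
            for t, a, s in zip(trials, amps, shifts):
                idx = grid.index_at(t.cs_onset) + int(s)
                seg = rf_scr.samples[: grid.n_samples - idx]
                y[idx:idx + len(seg)] += a * seg
            true_peaks = amps * rf_scr.samples.max()
            dm_c = build_glm_design(design, rf_scr, grid, mode="trials")
            fit_c = fit_glm(y, dm_c)
            est_c = np.array([fit_c.betas[dm_c.columns_for_trial(i)[0]]
                              for i in range(len(trials))]) * rf_scr.samples.max()
            dm_d = build_glm_design(design, rf_scr, grid, mode="trials",
                                    basis="canonical+derivatives")
            fit_d = fit_glm(y, dm_d)
            est_d = np.array([reconstruct_trial_peak(fit_d, i)
                              for i in range(len(trials))])

            def r2(est):
                ss = np.sum((true_peaks - est) ** 2)
                return 1 - ss / np.sum((true_peaks - true_peaks.mean()) ** 2)

            r2_canon.append(r2(est_c))
            r2_recon.append(r2(est_d))
        assert np.mean(r2_recon) >= np.mean(r2_canon) - 1e-9


class TestConditionTrialAgreement:
    def test_equal_amplitude_betas_agree(self, rf_scr, rf_sf):
        # noiseless, identical per-condition amplitudes: per-trial beta means
        # equal the condition-mode betas
        trials = [
            Trial(index=0, cs_onset=10.0, soa=4.0, cs_type="CS-"),
            Trial(index=1, cs_onset=40.0, soa=4.0, cs_type="CS+", reinforced=False),
            Trial(index=2, cs_onset=70.0, soa=4.0, cs_type="CS-"),
            Trial(index=3, cs_onset=100.0, soa=4.0, cs_type="CS+", reinforced=False),
        ]
        design = TrialDesign(trials=trials, session_end=140.0)
        grid = TimeGrid(10.0, 1400)
        y = np.zeros(grid.n_samples)
        for t, amp in zip(trials, [1.0, 2.0, 1.0, 2.0]):
            idx = grid.index_at(t.cs_onset)
            y[idx:idx + len(rf_scr.samples)] += amp * rf_scr.samples
        dm_cond = build_glm_design(design, rf_scr, grid, mode="conditions")
        dm_tr = build_glm_design(design, rf_scr, grid, mode="trials")
        fit_cond = fit_glm(y, dm_cond)
        fit_tr = fit_glm(y, dm_tr)
        cond_betas = {lab: b for (lab, _, _), b in zip(dm_cond.labels, fit_cond.betas)}
        minus_mean = np.mean([fit_tr.betas[dm_tr.columns_for_trial(i)[0]]
                              for i in (0, 2)])
        plus_mean = np.mean([fit_tr.betas[dm_tr.columns_for_trial(i)[0]]
                             for i in (1, 3)])
        assert minus_mean == pytest.approx(cond_betas["CS-"], abs=1e-6)
        assert plus_mean == pytest.approx(cond_betas["CS+noUS"], abs=1e-6)


class TestKernelPartials:
    def test_partials_shapes_and_magnitude(self, rf_scr):
        base, d_lat, d_disp = kernel_with_partials(rf_scr)
        assert base.shape == d_lat.shape == d_disp.shape
        assert np.linalg.norm(d_lat) > 0
        assert np.linalg.norm(d_disp) > 0
        # latency derivative should approximate -d(kernel)/dt
        grad = -np.gradient(base, 1.0 / rf_scr.sampling_rate)
        cos = (d_lat @ grad) / (np.linalg.norm(d_lat) * np.linalg.norm(grad))
        assert cos > 0.97
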