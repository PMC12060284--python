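"""Biodegradation kinetics: Q10 scaling, rate arithmetic, likelihood,
MLE and posterior sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from seepfate import kinetics as kin
from conftest import TRUE_PARAMS


class TestHalflifeScaling:
    def test_identity_at_reference(self):
        assert kin.scale_halflife(10.0, 5.0) == pytest.approx(10.0)

    def test_q10_halves_per_10_degrees(self):
        assert kin.scale_halflife(10.0, 15.0, Q10=2.0, T_ref=5.0) == pytest.approx(5.0)
        assert kin.scale_halflife(10.0, -5.0, Q10=2.0, T_ref=5.0) == pytest.approx(20.0)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            kin.scale_halflife(-1.0, 5.0)
        with pytest.raises(ValueError):
            kin.scale_halflife(10.0, 5.0, Q10=0.0)


class TestRateArithmetic:
    def test_printed_correspondence(self):
        # 20-day half-life corresponds to 0.035 1/d at two significant figures
        assert float(kin.halflife_to_rate(20.0)) == pytest.approx(0.0347, abs=5e-4)
        assert round(float(kin.halflife_to_rate(20.0)), 3) == 0.035

    def test_one_day(self):
        assert float(kin.halflife_to_rate(1.0)) == pytest.approx(np.log(2.0))

    @given(st.floats(min_value=1e-3, max_value=1e4))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, t12):
        back = float(kin.rate_to_halflife(kin.halflife_to_rate(t12)))
        assert back == pytest.approx(t12, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            kin.halflife_to_rate(0.0)
        with pytest.raises(ValueError):
            kin.rate_to_halflife(-1.0)


class TestPredictActivity:
    def test_boundary_and_asymptote(self):
        p = TRUE_PARAMS
        assert float(kin.predict_activity(p, 0.0, 5.0)) == pytest.approx(p.Cb)
        t12 = p.t12_ref
        mid = float(kin.predict_activity(p, t12, 5.0))
        assert mid == pytest.approx(0.5 * (p.Cb + p.Ctot))
        tail = float(kin.predict_activity(p, 10 * t12, 5.0))
        assert abs(tail - p.Ctot) <= 2.0**-10 * (p.Ctot - p.Cb) * 1.001

    def test_monotone_in_time(self):
        t = np.linspace(0, 60, 200)
        c = kin.predict_activity(TRUE_PARAMS, t, 8.5)
        assert np.all(np.diff(c) >= 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            kin.predict_activity(TRUE_PARAMS, -1.0, 5.0)


class TestLogLikelihood:
    def test_closed_form_at_zero_residuals(self, tracer_noise_free):
        p = kin.KineticsParams(TRUE_PARAMS.t12_ref, TRUE_PARAMS.Cb,
                               TRUE_PARAMS.Ctot, ln_sigma=0.0)
        n = len(tracer_noise_free)
        ll = kin.log_likelihood(p, tracer_noise_free)
        assert ll == pytest.approx(-0.5 * n * np.log(2 * np.pi), rel=1e-9)

    def test_growing_residual_lowers_value(self, tracer_noise_free):
        frame = tracer_noise_free.frame.copy()
        base = kin.log_likelihood(TRUE_PARAMS, tracer_noise_free)
        frame.loc[0, "activity_normalized"] += 1.0
        worse = kin.log_likelihood(TRUE_PARAMS, kin.TracerDataset(frame))
        assert worse < base

    def test_mle_is_local_optimum(self, tracer_noisy):
        fit = kin.fit_mle(tracer_noisy)
        best = kin.log_likelihood(fit.params, tracer_noisy)
        rng = np.random.default_rng(0)
        theta = fit.params.free_vector()
        for _ in range(50):
            pert = theta * (1 + 0.02 * rng.standard_normal(4))
            if pert[0] <= 0:
                continue
            ll = kin.log_likelihood(fit.params.with_free_vector(pert), tracer_noisy)
            assert ll <= best + 1e-9

    def test_empty_dataset_rejected(self):
        empty = kin.TracerDataset(pd.DataFrame(columns=list(kin.TracerDataset.COLUMNS)))
        with pytest.raises(ValueError):
            kin.log_likelihood(TRUE_PARAMS, empty)


class TestMLE:
    def test_noise_free_recovery(self, tracer_noise_free):
        fit = kin.fit_mle(tracer_noise_free)
        got = fit.params.free_vector()[:3]
        want = TRUE_PARAMS.free_vector()[:3]
        np.testing.assert_allclose(got, want, rtol=1e-6)

    def test_recovery_within_three_stderr(self):
        """Calibration over repeated simulations at the laboratory truth."""
        from seepfate.environment import TracerExperimentDesign, \
            simulate_tracer_experiment
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            data = simulate_tracer_experiment(
                TracerExperimentDesign(replicates=3, true_params=TRUE_PARAMS),
                seed=20_000 + rep)
            fit = kin.fit_mle(data)
            se = fit.stderr["t12_ref"]
            if np.isfinite(se) and abs(fit.params.t12_ref - TRUE_PARAMS.t12_ref) <= 3 * se:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_no_signal_flagged_unidentifiable(self):
        rows = [(d, 5.0, r, "test", 0.5) for d in (2, 4, 13, 17, 27)
                for r in range(3)]
        rows += [(0.0, 5.0, i, "control", 0.5) for i in range(4)]
        rows += [(0.0, 5.0, i, "pre", 0.5) for i in range(4)]
        flat = kin.TracerDataset(pd.DataFrame(rows, columns=list(kin.TracerDataset.COLUMNS)))
        fit = kin.fit_mle(flat)
        se = fit.stderr["t12_ref"]
        assert (not np.isfinite(se)) or se > 50.0 \
            or fit.params.t12_ref >= 0.99 * kin.HALFLIFE_MAX

    def test_halflife_invariant_under_rescaling(self, tracer_noisy):
        fit = kin.fit_mle(tracer_noisy)
        scaled = tracer_noisy.frame.copy()
        scaled["activity_normalized"] *= 37.0
        fit2 = kin.fit_mle(kin.TracerDataset(scaled))
        assert fit2.params.t12_ref == pytest.approx(fit.params.t12_ref, rel=1e-5)
        assert fit2.params.Ctot == pytest.approx(37.0 * fit.params.Ctot, rel=1e-5)

    def test_likelihood_shift_under_joint_rescaling(self, tracer_noisy):
        gamma = 37.0
        p = kin.fit_mle(tracer_noisy).params
        scaled_frame = tracer_noisy.frame.copy()
        scaled_frame["activity_normalized"] *= gamma
        p_scaled = kin.KineticsParams(p.t12_ref, gamma * p.Cb, gamma * p.Ctot,
                                      p.ln_sigma + np.log(gamma))
        ll = kin.log_likelihood(p, tracer_noisy)
        ll_scaled = kin.log_likelihood(p_scaled, kin.TracerDataset(scaled_frame))
        n = len(tracer_noisy)
        assert ll_scaled == pytest.approx(ll - n * np.log(gamma), rel=1e-9)


@pytest.fixture(scope="module")
def posterior(tracer_noisy):
    return kin.sample_posterior(tracer_noisy, seed=1, n_steps=3000, n_burn=800)


class TestPosterior:

    def test_percentile_ordering(self, posterior):
        s = posterior.summary
        assert (s["p16"] <= s["p50"]).all()
        assert (s["p50"] <= s["p84"]).all()

    def test_samples_respect_prior_support(self, posterior, tracer_noisy):
        box = kin.UniformPriors.from_dataset(tracer_noisy).as_array()
        flat = posterior.flat
        assert np.all(flat >= box[:, 0]) and np.all(flat <= box[:, 1])

    def test_mle_and_median_agree_within_one_stderr(self, posterior):
        s = posterior.summary
        for p in ("t12_ref", "Ctot"):
            assert abs(s.loc[p, "mle"] - s.loc[p, "p50"]) < s.loc[p, "stderr"]

    def test_reproducible_for_fixed_seed(self, tracer_noisy, posterior):
        again = kin.sample_posterior(tracer_noisy, seed=1,
                                     n_steps=3000, n_burn=800)
        np.testing.assert_array_equal(again.chain, posterior.chain)

    def test_interval_tightens_with_noise(self):
        from seepfate.environment import TracerExperimentDesign, \
            simulate_tracer_experiment
        widths = []
        for noise in (0.3, 0.01):
            data = simulate_tracer_experiment(
                TracerExperimentDesign(replicates=3, true_params=TRUE_PARAMS,
                                       noise_scale=noise), seed=11)
            post = kin.sample_posterior(data, seed=2, n_steps=2500, n_burn=700)
            s = post.summary.loc["t12_ref"]
            widths.append(s["p84"] - s["p16"])
        assert widths[1] < 0.2 * widths[0]

    def test_summary_io(self, posterior, tmp_path):
        posterior.to_csv(tmp_path / "summary.csv")
        back = pd.read_csv(tmp_path / "summary.csv", index_col="parameter")
        assert set(back.columns) == {"mle", "stderr", "p16", "p50", "p84"}
        posterior.chain_to_netcdf(tmp_path / "chains.nc")
        import xarray as xr
        with xr.open_dataset(tmp_path / "chains.nc", engine="scipy") as ds:
            assert ds["chain"].dims == ("walker", "step", "parameter")

    def test_bad_settings_rejected(self, tracer_noisy):
        with pytest.raises(ValueError):
            kin.sample_posterior(tracer_noisy, n_steps=100, n_burn=100)
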