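import numpy as np
import pytest
from scipy import stats

from halotaxis import ModelSpec, default_params
from halotaxis.calibration import (
    FitProblem,
    NoiseModel,
    fit_parameters,
    generate_synthetic_fractions,
    get_param,
    identifiability_report,
    set_param,
    simulate_fractions,
)
from halotaxis.flow_assay import FractionSeries
from halotaxis.stimuli import Segment, StimulusProtocol

SPEC = ModelSpec(6)
PARAMS = default_params(6)
PROT = StimulusProtocol((Segment(200.0, 500.0, "ligand", 5.0),))
T_END = 900.0


@pytest.fixture(scope="module")
def clean_series():
    return simulate_fractions(SPEC, PARAMS, PROT, T_END)


class TestNoiseModel:
    def test_same_seed_reproduces(self, clean_series):
        noise = NoiseModel("poisson_counts", seed=11)
        a = noise.apply(clean_series)
        b = NoiseModel("poisson_counts", seed=11).apply(clean_series)
        assert np.array_equal(a.counts, b.counts)

    def test_zero_scale_gaussian_is_identity(self, clean_series):
        out = NoiseModel("gaussian_relative", scale=0.0, seed=1).apply(clean_series)
        assert np.array_equal(out.counts, clean_series.counts)

    def test_poisson_mean_variance(self):
        """Sample variance of replicate fractions sits in the chi-square band."""
        mu = 400.0
        series = FractionSeries(
            15.0 + 30.0 * np.arange(1000), np.full(1000, mu), 30.0
        )
        noisy = NoiseModel("poisson_counts", seed=5).apply(series)
        var = noisy.counts.var(ddof=1)
        assert 320.0 < var < 480.0
        # and the exact 99% chi-square band around the true variance
        lo = mu * stats.chi2.ppf(0.005, 999) / 999
        hi = mu * stats.chi2.ppf(0.995, 999) / 999
        assert lo < var < hi

    def test_gain_reduces_relative_noise(self, clean_series):
        lo = NoiseModel("poisson_counts", seed=3, gain=1.0).apply(clean_series)
        hi = NoiseModel("poisson_counts", seed=3, gain=100.0).apply(clean_series)
        rel = lambda s: np.std((s.counts - clean_series.counts) / clean_series.counts)
        assert rel(hi) < rel(lo)

    def test_validation(self):
        with pytest.raises(ValueError):
            NoiseModel("weird")
        with pytest.raises(ValueError):
            NoiseModel(gain=0.0)


class TestParamAddressing:
    def test_dotted_path_round_trip(self):
        p = set_param(PARAMS, "feedback.k_dm", 1.0e-3)
        assert get_param(p, "feedback.k_dm") == 1.0e-3
        assert get_param(PARAMS, "feedback.k_dm") != 1.0e-3  # original untouched

    def test_bare_unique_name(self):
        p = set_param(PARAMS, "k_decay_sri", 2.0)
        assert p.photocycles.k_decay_sri == 2.0

    def test_top_level_name(self):
        p = set_param(PARAMS, "htr_tot", 9000.0)
        assert p.htr_tot == 9000.0

    def test_unknown_name(self):
        with pytest.raises(KeyError):
            set_param(PARAMS, "feedback.k_zz", 1.0)


class TestFitting:
    def test_noiseless_fit_from_truth_is_a_fixed_point(self, clean_series):
        kd = get_param(PARAMS, "feedback.k_dm")
        problem = FitProblem(
            clean_series, SPEC, PROT, T_END, {"feedback.k_dm": (kd / 4, kd * 4)}
        )
        fit = fit_parameters(problem, x0=[kd])
        assert fit.estimates["feedback.k_dm"] == pytest.approx(kd, rel=1e-6)
        assert fit.loss <= 1e-12 * float(clean_series.counts @ clean_series.counts)

    def test_misspecified_mechanism_fits_worse(self, clean_series):
        """Fitting a linear-rate model to feedback-generated data leaves a
        larger residual than the well-specified fit (nested objectives,
        compared on clean data where the well-specified loss is ~0)."""
        kd = get_param(PARAMS, "feedback.k_dm")
        good = fit_parameters(
            FitProblem(clean_series, SPEC, PROT, T_END, {"feedback.k_dm": (kd / 4, kd * 4)}),
            x0=[1.3 * kd],
        )
        bad = fit_parameters(
            FitProblem(
                clean_series,
                ModelSpec(6, feedback="linear"),
                PROT,
                T_END,
                {"feedback.k_dm": (kd / 4, kd * 10)},
            ),
            x0=[1.3 * kd],
        )
        assert good.loss < bad.loss
        assert bad.loss > 1e3 * max(good.loss, 1e-12)

    def test_failed_simulation_penalized_not_fatal(self, clean_series):
        problem = FitProblem(
            clean_series, SPEC, PROT, T_END, {"flow.t_s": (-30.0, 30.0)}
        )
        from halotaxis.calibration import _residuals

        r = _residuals(problem, np.array([-5.0]), penalty=123.0)
        assert np.all(r == 123.0)

    def test_bounds_validation(self, clean_series):
        with pytest.raises(ValueError):
            FitProblem(clean_series, SPEC, PROT, T_END, {})
        with pytest.raises(ValueError):
            FitProblem(clean_series, SPEC, PROT, T_END, {"feedback.k_dm": (1.0, 1.0)})


class TestIdentifiability:
    def test_inert_parameter_flagged(self, clean_series):
        """k_chec has no effect while the CheC variant is disabled."""
        kd = get_param(PARAMS, "feedback.k_dm")
        problem = FitProblem(
            clean_series,
            SPEC,
            PROT,
            T_END,
            {
                "signaling.k_chec": (1e-4, 10.0),
                "feedback.k_dm": (kd / 4, kd * 4),
            },
        )
        report = identifiability_report(
            problem, {"signaling.k_chec": 1.0, "feedback.k_dm": kd}
        )
        assert not report["signaling.k_chec"]["identifiable"]
        assert report["feedback.k_dm"]["identifiable"]
        assert all(v["sensitivity"] >= 0.0 for v in report.values())


class TestEstimatorConsistency:
    def test_recovery_error_shrinks_with_counting_gain(self, clean_series):
        """Median k_dm recovery error over seeds drops as counts increase 100x."""
        kd = get_param(PARAMS, "feedback.k_dm")
        bounds = {"feedback.k_dm": (kd / 4, kd * 4)}

        def median_error(gain):
            errors = []
            for seed in (0, 1, 2):
                obs = NoiseModel("poisson_counts", seed=seed, gain=gain).apply(clean_series)
                fit = fit_parameters(
                    FitProblem(obs, SPEC, PROT, T_END, bounds), x0=[1.5 * kd]
                )
                errors.append(abs(fit.estimates["feedback.k_dm"] - kd) / kd)
            return float(np.median(errors))

        assert median_error(100.0) < median_error(1.0)
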