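import numpy as np
import pytest
from scipy.integrate import solve_ivp

from halotaxis.methylation import (
    FeedbackConfig,
    MethioninePool,
    MethylationPools,
    Regulators,
    demethylation_rates,
    methylation_label_rhs,
)


def regs(**kwargs):
    defaults = dict(che_y_reg=0.0, che_yp=0.0, che_b=0.0, che_bp=0.0,
                    y_tot=1000.0, b_tot=100.0)
    defaults.update(kwargs)
    return Regulators(**defaults)


class TestDemethylationRates:
    def test_linear(self):
        cfg = FeedbackConfig(mechanism="linear", k_dm=1.0)
        assert demethylation_rates(0.3, regs(), cfg) == pytest.approx((0.3, 0.7))

    def test_quadratic(self):
        cfg = FeedbackConfig(mechanism="quadratic", k_dm=1.0)
        dm_a, dm_i = demethylation_rates(0.3, regs(), cfg)
        assert (dm_a, dm_i) == pytest.approx((0.09, 0.49))

    def test_fbm1_reciprocal_chey_dependence(self):
        cfg = FeedbackConfig(mechanism="fbm1", k_dm=1.0, k_dmy=2.0)
        dm_a, dm_i = demethylation_rates(
            0.5, regs(che_yp=500.0, che_y_reg=500.0, y_tot=1000.0), cfg
        )
        assert dm_a == pytest.approx(0.25)
        assert dm_i == pytest.approx(0.25)

    def test_fbm2_chey_deletion_limits(self):
        """With CheY = 0: dm_A = k_dm*A*(1+k_dmY) and dm_I = k_dm*I exactly."""
        cfg = FeedbackConfig(mechanism="fbm2", k_dm=1.0, k_dmy=1.0)
        dm_a, dm_i = demethylation_rates(0.4, regs(che_y_reg=0.0), cfg)
        assert dm_a == pytest.approx(0.4 * (1 + 1.0), abs=0.0)
        assert dm_i == pytest.approx(0.6, abs=0.0)

    def test_fbm2_saturating_chey(self):
        cfg = FeedbackConfig(mechanism="fbm2", k_dm=1.0, k_dmy=1.0, k_y=1.0)
        dm_a, dm_i = demethylation_rates(0.4, regs(che_y_reg=1e12), cfg)
        assert dm_a == pytest.approx(0.4, rel=1e-9)
        assert dm_i == pytest.approx(1.2, rel=1e-9)

    def test_fbm3_mirror_roles(self):
        """CheYp enhances dm_A and its absence enhances dm_I."""
        cfg = FeedbackConfig(mechanism="fbm3", k_dm=1.0, k_dmy=1.0)
        dm_a, dm_i = demethylation_rates(0.4, regs(che_yp=0.0), cfg)
        assert dm_a == pytest.approx(0.4)
        assert dm_i == pytest.approx(0.6 * 2.0)

    @pytest.mark.parametrize("mech, k1", [("fbm4", 1.0), ("fbm5", 2.0)])
    def test_cheb_mechanisms(self, mech, k1):
        cfg = FeedbackConfig(mechanism=mech, k_dm=1.0, k1=k1, k2=3.0)
        r = regs(che_b=50.0, che_bp=50.0, b_tot=100.0)
        dm_a, dm_i = demethylation_rates(0.5, r, cfg)
        assert dm_a == pytest.approx(0.5**k1 * 0.5**3)
        assert dm_i == pytest.approx(0.5**k1 * 0.5**3)

    def test_bp_modifier_scales_both_rates(self):
        cfg = FeedbackConfig(mechanism="linear", k_dm=1.0, bp_modifier=True, k_dmb=3.0)
        r = regs(che_b=50.0, che_bp=50.0, b_tot=100.0)
        dm_a, dm_i = demethylation_rates(0.5, r, cfg)
        factor = (50.0 + 3.0 * 50.0) / 100.0
        assert dm_a == pytest.approx(0.5 * factor)
        assert dm_i == pytest.approx(0.5 * factor)

    def test_cheb_mechanism_requires_cheb(self):
        cfg = FeedbackConfig(mechanism="fbm4", k1=1.0)
        with pytest.raises(ValueError, match="CheB"):
            demethylation_rates(0.5, regs(b_tot=0.0), cfg)

    def test_activity_out_of_range(self):
        with pytest.raises(ValueError):
            demethylation_rates(1.5, regs(), FeedbackConfig(mechanism="linear"))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FeedbackConfig(mechanism="fbm2", k_dmy=0.5)
        with pytest.raises(ValueError):
            FeedbackConfig(mechanism="fbm4", k1=0.5)
        with pytest.raises(ValueError):
            FeedbackConfig(mechanism="nope")


class TestCompensation:
    def test_linear_rates_compensate_at_symmetric_state(self):
        """An activity step leaves dm_A + dm_I unchanged for linear rates."""
        cfg = FeedbackConfig(mechanism="linear", k_dm=1.0)
        for delta in (-0.3, -0.1, 0.2, 0.4):
            before = sum(demethylation_rates(0.5, regs(), cfg))
            after = sum(demethylation_rates(0.5 + delta, regs(), cfg))
            assert after == pytest.approx(before, abs=1e-15)

    def test_quadratic_rates_increase_for_steps_in_either_direction(self):
        cfg = FeedbackConfig(mechanism="quadratic", k_dm=1.0)
        base = sum(demethylation_rates(0.5, regs(), cfg))
        for delta in (-0.3, -0.1, 0.1, 0.3):
            assert sum(demethylation_rates(0.5 + delta, regs(), cfg)) > base


class TestLabelBookkeeping:
    def test_no_sinks_without_rates(self):
        pools = MethylationPools(0.2, 0.1, 0.3, 0.2)
        met = MethioninePool(1e6, 5e5, 0.0)
        cfg = FeedbackConfig(mechanism="linear", k_m=0.0)
        d_pools, d_met, r = methylation_label_rhs(pools, met, 0.0, 0.0, cfg, 100.0)
        assert d_pools == (0.0, 0.0, 0.0, 0.0)
        assert d_met == 0.0 and r == 0.0

    def test_fully_labeled_site_release(self):
        pools = MethylationPools(0.0, 1.0, 0.0, 0.0)
        met = MethioninePool(1e6, 0.0, 0.0)
        cfg = FeedbackConfig(mechanism="linear", k_m=0.0)
        _, _, r = methylation_label_rhs(pools, met, 0.5, 0.0, cfg, 100.0)
        assert r == pytest.approx(50.0)

    def test_closed_system_label_balance(self):
        """With k_Met = 0, labeled methyl groups are conserved:
        methionine pool + transducer-bound + cumulative methanol."""
        cfg = FeedbackConfig(mechanism="linear", k_m=0.02, k_dm=0.05)
        n_sites = 500.0
        met_tot = 1e4

        def rhs(t, y):
            pools = MethylationPools(*y[:4])
            met = MethioninePool(met_tot, min(max(y[4], 0.0), met_tot), 0.0)
            dm_a, dm_i = demethylation_rates(0.3, regs(), cfg)
            d_pools, d_met, r = methylation_label_rhs(pools, met, dm_a, dm_i, cfg, n_sites)
            return [*d_pools, d_met, r]

        y0 = [0.1, 0.3, 0.2, 0.2, 4e3, 0.0]
        sol = solve_ivp(rhs, (0, 400.0), y0, rtol=1e-10, atol=1e-12)
        y = sol.y[:, -1]
        total0 = y0[4] + (y0[1] + y0[3]) * n_sites
        total1 = y[4] + (y[1] + y[3]) * n_sites + y[5]
        assert total1 == pytest.approx(total0, rel=1e-6)

    def test_site_fractions_and_label_ordering_stay_valid(self):
        cfg = FeedbackConfig(mechanism="linear", k_m=0.02, k_dm=0.05)

        def rhs(t, y):
            pools = MethylationPools(*np.clip(y[:4], 0.0, 1.0))
            met = MethioninePool(1e4, min(max(y[4], 0.0), 1e4), 1e-4)
            dm_a, dm_i = demethylation_rates(0.7, regs(), cfg)
            d_pools, d_met, _ = methylation_label_rhs(pools, met, dm_a, dm_i, cfg, 100.0)
            return [*d_pools, d_met]

        sol = solve_ivp(rhs, (0, 500.0), [0.4, 0.4, 0.1, 0.5, 9e3], rtol=1e-9, atol=1e-12)
        assert np.all(sol.y[:4] >= -1e-9)
        assert np.all(sol.y[0] + sol.y[1] <= 1 + 1e-9)
        assert np.all(sol.y[2] + sol.y[3] <= 1 + 1e-9)

    def test_pool_validation(self):
        with pytest.raises(ValueError):
            MethylationPools(0.7, 0.5, 0.0, 0.0)
        with pytest.raises(ValueError):
            MethioninePool(1e6, 2e6, 0.0)
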