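import math

import numpy as np
import pytest

from halotaxis.cluster import (
    FreeEnergyParams,
    SpeciesSpec,
    UnitComposition,
    complex_delta_f,
    enumerate_unit_activity,
    ligand_occupancy,
    superposed_activity,
    unit_activity,
)
from halotaxis.photocycles import SRIIState, SRIState


def neutral_energies(**kwargs):
    defaults = dict(
        f0=0.0, df_meth_act=0.0, df_meth_inact=0.0,
        dg_sri373_act=0.0, dg_sri373_inact=0.0,
        dg_srii360_act=0.0, dg_srii360_inact=0.0,
        dg_srii540_act=0.0, dg_srii540_inact=0.0,
        dg_ligand_act=0.0, dg_ligand_inact=0.0,
    )
    defaults.update(kwargs)
    return FreeEnergyParams(**defaults)


SRI = SpeciesSpec("sri", 1, "SRI")


class TestLigandOccupancy:
    @pytest.mark.parametrize(
        "lig, k_d, expected", [(1.0, 1.0, 0.5), (0.0, 2.0, 0.0), (3.0, 1.0, 0.75)]
    )
    def test_values(self, lig, k_d, expected):
        assert ligand_occupancy(lig, k_d) == pytest.approx(expected)

    def test_invalid_kd(self):
        with pytest.raises(ValueError):
            ligand_occupancy(1.0, 0.0)


class TestComplexDeltaF:
    def test_neutral_complex(self):
        assert complex_delta_f(SRI, SRIState(0.3), 0.0, (0.0, 0.0), neutral_energies()) == 0.0

    def test_single_state_log_ratio(self):
        e = neutral_energies(f0=0.7, dg_sri373_act=1.0, dg_sri373_inact=-0.5)
        delta = complex_delta_f(SRI, SRIState(1.0), 0.0, None, e)
        assert delta == pytest.approx(0.7 + 1.0 - (-0.5))

    def test_mixed_photostate(self):
        """Half the receptors in an intermediate stabilizing the inactive state."""
        e = neutral_energies(dg_sri373_inact=-1.0)
        delta = complex_delta_f(SRI, SRIState(0.5), 0.0, (0.0, 0.0), e)
        assert delta == pytest.approx(math.log(0.5 + 0.5 * math.e), rel=1e-12)

    def test_methylation_term_counts_two_transducers(self):
        e = neutral_energies(df_meth_act=-2.0, df_meth_inact=3.0)
        delta = complex_delta_f(SRI, SRIState(0.0), 0.0, (0.5, 0.25), e)
        assert delta == pytest.approx(2 * (0.5 * -2.0 + 0.25 * 3.0))

    def test_nonmethylatable_species_has_no_methylation_term(self):
        e = neutral_energies(df_meth_act=-2.0)
        sp = SpeciesSpec("sri", 1, "SRI", methylatable=False)
        assert complex_delta_f(sp, SRIState(0.0), 0.0, (1.0, 1.0), e) == 0.0

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            complex_delta_f(SRI, SRIState(0.0), 0.0, (1.5, 0.0), neutral_energies())


class TestUnitActivity:
    def test_symmetric_unit_is_half(self):
        comp = UnitComposition((SRI,), neutral_energies())
        assert unit_activity(comp, {"sri": SRIState(0.4)}, {}, {}) == pytest.approx(0.5)

    def test_log_balance_of_ln9(self):
        """delta = ln 9 gives A = 1/(1+9) = 0.1 (two-state Boltzmann)."""
        comp = UnitComposition((SRI,), neutral_energies(f0=math.log(9.0)))
        assert unit_activity(comp, {"sri": SRIState(0.0)}, {}, {}) == pytest.approx(0.1)

    @pytest.mark.parametrize("n", [1, 2, 4])
    def test_identical_complexes_share_one_exponent(self, n):
        f = 0.8
        comp = UnitComposition(
            (SpeciesSpec("sri", n, "SRI"),), neutral_energies(f0=f)
        )
        a = unit_activity(comp, {"sri": SRIState(0.0)}, {}, {})
        assert a == pytest.approx(1.0 / (1.0 + math.exp(n * f)), rel=1e-12)

    def test_cooperativity_sharpens_with_unit_size(self):
        """|dA/d(delta)| at A = 1/2 scales linearly with N_tot."""
        slopes = []
        h = 1e-6
        for n in (1, 2, 4):
            def act(f0, n=n):
                comp = UnitComposition(
                    (SpeciesSpec("sri", n, "SRI"),), neutral_energies(f0=f0)
                )
                return unit_activity(comp, {"sri": SRIState(0.0)}, {}, {})

            slopes.append(abs(act(h) - act(-h)) / (2 * h) / n)
        # per-complex slope (slope / N) is constant = 1/4
        assert np.allclose(slopes, 0.25, rtol=1e-4)


class TestEnumerationOracle:
    def test_hand_enumerated_four_term_sum(self):
        """N_tot = 1 with a two-state receptor: explicit 4-term Boltzmann sum."""
        e = neutral_energies(f0=0.3, dg_sri373_act=-0.7, dg_sri373_inact=0.4)
        p373 = 0.6
        comp = UnitComposition((SRI,), e)
        z_act = (1 - p373) * math.exp(-0.3) + p373 * math.exp(-(0.3 - 0.7))
        z_inact = (1 - p373) * 1.0 + p373 * math.exp(-0.4)
        expected = z_act / (z_act + z_inact)
        got = enumerate_unit_activity(comp, {"sri": SRIState(p373)}, {}, {})
        assert got == pytest.approx(expected, rel=1e-14)
        assert unit_activity(comp, {"sri": SRIState(p373)}, {}, {}) == pytest.approx(
            expected, rel=1e-12
        )

    def test_degenerate_unit_is_half(self):
        comp = UnitComposition(
            (SRI, SpeciesSpec("bast", 2, "chemo")), neutral_energies()
        )
        a = enumerate_unit_activity(
            comp, {"sri": SRIState(0.5)}, {"bast": 0.5}, {}
        )
        assert a == pytest.approx(0.5, rel=1e-14)

    def test_state_cap(self):
        comp = UnitComposition((SpeciesSpec("sri", 3, "SRI"),), neutral_energies())
        with pytest.raises(ValueError, match="cap"):
            enumerate_unit_activity(comp, {"sri": SRIState(0.5)}, {}, {}, max_states=4)


class TestSuperposedActivity:
    @pytest.mark.parametrize(
        "activities, weights, expected",
        [
            ([0.3, 0.3], [1.0, 5.0], 0.3),
            ([0.0, 1.0], [2.0, 2.0], 0.5),
            ([0.6, 0.3], [2.0, 1.0], 0.5),
        ],
    )
    def test_weighted_mean(self, activities, weights, expected):
        assert superposed_activity(activities, weights) == pytest.approx(expected)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            superposed_activity([0.5], [0.0])


class TestMonotonicity:
    def test_methylated_activating_sites_raise_activity(self):
        e = FreeEnergyParams()
        comp = UnitComposition((SRI,), e)
        acts = [
            unit_activity(comp, {"sri": SRIState(0.0)}, {}, {"sri": (m, 0.3)})
            for m in np.linspace(0, 1, 9)
        ]
        assert np.all(np.diff(acts) > 0)

    def test_sri373_lowers_activity_in_wildtype(self):
        comp = UnitComposition((SRI,), FreeEnergyParams())
        acts = [
            unit_activity(comp, {"sri": SRIState(p)}, {}, {"sri": (0.3, 0.3)})
            for p in np.linspace(0, 1, 9)
        ]
        assert np.all(np.diff(acts) < 0)

    def test_attractant_occupancy_lowers_activity(self):
        comp = UnitComposition((SpeciesSpec("bast", 1, "chemo"),), FreeEnergyParams())
        acts = [
            unit_activity(comp, {}, {"bast": occ}, {"bast": (0.3, 0.3)})
            for occ in np.linspace(0, 1, 9)
        ]
        assert np.all(np.diff(acts) < 0)

    def test_inverted_sri_mutant_flips_orange_response(self):
        """Swapping the SRI_373 increments inverts the light response of A."""
        wt = UnitComposition((SRI,), FreeEnergyParams())
        inv = UnitComposition((SRI,), FreeEnergyParams().inverted_sri())
        meth = {"sri": (0.3, 0.3)}
        d_wt = unit_activity(wt, {"sri": SRIState(0.6)}, {}, meth) - unit_activity(
            wt, {"sri": SRIState(0.0)}, {}, meth
        )
        d_inv = unit_activity(inv, {"sri": SRIState(0.6)}, {}, meth) - unit_activity(
            inv, {"sri": SRIState(0.0)}, {}, meth
        )
        assert d_wt < 0 < d_inv

    def test_activity_strictly_inside_unit_interval(self, rng):
        for _ in range(20):
            e = neutral_energies(
                f0=rng.uniform(-5, 5),
                df_meth_act=rng.uniform(-5, 0),
                df_meth_inact=rng.uniform(0, 5),
                dg_sri373_act=rng.uniform(-3, 3),
                dg_sri373_inact=rng.uniform(-3, 3),
            )
            comp = UnitComposition((SpeciesSpec("sri", 3, "SRI"),), e)
            a = unit_activity(
                comp,
                {"sri": SRIState(rng.uniform())},
                {},
                {"sri": (rng.uniform(), rng.uniform())},
            )
            assert 0.0 < a < 1.0
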