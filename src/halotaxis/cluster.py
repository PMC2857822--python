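"""Two-state activity of cooperative R-TWA signaling units.

An R-TWA signaling unit is a group of N_tot receptor-transducer-CheW-CheA
complexes that are conformationally coupled: at any moment the whole unit is
either active or inactive (MWC two-state formalism).  The probability A of
being active is a Boltzmann weight over the two conformations, with the free
energy of each conformation summed over the complexes in the unit.  Each
complex contributes

* a structural baseline F0 (active minus inactive, kT units),
* a methylation term: two transducers per complex, each carrying one
  activating and one inactivating methylation site whose mean methylated
  fractions shift the balance (methylated activating sites favor the active
  conformation),
* a receptor term: the receptor's photointermediate populations (or the
  ligand-bound fraction for chemoreceptors) weight per-state free-energy
  increments on each conformation.

The factorized form used in the ODE models treats receptor states as
continuous population fractions; ``enumerate_unit_activity`` computes the
same Boltzmann sum by explicit enumeration of the joint receptor-state
space and is the exact oracle for the factorized expression.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "RECEPTOR_KINDS",
    "SpeciesSpec",
    "FreeEnergyParams",
    "UnitComposition",
    "ligand_occupancy",
    "receptor_state_table",
    "complex_delta_f",
    "unit_activity",
    "enumerate_unit_activity",
    "superposed_activity",
]

RECEPTOR_KINDS = ("SRI", "SRII", "chemo", "none")


@dataclass(frozen=True)
class SpeciesSpec:
    """One receptor-transducer species within a signaling unit.

    ``count_in_unit`` R-TWA complexes of this species belong to each unit;
    every complex is a transducer homodimer (two methylation-site pairs).
    ``methylatable=False`` models transducers whose methylation sites were
    removed by mutagenesis (the methylation-deficient HtrI genotype).
    """

    name: str
    count_in_unit: int = 1
    receptor_kind: str = "none"
    methylatable: bool = True
    n_transducers_per_complex: int = 2

    def __post_init__(self) -> None:
        if self.receptor_kind not in RECEPTOR_KINDS:
            raise ValueError(f"receptor_kind must be one of {RECEPTOR_KINDS}")
        if self.count_in_unit < 0:
            raise ValueError("count_in_unit must be >= 0")


@dataclass(frozen=True)
class FreeEnergyParams:
    """Free-energy increments in kT units; negative values stabilize a state.

    The wildtype attractant configuration has the SRI_373 intermediate
    favoring the inactive conformation (dg_sri373_inact < dg_sri373_act);
    the in-silico inverted-response SRI mutant swaps the two.  Blue-light
    SRII signaling intermediates and (for repellent chemicals) ligand
    binding favor the active conformation by the symmetric mechanism.
    Ground states carry zero increment; their conformational energies are
    folded into f0.
    """

    f0: float = 0.0
    df_meth_act: float = -12.0
    df_meth_inact: float = 12.0
    dg_sri373_act: float = 0.0
    dg_sri373_inact: float = -2.0
    dg_srii360_act: float = -2.0
    dg_srii360_inact: float = 0.0
    dg_srii540_act: float = -2.0
    dg_srii540_inact: float = 0.0
    dg_ligand_act: float = 0.0
    dg_ligand_inact: float = -2.0

    def inverted_sri(self) -> "FreeEnergyParams":
        """Swap the SRI_373 increments (inverted orange-light response mutant)."""
        return replace(
            self,
            dg_sri373_act=self.dg_sri373_inact,
            dg_sri373_inact=self.dg_sri373_act,
        )


@dataclass(frozen=True)
class UnitComposition:
    """An R-TWA unit: N_tot complexes partitioned over species, plus energies."""

    species: tuple[SpeciesSpec, ...]
    energies: FreeEnergyParams = field(default_factory=FreeEnergyParams)

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if self.n_tot < 1:
            raise ValueError("a unit needs at least one complex")

    @property
    def n_tot(self) -> int:
        return sum(s.count_in_unit for s in self.species)


def ligand_occupancy(lig: float, k_d: float) -> float:
    """Quasi-steady-state fraction of ligand-bound binding protein, Lig/(K_D+Lig)."""
    if k_d <= 0:
        raise ValueError("K_D must be > 0")
    if lig < 0:
        raise ValueError("ligand concentration must be >= 0")
    return lig / (k_d + lig)


def receptor_state_table(
    species: SpeciesSpec,
    receptor_state,
    occupancy: float,
    energies: FreeEnergyParams,
) -> list[tuple[float, float, float]]:
    """(probability, dG_active, dG_inactive) per receptor intermediate.

    ``receptor_state`` is an :class:`~halotaxis.photocycles.SRIState` or
    :class:`~halotaxis.photocycles.SRIIState` for photoreceptor species and
    ignored otherwise; ``occupancy`` is the bound fraction for chemo species.
    """
    kind = species.receptor_kind
    e = energies
    if kind == "SRI":
        p373 = receptor_state.p373
        _check_prob(p373)
        return [(1.0 - p373, 0.0, 0.0), (p373, e.dg_sri373_act, e.dg_sri373_inact)]
    if kind == "SRII":
        p360, p540 = receptor_state.p360, receptor_state.p540
        _check_prob(p360)
        _check_prob(p540)
        return [
            (1.0 - p360 - p540, 0.0, 0.0),
            (p360, e.dg_srii360_act, e.dg_srii360_inact),
            (p540, e.dg_srii540_act, e.dg_srii540_inact),
        ]
    if kind == "chemo":
        _check_prob(occupancy)
        return [
            (1.0 - occupancy, 0.0, 0.0),
            (occupancy, e.dg_ligand_act, e.dg_ligand_inact),
        ]
    return [(1.0, 0.0, 0.0)]


def _check_prob(p: float) -> None:
    if not -1e-9 <= p <= 1.0 + 1e-9:
        raise ValueError(f"probability/fraction {p} outside [0, 1]")


def complex_delta_f(
    species: SpeciesSpec,
    receptor_state,
    occupancy: float,
    meth_state: tuple[float, float] | None,
    energies: FreeEnergyParams,
) -> float:
    """Per-complex log balance delta (kT) between active and inactive.

    delta = F0 + 2*(mA*dF_meth_act + mI*dF_meth_inact)
            - ln( sum_s p_s e^{-dG_s_act} / sum_s p_s e^{-dG_s_inact} )

    where ``meth_state = (mA, mI)`` holds the mean methylated fraction of the
    activating and inactivating site class and the factor 2 counts the two
    transducers per complex.  Non-methylatable species contribute no
    methylation term.  ``meth_state=None`` or a 1-tuple supports the
    single-site model variant (no inactivating class).
    """
    delta = energies.f0
    if species.methylatable and meth_state is not None:
        m = tuple(meth_state)
        for frac in m:
            _check_prob(frac)
        m_act = m[0]
        m_inact = m[1] if len(m) > 1 else 0.0
        n = species.n_transducers_per_complex
        delta += n * (m_act * energies.df_meth_act + m_inact * energies.df_meth_inact)
    z_act = 0.0
    z_inact = 0.0
    for p, dg_a, dg_i in receptor_state_table(species, receptor_state, occupancy, energies):
        z_act += p * math.exp(-dg_a)
        z_inact += p * math.exp(-dg_i)
    delta -= math.log(z_act) - math.log(z_inact)
    return delta


def unit_activity(
    composition: UnitComposition,
    receptor_states: dict,
    occupancies: dict,
    meth_states: dict,
) -> float:
    """Probability A that the whole unit is active, 1/(1 + exp(sum count*delta)).

    Dict arguments are keyed by species name; missing occupancy defaults to
    0 and missing methylation state to None.
    """
    total = 0.0
    for sp in composition.species:
        delta = complex_delta_f(
            sp,
            receptor_states.get(sp.name),
            occupancies.get(sp.name, 0.0),
            meth_states.get(sp.name),
            composition.energies,
        )
        total += sp.count_in_unit * delta
    return 1.0 / (1.0 + math.exp(total))


def enumerate_unit_activity(
    composition: UnitComposition,
    receptor_states: dict,
    occupancies: dict,
    meth_states: dict,
    max_states: int = 10**6,
) -> float:
    """Exact Boltzmann sum over conformation x joint receptor-state assignments.

    Enumerates every assignment of one receptor intermediate (or ligand
    binding state) to every complex in the unit, weights it by the product of
    state probabilities, and sums e^{-E} over the two conformations:
    A = Z_act / (Z_act + Z_inact).  Serves as the brute-force oracle for the
    factorized :func:`unit_activity`.
    """
    e = composition.energies
    per_complex: list[list[tuple[float, float, float]]] = []
    for sp in composition.species:
        table = receptor_state_table(
            sp, receptor_states.get(sp.name), occupancies.get(sp.name, 0.0), e
        )
        # Conformational offset of this complex: F0 plus the methylation term,
        # assigned entirely to the active conformation (only differences matter).
        offset = e.f0
        meth = meth_states.get(sp.name)
        if sp.methylatable and meth is not None:
            m = tuple(meth)
            m_act = m[0]
            m_inact = m[1] if len(m) > 1 else 0.0
            offset += sp.n_transducers_per_complex * (
                m_act * e.df_meth_act + m_inact * e.df_meth_inact
            )
        states = [(p, offset + a, i) for p, a, i in table]
        per_complex.extend([states] * sp.count_in_unit)

    n_joint = 1
    for states in per_complex:
        n_joint *= len(states)
    if n_joint > max_states:
        raise ValueError(
            f"joint state count {n_joint} exceeds cap {max_states}; use the factorized unit_activity"
        )

    z_act = 0.0
    z_inact = 0.0
    for assignment in itertools.product(*per_complex):
        weight = 1.0
        e_act = 0.0
        e_inact = 0.0
        for p, dg_a, dg_i in assignment:
            weight *= p
            e_act += dg_a
            e_inact += dg_i
        z_act += weight * math.exp(-e_act)
        z_inact += weight * math.exp(-e_inact)
    return z_act / (z_act + z_inact)


def superposed_activity(activities, weights) -> float:
    """Weighted-mean activity of conformationally independent populations.

    Used where stimulated and unstimulated transducer populations are
    functionally coupled only through the diffusible CheY feedback:
    A = sum(w_i * A_i) / sum(w_i).
    """
    activities = list(activities)
    weights = list(weights)
    if len(activities) != len(weights):
        raise ValueError("activities and weights must have equal length")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be >= 0")
    total = sum(weights)
    if total == 0:
        raise ValueError("weights must not all be zero")
    return sum(w * a for w, a in zip(weights, activities)) / total
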