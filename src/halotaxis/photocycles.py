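"""Photocycle kinetics of the sensory rhodopsins SRI and SRII.

SRI (orange/near-uv receptor) is reduced to a two-state cycle between the
ground state SRI_587 and the long-lived attractant signaling intermediate
SRI_373; uv excitation of SRI_373 is not modeled.  SRII (blue receptor) is a
three-state cycle SRII_487 --(light)--> SRII_360 --> SRII_540 --> SRII_487
whose long-lived intermediates are repellent signaling states.  Short-lived
intermediates are omitted.  Excitation rates are linear in photon flux,
k_exc = sigma * phi * I, with sigma*phi a single excitation-efficiency
parameter (cm^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SRIState",
    "SRIIState",
    "PhotocycleParams",
    "sri_rhs",
    "srii_rhs",
    "photocycle_steady_state",
]


@dataclass(frozen=True)
class SRIState:
    """SRI population state; p587 = 1 - p373 is implied."""

    p373: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p373 <= 1.0:
            raise ValueError("p373 must lie in [0, 1]")

    @property
    def p587(self) -> float:
        return 1.0 - self.p373


@dataclass(frozen=True)
class SRIIState:
    """SRII population state; p487 = 1 - p360 - p540 is implied."""

    p360: float = 0.0
    p540: float = 0.0

    def __post_init__(self) -> None:
        if self.p360 < 0 or self.p540 < 0 or self.p360 + self.p540 > 1.0 + 1e-12:
            raise ValueError("SRII fractions must be >= 0 with p360 + p540 <= 1")

    @property
    def p487(self) -> float:
        return 1.0 - self.p360 - self.p540


@dataclass(frozen=True)
class PhotocycleParams:
    """Rate parameters of both photocycles.

    sigma_phi_* are excitation efficiencies (absorption cross-section times
    quantum yield, cm^2); rate constants are s^-1.  Defaults put the SRI
    photocycle on its ~800 ms scale and the SRII signaling states on the
    seconds scale; all are configuration-exposed.
    """

    sigma_phi_sri: float = 1.5e-15
    k_decay_sri: float = 1.25
    sigma_phi_srii: float = 1.5e-15
    k_360_540: float = 3.0
    k_540_487: float = 0.8

    def __post_init__(self) -> None:
        for name in ("sigma_phi_sri", "k_decay_sri", "sigma_phi_srii", "k_360_540", "k_540_487"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def sri_rhs(state: SRIState | float, orange_flux: float, params: PhotocycleParams) -> float:
    """d(p373)/dt for the two-state SRI photocycle.

    Excitation of the ground state SRI_587 populates the attractant
    signaling state SRI_373, which decays thermally back.
    """
    if orange_flux < 0:
        raise ValueError("photon flux must be >= 0")
    p373 = state.p373 if isinstance(state, SRIState) else float(state)
    k_exc = params.sigma_phi_sri * orange_flux
    return k_exc * (1.0 - p373) - params.k_decay_sri * p373


def srii_rhs(
    state: SRIIState | tuple[float, float], blue_flux: float, params: PhotocycleParams
) -> tuple[float, float]:
    """(d(p360)/dt, d(p540)/dt) for the three-state SRII photocycle.

    The cycle conserves total population: the implied d(p487)/dt is the
    negative of the returned derivatives' sum.
    """
    if blue_flux < 0:
        raise ValueError("photon flux must be >= 0")
    if isinstance(state, SRIIState):
        p360, p540 = state.p360, state.p540
    else:
        p360, p540 = state
    p487 = 1.0 - p360 - p540
    k_exc = params.sigma_phi_srii * blue_flux
    d360 = k_exc * p487 - params.k_360_540 * p360
    d540 = params.k_360_540 * p360 - params.k_540_487 * p540
    return d360, d540


def photocycle_steady_state(
    params: PhotocycleParams, orange_flux: float, blue_flux: float
) -> tuple[SRIState, SRIIState]:
    """Unique fixed point of both photocycles under constant illumination."""
    if orange_flux < 0 or blue_flux < 0:
        raise ValueError("photon flux must be >= 0")
    k_exc_sri = params.sigma_phi_sri * orange_flux
    denom = k_exc_sri + params.k_decay_sri
    p373 = k_exc_sri / denom if denom > 0 else 0.0

    k_exc = params.sigma_phi_srii * blue_flux
    if k_exc == 0:
        srii = SRIIState(0.0, 0.0)
    else:
        # Flux balance through the cycle: k_exc*p487 = k36*p360 = k54*p540.
        mat = np.array(
            [
                [k_exc + params.k_360_540, k_exc],
                [-params.k_360_540, params.k_540_487],
            ]
        )
        rhs = np.array([k_exc, 0.0])
        p360, p540 = np.linalg.solve(mat, rhs)
        srii = SRIIState(float(p360), float(p540))
    return SRIState(p373), srii
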