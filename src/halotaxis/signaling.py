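"""Two-component phosphorylation cascade and CheY binding to R-TWA complexes.

CheA autophosphorylation is gated multiplicatively by the unit activity A;
the phosphate group is transferred to free CheY, and CheYp is hydrolyzed in
a first-order reaction (optionally catalyzed further by a CheC phosphatase).
Unphosphorylated CheY binds reversibly to R-TWA complexes; the bound pool
TWAY is the quantity that regulates transducer demethylation in the final
model.  An optional CheB phospho-cycle (CheA -> CheBp -> hydrolysis)
supports the CheBp model variants.  All species obey strict conservation:
CheY_free = Y_tot - CheYp - TWAY, CheA = A_tot - CheAp, CheB = B_tot - CheBp.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SignalingState",
    "SignalingParams",
    "phospho_rhs",
    "chey_binding_rhs",
    "conservation_totals",
]


@dataclass(frozen=True)
class SignalingParams:
    """Copy numbers (molecules/cell) and rate constants of the cascade.

    k_ap (s^-1) is the activity-gated autophosphorylation constant, k_pt
    (cell molecules^-1 s^-1) the phosphotransfer constant, k_hy (s^-1) the
    CheYp hydrolysis rate.  k_on/k_off govern CheY binding to R-TWA
    complexes; k_bp/k_bhy the optional CheB phospho-cycle; k_chec/chec_tot
    the optional CheC phosphatase.
    """

    a_tot: float = 2000.0
    y_tot: float = 2000.0
    b_tot: float = 300.0
    twa_tot: float = 2000.0
    k_ap: float = 2.0
    k_pt: float = 2.0e-2
    k_hy: float = 1.0
    k_on: float = 1.0e-3
    k_off: float = 1.0
    k_bp: float = 1.0e-4
    k_bhy: float = 0.1
    k_chec: float = 1.3
    chec_tot: float = 1000.0
    k_m_chec: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "a_tot", "y_tot", "b_tot", "twa_tot", "k_ap", "k_pt", "k_hy",
            "k_on", "k_off", "k_bp", "k_bhy", "k_chec", "chec_tot", "k_m_chec",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SignalingState:
    """Phospho- and bound-species amounts (molecules/cell)."""

    che_ap: float = 0.0
    che_yp: float = 0.0
    tway: float = 0.0
    che_bp: float = 0.0

    def che_y_free(self, params: SignalingParams) -> float:
        return params.y_tot - self.che_yp - self.tway

    def validate(self, params: SignalingParams) -> None:
        tol = 1e-6 * max(1.0, params.a_tot, params.y_tot, params.b_tot)
        if not -tol <= self.che_ap <= params.a_tot + tol:
            raise ValueError("CheAp outside [0, A_tot]")
        if self.che_yp < -tol or self.tway < -tol or self.che_y_free(params) < -tol:
            raise ValueError("CheY partition violates conservation")
        if not -tol <= self.che_bp <= params.b_tot + tol:
            raise ValueError("CheBp outside [0, B_tot]")


def phospho_rhs(
    state: SignalingState,
    a: float,
    params: SignalingParams,
    che_b_phospho: bool = False,
    che_c: bool = False,
) -> tuple[float, float, float]:
    """(d(CheAp)/dt, d(CheYp)/dt, d(CheBp)/dt) under unit activity ``a``."""
    if not -1e-9 <= a <= 1.0 + 1e-9:
        raise ValueError("activity A must lie in [0, 1]")
    y_free = state.che_y_free(params)
    d_ap = params.k_ap * a * (params.a_tot - state.che_ap) - params.k_pt * state.che_ap * y_free
    d_yp = params.k_pt * state.che_ap * y_free - params.k_hy * state.che_yp
    d_bp = 0.0
    if che_b_phospho:
        transfer_b = params.k_bp * state.che_ap * (params.b_tot - state.che_bp)
        d_ap -= transfer_b
        d_bp = transfer_b - params.k_bhy * state.che_bp
    if che_c:
        # Saturable (Michaelis-Menten) phosphatase: near zero-order above
        # k_m_chec, so a stimulus transient can overshoot severalfold.
        d_yp -= (
            params.k_chec * params.chec_tot * state.che_yp
            / (params.k_m_chec + state.che_yp)
        )
    return d_ap, d_yp, d_bp


def chey_binding_rhs(state: SignalingState, params: SignalingParams) -> float:
    """d(TWAY)/dt for reversible CheY binding to R-TWA complexes."""
    if state.tway > min(params.y_tot, params.twa_tot) * (1 + 1e-6) + 1e-9:
        raise ValueError("TWAY exceeds an available total")
    y_free = state.che_y_free(params)
    return params.k_on * y_free * (params.twa_tot - state.tway) - params.k_off * state.tway


def conservation_totals(
    state: SignalingState, params: SignalingParams
) -> tuple[float, float, float]:
    """(total CheY, total CheA, total CheB) recomputed from parts.

    The parts of each pool sum to the configured total by construction; this
    is the instrument the trajectory conservation checks use.
    """
    total_y = state.che_yp + state.tway + state.che_y_free(params)
    total_a = state.che_ap + (params.a_tot - state.che_ap)
    total_b = state.che_bp + (params.b_tot - state.che_bp)
    return total_y, total_a, total_b
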