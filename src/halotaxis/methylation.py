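"""Antagonistic transducer methylation/demethylation and radiolabel bookkeeping.

Each transducer carries one activating and one inactivating methylation
site.  Methylation (by CheR) proceeds at a constant per-site rate constant
``k_m``; demethylation (by CheB) of the two site classes is regulated by the
conformational state of the transducer's unit and, depending on the feedback
mechanism, by CheY, CheYp, or CheB/CheBp.  The alternative mechanisms of the
model ladder are selected by :class:`FeedbackConfig.mechanism`:

``linear``      dm_A = k_dm*A,            dm_I = k_dm*I            (Model 2)
``quadratic``   dm_A = k_dm*A^2,          dm_I = k_dm*I^2          (Model 3)
``fbm1``        dm_A = k_dm*A*(CheYp/Y_tot), dm_I = k_dm*I*(CheY/Y_tot)
``fbm2``        unphosphorylated CheY inhibits dm_A and enhances dm_I
                through Michaelis-Menten factors (the favored mechanism)
``fbm3``        mirror of fbm2 driven by CheYp, site roles exchanged
``fbm4/fbm5``   dm_A = k_dm*A^k1*(CheBp/B_tot)^k2, dm_I = k_dm*I^k1*(CheB/B_tot)^k2
                (fbm4: k1 = 1; fbm5: k1 > 1)

The Michaelis-Menten factors of fbm2 satisfy the two limits the mechanism is
defined by: in a cheY deletion (CheY = 0) dm_A -> k_dm*A*(1 + k_dmY) and
dm_I -> k_dm*I, while at saturating CheY dm_A -> k_dm*A and
dm_I -> k_dm*I*(1 + k_dmY).

For the flow-assay measurement model every site class is split into a
[methyl-3H]-labeled and an unlabeled pool; new methyl groups draw on the
labeled fraction of the intracellular methionine storage, and demethylation
of a labeled site releases one molecule of [methyl-3H]-methanol.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MECHANISMS",
    "MethylationPools",
    "MethioninePool",
    "FeedbackConfig",
    "Regulators",
    "demethylation_rates",
    "methylation_label_rhs",
]

MECHANISMS = ("none", "linear", "quadratic", "fbm1", "fbm2", "fbm3", "fbm4", "fbm5")


@dataclass(frozen=True)
class MethylationPools:
    """Per-species site-state fractions (of that species' sites per class).

    ``m*_u`` are methylated-unlabeled, ``m*_l`` methylated-labeled fractions
    of the activating (A) and inactivating (I) site classes; the remainders
    are unmethylated.
    """

    m_a_u: float = 0.0
    m_a_l: float = 0.0
    m_i_u: float = 0.0
    m_i_l: float = 0.0

    def __post_init__(self) -> None:
        for name in ("m_a_u", "m_a_l", "m_i_u", "m_i_l"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"{name} must be >= 0")
        if self.m_a_u + self.m_a_l > 1.0 + 1e-9 or self.m_i_u + self.m_i_l > 1.0 + 1e-9:
            raise ValueError("methylated fractions of a site class must not exceed 1")

    @property
    def m_a(self) -> float:
        return self.m_a_u + self.m_a_l

    @property
    def m_i(self) -> float:
        return self.m_i_u + self.m_i_l


@dataclass(frozen=True)
class MethioninePool:
    """Intracellular methionine storage.

    The total pool is constant; only the [methyl-3H]-labeled part has
    dynamics, decaying with first-order rate k_met (diffusion/exchange) and
    being consumed by methylation.
    """

    met_tot: float = 1.0e6
    met_3h: float = 0.0
    k_met: float = 1.0e-4

    def __post_init__(self) -> None:
        if self.met_tot <= 0:
            raise ValueError("Met_tot must be > 0")
        if not -1e-9 <= self.met_3h <= self.met_tot * (1 + 1e-9):
            raise ValueError("Met3H must lie in [0, Met_tot]")
        if self.k_met < 0:
            raise ValueError("k_Met must be >= 0")


@dataclass(frozen=True)
class FeedbackConfig:
    """Methylation-system rate constants and feedback mechanism selection.

    k_m, k_dm are basal per-site rate constants (s^-1); k_dmY >= 1 is the
    CheY feedback gain, K_Y the Michaelis constant of the CheY-dependent
    factors (same units as the regulating CheY quantity); k_dmB > 1 scales
    the esterase activity of phosphorylated CheB; k1, k2 >= 1 are the
    activity and CheB exponents of the fbm4/fbm5 variants.
    """

    mechanism: str = "fbm2"
    k_m: float = 1.0e-3
    k_dm: float = 5.7e-4
    k_dmy: float = 12.0
    k_y: float = 500.0
    k_dmb: float = 3.0
    k1: float = 1.0
    k2: float = 3.0
    bp_modifier: bool = False

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        for name in ("k_m", "k_dm", "k_y"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mechanism in ("fbm1", "fbm2", "fbm3") and self.k_dmy < 1:
            raise ValueError("k_dmY must be >= 1 for the CheY feedback mechanisms")
        if self.bp_modifier and self.k_dmb < 1:
            raise ValueError("k_dmB must be >= 1 when the CheBp modifier is enabled")
        if self.mechanism in ("fbm4", "fbm5") and (self.k1 < 1 or self.k2 < 1):
            raise ValueError("k1 and k2 must be >= 1 for the CheB feedback mechanisms")


@dataclass(frozen=True)
class Regulators:
    """Concentrations the demethylation feedback may depend on (molecules/cell).

    ``che_y_reg`` is the regulating unphosphorylated CheY quantity: the free
    CheY concentration in Models 3-4, complex-bound CheY (TWAY) in
    Models 5-6.  ``y_tot``/``b_tot`` normalize the fbm1 and fbm4/5 ratios.
    """

    che_y_reg: float = 0.0
    che_yp: float = 0.0
    che_b: float = 0.0
    che_bp: float = 0.0
    y_tot: float = 0.0
    b_tot: float = 0.0


def demethylation_rates(
    a: float, regulators: Regulators, config: FeedbackConfig
) -> tuple[float, float]:
    """Per-methylated-site demethylation rates (dm_A, dm_I) in s^-1."""
    if not -1e-9 <= a <= 1.0 + 1e-9:
        raise ValueError("activity A must lie in [0, 1]")
    i = 1.0 - a
    k_dm = config.k_dm
    mech = config.mechanism
    reg = regulators

    if mech == "none":
        dm_a = dm_i = 0.0
    elif mech == "linear":
        dm_a, dm_i = k_dm * a, k_dm * i
    elif mech == "quadratic":
        dm_a, dm_i = k_dm * a * a, k_dm * i * i
    elif mech == "fbm1":
        if reg.y_tot <= 0:
            ratio_p = ratio_u = 0.0
        else:
            ratio_p = reg.che_yp / reg.y_tot
            ratio_u = reg.che_y_reg / reg.y_tot
        dm_a = k_dm * a * ratio_p
        dm_i = k_dm * i * ratio_u
    elif mech == "fbm2":
        y = max(reg.che_y_reg, 0.0)
        denom = config.k_y + y
        dm_a = k_dm * a * (1.0 + config.k_dmy * config.k_y / denom)
        dm_i = k_dm * i * (1.0 + config.k_dmy * y / denom)
    elif mech == "fbm3":
        yp = max(reg.che_yp, 0.0)
        denom = config.k_y + yp
        dm_a = k_dm * a * (1.0 + config.k_dmy * yp / denom)
        dm_i = k_dm * i * (1.0 + config.k_dmy * config.k_y / denom)
    else:  # fbm4 / fbm5
        if reg.b_tot <= 0:
            raise ValueError(f"mechanism {mech!r} requires CheB (B_tot > 0)")
        frac_bp = max(reg.che_bp, 0.0) / reg.b_tot
        frac_b = max(reg.che_b, 0.0) / reg.b_tot
        dm_a = k_dm * a**config.k1 * frac_bp**config.k2
        dm_i = k_dm * i**config.k1 * frac_b**config.k2
    if config.bp_modifier:
        if reg.b_tot <= 0:
            raise ValueError("the CheBp modifier requires CheB (B_tot > 0)")
        factor = (max(reg.che_b, 0.0) + config.k_dmb * max(reg.che_bp, 0.0)) / reg.b_tot
        dm_a *= factor
        dm_i *= factor
    return dm_a, dm_i


def methylation_label_rhs(
    pools: MethylationPools,
    met: MethioninePool,
    dm_a: float,
    dm_i: float,
    config: FeedbackConfig,
    n_sites: float,
) -> tuple[tuple[float, float, float, float], float, float]:
    """Label-resolved site dynamics for one transducer species.

    Returns the derivatives of (m_a_u, m_a_l, m_i_u, m_i_l), the methylation
    drain on the labeled methionine pool d(Met3H)/dt, and the instantaneous
    [methyl-3H]-methanol release rate (molecules cell^-1 s^-1).  ``n_sites``
    is the number of sites per class per cell for this species.  The caller
    adds the first-order label loss -k_Met*Met3H once, not per species.
    """
    frac_label = met.met_3h / met.met_tot
    if not -1e-9 <= frac_label <= 1.0 + 1e-9:
        raise ValueError("Met3H must lie in [0, Met_tot]")
    k_m = config.k_m

    free_a = 1.0 - pools.m_a_u - pools.m_a_l
    free_i = 1.0 - pools.m_i_u - pools.m_i_l
    d_a_l = k_m * free_a * frac_label - dm_a * pools.m_a_l
    d_a_u = k_m * free_a * (1.0 - frac_label) - dm_a * pools.m_a_u
    d_i_l = k_m * free_i * frac_label - dm_i * pools.m_i_l
    d_i_u = k_m * free_i * (1.0 - frac_label) - dm_i * pools.m_i_u

    d_met3h = -k_m * (free_a + free_i) * frac_label * n_sites
    r_meoh3h = (dm_a * pools.m_a_l + dm_i * pools.m_i_l) * n_sites
    return (d_a_u, d_a_l, d_i_u, d_i_l), d_met3h, r_meoh3h
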