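"""Measurement model of the methanol flow assay.

The cells' instantaneous [methyl-3H]-methanol release rate is not observed
directly: the methanol is carried through the apparatus (first-order outflow
lag ``T_out``), collected in fractions of ``T_S`` seconds, and quantified by
liquid scintillation counting.  This module provides the output filter, the
fraction integrator, and the molecules <-> counts conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AVOGADRO",
    "CURIE",
    "FractionSeries",
    "output_delay_rhs",
    "collect_fractions",
    "decays_per_molecule_per_s",
    "counts_conversion",
    "counts_to_molecules",
]

AVOGADRO = 6.022e23  # molecules per mol
CURIE = 3.7e10  # decays per second per Ci


@dataclass(frozen=True)
class FractionSeries:
    """Per-fraction methanol output of the flow assay.

    ``t_mid`` are fraction mid-times (s), ``counts`` the per-fraction amounts
    (molecules/cell, or cpm after conversion); ``t_s`` records the uniform
    fraction length and ``units`` what the counts column holds.
    """

    t_mid: np.ndarray
    counts: np.ndarray
    t_s: float
    units: str = "molecules/cell"

    def __post_init__(self) -> None:
        object.__setattr__(self, "t_mid", np.asarray(self.t_mid, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        if self.t_mid.shape != self.counts.shape:
            raise ValueError("t_mid and counts must have matching shapes")
        if np.any(self.counts < 0):
            raise ValueError("fraction counts must be >= 0")
        if self.t_s <= 0:
            raise ValueError("T_S must be > 0")
        if len(self.t_mid) > 1 and not np.allclose(np.diff(self.t_mid), self.t_s, rtol=1e-6):
            raise ValueError("fractions must be uniformly spaced by T_S")

    def __len__(self) -> int:
        return len(self.t_mid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_mid": self.t_mid, "counts": self.counts})

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# fraction length T_S = {self.t_s} s; counts in {self.units}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, t_s: float | None = None, units: str = "molecules/cell"):
        df = pd.read_csv(path, sep="\t", comment="#")
        t_mid = df.iloc[:, 0].to_numpy(float)
        if t_s is None:
            if len(t_mid) < 2:
                raise ValueError("cannot infer T_S from fewer than two fractions")
            t_s = float(t_mid[1] - t_mid[0])
        return cls(t_mid, df.iloc[:, 1].to_numpy(float), t_s, units)


def output_delay_rhs(m_out: float, r_release: float, t_out: float) -> float:
    """First-order outflow lag: d(M_out)/dt = (r_release - M_out)/T_out."""
    if t_out <= 0:
        raise ValueError("T_out must be > 0 (use the bypass flag for the undelayed limit)")
    return (r_release - m_out) / t_out


def collect_fractions(
    t_grid: np.ndarray, m_out: np.ndarray, t_s: float, t0: float = 0.0
) -> FractionSeries:
    """Integrate the delayed release rate over consecutive T_S windows.

    fraction_i = integral of M_out over [t0 + (i-1)*T_S, t0 + i*T_S), by
    trapezoidal quadrature on the solver grid with linear interpolation at
    window edges.  Only complete fractions are emitted; a partial trailing
    window is dropped.
    """
    if t_s <= 0:
        raise ValueError("T_S must be > 0")
    t_grid = np.asarray(t_grid, dtype=float)
    m_out = np.asarray(m_out, dtype=float)
    if t_grid[-1] - t0 < t_s:
        raise ValueError("trajectory shorter than one fraction")
    n_frac = int(np.floor((t_grid[-1] - t0) / t_s + 1e-9))
    edges = t0 + t_s * np.arange(n_frac + 1)
    fracs = np.empty(n_frac)
    for i in range(n_frac):
        lo, hi = edges[i], edges[i + 1]
        mask = (t_grid > lo) & (t_grid < hi)
        ts = np.concatenate(([lo], t_grid[mask], [hi]))
        vals = np.interp(ts, t_grid, m_out)
        fracs[i] = np.trapezoid(vals, ts)
    t_mid = edges[:-1] + t_s / 2.0
    return FractionSeries(t_mid, np.maximum(fracs, 0.0), t_s)


def decays_per_molecule_per_s(specific_activity: float) -> float:
    """Radioactive decay rate per labeled molecule for a given specific activity.

    specific_activity is in Ci/mmol; one Ci is 3.7e10 decays/s and one mmol
    holds 6.022e20 molecules, so 75 Ci/mmol gives about 4.608e-9 s^-1.
    """
    if specific_activity <= 0:
        raise ValueError("specific activity must be > 0")
    return specific_activity * CURIE / (AVOGADRO * 1e-3)


def counts_conversion(
    series: FractionSeries, specific_activity: float = 75.0, efficiency: float = 0.5
) -> FractionSeries:
    """Convert per-fraction molecules/cell to scintillation cpm per cell."""
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("counting efficiency must lie in (0, 1]")
    rate = decays_per_molecule_per_s(specific_activity)
    cpm = series.counts * rate * 60.0 * efficiency
    return FractionSeries(series.t_mid, cpm, series.t_s, units="cpm/cell")


def counts_to_molecules(
    series: FractionSeries, specific_activity: float = 75.0, efficiency: float = 0.5
) -> FractionSeries:
    """Inverse of :func:`counts_conversion`, for reading experimental counts."""
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("counting efficiency must lie in (0, 1]")
    rate = decays_per_molecule_per_s(specific_activity)
    molecules = series.counts / (rate * 60.0 * efficiency)
    return FractionSeries(series.t_mid, molecules, series.t_s, units="molecules/cell")
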