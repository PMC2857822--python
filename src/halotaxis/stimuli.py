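"""Timed stimulus protocols and flow-chamber input dynamics.

A cell on the flow-assay filter experiences piecewise-constant inputs on up
to three channels: attractant orange light (sensed by SRI), repellent blue
light (sensed by SRII), and a chemoattractant (branched-chain amino acids
sensed through BasB/BasT).  Light reaches the cells instantaneously, while
the chemoattractant is subject to the flow dynamics of the apparatus: a
transport dead time ``T_delay`` and a first-order mixing lag ``T_in``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "CHANNELS",
    "LIGHT_CHANNELS",
    "Segment",
    "StimulusProtocol",
    "FlowDynamicsParams",
    "protocol_value",
    "delayed_protocol",
    "ligand_inflow_rhs",
]

CHANNELS = ("orange", "blue", "ligand")
LIGHT_CHANNELS = ("orange", "blue")


@dataclass(frozen=True)
class Segment:
    """One constant-magnitude stimulus interval, right-open [t_start, t_end).

    Magnitude is a photon flux (photons cm^-2 s^-1) for light channels and a
    concentration (arbitrary units) for the ligand channel.
    """

    t_start: float
    t_end: float
    channel: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if not self.t_start < self.t_end:
            raise ValueError(f"segment requires t_start < t_end, got [{self.t_start}, {self.t_end})")
        if self.magnitude < 0:
            raise ValueError("stimulus magnitude must be >= 0")

    def covers(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


@dataclass(frozen=True)
class StimulusProtocol:
    """A list of non-overlapping stimulus segments across channels."""

    segments: tuple[Segment, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        segs = tuple(
            s if isinstance(s, Segment) else Segment(*s) for s in self.segments
        )
        object.__setattr__(self, "segments", segs)
        for channel in CHANNELS:
            chan = sorted(
                (s for s in segs if s.channel == channel), key=lambda s: s.t_start
            )
            for a, b in zip(chan, chan[1:]):
                if b.t_start < a.t_end:
                    raise ValueError(
                        f"overlapping segments on channel {channel!r}: "
                        f"[{a.t_start}, {a.t_end}) and [{b.t_start}, {b.t_end})"
                    )

    def value(self, t: float, channel: str) -> float:
        return protocol_value(self, t, channel)

    def switch_times(self) -> list[float]:
        """Sorted unique segment endpoints (integration restart points)."""
        times = set()
        for s in self.segments:
            times.add(s.t_start)
            times.add(s.t_end)
        return sorted(times)


def protocol_value(protocol: StimulusProtocol, t: float, channel: str) -> float:
    """Magnitude of the unique segment covering ``t`` on ``channel``, else 0.

    Segments are right-open: a segment [t0, t1) covers t0 but not t1.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    for s in protocol.segments:
        if s.channel == channel and s.covers(t):
            return s.magnitude
    return 0.0


def delayed_protocol(protocol: StimulusProtocol, t_delay: float) -> StimulusProtocol:
    """Shift ligand segments by the transport dead time; light is unaffected.

    The mixing/transport delay of the flow chamber applies only to the
    chemoattractant; photostimuli act on the cells without delay.
    """
    if t_delay < 0:
        raise ValueError("T_delay must be >= 0")
    if t_delay == 0:
        return protocol
    segs = tuple(
        replace(s, t_start=s.t_start + t_delay, t_end=s.t_end + t_delay)
        if s.channel == "ligand"
        else s
        for s in protocol.segments
    )
    return StimulusProtocol(segs)


def ligand_inflow_rhs(lig: float, lig_in: float, t_in: float) -> float:
    """First-order mixing lag of the flow chamber: d(Lig)/dt = (Lig_in - Lig)/T_in.

    ``Lig_in`` is the commanded stimulus, ``Lig`` the concentration the cells
    actually sense.  For the instantaneous limit bypass the lag instead of
    passing T_in = 0.
    """
    if t_in <= 0:
        raise ValueError("T_in must be > 0 (use the bypass flag for the instantaneous limit)")
    return (lig_in - lig) / t_in


@dataclass(frozen=True)
class FlowDynamicsParams:
    """Apparatus time constants of the flow assay.

    T_in:    ligand mixing lag in the chamber (s)
    T_out:   methanol outflow lag to the fraction collector (s)
    T_delay: transport dead time applied to the chemo-stimulus onset (s)
    T_S:     fraction length of the collector (s)
    """

    t_in: float = 15.0
    t_out: float = 15.0
    t_delay: float = 10.0
    t_s: float = 30.0

    def __post_init__(self) -> None:
        for name in ("t_in", "t_out", "t_delay", "t_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.t_s <= 0:
            raise ValueError("T_S must be > 0")
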