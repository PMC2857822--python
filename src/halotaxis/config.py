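"""TOML run-configuration parsing.

A run configuration declares which model to assemble, the genotype and
variant flags, parameter overrides per group, and the stimulus protocol:

.. code-block:: toml

    [model]
    id = 6
    feedback = "fbm2"        # optional override of the model default
    genotype = ["wildtype"]
    chec = false

    [photocycles]
    k_decay_sri = 1.25

    [energies]
    df_meth_act = -12.0

    [[protocol.segments]]
    channel = "orange"
    t_start = 200.0
    t_end = 800.0
    magnitude = 1.0e15

    [simulation]
    t_end = 2600.0
    dt_out = 1.0

Unspecified constants fall back to the curated defaults of the selected
model (:func:`halotaxis.params.default_params`).
"""

from __future__ import annotations

import tomllib
from dataclasses import replace
from pathlib import Path

from .models import ModelSpec
from .params import Params, default_params
from .stimuli import Segment, StimulusProtocol

__all__ = ["RunConfig", "load_config", "parse_config"]

_PARAM_GROUPS = ("photocycles", "energies", "feedback", "signaling", "flow", "labeling")
_TOP_LEVEL_PARAMS = (
    "htr_tot", "k_d_ligand", "k_u", "k_s", "regulator", "bypass_t_in", "bypass_t_out",
)


class RunConfig:
    """A parsed run configuration: model spec, parameters, protocol, options."""

    def __init__(self, spec: ModelSpec, params: Params, protocol: StimulusProtocol,
                 t_end: float, dt_out: float):
        self.spec = spec
        self.params = params
        self.protocol = protocol
        self.t_end = t_end
        self.dt_out = dt_out


def parse_config(data: dict) -> RunConfig:
    model = data.get("model", {})
    spec = ModelSpec(
        model_id=int(model.get("id", 6)),
        feedback=model.get("feedback"),
        cheb_phospho=bool(model.get("cheb_phospho", False)),
        chec=bool(model.get("chec", False)),
        genotype=frozenset(model.get("genotype", ["wildtype"])),
    )
    params = default_params(spec.model_id)
    for group in _PARAM_GROUPS:
        overrides = data.get(group)
        if overrides:
            sub = getattr(params, group)
            unknown = [k for k in overrides if not hasattr(sub, k)]
            if unknown:
                raise KeyError(f"unknown keys {unknown} in [{group}]")
            params = params.replace(**{group: replace(sub, **overrides)})
    top = data.get("params", {})
    unknown = [k for k in top if k not in _TOP_LEVEL_PARAMS]
    if unknown:
        raise KeyError(f"unknown keys {unknown} in [params]")
    if top:
        params = params.replace(**top)

    segments = tuple(
        Segment(float(s["t_start"]), float(s["t_end"]), s["channel"], float(s["magnitude"]))
        for s in data.get("protocol", {}).get("segments", [])
    )
    protocol = StimulusProtocol(segments)
    sim = data.get("simulation", {})
    t_end = float(sim.get("t_end", max((s.t_end for s in segments), default=0.0) + 600.0))
    dt_out = float(sim.get("dt_out", 1.0))
    return RunConfig(spec, params, protocol, t_end, dt_out)


def load_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        return parse_config(tomllib.load(fh))
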