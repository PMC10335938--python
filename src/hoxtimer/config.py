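"""Run configuration: TOML files mapping onto the parameter dataclasses.

A config file has sections ``[locus]`` (genotype name or BED overrides),
``[sim]`` (SimulationParams fields), ``[timer]`` (TimerParams fields) and
``[output]``; top-level ``seeds`` lists replicate seeds.  Unknown keys are
rejected.  The shipped default (``data/default_config.toml``) is the output
of the committed calibration script (``scripts/calibrate.py``).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .extrusion import SimulationParams
from .timer import TimerParams

__all__ = ["RunConfig", "load_config", "parse_config", "default_params"]


@dataclass
class RunConfig:
    genotype: str = "wild_type"
    genes_bed: str | None = None
    cbs_bed: str | None = None
    regions_bed: str | None = None
    sim: SimulationParams = field(default_factory=SimulationParams)
    timer: TimerParams = field(default_factory=TimerParams)
    out_dir: str = "."
    snapshot_every: float = 0.05
    t_start: float = 48.0
    t_end: float = 168.0
    seeds: tuple[int, ...] = (1,)


_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationParams)}
_TIMER_FIELDS = {f.name for f in dataclasses.fields(TimerParams)}
_LOCUS_KEYS = {"genotype", "genes_bed", "cbs_bed", "regions_bed"}
_OUTPUT_KEYS = {"out_dir", "snapshot_every", "t_start", "t_end"}


def parse_config(doc: dict, base: RunConfig | None = None) -> RunConfig:
    """Build a validated RunConfig from a parsed TOML document."""
    cfg = base or RunConfig()
    known_sections = {"locus", "sim", "timer", "output", "seeds"}
    unknown = set(doc) - known_sections
    if unknown:
        raise ValueError(f"unknown config section(s)/key(s): {sorted(unknown)}")

    locus_sec = doc.get("locus", {})
    bad = set(locus_sec) - _LOCUS_KEYS
    if bad:
        raise ValueError(f"unknown [locus] key(s): {sorted(bad)}")
    for k, v in locus_sec.items():
        setattr(cfg, k, v)

    sim_sec = doc.get("sim", {})
    bad = set(sim_sec) - _SIM_FIELDS
    if bad:
        raise ValueError(f"unknown [sim] key(s): {sorted(bad)}")
    if sim_sec:
        cfg.sim = dataclasses.replace(cfg.sim, **sim_sec)

    timer_sec = doc.get("timer", {})
    bad = set(timer_sec) - _TIMER_FIELDS
    if bad:
        raise ValueError(f"unknown [timer] key(s): {sorted(bad)}")
    if timer_sec:
        cfg.timer = dataclasses.replace(cfg.timer, **timer_sec)

    out_sec = doc.get("output", {})
    bad = set(out_sec) - _OUTPUT_KEYS
    if bad:
        raise ValueError(f"unknown [output] key(s): {sorted(bad)}")
    for k, v in out_sec.items():
        setattr(cfg, k, v)

    if "seeds" in doc:
        cfg.seeds = tuple(int(s) for s in doc["seeds"])
    return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    return parse_config(doc, base=_default_runconfig())


def _default_doc() -> dict:
    ref = resources.files("hoxtimer") / "data" / "default_config.toml"
    with ref.open("rb") as fh:
        return tomllib.load(fh)


def _default_runconfig() -> RunConfig:
    return parse_config(_default_doc())


def default_params() -> tuple[SimulationParams, TimerParams]:
    """The shipped calibrated wild-type parameters."""
    cfg = _default_runconfig()
    return cfg.sim, cfg.timer
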