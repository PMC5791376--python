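"""Experiment configuration: YAML in, validated dataclasses out.

Every stochastic stage receives a seed derived deterministically from the
global seed and the stage name, so a whole experiment is reproducible from
one integer and reruns are byte-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .simulate import PRESETS, EvoParams, SimParams
from .sweep import SweepConfig
from .synteny import ChainParams

EXPERIMENTS = ("sweep", "go_stability", "scaffold_pitfall")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class ExperimentConfig:
    experiment: str = "sweep"
    sim: SimParams = field(default_factory=SimParams)
    evo: EvoParams = field(default_factory=EvoParams)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    chain: ChainParams = field(default_factory=ChainParams)
    outdir: str = "syntfrag_out"
    seed: int = 0
    # go_stability settings
    go_fragment_size: int = 100_000
    go_replicates: int = 20
    go_n_terms: int = 50
    # scaffold_pitfall settings
    scaffold_fragment_size: int = 100_000
    scaffold_gap_len: int = 100

    def validate(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}")
        self.sim.validate()
        self.evo.validate()
        # ChainParams/SweepConfig validate in __post_init__

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)


def _build_sim(d: dict) -> SimParams:
    if "preset" in d:
        base = PRESETS[d.pop("preset")]
        return SimParams(**{**asdict(base), **d})
    return SimParams(**d)


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "sim" in kwargs:
        kwargs["sim"] = _build_sim(dict(kwargs["sim"]))
    if "evo" in kwargs:
        kwargs["evo"] = EvoParams(**kwargs["evo"])
    if "chain" in kwargs:
        kwargs["chain"] = ChainParams(**kwargs["chain"])
    if "sweep" in kwargs:
        sw = dict(kwargs["sweep"])
        if "chain_params" in sw:
            sw["chain_params"] = ChainParams(**sw["chain_params"])
        if "fragment_sizes" in sw:
            sw["fragment_sizes"] = tuple(sw["fragment_sizes"])
        kwargs["sweep"] = SweepConfig(**sw)
    cfg = ExperimentConfig(**kwargs)
    cfg.validate()
    return cfg
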