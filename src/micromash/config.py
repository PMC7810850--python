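"""Run configuration: program, noise model, thresholds, seed — YAML-backed.

A single RunConfig drives the CLI subcommands and the full demo. Every
output carries the config hash and seed so any result can be reproduced
exactly from its header.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .program import MashProgram, MashStage, default_program
from .simulate import NoiseModel

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    program: MashProgram = field(default_factory=default_program)
    noise: NoiseModel = field(default_factory=NoiseModel)
    alpha_protein: float = 0.05
    alpha_peptide: float = 1e-5
    family_mode: str = "global"   # Bonferroni family for the difference map
    delta: float = 0.05           # ground-truth relative-change threshold
    seed: int = 0

    def __post_init__(self) -> None:
        for name, a in (("alpha_protein", self.alpha_protein),
                        ("alpha_peptide", self.alpha_peptide),
                        ("delta", self.delta)):
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.family_mode not in ("global", "per-feature"):
            raise ValueError("family_mode must be 'global' or 'per-feature'")

    def to_dict(self) -> dict:
        d = {
            "program": {
                "stages": [asdict(s) for s in self.program.stages],
            },
            "noise": asdict(self.noise),
            "alpha_protein": self.alpha_protein,
            "alpha_peptide": self.alpha_peptide,
            "family_mode": self.family_mode,
            "delta": self.delta,
            "seed": self.seed,
        }
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        prog = kwargs.pop("program", None)
        if prog is not None:
            stages = tuple(MashStage(**s) for s in prog["stages"])
            kwargs["program"] = MashProgram(stages=stages)
        noise = kwargs.pop("noise", None)
        if noise is not None:
            kwargs["noise"] = NoiseModel(**noise)
        return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(d)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the canonical YAML form."""
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
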