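"""Pipeline configuration: every threshold in one place, TOML round-trip.

Defaults encode the documented rule set (read filters, the 3-reads-in-3-
replicates position filter with its sqrt(9) = 3 signal-to-noise floor, a
25 bp cluster gap, the 10-40 bp poly(A)-signal scan window, internal-
priming A-run rules, 50 bp significant-gap length, 10 bp terminus
tolerance, the 10 kb downstream search cap and the optional 300 bp
automated-baseline window, and miRNA arm-pair bounds).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .bridge import BridgeParams
from .decision import DecisionParams
from .peaks import ReadFilterParams
from .srna import ArmPairParams


@dataclass
class SignalParams:
    pas_window_min: int = 10
    pas_window_max: int = 40
    priming_window_down: int = 10
    priming_min_a_run: int = 6
    priming_a_fraction: float = 0.7


@dataclass
class PipelineConfig:
    read_filter: ReadFilterParams = field(default_factory=ReadFilterParams)
    signals: SignalParams = field(default_factory=SignalParams)
    bridge: BridgeParams = field(default_factory=BridgeParams)
    decision: DecisionParams = field(default_factory=DecisionParams)
    arm_pair: ArmPairParams = field(default_factory=ArmPairParams)
    max_cluster_gap: int = 25
    opposite_strand_margin: int = 50  # "within/near annotation", bp
    stranded_rnaseq_available: bool = False
    seed: int = 0
    genome_build: str = "synthetic"

    def to_toml(self) -> str:
        lines = []
        scalars = {
            "max_cluster_gap": self.max_cluster_gap,
            "opposite_strand_margin": self.opposite_strand_margin,
            "stranded_rnaseq_available": self.stranded_rnaseq_available,
            "seed": self.seed,
            "genome_build": self.genome_build,
        }
        for k, v in scalars.items():
            lines.append(f"{k} = {_toml_value(v)}")
        for section in ("read_filter", "signals", "bridge", "decision", "arm_pair"):
            obj = getattr(self, section)
            lines.append("")
            lines.append(f"[{section}]")
            for f_ in dataclasses.fields(obj):
                v = getattr(obj, f_.name)
                if v is None:
                    continue  # TOML has no null; absent key means default None
                lines.append(f"{f_.name} = {_toml_value(v)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        sections = {
            "read_filter": ReadFilterParams,
            "signals": SignalParams,
            "bridge": BridgeParams,
            "decision": DecisionParams,
            "arm_pair": ArmPairParams,
        }
        for key, value in data.items():
            if key in sections:
                kwargs[key] = sections[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return f'"{v}"'
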