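"""Run configuration: input paths, output directory, stages, parameter
overrides.  Unknown keys are rejected and the resolved configuration is
echoed verbatim to the run log."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import PipelineParams, ValidationError

STAGES = ("annotate", "editing", "ecr", "splicing", "diffexp", "structure", "report")

_TOP_KEYS = {"inputs", "outdir", "seed", "stages", "params"}

INPUT_KEYS = {
    "gtf", "repeats", "clip_peaks", "snps", "pileup_dir", "design",
    "gene_counts", "intron_counts", "ecr_counts", "ecr_lengths",
    "splice_counts", "splice_significance", "structures", "isgs",
}


@dataclass
class RunConfig:
    inputs: dict[str, str] = field(default_factory=dict)
    outdir: str = "ecrscan_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    params: PipelineParams = field(default_factory=PipelineParams)

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValidationError("stage list must not be empty")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stage(s): {sorted(unknown)}")
        bad = set(self.inputs) - INPUT_KEYS
        if bad:
            raise ValidationError(f"unknown input key(s): {sorted(bad)}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _TOP_KEYS
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        params = PipelineParams().override(**data.get("params", {}))
        return cls(
            inputs={k: str(v) for k, v in data.get("inputs", {}).items()},
            outdir=str(data.get("outdir", "ecrscan_out")),
            seed=int(data.get("seed", 0)),
            stages=list(data.get("stages", STAGES)),
            params=params,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def echo(self) -> str:
        """Resolved configuration, one line per entry, for the run log."""
        lines = [f"outdir = {self.outdir}", f"seed = {self.seed}",
                 f"stages = {','.join(self.stages)}"]
        for k in sorted(self.inputs):
            lines.append(f"input {k} = {self.inputs[k]}")
        for k, v in self.params.as_dict().items():
            lines.append(f"param {k} = {v}")
        return "\n".join(lines)
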