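"""Parameter containers for DMR calling and the end-to-end pipeline.

The defaults reproduce the study design this pipeline models: per-sample
coverage of at least 5x at every CpG of a comparison, a maximum of 100 bp
between two CpGs of one region, congruence in at least 4 of 5 sire groups
for liver (all 5 for testis, where the input libraries are sire-pooled),
and 100 per-position permutations per sire group for the empirical
false-positive check.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError


@dataclass(frozen=True)
class DmrCallParams:
    """Parameters of the filter -> test -> cluster chain for one comparison."""

    min_coverage: int = 5        # reads per CpG per sample (joint filter)
    alpha: float = 0.05          # site-level two-sided Fisher threshold, strict <
    max_gap: int = 100           # bp between consecutive member CpGs, inclusive
    min_sites: int = 2           # CpGs per region
    break_on_nonsig: bool = False  # break runs on covered non-significant sites

    def validate(self) -> "DmrCallParams":
        if self.min_coverage < 1:
            raise ConfigurationError("min_coverage must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigurationError("alpha must lie in (0, 1]")
        if self.max_gap < 0:
            raise ConfigurationError("max_gap must be non-negative")
        if self.min_sites < 1:
            raise ConfigurationError("min_sites must be >= 1")
        return self


@dataclass(frozen=True)
class PipelineConfig:
    """Everything `run_pipeline` needs, loadable from one YAML file."""

    counts_dir: str = "counts"
    design_path: str = "design.tsv"
    annotation_paths: Mapping[str, str] = field(default_factory=dict)  # class -> BED
    truth_path: str | None = None
    output_dir: str = "out"
    call: DmrCallParams = field(default_factory=DmrCallParams)
    k_min: Mapping[str, int] = field(
        default_factory=lambda: {"liver": 4, "testis": 5})
    n_permutations: int = 100
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        self.call.validate()
        if self.n_permutations < 0:
            raise ConfigurationError("n_permutations must be >= 0")
        for organ, k in self.k_min.items():
            if k < 1:
                raise ConfigurationError(f"k_min[{organ}] must be >= 1")
        return self

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        call_keys = {f.name for f in dataclasses.fields(DmrCallParams)}
        call = DmrCallParams(**{k: raw.pop(k) for k in list(raw) if k in call_keys})
        known = {f.name for f in dataclasses.fields(cls)} - {"call"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(call=call, **raw).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        call = out.pop("call")
        out.update(call)
        out["annotation_paths"] = dict(self.annotation_paths)
        out["k_min"] = dict(self.k_min)
        return out
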