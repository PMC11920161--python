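"""Experiment configuration: schema, defaults, and YAML validation.

A single config file drives the full pipeline (simulate -> embed -> train ->
evaluate). The defaults are the reference training protocol: 50-dimensional
embeddings per proximity order (100-d concatenated concepts), learning rate
1e-4, batch size 256, 10% dropout, 400 epochs, concatenated inputs scaled by
a factor of 10.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .edge_model import EdgeReprConfig, ModelConfig
from .line_embed import LineConfig
from .synthetic_kg import SynthConfig

__all__ = ["ExperimentConfig", "validate_config"]


@dataclass
class ExperimentConfig:
    """Validated settings for one reproducible experiment.

    ``manifest`` points at an on-disk dataset (written by the simulator or
    converted from external triplet files); when absent, a synthetic dataset
    is generated from ``synth``. ``seeds`` must list one seed per run.
    """

    line: LineConfig = field(default_factory=LineConfig)
    repr_cfg: EdgeReprConfig = field(default_factory=EdgeReprConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    manifest: str | None = None
    vocab_mode: str = "evaluation"
    runs: int = 1
    seeds: list[int] = field(default_factory=lambda: [0])
    outdir: str = "runs"

    def __post_init__(self) -> None:
        if self.vocab_mode not in ("evaluation", "comprehensive"):
            raise ValueError(f"vocab_mode must be evaluation|comprehensive, got {self.vocab_mode!r}")
        if self.runs <= 0:
            raise ValueError("runs must be positive")
        if len(self.seeds) != self.runs:
            raise ValueError(f"need exactly {self.runs} seeds, got {len(self.seeds)}")

    def to_dict(self) -> dict:
        d = {
            "line": asdict(self.line),
            "repr": asdict(self.repr_cfg),
            "model": asdict(self.model),
            "synth": asdict(self.synth),
            "manifest": self.manifest,
            "vocab_mode": self.vocab_mode,
            "runs": self.runs,
            "seeds": list(self.seeds),
            "outdir": self.outdir,
        }
        d["synth"]["docs_per_edge"] = list(d["synth"]["docs_per_edge"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


_SECTION_TYPES = {
    "line": LineConfig,
    "repr": EdgeReprConfig,
    "model": ModelConfig,
    "synth": SynthConfig,
}
_TOP_LEVEL = {"line", "repr", "model", "synth", "manifest", "vocab_mode",
              "runs", "seeds", "outdir"}


def _build_section(name: str, values: dict):
    cls = _SECTION_TYPES[name]
    valid = set(cls.__dataclass_fields__)
    unknown = set(values) - valid
    if unknown:
        raise ValueError(f"unknown key(s) in section '{name}': {', '.join(sorted(unknown))}")
    if name == "synth" and "docs_per_edge" in values:
        values = dict(values, docs_per_edge=tuple(values["docs_per_edge"]))
    return cls(**values)


def validate_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML experiment config; an empty file yields the
    full defaults. Unknown keys are rejected with the offending name."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path.name}: top level must be a mapping")
    unknown = set(raw) - _TOP_LEVEL
    if unknown:
        raise ValueError(f"{path.name}: unknown key(s): {', '.join(sorted(unknown))}")
    kwargs: dict = {}
    for section in _SECTION_TYPES:
        if section in raw:
            values = raw[section]
            if not isinstance(values, dict):
                raise ValueError(f"{path.name}: section '{section}' must be a mapping")
            key = "repr_cfg" if section == "repr" else section
            try:
                kwargs[key] = _build_section(section, values)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path.name}: {exc}") from exc
    for key in ("manifest", "vocab_mode", "runs", "outdir"):
        if key in raw:
            kwargs[key] = raw[key]
    if "seeds" in raw:
        kwargs["seeds"] = [int(s) for s in raw["seeds"]]
        kwargs.setdefault("runs", len(kwargs["seeds"]))
    elif "runs" in raw:
        kwargs["seeds"] = list(range(int(raw["runs"])))
    try:
        return ExperimentConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path.name}: {exc}") from exc
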