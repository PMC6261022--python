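"""Run configuration: one YAML/JSON-serializable object for the pipeline.

Defaults reproduce the study conditions of the stop-signal protocol the
package models: 300 trials with 75 stops, 2,000 ms ITI, SSD staircase
from 250 ms in 50 ms steps, three 20 s rests, TR 2 s over 502 volumes,
vwGLM burn-in at the 50th volume, FD censoring at 0.5, robust decay
fitting, and 1000-resample balanced LOOCV with a Bonferroni family of 16.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .paradigm import ParadigmConfig, RaceModel
from .synth import CohortSpec

__all__ = ["RunConfig", "load_config", "spawn_stage_seed"]


@dataclass
class VwglmBlock:
    burn_in: int = 50
    fd_threshold: float = 0.5
    engine: str = "direct"  # direct | qr
    ar1_rho: float | None = None
    drift_cutoff_hz: float = 1.0 / 128.0


@dataclass
class DecayBlock:
    robust: bool = True
    anchor: str = "t_start"  # t_start | zero
    k_values: tuple[int, ...] = (1, 2, 3, 4)


@dataclass
class ValidationBlock:
    n_resamples: int = 1000
    k_values: tuple[int, ...] = (1, 2, 3, 4)
    bonferroni_family: int = 16
    residualize_sex: bool = False
    standardize: bool = False


@dataclass
class RunConfig:
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    race: RaceModel = field(default_factory=RaceModel)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    vwglm: VwglmBlock = field(default_factory=VwglmBlock)
    decay: DecayBlock = field(default_factory=DecayBlock)
    validation: ValidationBlock = field(default_factory=ValidationBlock)
    seed: int = 0
    output_dir: str = "ostfmri-out"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(klass, block):
            if block is None:
                return klass()
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(block) - names
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            kwargs = dict(block)
            for f in dataclasses.fields(klass):
                if f.name in kwargs and isinstance(kwargs[f.name], list):
                    default = getattr(klass(), f.name, None)
                    if isinstance(default, tuple):
                        kwargs[f.name] = tuple(kwargs[f.name])
            return klass(**kwargs)

        return cls(
            paradigm=build(ParadigmConfig, data.get("paradigm")),
            race=build(RaceModel, data.get("race")),
            cohort=build(CohortSpec, data.get("cohort")),
            vwglm=build(VwglmBlock, data.get("vwglm")),
            decay=build(DecayBlock, data.get("decay")),
            validation=build(ValidationBlock, data.get("validation")),
            seed=int(data.get("seed", 0)),
            output_dir=data.get("output_dir", "ostfmri-out"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def digest(self) -> str:
        """Stable hash of the configuration (for the run manifest)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    return RunConfig() if path is None else RunConfig.from_yaml(path)


def spawn_stage_seed(seed: int, stage: str, index: int = 0) -> int:
    """Derive a per-stage, per-unit child seed from the global seed.

    Splitting rule: SHA-256 of "seed:stage:index" truncated to 31 bits,
    so adding a subject or stage never perturbs the others' streams.
    """
    digest = hashlib.sha256(f"{seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
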