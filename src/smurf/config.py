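"""Run configuration: nested sections with defaults, strict key checking.

Every knob of the pipeline lives in one of six sections (encoder, align,
mrf, train, eval, simulate); a top-level integer seed is mandatory and is
the single source of randomness for a run.  Unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .smooth_align import AlignParams


@dataclass
class EncoderSection:
    window_half_width: int = 9
    filters: int = 512
    alphabet: str = "protein"


@dataclass
class AlignSection:
    temperature: float = 1.0
    gap_mode: str = "affine"
    align_mode: str = "local"
    gap: float = -3.0
    open: float = -6.0
    extend: float = -2.0
    restrict_turns: bool = True

    def to_params(self) -> AlignParams:
        return AlignParams(temperature=self.temperature, gap=self.gap,
                           open=self.open, extend=self.extend,
                           gap_mode=self.gap_mode, align_mode=self.align_mode,
                           restrict_turns=self.restrict_turns)


@dataclass
class MRFSection:
    mask_rate: float = 0.15
    lam_v: float = 0.01
    lam_w: float = 0.01


@dataclass
class TrainSection:
    basic_steps: int = 300
    basic_learning_rate: float = 0.01
    basic_gap_weight: float = 2.0
    basic_batch_size: Optional[int] = 100
    mrf_steps: int = 100
    mrf_learning_rate: float = 0.02
    mrf_mask_rate: float = 0.35
    mrf_batch_size: Optional[int] = 100
    refit_steps: int = 150
    refit_learning_rate: float = 0.1
    refit_ensemble: int = 3
    cycles: int = 1
    batch_size: Optional[int] = None  # gremlin baseline batching


@dataclass
class EvalSection:
    min_sep: int = 6
    gap_open: float = -11.0
    gap_extend: float = -1.0


@dataclass
class SimulateSection:
    length: int = 30
    n_contacts: int = 20
    strength: Optional[float] = None  # None -> calibrated default
    n_seqs: int = 400
    sweeps: int = 30
    ins_rate: float = 0.05
    del_rate: float = 0.05
    field_scale: Optional[float] = None
    alphabet: str = "protein"


_SECTIONS = {
    "encoder": EncoderSection,
    "align": AlignSection,
    "mrf": MRFSection,
    "train": TrainSection,
    "eval": EvalSection,
    "simulate": SimulateSection,
}


@dataclass
class RunConfig:
    seed: int
    encoder: EncoderSection = field(default_factory=EncoderSection)
    align: AlignSection = field(default_factory=AlignSection)
    mrf: MRFSection = field(default_factory=MRFSection)
    train: TrainSection = field(default_factory=TrainSection)
    eval: EvalSection = field(default_factory=EvalSection)
    simulate: SimulateSection = field(default_factory=SimulateSection)


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    if "seed" not in data:
        raise ValueError("config requires a top-level integer 'seed'")
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    sections = {name: _build(cls, data.get(name, {}) or {}, name)
                for name, cls in _SECTIONS.items()}
    return RunConfig(seed=int(data["seed"]), **sections)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(data)


def dump_config(cfg: RunConfig, path) -> None:
    data = dataclasses.asdict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
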