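"""Run configuration: every tunable threshold and constant of the pipeline.

Defaults follow the published constants of the behaviour definitions where a
value is printed (node radius 1.7 px, minimum 14 node members, step ratio 0.85,
St/m threshold 0.2, MC threshold 0.3, 30 deg inspection angle, a chain gate of
4 steps, 33 fps acquisition); the remaining thresholds are exposed here because
no canonical value exists for them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class CostWeights:
    """Constants of the two identity-resolution cost functions.

    ``a1, a2, a3`` weight the merge-resolution cost
    ``W = a1*N_black + a2*N_white - a3*N_cyprid``; ``w1, w2, w3`` weight the
    split-assignment cost ``Et = w1*Es + w2*Ed + w3*Ep``. All must be > 0.
    """

    a1: float = 1.0
    a2: float = 1.0
    a3: float = 1.0
    w1: float = 1.0
    w2: float = 1.0
    w3: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "a3", "w1", "w2", "w3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cost weight {name} must be strictly positive")


@dataclass
class RunConfig:
    """All pipeline parameters, round-trippable through YAML."""

    # -- imaging ----------------------------------------------------------
    diff_threshold: float = 30.0   # background-update difference gate (intensity)
    bin_threshold: float = 70.0    # segmentation threshold: half the nominal
    #                                blob/background contrast of the renderer
    min_area: int = 5              # discard components below this pixel count
    max_passes: int = 50           # background convergence guard
    invert: bool = False           # set True for bright animals on dark ground
    # -- tracking ---------------------------------------------------------
    weights: CostWeights = field(default_factory=CostWeights)
    miss_patience: int = 10        # frames a lost animal is retained (~0.3 s @33fps)
    ellipse_method: str = "moments"  # "moments" (filled blob) or "lsq" (boundary)
    # -- kinematics -------------------------------------------------------
    dis_th: float = 1.7            # node radius, px
    mn_th: int = 14                # minimum node members
    strict_mn: bool = True         # node emitted when Mn > mn_th (strict) vs >=
    # -- ethology ---------------------------------------------------------
    step_factor: float = 0.85      # expected step length as a fraction of CL
    ratio_threshold: float = 0.2   # St/m gate for walking windows
    mc_threshold: float = 0.3      # maximum-change gate for walking windows
    max_step_duration_s: float = 0.5  # longer inter-node travel is not a step
    angle_threshold_deg: float = 30.0  # inspection body-sweep gate
    chain_steps: float = 4.0       # close-search gate: < chain_steps*step_factor*CL
    inspection_member_cap_s: float = 20.0  # nodes dwelling longer stay inspection
    # -- acquisition ------------------------------------------------------
    frame_rate: float = 33.0       # fps
    seed: int = 0

    def member_cap(self) -> int:
        """Close-search member cap expressed in frames."""
        return int(round(self.inspection_member_cap_s * self.frame_rate))

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "weights" in d and isinstance(d["weights"], dict):
            d["weights"] = CostWeights(**d["weights"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
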