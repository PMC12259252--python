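"""Run configuration: every pipeline parameter with a default, YAML
round-trip, and deterministic per-stage seed derivation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

from .synthetic import FlowFieldSpec, AcquisitionSpec, healthy_flow, injured_flow
from .tracking import SelectionSpec

__all__ = ["LinkingSpec", "RunConfig", "derive_seed"]


@dataclass(frozen=True)
class LinkingSpec:
    """Detection and linking parameters."""

    max_disp: float = 3.0             # μm, frame-to-frame gate
    threshold_sd: float = 5.0         # detection threshold, robust sd units
    psf_sigma_hint: float = 0.5       # μm

    def __post_init__(self) -> None:
        if self.max_disp <= 0:
            raise ValueError("max_disp: must be > 0")


@dataclass
class RunConfig:
    """Full configuration of a simulation-to-report run.

    ``groups`` maps group label -> FlowFieldSpec; the default contrasts a
    coherent ("healthy") with an erratic ("injured") surface. All per-record
    seeds are derived deterministically from ``seed``.
    """

    seed: int = 0
    out_dir: str = "results"
    n_animals_per_group: int = 5
    records_per_animal: int = 2
    use_rendering: bool = False
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    groups: dict = field(default_factory=lambda: {"healthy": healthy_flow(),
                                                  "injured": injured_flow()})
    linking: LinkingSpec = field(default_factory=LinkingSpec)
    selection: SelectionSpec = field(default_factory=SelectionSpec)
    tracks_csv: str | None = None     # skip simulation, analyze these tracks

    def to_dict(self) -> dict:
        d = asdict(self)
        d["acquisition"] = asdict(self.acquisition)
        d["groups"] = {k: asdict(v) for k, v in self.groups.items()}
        d["linking"] = asdict(self.linking)
        d["selection"] = asdict(self.selection)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "acquisition" in d:
            d["acquisition"] = AcquisitionSpec(**d["acquisition"])
        if "groups" in d:
            d["groups"] = {k: FlowFieldSpec(**v)
                           for k, v in d["groups"].items()}
        if "linking" in d:
            d["linking"] = LinkingSpec(**d["linking"])
        if "selection" in d:
            d["selection"] = SelectionSpec(**d["selection"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def derive_seed(master: int, *key: int) -> int:
    """Deterministic child seed (< 2^31) from a master seed and an integer
    key path (group index, animal index, record index, stage index)."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))
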