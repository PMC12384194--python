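"""Run configuration with the study's default analysis settings."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

from .series import EntropyParams, HurstParams

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All tunables of the subject and cohort workflows.

    Defaults are the study settings: discard 5 equilibration volumes,
    band-pass 0.008-0.1 Hz, mask at 10% of peak mean intensity, entropy
    with m = 2, k = 0.25 (r = 0.25 x SD), tau = 1, 95% confidence
    intervals, FDR at q = 0.05, groups coded ASD = 1 / Control = 2.
    """

    n_discard: int = 5
    low_hz: float = 0.008
    high_hz: float = 0.1
    mask_fraction: float = 0.10
    m: int = 2
    k: float = 0.25
    tau: int = 1
    min_windows: int = 4
    conf: float = 0.95
    q: float = 0.05
    group_coding: tuple = (("ASD", 1), ("Control", 2))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_discard < 0:
            raise ValueError("n_discard must be nonnegative")
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("require 0 < low_hz < high_hz")
        if not (0 < self.mask_fraction < 1):
            raise ValueError("mask_fraction must lie in (0, 1)")
        if not (0 < self.conf < 1) or not (0 < self.q < 1):
            raise ValueError("conf and q must lie in (0, 1)")
        # delegate m/k/tau validation
        self.entropy_params()

    def entropy_params(self) -> EntropyParams:
        return EntropyParams(m=self.m, k=self.k, tau=self.tau)

    def hurst_params(self) -> HurstParams:
        return HurstParams(min_windows=self.min_windows)

    def asdict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_coding"] = dict(self.group_coding)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.asdict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config field(s): {sorted(unknown)}")
        if "group_coding" in raw:
            raw["group_coding"] = tuple(sorted(raw["group_coding"].items()))
        return cls(**raw)
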