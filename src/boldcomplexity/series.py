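"""Core value types shared across the complexity estimators.

A single voxel's BOLD signal is modelled as a uniformly sampled real
series; the entropy and Hurst estimators below consume it together with
small parameter bundles.  These types are deliberately thin: validation
happens at construction, and the arrays inside are plain NumPy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UniformTimeSeries",
    "EntropyParams",
    "HurstParams",
    "MetricValue",
]


@dataclass(frozen=True)
class UniformTimeSeries:
    """A regularly sampled scalar signal.

    Parameters
    ----------
    values : array-like
        Ordered real samples ``u(1..N)`` in arbitrary signal units.
    dt : float
        Sampling interval in seconds (the repetition time, 2.0 s for
        study-like BOLD data).
    """

    values: np.ndarray
    dt: float = 2.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must all be finite")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EntropyParams:
    """Parameters of the fuzzy entropy estimators.

    ``m`` is the embedding (template) dimension, ``k`` scales the
    similarity tolerance (``r = k * SD(signal)``), ``tau`` is the time
    delay between embedded samples.  ``membership`` selects the fuzzy
    similarity kernel; only the mirrored-quadratic kernel is supported.
    ``auto_width`` toggles an experimental automatic fuzzy-width
    adjustment; it is not implemented and must stay False.
    """

    m: int = 2
    k: float = 0.25
    tau: int = 1
    membership: str = "mirrored_quadratic"
    auto_width: bool = False

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ValueError(f"m must be a positive integer, got {self.m}")
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if not (isinstance(self.tau, (int, np.integer)) and self.tau >= 1):
            raise ValueError(f"tau must be a positive integer, got {self.tau}")
        if self.membership != "mirrored_quadratic":
            raise ValueError(
                f"unsupported membership function {self.membership!r}; "
                "only 'mirrored_quadratic' is available"
            )

    def require_length(self, n: int) -> None:
        """Raise if a series of length ``n`` is too short for (m, tau)."""
        if n - self.m * self.tau < 2:
            raise ValueError(
                f"series of length {n} too short for m={self.m}, tau={self.tau} "
                f"(need N - m*tau >= 2)"
            )


def _dyadic_scales(n: int, min_windows: int) -> tuple[int, ...]:
    scales = []
    m = 1
    while n // m >= min_windows:
        scales.append(m)
        m *= 2
    return tuple(scales)


@dataclass(frozen=True)
class HurstParams:
    """Configuration of the dispersional-analysis Hurst estimator.

    ``scales`` are the window sizes of the log-log regression; when left
    empty they default to the dyadic set {1, 2, 4, ...} truncated so every
    scale still yields at least ``min_windows`` complete windows.
    """

    min_windows: int = 4
    scales: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.min_windows < 2:
            raise ValueError("min_windows must be >= 2")
        sc = tuple(int(s) for s in self.scales)
        if sc:
            if any(s < 1 for s in sc):
                raise ValueError("every scale must be >= 1")
            if any(b <= a for a, b in zip(sc, sc[1:])):
                raise ValueError("scales must be strictly increasing")
        object.__setattr__(self, "scales", sc)

    def resolve_scales(self, n: int) -> tuple[int, ...]:
        sc = self.scales or _dyadic_scales(n, self.min_windows)
        usable = tuple(s for s in sc if n // s >= self.min_windows)
        return usable


@dataclass(frozen=True)
class MetricValue:
    """A scalar complexity estimate with a degeneracy flag.

    ``degenerate`` marks inputs that forced a defined fallback (for
    example a constant series, whose tolerance r is zero); the value is
    then the documented fallback rather than an estimate.
    """

    value: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not np.isfinite(self.value):
            raise ValueError("non-degenerate MetricValue must be finite")

    def asdict(self) -> dict:
        return dataclasses.asdict(self)
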