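"""Synthetic inputs for every pipeline stage.

Four generators, all pure functions of (spec, seed):

* :func:`gen_fgn` — fractional Gaussian noise with an exact target Hurst
  parameter, via circulant embedding of the fGn autocovariance
  (Davies-Harte), used as the validation oracle for the dispersional
  estimator;
* :func:`gen_mix` — the MIX(p) benchmark from the approximate-entropy
  literature: a period-12 sinusoid whose samples are independently
  replaced by matched-variance uniform noise with probability p, used to
  validate entropy monotonicity in irregularity;
* :func:`gen_phantom` — a small BOLD-like 4-D volume with regions
  carrying prescribed signal generators over near-zero background, plus
  plausible 6-column motion traces;
* :func:`gen_cohort` — a two-group cohort whose within-group means/SDs
  and entropy-PIQ correlations are prescribed, with the three complexity
  summaries mutually correlated at 0.99.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import Volume4D
from .series import UniformTimeSeries
from .stats import ANALYSIS_VARS, CohortTable

__all__ = [
    "gen_fgn",
    "gen_mix",
    "Region",
    "PhantomSpec",
    "gen_phantom",
    "CohortSpec",
    "gen_cohort",
    "TABLE1_DEFAULTS",
]


# ---------------------------------------------------------------------------
# fractional Gaussian noise


def _fgn_autocov(h: float, n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    return 0.5 * (np.abs(k + 1) ** (2 * h) - 2 * np.abs(k) ** (2 * h)
                  + np.abs(k - 1) ** (2 * h))


def gen_fgn(h: float, n: int, seed, dt: float = 2.0) -> UniformTimeSeries:
    """Fractional Gaussian noise with Hurst parameter ``h``, unit variance.

    Circulant embedding of the exact autocovariance (Davies-Harte).  If
    the embedding is not nonnegative-definite (pathological h/n
    combinations) the generator falls back to spectral synthesis from the
    fGn power spectrum with a warning.
    """
    if not (0.0 < h < 1.0):
        raise ValueError(f"h must lie in (0, 1), got {h}")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    gamma = _fgn_autocov(h, n)
    # first row of the 2(n-1)-circulant embedding the Toeplitz covariance
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    if np.min(lam) < -1e-10 * np.max(lam):
        warnings.warn(
            "circulant embedding not nonnegative definite; "
            "falling back to spectral synthesis",
            RuntimeWarning,
            stacklevel=2,
        )
        return _fgn_spectral(h, n, rng, dt)
    lam = np.clip(lam, 0.0, None)
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(lam / (2.0 * m)) * z)
    return UniformTimeSeries(x.real[:n] * np.sqrt(2.0), dt=dt)


def _fgn_spectral(h: float, n: int, rng: np.random.Generator,
                  dt: float) -> UniformTimeSeries:
    """Approximate fGn by shaping white noise with the |f|^(1-2H)-like
    spectrum implied by the autocovariance; used only as a fallback."""
    gamma = _fgn_autocov(h, n)
    # symmetrized autocovariance -> nonneg spectrum via clipping
    spec = np.fft.fft(np.concatenate([gamma, gamma[-2:0:-1]])).real
    spec = np.clip(spec, 0.0, None)
    m = spec.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.ifft(np.sqrt(spec) * np.fft.fft(z)).real[:n]
    sd = x.std(ddof=1)
    return UniformTimeSeries(x / sd if sd > 0 else x, dt=dt)


# ---------------------------------------------------------------------------
# MIX process


def gen_mix(p: float, n: int, seed, dt: float = 2.0,
            period: int = 12) -> UniformTimeSeries:
    """MIX(p): sinusoid with samples replaced by uniform noise w.p. ``p``.

    The deterministic component is sqrt(2)*sin(2*pi*j/period) (unit
    variance over whole periods); the replacement noise is uniform on
    [-sqrt(3), sqrt(3)] (unit variance), so the marginal variance is
    matched for every p.  p = 0 is purely periodic; p = 1 is i.i.d.
    uniform noise.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    j = np.arange(n)
    sine = np.sqrt(2.0) * np.sin(2.0 * np.pi * j / period)
    noise = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=n)
    replace = rng.random(n) < p
    return UniformTimeSeries(np.where(replace, noise, sine), dt=dt)


# ---------------------------------------------------------------------------
# BOLD-like phantom


@dataclass(frozen=True)
class Region:
    """A rectangular block of voxels sharing one signal generator.

    ``slices`` are (start, stop) index pairs per spatial axis;
    ``generator`` is one of 'fgn', 'mix', 'sine', 'white' with its scalar
    ``param`` (H for fgn, p for mix, period in samples for sine, ignored
    for white); ``mean_intensity`` is added to every sample so intensity
    masking can find the region.
    """

    name: str
    slices: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    generator: str = "white"
    param: float = 0.5
    mean_intensity: float = 1000.0
    amplitude: float = 10.0

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = self.slices
        m[x0:x1, y0:y1, z0:z1] = True
        return m


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and contents of a synthetic BOLD acquisition.

    Defaults give a 16x16x8 grid of 250 volumes at TR = 2 s — a reduced
    version of a 64x64x37 whole-brain EPI acquisition — with two regions
    of differing irregularity over near-zero background.
    """

    shape: tuple[int, int, int] = (16, 16, 8)
    tr_seconds: float = 2.0
    n_volumes: int = 250
    regions: tuple[Region, ...] = (
        Region("regular", ((2, 7), (2, 14), (1, 7)), "mix", 0.1),
        Region("irregular", ((9, 14), (2, 14), (1, 7)), "mix", 0.9),
    )
    background_intensity: float = 0.0
    motion_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 50:
            raise ValueError("n_volumes must be >= 50")
        occupancy = np.zeros(self.shape, dtype=int)
        for reg in self.regions:
            occupancy += reg.mask(self.shape)
        if np.any(occupancy > 1):
            raise ValueError("phantom regions overlap")


_GENERATORS = ("fgn", "mix", "sine", "white")


def _region_series(reg: Region, n: int, dt: float, child_seed) -> np.ndarray:
    if reg.generator == "fgn":
        return gen_fgn(reg.param, n, child_seed, dt).values
    if reg.generator == "mix":
        return gen_mix(reg.param, n, child_seed, dt).values
    if reg.generator == "sine":
        rng = np.random.default_rng(child_seed)
        phase = rng.uniform(0, 2 * np.pi)
        return np.sqrt(2.0) * np.sin(2 * np.pi * np.arange(n) / reg.param + phase)
    if reg.generator == "white":
        return np.random.default_rng(child_seed).standard_normal(n)
    raise ValueError(f"unknown generator {reg.generator!r}; choose from {_GENERATORS}")


def gen_phantom(spec: PhantomSpec) -> tuple[Volume4D, np.ndarray, dict]:
    """Materialise a phantom: (volume, motion t x 6, region ground truth).

    Every region voxel gets an independent draw from the region's
    generator, scaled by the region amplitude and offset by its mean
    intensity.  Motion traces are smooth low-amplitude random walks,
    independent of the signal.  Same spec and seed give bit-identical
    output.
    """
    root = np.random.SeedSequence(spec.seed)
    region_seeds = root.spawn(len(spec.regions) + 1)
    n = spec.n_volumes
    data = np.full((*spec.shape, n), float(spec.background_intensity))
    truth = {}
    for reg, rseed in zip(spec.regions, region_seeds[:-1]):
        m = reg.mask(spec.shape)
        truth[reg.name] = m
        voxel_seeds = rseed.spawn(int(m.sum()))
        for (x, y, z), vseed in zip(np.argwhere(m), voxel_seeds):
            s = _region_series(reg, n, spec.tr_seconds, vseed)
            data[x, y, z, :] = reg.mean_intensity + reg.amplitude * s
    rng = np.random.default_rng(region_seeds[-1])
    steps = rng.standard_normal((n, 6)) * spec.motion_amplitude / np.sqrt(n)
    motion = np.cumsum(steps, axis=0)
    vol = Volume4D(data, tr_seconds=spec.tr_seconds)
    return vol, motion, truth


# ---------------------------------------------------------------------------
# cohort generator

# per-group (mean, sd) defaults for a study-scale ASD/Control cohort
TABLE1_DEFAULTS = {
    "ASD": {
        "age": (21.86, 4.11), "fiq": (109.43, 13.09), "viq": (110.43, 12.45),
        "piq": (107.36, 18.88), "hurst": (0.45, 0.03), "fapen": (0.87, 0.03),
        "fsampen": (1.09, 0.07),
    },
    "Control": {
        "age": (23.27, 2.91), "fiq": (114.80, 12.86), "viq": (117.47, 9.86),
        "piq": (109.13, 17.68), "hurst": (0.46, 0.04), "fapen": (0.86, 0.03),
        "fsampen": (1.07, 0.07),
    },
}

_DEFAULT_PIQ_CORR = {
    "ASD": {"fapen": -0.702, "fsampen": -0.676},
    "Control": {"fapen": 0.197, "fsampen": 0.201},
}


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with prescribed moments and correlation targets.

    ``moments[group][var]`` holds (mean, sd) per variable;
    ``piq_corr[group][entropy]`` the target within-group correlation
    between that whole-brain entropy and PIQ; ``complexity_corr`` the
    mutual correlation of the three complexity summaries (they track a
    common latent complexity factor).
    """

    n: dict = field(default_factory=lambda: {"ASD": 14, "Control": 15})
    moments: dict = field(default_factory=lambda: TABLE1_DEFAULTS)
    piq_corr: dict = field(default_factory=lambda: _DEFAULT_PIQ_CORR)
    complexity_corr: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        for g in ("ASD", "Control"):
            if self.n[g] < 4:
                raise ValueError(f"need n >= 4 per group, got {self.n[g]} for {g}")
            for v in ANALYSIS_VARS:
                mu, sd = self.moments[g][v]
                if not sd > 0:
                    raise ValueError(f"SD must be positive for {g}/{v}")
            for ent, r in self.piq_corr[g].items():
                if not abs(r) < 1:
                    raise ValueError(f"|target correlation| must be < 1 ({g}/{ent})")


def _group_correlation(spec: CohortSpec, group: str) -> np.ndarray:
    """7x7 target correlation over ANALYSIS_VARS for one group."""
    idx = {v: i for i, v in enumerate(ANALYSIS_VARS)}
    rmat = np.eye(len(ANALYSIS_VARS))

    def put(a, b, v):
        rmat[idx[a], idx[b]] = rmat[idx[b], idx[a]] = v

    c = spec.complexity_corr
    put("hurst", "fapen", c)
    put("hurst", "fsampen", c)
    put("fapen", "fsampen", c)
    r_fa = spec.piq_corr[group].get("fapen", 0.0)
    r_fs = spec.piq_corr[group].get("fsampen", 0.0)
    put("piq", "fapen", r_fa)
    put("piq", "fsampen", r_fs)
    # H rides the same latent complexity factor, so its PIQ correlation
    # sits between the two entropy targets (keeps the matrix PD)
    put("piq", "hurst", 0.5 * (r_fa + r_fs))
    return rmat


def gen_cohort(spec: CohortSpec | None = None) -> CohortTable:
    """Draw a two-group cohort from per-group multivariate normals.

    Each group is sampled from a 7-variate normal with the prescribed
    means/SDs and the correlation structure of
    :func:`_group_correlation`.  An infeasible (non-positive-definite)
    structure raises naming the offending pair.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group in ("ASD", "Control"):
        rmat = _group_correlation(spec, group)
        try:
            chol = np.linalg.cholesky(rmat)
        except np.linalg.LinAlgError:
            # identify the most negative-eigenvalue-loading pair for the message
            w, v = np.linalg.eigh(rmat)
            load = np.abs(v[:, 0])
            a, b = np.argsort(load)[-2:]
            raise ValueError(
                "infeasible correlation structure (not positive definite); "
                f"check the pair {ANALYSIS_VARS[a]!r}-{ANALYSIS_VARS[b]!r}"
            ) from None
        ng = spec.n[group]
        z = rng.standard_normal((ng, len(ANALYSIS_VARS))) @ chol.T
        for i in range(ng):
            rec = {"id": f"{group.lower()}{i + 1:03d}", "group": group}
            for j, var in enumerate(ANALYSIS_VARS):
                mu, sd = spec.moments[group][var]
                rec[var] = mu + sd * z[i, j]
            rows.append(rec)
    return CohortTable(pd.DataFrame(rows))
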