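"""Fuzzy approximate and fuzzy sample entropy of a uniform time series.

Both estimators compare delay-embedded template vectors under a continuous
(fuzzy) similarity kernel instead of the hard Heaviside threshold of the
classical ApEn/SampEn family.  The kernel used here is a pair of mirrored
quadratic curves: similarity 1 at zero distance, 0.5 at one tolerance
unit, and exactly 0 beyond two tolerance units.  The tolerance is
``r = k * SD(signal)`` so both entropies are invariant under affine maps
``a*u + b`` (a > 0) of the input.

Conventions (fixed by design, see docs/methods.md):

* fApEn embeds baseline-subtracted vectors (each template minus its own
  mean) and *includes* the self-match j = i, so every template's mean
  similarity is strictly positive and the logarithm is safe.
* fSampEn embeds raw vectors, *excludes* the self-match, and uses the
  same template index range i = 1..N-m for both the m- and (m+1)-length
  vectors so numerator and denominator counts agree.
* A constant series (zero tolerance) returns value 0 with the degenerate
  flag set rather than raising, so voxel-wise maps never abort.
"""

from __future__ import annotations

import warnings

import numpy as np

from .series import EntropyParams, MetricValue, UniformTimeSeries

__all__ = [
    "quadratic_membership",
    "tolerance_r",
    "fuzzy_apen",
    "fuzzy_sampen",
]


def quadratic_membership(x):
    """Mirrored-quadratic fuzzy similarity as a function of scaled distance.

    Piecewise: ``(2 - x^2)/2`` on 0 <= x <= 1, ``(2 - x)^2 / 2`` on
    1 < x <= 2, and 0 beyond.  Continuous, non-increasing, exactly 1 at
    x = 0 and exactly 0 for x >= 2.  Accepts scalars or arrays of
    nonnegative scaled distances ``x = distance / r``.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("scaled distance must be nonnegative")
    out = np.zeros_like(arr)
    near = arr <= 1.0
    out[near] = (2.0 - arr[near] ** 2) / 2.0
    mid = (arr > 1.0) & (arr <= 2.0)
    out[mid] = (2.0 - arr[mid]) ** 2 / 2.0
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def tolerance_r(series: UniformTimeSeries, k: float) -> float:
    """Similarity tolerance ``r = k * SD(signal)`` in signal units.

    Uses the sample standard deviation (denominator N-1).  A zero-variance
    series returns 0; callers must treat that as degenerate.
    """
    if not k > 0:
        raise ValueError(f"k must be positive, got {k}")
    u = series.values
    if u.size < 2:
        raise ValueError("tolerance requires at least 2 samples")
    if np.ptp(u) == 0.0:  # exactly constant: avoid fp dust from np.std
        return 0.0
    return float(k * np.std(u, ddof=1))


def _embed(u: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Delay-embed: rows are templates (u(i), u(i+tau), ..., u(i+(m-1)tau))."""
    n_templates = u.size - (m - 1) * tau
    idx = np.arange(n_templates)[:, None] + tau * np.arange(m)[None, :]
    return u[idx]


def _chebyshev_pairs(x: np.ndarray) -> np.ndarray:
    """Pairwise Chebyshev (max-abs) distance between template rows."""
    return np.max(np.abs(x[:, None, :] - x[None, :, :]), axis=2)


def _check_params(series: UniformTimeSeries, params: EntropyParams) -> float:
    if params.auto_width:
        raise NotImplementedError(
            "automatic fuzzy-width adjustment is experimental and not implemented"
        )
    params.require_length(len(series))
    return tolerance_r(series, params.k)


def _phi_apen(u: np.ndarray, m: int, tau: int, r: float) -> float:
    x = _embed(u, m, tau)
    x0 = x - x.mean(axis=1, keepdims=True)
    d = _chebyshev_pairs(x0)
    sim = quadratic_membership(d / r)
    c = sim.mean(axis=1)  # self-match included: c > 0 always
    return float(np.mean(np.log(c)))


def fuzzy_apen(series: UniformTimeSeries, params: EntropyParams) -> MetricValue:
    """Fuzzy approximate entropy fApEn(m, r, N) = Phi^m(r) - Phi^{m+1}(r).

    Templates are baseline-subtracted (each window minus its own mean) and
    compared by Chebyshev distance; per-template mean similarity includes
    the self-match, and Phi is the mean log of those similarities.
    """
    r = _check_params(series, params)
    if r == 0.0:
        return MetricValue(0.0, degenerate=True)
    u = series.values
    phi_m = _phi_apen(u, params.m, params.tau, r)
    phi_m1 = _phi_apen(u, params.m + 1, params.tau, r)
    return MetricValue(phi_m - phi_m1)


def fuzzy_sampen(series: UniformTimeSeries, params: EntropyParams) -> MetricValue:
    """Fuzzy sample entropy fSampEn(m, r, N) = -ln(phi^{m+1} / phi^m).

    Raw (non-baseline-subtracted) templates, self-matches excluded, and
    the template index runs over the same range for both vector lengths.
    If no (m+1)-length pair retains any similarity (phi^{m+1} = 0) the
    estimate is undefined: NaN is returned with the degenerate flag and a
    warning rather than a divide/log error.
    """
    r = _check_params(series, params)
    if r == 0.0:
        return MetricValue(0.0, degenerate=True)
    u = series.values
    m, tau = params.m, params.tau
    n_templates = u.size - m * tau  # common range for both lengths

    def phi(mm: int) -> float:
        x = _embed(u, mm, tau)[:n_templates]
        sim = quadratic_membership(_chebyshev_pairs(x) / r)
        np.fill_diagonal(sim, 0.0)
        per_template = sim.sum(axis=1) / (n_templates - 1)
        return float(per_template.mean())

    phi_m = phi(m)
    phi_m1 = phi(m + 1)
    if phi_m1 <= 0.0 or phi_m <= 0.0:
        warnings.warn(
            "fuzzy_sampen: no template pairs retain similarity at length m+1; "
            "entropy undefined for this series",
            RuntimeWarning,
            stacklevel=2,
        )
        return MetricValue(float("nan"), degenerate=True)
    return MetricValue(-np.log(phi_m1 / phi_m))
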