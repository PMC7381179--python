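"""Morphology features for motor evoked potential (MEP) traces.

The central statistic is approximate entropy (ApEn), a regularity measure
for short, noisy time series.  For an MEP it behaves as a continuous
morphological-abnormality score: a clean biphasic response is highly
regular (low ApEn) while a polyphasic, temporally dispersed response
fluctuates steeply and for a long time (high ApEn).

ApEn(m, r, N) for a series ``u`` of length ``N``:

* template vectors  ``x_i = (u_i, ..., u_{i+m-1})``,
* ``C_i^m(r)`` = fraction of ``j`` (self-match included) with
  ``max_k |u_{i+k} - u_{j+k}| <= r``  (Chebyshev distance),
* ``Phi^m(r) = mean_i ln C_i^m(r)``,
* ``ApEn = Phi^m(r) - Phi^{m+1}(r)``.

The tolerance ``r`` is expressed as a multiple of the series standard
deviation so the statistic is invariant under amplitude scaling.
Each sampled point also carries a per-point contribution
``a_i = ln C_i^m - ln C_i^{m+1}`` whose average approximates the final
value; plotted along the trace it localises *where* the irregularity
lives (steep, long-lasting fluctuations light up).

Auxiliary features: number of phases (noise-gated zero-line crossings),
onset latency, and peak-to-peak amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

__all__ = [
    "ApEnParams",
    "ApEnResult",
    "apen",
    "apen_bruteforce",
    "calibrate_normalization",
    "count_peaks",
    "latency",
    "peak_to_peak",
]

#: Decision threshold on normalised ApEn separating normal from abnormal
#: morphology (configuration default, not a constant of the method).
DEFAULT_APEN_THRESHOLD = 0.545

_SMOOTH_WINDOW = 11  # moving-average window for contribution plots


@dataclass(frozen=True)
class ApEnParams:
    """Parameters of the approximate-entropy computation.

    m
        Embedding (template) dimension; the classic choice is 2.
    r_factor
        Tolerance as a multiple of the series standard deviation.
    c
        Normalisation constant dividing the raw value before clipping to
        [0, 1].  ``"auto"`` calibrates it against Gaussian noise of the
        same length (see :func:`calibrate_normalization`), which makes
        "normalised ApEn close to 1" read as "as irregular as noise".
    """

    m: int = 2
    r_factor: float = 0.2
    c: Union[float, str] = "auto"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if not self.r_factor > 0:
            raise ValueError(f"r_factor must be > 0, got {self.r_factor}")
        if isinstance(self.c, str):
            if self.c != "auto":
                raise ValueError(f"c must be a positive number or 'auto', got {self.c!r}")
        elif not self.c > 0:
            raise ValueError(f"c must be > 0, got {self.c}")


@dataclass(frozen=True)
class ApEnResult:
    """Raw and normalised ApEn plus per-point contributions."""

    raw: float
    normalized: float
    contributions: np.ndarray = field(repr=False)
    smoothed_contributions: np.ndarray = field(repr=False)
    c: float = float("nan")


def _validate_series(series: np.ndarray, m: int) -> np.ndarray:
    u = np.asarray(series, dtype=float).ravel()
    if u.size <= m + 1:
        raise ValueError(
            f"series of length {u.size} is too short for ApEn with m={m}; "
            f"need at least {m + 2} samples"
        )
    return u


def _match_counts(close: np.ndarray, m: int) -> np.ndarray:
    """Template-match counts for dimension m from the pairwise closeness matrix."""
    d = close
    for k in range(1, m):
        d = d[:-1, :-1] & close[k:, k:]
    return d.sum(axis=1)


def _phi_terms(u: np.ndarray, m: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    """ln C_i^m and ln C_i^{m+1} for every template index."""
    n = u.size
    close = np.abs(u[:, None] - u[None, :]) <= r
    counts_m = _match_counts(close, m)
    d = close
    for k in range(1, m):
        d = d[:-1, :-1] & close[k:, k:]
    d = d[:-1, :-1] & close[m:, m:]
    counts_m1 = d.sum(axis=1)
    log_cm = np.log(counts_m / (n - m + 1))
    log_cm1 = np.log(counts_m1 / (n - m))
    return log_cm, log_cm1


def _smooth(a: np.ndarray, window: int = _SMOOTH_WINDOW) -> np.ndarray:
    if a.size == 0:
        return a.copy()
    half = window // 2
    cs = np.concatenate(([0.0], np.cumsum(a)))
    idx = np.arange(a.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, a.size)
    return (cs[hi] - cs[lo]) / (hi - lo)


def _resolve_c(params: ApEnParams, n: int) -> float:
    if params.c == "auto":
        return calibrate_normalization(params, n_ref=n)
    return float(params.c)


def apen(series, params: ApEnParams = ApEnParams()) -> ApEnResult:
    """Approximate entropy of a series, with per-point contributions.

    Self-matches are included in the conditional counts (the original
    definition), which keeps every logarithm finite.  A constant series
    has no fluctuations and returns 0 by convention.

    Raises
    ------
    ValueError
        If the series is shorter than ``m + 2`` samples.
    """
    u = _validate_series(series, params.m)
    n = u.size
    sd = float(np.std(u))
    if sd == 0.0:
        k = n - params.m
        zeros = np.zeros(k)
        return ApEnResult(0.0, 0.0, zeros, zeros.copy(), _resolve_c(params, n))
    r = params.r_factor * sd
    log_cm, log_cm1 = _phi_terms(u, params.m, r)
    raw = float(log_cm.mean() - log_cm1.mean())
    # contributions over the common index range 0 .. N - m - 1
    contrib = log_cm[: n - params.m] - log_cm1
    c = _resolve_c(params, n)
    normalized = float(np.clip(raw / c, 0.0, 1.0))
    return ApEnResult(raw, normalized, contrib, _smooth(contrib), c)


def apen_bruteforce(series, params: ApEnParams = ApEnParams()) -> float:
    """Reference ApEn by direct evaluation of the definition.

    Deliberately written as plain nested loops over template pairs so it
    shares no code path with :func:`apen`; used to verify the vectorised
    implementation.  Guarded to short series because the cost is cubic-ish.
    """
    u = _validate_series(series, params.m)
    n = u.size
    if n > 2000:
        raise ValueError("apen_bruteforce is a reference oracle; use series with N <= 2000")
    sd = float(np.std(u))
    if sd == 0.0:
        return 0.0
    r = params.r_factor * sd

    def phi(m: int) -> float:
        n_templates = n - m + 1
        total = 0.0
        for i in range(n_templates):
            count = 0
            for j in range(n_templates):
                ok = True
                for k in range(m):
                    if abs(u[i + k] - u[j + k]) > r:
                        ok = False
                        break
                if ok:
                    count += 1
            total += math.log(count / n_templates)
        return total / n_templates

    return phi(params.m) - phi(params.m + 1)


_CALIBRATION_SEED = 20200714
_calibration_cache: dict[tuple, float] = {}


def calibrate_normalization(
    params: ApEnParams,
    n_ref: int = 1920,
    n_rep: int = 50,
    seed: int = _CALIBRATION_SEED,
) -> float:
    """Gaussian-noise reference value used to normalise raw ApEn to [0, 1].

    Returns the mean raw ApEn over ``n_rep`` i.i.d. standard-normal series
    of length ``n_ref`` at the given (m, r_factor).  White noise is the
    most irregular signal the statistic will realistically meet, so
    dividing by this constant maps "noise-like" traces near 1 and smooth
    biphasic responses near 0, at any trace length.
    """
    if n_ref < 64:
        raise ValueError(f"n_ref must be >= 64, got {n_ref}")
    if n_rep < 10:
        raise ValueError(f"n_rep must be >= 10, got {n_rep}")
    key = (params.m, params.r_factor, n_ref, n_rep, seed)
    if key in _calibration_cache:
        return _calibration_cache[key]
    rng = np.random.default_rng(seed)
    raw_params = ApEnParams(m=params.m, r_factor=params.r_factor, c=1.0)
    values = [apen(rng.standard_normal(n_ref), raw_params).raw for _ in range(n_rep)]
    c = float(np.mean(values))
    _calibration_cache[key] = c
    return c


def count_peaks(series, noise_floor_factor: float = 4.0, baseline_frac: float = 0.1) -> int:
    """Number of phases: noise-gated crossings of the baseline zero line.

    The series is re-referenced to the median of a pre-onset baseline
    window (the leading ``baseline_frac`` of the samples).  Excursions
    smaller than ``noise_floor_factor`` times the baseline standard
    deviation are ignored (hysteresis), then each entry into a new sign
    state is counted.  A single biphasic deflection therefore counts 2,
    matching the clinical reading of "phases"; a constant series counts 0.
    """
    u = np.asarray(series, dtype=float).ravel()
    if u.size < 3:
        raise ValueError("count_peaks needs at least 3 samples")
    n_base = max(2, int(round(u.size * baseline_frac)))
    baseline = u[:n_base]
    x = u - float(np.median(baseline))
    theta = noise_floor_factor * float(np.std(baseline))
    count = 0
    state = 0
    for v in x:
        if v > theta and state != 1:
            count += 1
            state = 1
        elif v < -theta and state != -1:
            count += 1
            state = -1
    return count


def latency(
    trace,
    onset_k: float = 3.5,
    min_duration: float = 0.5,
    baseline_window: tuple[float, float] = (5.0, 15.0),
) -> Optional[float]:
    """Response onset in ms after the stimulus, or ``None`` when absent.

    The baseline mean and SD are taken from ``baseline_window`` (ms),
    which must lie after the stimulus artifact and before the earliest
    physiologic onset.  The latency is the first time, searched from the
    start of the baseline window onward, where the signal deviates from
    the baseline mean by more than ``onset_k`` baseline SDs continuously
    for at least ``min_duration`` ms.  The threshold scales with the
    baseline SD, so the result is invariant under amplitude scaling.

    ``trace`` may be anything with ``samples`` and ``sampling_rate`` (kHz)
    attributes.
    """
    u = np.asarray(trace.samples, dtype=float).ravel()
    fs = float(trace.sampling_rate)  # kHz == samples per ms
    i0 = int(round(baseline_window[0] * fs))
    i1 = int(round(baseline_window[1] * fs))
    if not 0 <= i0 < i1 <= u.size:
        raise ValueError("baseline window out of range for this trace")
    base = u[i0:i1]
    mu = float(base.mean())
    theta = onset_k * float(base.std())
    dev = np.abs(u - mu) > theta
    dev[:i0] = False
    need = max(1, int(round(min_duration * fs)))
    run = 0
    for i in range(i0, u.size):
        run = run + 1 if dev[i] else 0
        if run >= need:
            return (i - need + 1) / fs
    return None


def peak_to_peak(series) -> float:
    """Peak-to-peak amplitude max(u) - min(u), in the series' units (uV)."""
    u = np.asarray(series, dtype=float).ravel()
    if u.size < 1:
        raise ValueError("peak_to_peak needs at least one sample")
    return float(u.max() - u.min())
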