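"""Coordination and frequency-structure statistics for locomotor rhythms.

Implements the four rhythm read-outs used on ventral-root burst trains and
envelopes:

* per-cycle circular phases between a reference and a target root
  (:func:`pair_phases`), summarised by circular statistics and a Rayleigh
  non-uniformity test (:func:`circular_stats`);
* per-lag Pearson cross-correlograms with a cross-correlation-coefficient
  (CCC) rhythm-strength index (:func:`cross_correlogram_ccc`);
* an autocorrelation rhythmicity index (:func:`autocorr_rhythmicity`);
* kernel-density cycle-frequency mode detection (:func:`frequency_modes`)
  and a two-sample Kolmogorov-Smirnov comparison (:func:`ks_two_sample`).

Phase convention: for each reference cycle ``[onset_k, onset_{k+1})`` the
phase of the first target onset inside the cycle is
``360 * (t_target - onset_k) / period_k`` degrees; 0 deg is synchrony,
180 deg strict alternation.  Reference cycles containing no target onset are
skipped and counted — this tolerates occasional extra bursts on one root.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _sig
from scipy import stats as _stats

from .burst import BurstTrain, FrequencySample
from .trace import Envelope

__all__ = [
    "PhaseSample",
    "Correlogram",
    "TestResult",
    "pair_phases",
    "phases_from_onsets",
    "circular_stats",
    "cross_correlogram_ccc",
    "autocorr_rhythmicity",
    "frequency_modes",
    "ks_two_sample",
]


@dataclass(frozen=True)
class TestResult:
    """A named test statistic with its p-value and sample-size context."""

    name: str
    statistic: float
    pvalue: float
    n: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0 or np.isnan(self.pvalue)):
            raise ValueError(f"p-value out of [0, 1]: {self.pvalue}")


@dataclass(frozen=True)
class PhaseSample:
    """Per-cycle circular phases (degrees in [0, 360)) for an ordered root pair."""

    phases: np.ndarray
    pair: tuple[str, str] = ("ref", "target")
    n_skipped: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.phases, dtype=float).ravel()
        object.__setattr__(self, "phases", p)
        if p.size and (np.any(p < 0) or np.any(p >= 360) or not np.all(np.isfinite(p))):
            raise ValueError("phases must lie in [0, 360)")

    def __len__(self) -> int:
        return self.phases.size


@dataclass(frozen=True)
class Correlogram:
    """Normalized cross-correlogram over symmetric lags."""

    lags: np.ndarray
    coefficients: np.ndarray
    pair: tuple[str, str] = ("a", "b")

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        coef = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "coefficients", coef)
        if lags.shape != coef.shape:
            raise ValueError("lags and coefficients must have equal shape")
        if coef.size and np.nanmax(np.abs(coef)) > 1 + 1e-9:
            raise ValueError("correlation coefficients must lie in [-1, 1]")


def phases_from_onsets(
    ref_onsets: np.ndarray,
    target_onsets: np.ndarray,
    pair: tuple[str, str] = ("ref", "target"),
) -> PhaseSample:
    """Circular phases of target onsets within reference cycles.

    This is the single shared phase engine: burst-train pairs and swim
    flexion trains both route through it.
    """
    ref = np.sort(np.asarray(ref_onsets, dtype=float).ravel())
    tgt = np.sort(np.asarray(target_onsets, dtype=float).ravel())
    if ref.size < 2 or tgt.size < 1:
        return PhaseSample(phases=np.empty(0), pair=pair, n_skipped=0)
    if tgt[-1] < ref[0] or tgt[0] >= ref[-1]:
        warnings.warn(
            f"pair {pair}: reference and target spans are disjoint", stacklevel=2
        )
        return PhaseSample(phases=np.empty(0), pair=pair, n_skipped=ref.size - 1)
    phases = []
    skipped = 0
    # first target onset at or after each reference onset
    first_idx = np.searchsorted(tgt, ref[:-1], side="left")
    for k in range(ref.size - 1):
        period = ref[k + 1] - ref[k]
        i = first_idx[k]
        if i < tgt.size and tgt[i] < ref[k + 1]:
            phi = 360.0 * (tgt[i] - ref[k]) / period
            phases.append(min(phi, np.nextafter(360.0, 0.0)))
        else:
            skipped += 1
    return PhaseSample(phases=np.asarray(phases), pair=pair, n_skipped=skipped)


def pair_phases(reference: BurstTrain, target: BurstTrain) -> PhaseSample:
    """Per-cycle phases of ``target`` burst onsets relative to ``reference``."""
    return phases_from_onsets(
        reference.onsets, target.onsets, pair=(reference.channel, target.channel)
    )


def _rayleigh_p_approx(n: int, R: float) -> float:
    """Series approximation of the Rayleigh test p-value (Zar 1999)."""
    Z = n * R * R
    p = np.exp(-Z) * (
        1.0
        + (2.0 * Z - Z * Z) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n * n)
    )
    return float(min(max(p, 0.0), 1.0))


def _rayleigh_p_simulated(n: int, R: float, n_sim: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, size=(n_sim, n))
    R_null = np.hypot(np.cos(theta).mean(axis=1), np.sin(theta).mean(axis=1))
    return float((np.count_nonzero(R_null >= R) + 1) / (n_sim + 1))


def circular_stats(
    ps: PhaseSample,
    rayleigh_method: str = "approx",
    n_sim: int = 20000,
    seed: int = 0,
) -> dict:
    """Circular mean, resultant length, circular SD and Rayleigh test.

    Returns ``mean_deg`` (in [0, 360), NaN when the resultant is numerically
    zero and ``mean_undefined`` is set), ``R`` in [0, 1],
    ``circ_sd_deg = sqrt(-2 ln R) * 180 / pi`` and a Rayleigh
    :class:`TestResult`.  ``rayleigh_method="simulation"`` replaces the
    large-sample series approximation by a seeded exact-null Monte-Carlo
    estimate, recommended for n < 10.
    """
    if len(ps) < 2:
        raise ValueError("circular statistics require at least 2 phases")
    theta = np.deg2rad(ps.phases)
    C, S = float(np.cos(theta).mean()), float(np.sin(theta).mean())
    R = float(np.hypot(C, S))
    undefined = R < 1e-8
    mean_deg = float("nan") if undefined else float(np.rad2deg(np.arctan2(S, C)) % 360.0)
    circ_sd = float("inf") if R == 0 else float(np.sqrt(-2.0 * np.log(min(R, 1.0))) * 180.0 / np.pi)
    n = len(ps)
    if rayleigh_method == "approx":
        p = _rayleigh_p_approx(n, R)
    elif rayleigh_method == "simulation":
        p = _rayleigh_p_simulated(n, R, n_sim, seed)
    else:
        raise ValueError("rayleigh_method must be 'approx' or 'simulation'")
    return {
        "mean_deg": mean_deg,
        "mean_undefined": bool(undefined),
        "R": R,
        "circ_sd_deg": circ_sd,
        "rayleigh": TestResult(name="rayleigh", statistic=n * R * R, pvalue=p, n={"n": n}),
    }


def _pearson_correlogram(a: np.ndarray, b: np.ndarray, max_lag_samples: int):
    """Per-lag Pearson correlation over the overlapping segment.

    Lag L pairs ``a[i]`` with ``b[i + L]``: a positive peak lag means the
    target channel b is delayed relative to a.  Windowed means and variances
    come from cumulative sums; cross products from one FFT convolution.
    """
    n = a.size
    L = max_lag_samples
    if L >= n:
        raise ValueError("max_lag must be shorter than the signals")
    # dot[k] = sum_i a[i] * b[i + lag],  lag = n - 1 - k
    full = _sig.fftconvolve(a, b[::-1], mode="full")
    lags = np.arange(-L, L + 1)
    dots = full[n - 1 - lags]

    csum_a = np.concatenate(([0.0], np.cumsum(a)))
    csum_a2 = np.concatenate(([0.0], np.cumsum(a * a)))
    csum_b = np.concatenate(([0.0], np.cumsum(b)))
    csum_b2 = np.concatenate(([0.0], np.cumsum(b * b)))

    coefs = np.empty(lags.size)
    for j, lag in enumerate(lags):
        if lag >= 0:
            a0, a1 = 0, n - lag
            b0, b1 = lag, n
        else:
            a0, a1 = -lag, n
            b0, b1 = 0, n + lag
        m = a1 - a0
        sa = csum_a[a1] - csum_a[a0]
        sa2 = csum_a2[a1] - csum_a2[a0]
        sb = csum_b[b1] - csum_b[b0]
        sb2 = csum_b2[b1] - csum_b2[b0]
        cov = dots[j] - sa * sb / m
        var_a = sa2 - sa * sa / m
        var_b = sb2 - sb * sb / m
        denom = np.sqrt(max(var_a, 0.0) * max(var_b, 0.0))
        coefs[j] = cov / denom if denom > 1e-12 * m else 0.0
    return lags, np.clip(coefs, -1.0, 1.0)


def cross_correlogram_ccc(
    a: Envelope,
    b: Envelope,
    max_lag_s: float,
    cycle_period_s: Optional[float] = None,
) -> dict:
    """Cross-correlogram, peak lag and the CCC rhythm-strength index.

    ``peak_lag_s`` is the local maximum of the correlogram nearest lag 0
    (global maximum as fallback).  ``ccc_index`` — the cross-correlation
    coefficient integrated over time — is the signed mean of the correlogram
    over a window of one cycle period centred at lag 0; it is bounded in
    [-1, 1], unit-free and decays toward 0 for arrhythmic signals.  When
    ``cycle_period_s`` is not given it is estimated from the autocorrelation
    of the reference envelope.
    """
    if a.rate != b.rate:
        raise ValueError("envelopes must share a sampling rate")
    if np.var(a.samples) == 0 or np.var(b.samples) == 0:
        raise ValueError("zero-variance input")
    n = min(len(a), len(b))
    x, y = a.samples[:n], b.samples[:n]
    L = int(round(max_lag_s * a.rate))
    if n < 4 * L:
        raise ValueError("overlapping span must be at least 4 * max_lag")
    lags, coefs = _pearson_correlogram(x, y, L)
    corr = Correlogram(lags=lags / a.rate, coefficients=coefs, pair=(a.channel, b.channel))

    # the coordination peak is the positive local maximum nearest lag 0;
    # shallow ripples on the anticorrelated trough of alternating pairs are
    # excluded by the height/prominence floor
    peaks, _ = _sig.find_peaks(coefs, height=0.0, prominence=0.05)
    if peaks.size:
        order = sorted(peaks, key=lambda i: (abs(int(lags[i])), lags[i] < 0))
        peak_idx = int(order[0])
    else:
        peak_idx = int(np.argmax(coefs))
    peak_lag_s = float(lags[peak_idx] / a.rate)

    if cycle_period_s is None:
        try:
            cycle_period_s = autocorr_rhythmicity(a, max_lag_s=max_lag_s)["period_estimate_s"]
        except ValueError:
            cycle_period_s = None
    if cycle_period_s is None or not np.isfinite(cycle_period_s):
        cycle_period_s = max_lag_s  # arrhythmic fallback: average the full window
    half = min(L, max(1, int(round(0.5 * cycle_period_s * a.rate))))
    center = L  # index of lag 0
    ccc_index = float(coefs[center - half : center + half + 1].mean())
    return {
        "corr": corr,
        "ccc_index": ccc_index,
        "peak_lag_s": peak_lag_s,
        "cycle_period_s": float(cycle_period_s),
    }


def autocorr_rhythmicity(
    env: Envelope,
    max_lag_s: Optional[float] = None,
    min_prominence: float = 0.05,
) -> dict:
    """Rhythmicity from the normalized autocorrelogram.

    ``index`` is the height of the first positive-lag local maximum with
    prominence >= ``min_prominence`` (0 when no such peak exists);
    ``period_estimate_s`` its lag; ``rhythmic`` is True when index > 0.2.
    The prominence floor suppresses sample-noise ripples on the
    autocorrelogram of arrhythmic envelopes.
    """
    if np.var(env.samples) == 0:
        raise ValueError("constant envelope has no autocorrelation structure")
    if max_lag_s is None:
        max_lag_s = min(30.0, env.duration / 4.0)
    L = int(round(max_lag_s * env.rate))
    x = env.samples
    lags, coefs = _pearson_correlogram(x, x, L)
    pos = coefs[L:]  # lags 0 .. L
    peaks, _ = _sig.find_peaks(pos, prominence=min_prominence)
    peaks = peaks[peaks > 0]
    if peaks.size == 0:
        return {
            "index": 0.0,
            "period_estimate_s": float("nan"),
            "rhythmic": False,
        }
    first = int(peaks[0])
    return {
        "index": float(pos[first]),
        "period_estimate_s": float(first / env.rate),
        "rhythmic": bool(pos[first] > 0.2),
    }


def frequency_modes(
    fs: FrequencySample,
    bandwidth_hz: Optional[float] = 0.02,
    grid_step_hz: float = 0.001,
    prominence_frac: float = 0.2,
) -> dict:
    """Peak-normalized Gaussian kernel density of cycle frequencies and its modes.

    The density is evaluated on a fixed grid from 0 to beyond the largest
    observed frequency, rescaled so its maximum is 1 (matching frequency
    distribution graphs normalized to peak value).  Modes are local maxima
    with prominence >= ``prominence_frac`` of the peak, sorted ascending.
    ``bandwidth_hz=None`` falls back to Silverman's rule.
    """
    f = fs.frequencies
    if f.size < 5:
        raise ValueError("frequency mode analysis requires at least 5 cycles")
    if bandwidth_hz is None:
        sd = np.std(f, ddof=1)
        iqr = np.subtract(*np.percentile(f, [75, 25]))
        spread = min(sd, iqr / 1.349) if iqr > 0 else sd
        bandwidth_hz = 0.9 * spread * f.size ** (-1 / 5) if spread > 0 else 0.02
    if bandwidth_hz <= 0:
        raise ValueError("bandwidth must be > 0")
    top = float(np.max(f) + 5 * bandwidth_hz)
    grid = np.arange(0.0, top + grid_step_hz, grid_step_hz)
    z = (grid[:, None] - f[None, :]) / bandwidth_hz
    density = np.exp(-0.5 * z * z).mean(axis=1)
    peak = density.max()
    if peak <= 0:
        raise ValueError("degenerate density")
    density = density / peak
    peaks, _ = _sig.find_peaks(density, prominence=prominence_frac)
    # a mode at the very grid edge (all mass in one cell) has no neighbours;
    # fall back to the global maximum when nothing is prominent
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(density))])
    modes = np.sort(grid[peaks])
    return {
        "grid_hz": grid,
        "density": density,
        "modes_hz": modes,
        "bandwidth_hz": float(bandwidth_hz),
    }


def ks_two_sample(a: FrequencySample | Sequence[float], b: FrequencySample | Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test on empirical distributions.

    D is the supremum ECDF distance; the p-value uses the asymptotic
    two-sample KS distribution.
    """
    xa = a.frequencies if isinstance(a, FrequencySample) else np.asarray(a, dtype=float)
    xb = b.frequencies if isinstance(b, FrequencySample) else np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("KS test requires at least 2 observations per sample")
    res = _stats.ks_2samp(xa, xb, method="asymp")
    return TestResult(
        name="ks_2samp",
        statistic=float(res.statistic),
        pvalue=float(min(max(res.pvalue, 0.0), 1.0)),
        n={"n1": int(xa.size), "n2": int(xb.size)},
    )
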