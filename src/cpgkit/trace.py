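"""Single-channel voltage traces and the discharge-envelope preprocessing chain.

A ventral-root recording enters the pipeline as a :class:`Trace` — a uniformly
sampled voltage series with a root label such as ``RL2`` (right L2).  Rhythm
analysis does not operate on the raw multi-unit signal but on its *discharge
envelope*: the trace is (optionally) median-detrended, full-wave rectified,
smoothed with a Hamming-weighted central moving average and decimated to a
modest rate.  Bursting discharges then appear as quasi-periodic waves that a
threshold detector can segment.

The default envelope parameters (200 Hz output rate, 0.25 s smoothing window)
are chosen to preserve bursts of 0.5 s and longer, i.e. locomotor bursts in
the 0.1-0.5 Hz cycle-frequency band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Optional

import numpy as np
from scipy import signal as _sig

__all__ = [
    "Trace",
    "Envelope",
    "EnvelopeConfig",
    "rectify",
    "smooth_wcma",
    "resample_uniform",
    "envelope",
]

#: Recognised ventral-root channel labels (side L/R x lumbar segment L2/L5).
ROOT_CHANNELS = ("RL2", "LL2", "RL5", "LL5")


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled single-channel voltage series.

    Parameters
    ----------
    samples
        Voltage samples, arbitrary units.  Must be finite and of length >= 2.
    rate
        Sampling rate in Hz, > 0.
    channel
        Root label (``RL2``/``LL2``/``RL5``/``LL5``) or ``"unlabeled"``.
    t0
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    rate: float
    channel: str = "unlabeled"
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("trace requires a 1-D sample array of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("trace samples must be finite")
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise ValueError(f"sampling rate must be > 0, got {self.rate!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span covered by the samples in seconds (n / rate)."""
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, ``t0 + i / rate``."""
        return self.t0 + np.arange(self.samples.size) / self.rate


@dataclass(frozen=True)
class EnvelopeConfig:
    """Parameters of the envelope chain.

    ``resample_rate`` is the output rate in Hz; ``smooth_window_s`` the
    Hamming window duration in seconds (converted to the nearest odd sample
    count at the input rate); ``detrend`` subtracts the channel median before
    rectification when ``"median"``; ``baseline_subtract`` additionally
    removes the median of the smoothed envelope and clamps at zero.
    """

    resample_rate: float = 200.0
    smooth_window_s: float = 0.25
    detrend: Optional[str] = "median"
    baseline_subtract: bool = False

    def __post_init__(self) -> None:
        if self.resample_rate <= 0:
            raise ValueError("resample_rate must be > 0")
        if self.smooth_window_s <= 0:
            raise ValueError("smooth_window_s must be > 0")
        if self.detrend not in (None, "median"):
            raise ValueError("detrend must be None or 'median'")


@dataclass(frozen=True)
class Envelope(Trace):
    """A nonnegative discharge envelope with its preprocessing provenance."""

    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.samples < 0):
            raise ValueError("envelope samples must be nonnegative")


def rectify(trace: Trace) -> Trace:
    """Full-wave rectification: sample-wise absolute value."""
    return replace(trace, samples=np.abs(trace.samples))


def _hamming_weights(window_len: int) -> np.ndarray:
    w = _sig.windows.hamming(window_len, sym=True)
    return w / w.sum()


def smooth_wcma(trace: Trace, window_len: int) -> Trace:
    """Weighted central moving average with normalized Hamming weights.

    At the edges the weights are renormalized over the available samples
    (equivalent to dividing by the local window mass), which avoids the
    amplitude droop that zero padding would cause on short traces.

    Parameters
    ----------
    window_len
        Odd window length in samples, ``1 <= window_len <= len(trace)``.
    """
    n = len(trace)
    if not isinstance(window_len, (int, np.integer)):
        raise ValueError("window_len must be an integer sample count")
    if window_len % 2 == 0 or not (1 <= window_len <= n):
        raise ValueError(
            f"window_len must be odd and in [1, {n}], got {window_len}"
        )
    if window_len == 1:
        return replace(trace, samples=trace.samples.copy())
    w = _hamming_weights(int(window_len))
    num = _sig.oaconvolve(trace.samples, w, mode="same")
    den = _sig.oaconvolve(np.ones(n), w, mode="same")
    return replace(trace, samples=num / den)


def resample_uniform(trace: Trace, new_rate: float) -> Trace:
    """Resample to ``new_rate`` over the same time span.

    Uses polyphase FIR resampling (anti-alias filtered when decimating).
    The rate ratio is approximated by a rational fraction with denominator
    <= 10^6, exact for all practically encountered rate pairs.
    """
    if not (np.isfinite(new_rate) and new_rate > 0):
        raise ValueError(f"new_rate must be > 0, got {new_rate!r}")
    if new_rate == trace.rate:
        return replace(trace, samples=trace.samples.copy())
    frac = Fraction(new_rate / trace.rate).limit_denominator(10**6)
    # linear-extension padding keeps constants exactly constant and avoids
    # the edge transients of zero padding
    out = _sig.resample_poly(
        trace.samples, frac.numerator, frac.denominator, padtype="line"
    )
    return replace(trace, samples=out, rate=trace.rate * frac.numerator / frac.denominator)


def envelope(trace: Trace, cfg: EnvelopeConfig | None = None) -> Envelope:
    """Full envelope chain: detrend -> rectify -> smooth -> resample.

    Represents bursting discharges as quasi-periodic wave oscillation events
    suitable for threshold-based burst segmentation.  The returned
    :class:`Envelope` carries a provenance record of every stage.
    """
    cfg = cfg or EnvelopeConfig()
    x = trace
    if cfg.detrend == "median":
        x = replace(x, samples=x.samples - np.median(x.samples))
    x = rectify(x)
    window_len = int(round(cfg.smooth_window_s * x.rate))
    if window_len % 2 == 0:
        window_len += 1
    window_len = max(1, min(window_len, len(x)))
    x = smooth_wcma(x, window_len)
    x = resample_uniform(x, cfg.resample_rate)
    samples = x.samples
    if cfg.baseline_subtract:
        samples = np.clip(samples - np.median(samples), 0.0, None)
    else:
        # Polyphase FIR edges can undershoot zero by a ulp-scale amount.
        samples = np.clip(samples, 0.0, None)
    provenance = {
        "rectified": True,
        "detrend": cfg.detrend,
        "smooth_window_s": cfg.smooth_window_s,
        "smooth_window_samples": window_len,
        "resample_rate_hz": x.rate,
        "baseline_subtract": cfg.baseline_subtract,
        "source_rate_hz": trace.rate,
    }
    return Envelope(
        samples=samples,
        rate=x.rate,
        channel=trace.channel,
        t0=trace.t0,
        provenance=provenance,
    )
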