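import numpy as np
import pytest

from cpgkit import BurstConfig, Envelope, Trace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_envelope(samples, rate=200.0, channel="RL2"):
    return Envelope(samples=np.asarray(samples, dtype=float), rate=rate, channel=channel)


def square_burst_trace(
    n_bursts=20,
    period_s=4.0,
    duty=0.4,
    rate=1000.0,
    amplitude=1.0,
    noise_sd=0.1,
    seed=0,
    lead_s=1.0,
):
    """Noisy square-wave burst trace with known burst edges (ground truth)."""
    rng = np.random.default_rng(seed)
    duration = lead_s * 2 + n_bursts * period_s
    n = int(duration * rate)
    x = np.zeros(n)
    onsets, offsets = [], []
    for k in range(n_bursts):
        on = lead_s + k * period_s
        off = on + duty * period_s
        x[int(on * rate) : int(off * rate)] = amplitude
        onsets.append(on)
        offsets.append(off)
    x = x + noise_sd * rng.standard_normal(n)
    return Trace(samples=x, rate=rate), np.array(onsets), np.array(offsets)


def oracle_detect(x, rate, cfg: BurstConfig):
    """Brute-force sample-by-sample hysteresis state machine.

    Independent of the vectorized detector: explicit state transitions,
    then the same merge-then-duration-filter rule, in plain Python.
    """
    x = np.asarray(x, dtype=float)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0:
        return []
    t_hi = med + cfg.threshold_k * mad
    t_lo = med + cfg.hysteresis * cfg.threshold_k * mad
    events = []
    is_open = False
    onset = None
    for i, v in enumerate(x):
        if not is_open:
            if v > t_hi:
                is_open = True
                onset = i
        else:
            if v < t_lo:
                events.append([onset, i])
                is_open = False
    if is_open:
        events.append([onset, len(x)])
    merged = []
    for on, off in events:
        if merged and (on - merged[-1][1]) < cfg.min_gap_s * rate:
            merged[-1][1] = off
        else:
            merged.append([on, off])
    return [
        (on, off)
        for on, off in merged
        if (off - on) >= cfg.min_duration_s * rate
    ]


def random_bumpy_envelope(rng, n, rate=200.0):
    """A random nonnegative envelope with burst-like structure."""
    raw = rng.standard_normal(n)
    k = int(rng.integers(5, 80)) | 1
    kernel = np.hanning(k)
    smooth = np.convolve(raw, kernel / kernel.sum(), mode="same")
    x = np.clip(smooth, 0, None) * rng.uniform(0.5, 5.0)
    return make_envelope(x, rate=rate, channel="RL2")
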