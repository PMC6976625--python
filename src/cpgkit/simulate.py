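"""Seeded phenomenological generators for every input the analyses consume.

Three generators emulate the statistical structure of the study system
without any biophysical modelling:

* :func:`gen_ventral_roots` — four-channel fictive-locomotion recordings
  (RL2, LL2, RL5, LL5) with left/right and flexor/extensor alternation
  (contralateral and ipsilateral pairs ~180° apart), synchronous diagonal
  pairs (~0°), a fixed or two-state (slow/fast) cycle-period process, and
  optional extra bursts injected preferentially into RL5;
* :func:`gen_positions` — soma position tables drawn from a two-cluster
  (central + medial) Gaussian mixture on the unit (ML, DV) square, with raw
  polar measurements produced by inverting the normalization;
* :func:`gen_swim` — alternating swim flexion/extension trains with
  seeded alternation lapses.

Every generator returns its ground truth (burst times, phase offsets,
regime labels, cluster labels, lapse labels) alongside the data, so each
downstream metric can be checked against what was actually generated.  The
same seed and config always reproduce byte-identical output.

Default simulation rate is 1 kHz with a 50-450 Hz noise carrier; both are
configurable up to full acquisition fidelity (10 kHz, 100 Hz-1.7 kHz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .behavior import SwimBout
from .trace import Trace

__all__ = [
    "VentralRootConfig",
    "PositionFieldConfig",
    "SwimConfig",
    "gen_ventral_roots",
    "gen_positions",
    "gen_swim",
]

#: Ideal inter-root phase offsets in degrees relative to RL2.
DEFAULT_PHASE_OFFSETS = {"RL2": 0.0, "LL2": 180.0, "RL5": 180.0, "LL5": 0.0}


@dataclass(frozen=True)
class VentralRootConfig:
    """Four-root fictive-locomotion simulator settings.

    ``cycle_process`` is ``"fixed"`` (period ``T_s``) or ``"two_state"``
    (Markov switching between ``T_slow_s`` and ``T_fast_s`` with per-cycle
    switch probability ``p_switch``).  Periods are jittered multiplicatively
    with coefficient of variation ``jitter_cv``.  Bursts of duration
    ``duty * period`` are rendered as band-limited noise under a smoothed
    rectangular envelope of amplitude ``burst_amplitude`` over baseline
    noise of SD ``noise_sd``.
    """

    seed: int = 0
    cycle_process: str = "fixed"
    T_s: float = 4.0
    T_slow_s: float = 6.25
    T_fast_s: float = 3.7
    p_switch: float = 0.1
    jitter_cv: float = 0.05
    duty: float = 0.4
    phase_offsets_deg: dict = field(
        default_factory=lambda: dict(DEFAULT_PHASE_OFFSETS)
    )
    burst_amplitude: float = 1.0
    noise_sd: float = 0.1
    carrier_band_hz: tuple[float, float] = (50.0, 450.0)
    rate_hz: float = 1000.0
    duration_s: float = 240.0
    extra_burst_prob: float = 0.05
    extra_burst_channel_weights: dict = field(
        default_factory=lambda: {"RL5": 0.7, "LL5": 0.3}
    )

    def __post_init__(self) -> None:
        if self.cycle_process not in ("fixed", "two_state"):
            raise ValueError("cycle_process must be 'fixed' or 'two_state'")
        for name in ("T_s", "T_slow_s", "T_fast_s", "rate_hz", "duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.p_switch <= 1) or not (0 <= self.extra_burst_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not (0 < self.duty < 1):
            raise ValueError("duty must lie in (0, 1)")
        if self.jitter_cv < 0 or self.noise_sd < 0:
            raise ValueError("jitter_cv and noise_sd must be >= 0")
        for ch, off in self.phase_offsets_deg.items():
            if not (0 <= off < 360):
                raise ValueError(f"phase offset for {ch} must lie in [0, 360)")
        lo, hi = self.carrier_band_hz
        if not (0 < lo < hi < self.rate_hz / 2):
            raise ValueError("carrier band must satisfy 0 < lo < hi < Nyquist")


def _cycle_sequence(cfg: VentralRootConfig, rng: np.random.Generator):
    """Reference onset train: onsets, per-cycle periods and regime labels."""
    t = 2.0  # lead-in so the first burst is fully inside the record
    onsets, periods, regimes = [], [], []
    state = int(rng.integers(0, 2)) if cfg.cycle_process == "two_state" else 0
    while True:
        if cfg.cycle_process == "fixed":
            base = cfg.T_s
            label = "fixed"
        else:
            base = cfg.T_slow_s if state == 0 else cfg.T_fast_s
            label = "slow" if state == 0 else "fast"
        period = base * max(0.2, 1.0 + cfg.jitter_cv * rng.standard_normal())
        if t + period > cfg.duration_s - 1.0:
            break
        onsets.append(t)
        periods.append(period)
        regimes.append(label)
        t += period
        if cfg.cycle_process == "two_state" and rng.random() < cfg.p_switch:
            state = 1 - state
    if len(onsets) < 3:
        raise ValueError("duration too short for 3 cycles at the configured period")
    return np.asarray(onsets), np.asarray(periods), regimes


def _render_channel(
    burst_windows: list[tuple[float, float]],
    cfg: VentralRootConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited noise carrier under smoothed rectangular burst envelopes."""
    n = int(round(cfg.duration_s * cfg.rate_hz))
    envelope = np.zeros(n)
    for on, dur in burst_windows:
        i0 = int(round(on * cfg.rate_hz))
        i1 = min(n, i0 + max(4, int(round(dur * cfg.rate_hz))))
        if i0 >= n:
            continue
        win = _sig.windows.tukey(i1 - i0, alpha=0.25)
        amp = cfg.burst_amplitude * (1.0 + 0.1 * rng.standard_normal())
        envelope[i0:i1] = np.maximum(envelope[i0:i1], max(0.1, amp) * win)
    sos = _sig.butter(
        4, cfg.carrier_band_hz, btype="bandpass", fs=cfg.rate_hz, output="sos"
    )
    carrier = _sig.sosfilt(sos, rng.standard_normal(n))
    carrier /= max(carrier.std(), 1e-12)
    return envelope * carrier + cfg.noise_sd * rng.standard_normal(n)


def gen_ventral_roots(cfg: VentralRootConfig | None = None, seed: Optional[int] = None):
    """Simulate a four-root fictive-locomotion recording.

    Returns ``(traces, ground_truth)``: ``traces`` maps channel label to
    :class:`~cpgkit.trace.Trace`; ``ground_truth`` carries the reference
    onsets, per-cycle periods and regime labels, the per-channel burst onset
    times, the configured phase offsets and every injected extra burst.
    """
    cfg = cfg or VentralRootConfig()
    if seed is not None:
        cfg = VentralRootConfig(**{**asdict(cfg), "seed": seed})
    rng = np.random.default_rng(cfg.seed)
    ref_onsets, periods, regimes = _cycle_sequence(cfg, rng)

    channel_onsets: dict[str, np.ndarray] = {}
    windows: dict[str, list[tuple[float, float]]] = {}
    for ch in ("RL2", "LL2", "RL5", "LL5"):
        off = cfg.phase_offsets_deg.get(ch, 0.0)
        onsets = ref_onsets + off / 360.0 * periods
        channel_onsets[ch] = onsets
        windows[ch] = [
            (float(t), float(cfg.duty * p)) for t, p in zip(onsets, periods)
        ]

    extra: list[tuple[str, float]] = []
    if cfg.extra_burst_prob > 0 and cfg.extra_burst_channel_weights:
        chans = sorted(cfg.extra_burst_channel_weights)
        w = np.array([cfg.extra_burst_channel_weights[c] for c in chans], dtype=float)
        w /= w.sum()
        for k, (t, p) in enumerate(zip(ref_onsets, periods)):
            if rng.random() < cfg.extra_burst_prob:
                ch = chans[int(rng.choice(len(chans), p=w))]
                # drop the extra burst into the middle of the target
                # channel's own inter-burst gap so it never fuses with a
                # locomotor burst
                gap_frac = cfg.duty + rng.uniform(0.2, 0.45) * (1.0 - cfg.duty)
                at = float(channel_onsets[ch][k] + gap_frac * p)
                windows[ch].append((at, float(0.3 * cfg.duty * p)))
                extra.append((ch, at))
    for ch in windows:
        windows[ch].sort()

    traces = {
        ch: Trace(
            samples=_render_channel(windows[ch], cfg, rng),
            rate=cfg.rate_hz,
            channel=ch,
        )
        for ch in ("RL2", "LL2", "RL5", "LL5")
    }
    ground_truth = {
        "ref_onsets_s": ref_onsets,
        "periods_s": periods,
        "regimes": regimes,
        "channel_onsets_s": channel_onsets,
        "phase_offsets_deg": dict(cfg.phase_offsets_deg),
        "extra_bursts": extra,
        "config": asdict(cfg),
    }
    return traces, ground_truth


@dataclass(frozen=True)
class PositionFieldConfig:
    """Two-cluster soma-position generator settings.

    Cluster means/SDs are fractions of the unit (ML, DV) square; the
    defaults (major central cluster, minor medial cluster) are invented
    fixture values of the right ventral-horn geometry, not measurements.
    Section heights and hemicord widths are drawn uniformly from
    ``H_range_um`` / ``W_range_um`` to produce raw polar measurements by
    inverse transform.
    """

    seed: int = 0
    n: int = 300
    weights: tuple[float, float] = (0.75, 0.25)
    means: tuple[tuple[float, float], tuple[float, float]] = ((0.50, 0.35), (0.15, 0.40))
    sds: tuple[float, float] = (0.08, 0.08)
    H_range_um: tuple[float, float] = (380.0, 480.0)
    W_range_um: tuple[float, float] = (250.0, 350.0)
    n_embryos: int = 3
    genotype: str = "control"
    level: str = "lumbar"

    def __post_init__(self) -> None:
        if self.n < 1 or self.n_embryos < 1:
            raise ValueError("n and n_embryos must be >= 1")
        if any(w < 0 for w in self.weights) or abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("cluster weights must be nonnegative and sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ValueError("cluster SDs must be > 0")
        for rng_ in (self.H_range_um, self.W_range_um):
            if not (0 < rng_[0] <= rng_[1]):
                raise ValueError("H/W ranges must be positive and ordered")


def gen_positions(cfg: PositionFieldConfig | None = None, seed: Optional[int] = None):
    """Draw soma positions from a truncated two-cluster Gaussian mixture.

    Returns ``(table, labels)``: a position table with raw polar columns
    (``d_um, alpha_deg, H_um, W_um``) obtained by inverting the DV/ML
    normalization, plus the sampled fractions, and the ground-truth cluster
    label of every cell (0 = central, 1 = medial).
    """
    cfg = cfg or PositionFieldConfig()
    if seed is not None:
        cfg = PositionFieldConfig(**{**asdict(cfg), "seed": seed})
    rng = np.random.default_rng(cfg.seed)
    labels = rng.choice(len(cfg.weights), size=cfg.n, p=np.asarray(cfg.weights))
    ml = np.empty(cfg.n)
    dv = np.empty(cfg.n)
    for i, lab in enumerate(labels):
        mx, my = cfg.means[lab]
        s = cfg.sds[lab]
        while True:  # truncate to the unit square by rejection
            x, y = rng.normal(mx, s), rng.normal(my, s)
            if 0.0 <= x <= 1.0 and 0.0 <= y <= 1.0:
                ml[i], dv[i] = x, y
                break
    H = rng.uniform(*cfg.H_range_um, size=cfg.n)
    W = rng.uniform(*cfg.W_range_um, size=cfg.n)
    # exact inverse of DV = d sin(a)/H, ML = d cos(a)/W
    y_um = dv * H
    x_um = ml * W
    d = np.hypot(x_um, y_um)
    alpha = np.rad2deg(np.arctan2(y_um, x_um))
    table = pd.DataFrame(
        {
            "embryo_id": [f"e{1 + i % cfg.n_embryos}" for i in range(cfg.n)],
            "genotype": cfg.genotype,
            "level": cfg.level,
            "d_um": d,
            "alpha_deg": alpha,
            "H_um": H,
            "W_um": W,
            "ml_frac_true": ml,
            "dv_frac_true": dv,
        }
    )
    return table, labels


@dataclass(frozen=True)
class SwimConfig:
    """Swim-bout generator settings.

    A left-hindlimb flexion train with period ``T_s`` (CV ``jitter_cv``);
    the right hindlimb flexes in antiphase (~180°) except during lapse runs
    entered with per-cycle probability ``lapse_prob`` and lasting
    ``lapse_run_length`` cycles, during which it flexes nearly in phase.
    Extensions fall midway between flexions.
    """

    seed: int = 0
    n_cycles: int = 20
    T_s: float = 0.5
    jitter_cv: float = 0.05
    lapse_prob: float = 0.0
    lapse_run_length: int = 1
    frame_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        if self.n_cycles < 3:
            raise ValueError("need at least 3 cycles")
        if self.T_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("T_s and frame_rate_hz must be > 0")
        if not (0 <= self.lapse_prob <= 1):
            raise ValueError("lapse_prob must lie in [0, 1]")
        if self.jitter_cv < 0 or self.lapse_run_length < 1:
            raise ValueError("jitter_cv >= 0 and lapse_run_length >= 1 required")


def gen_swim(cfg: SwimConfig | None = None, seed: Optional[int] = None):
    """Simulate one swimming bout; returns ``(SwimBout, ground_truth)``.

    ``ground_truth['lapse']`` marks, per left-hindlimb cycle, whether the
    right hindlimb failed to alternate in that cycle — by construction these
    are exactly the cycles whose LH->RH phase falls outside [90°, 270°].
    """
    cfg = cfg or SwimConfig()
    if seed is not None:
        cfg = SwimConfig(**{**asdict(cfg), "seed": seed})
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cycles
    periods = cfg.T_s * np.maximum(0.2, 1.0 + cfg.jitter_cv * rng.standard_normal(n))
    lh_flex = np.concatenate(([0.1], 0.1 + np.cumsum(periods)))

    lapse = np.zeros(n, dtype=bool)
    run = 0
    for k in range(n):
        if run > 0:
            lapse[k] = True
            run -= 1
        elif rng.random() < cfg.lapse_prob:
            lapse[k] = True
            run = cfg.lapse_run_length - 1
    # antiphase fraction ~0.5 (phase ~180 deg); lapse fraction ~0.05 (phase ~18 deg)
    frac = np.where(
        lapse,
        np.clip(rng.normal(0.05, 0.02, size=n), 0.01, 0.15),
        np.clip(rng.normal(0.50, 0.02, size=n), 0.30, 0.70),
    )
    rh_flex = lh_flex[:-1] + frac * periods

    rows = []
    for limb, flex in (("LH", lh_flex), ("RH", rh_flex)):
        ext = 0.5 * (flex[:-1] + flex[1:])
        for kind, times in (("full_flexion", flex), ("full_extension", ext)):
            for t in times:
                # paw image coordinates: a simple cyclic excursion, not used
                # by the metrics but exercised by the I/O round trip
                rows.append(
                    {
                        "limb": limb,
                        "event": kind,
                        "time_s": float(t),
                        "x": float(50 + 10 * np.cos(2 * np.pi * t / cfg.T_s)),
                        "y": float(80 + 10 * np.sin(2 * np.pi * t / cfg.T_s)),
                    }
                )
    events = pd.DataFrame(rows).sort_values(["limb", "time_s"], kind="stable")
    bout = SwimBout(events=events.reset_index(drop=True), frame_rate=cfg.frame_rate_hz)
    ground_truth = {
        "lh_flexions_s": lh_flex,
        "rh_flexions_s": rh_flex,
        "periods_s": periods,
        "lapse": lapse,
        "config": asdict(cfg),
    }
    return bout, ground_truth
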