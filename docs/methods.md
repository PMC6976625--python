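# Methods

This note records what each analysis computes, the assumptions baked into
the defaults, and the choices made where the procedure was genuinely open.

## Envelope extraction

A ventral-root trace is modelled as multi-unit discharge riding on a
roughly symmetric baseline. The chain is: subtract the channel median
(optional, default on) → full-wave rectify → Hamming-weighted central
moving average → polyphase anti-aliased resampling. Edge samples are
renormalized over the available window mass rather than zero-padded, which
avoids amplitude droop at the ends of short traces; polyphase resampling
uses linear-extension padding for the same reason. Envelopes are clamped at
zero (FIR edges can undershoot by rounding error) and carry a provenance
record of every stage.

Defaults: output rate 200 Hz, smoothing window 0.25 s. The window is about
1/15 of the slowest expected locomotor cycle (~6 s) and preserves bursts of
0.5 s and longer; there is no authoritative value for either parameter, so
they are declared here, not inferred. Hardware acquisition bandpass
filtering is not re-applied digitally: simulated and archived traces are
already band-limited, and only the optional median detrend precedes
rectification.

## Burst detection

The detector thresholds the envelope at median + k·MAD (default k = 3) and
closes at a hysteresis fraction (default 0.5) of that excursion. Robust
location/spread statistics make the threshold insensitive to slow baseline
drift and — because both scale linearly — the detector is exactly invariant
to uniform amplitude scaling. Events separated by gaps shorter than 0.3 s
are merged *before* events shorter than 0.2 s are dropped: a burst split by
a brief dip should be re-joined before the duration filter judges it,
otherwise valid fragments get deleted. A constant envelope (MAD = 0) yields
an empty train with an explanatory flag rather than an error.

Cycle period is onset-to-onset, the common fictive-locomotion convention;
it makes the phase definition below unambiguous. All supra-threshold events
are retained; events opening a cycle shorter than half the median period
can be flagged as probable extra (non-locomotor) bursts, but are never
silently discarded. The analysis interval is the caller's choice (long
acquisitions are usually restricted to the final rhythm-stabilized stretch);
no automatic selection is attempted.

## Phases and circular statistics

For each reference cycle [onset_k, onset_{k+1}) the phase of the first
target onset in the cycle is 360°·(t − onset_k)/T_k; cycles without a
target onset are skipped and counted, which tolerates occasional extra
bursts and dropouts. Phases are onset-anchored by default (correlogram
peak lags are also reported, so peak-based phase reading is available).

The circular summary is the standard one: mean direction from
atan2(mean sin, mean cos), resultant length R, circular SD √(−2 ln R).
The Rayleigh p-value uses the classical series approximation in n·R²; a
seeded Monte-Carlo null (R under uniformity) is available for very small n,
where the series is least trustworthy. A resultant below 1e−8 flags the
mean as undefined instead of reporting an arbitrary angle.

## Correlograms, CCC and rhythmicity

Correlograms are per-lag Pearson coefficients over the overlapping segment
(windowed means and variances from cumulative sums, cross products from one
FFT convolution), so corr(0) of a signal with itself is exactly 1 and every
coefficient is bounded in [−1, 1] regardless of lag. Positive lag means
the target channel is delayed relative to the reference.

"CCC integrated over time" is defined as the signed mean of the correlogram
over one mean cycle period centred at lag 0 — bounded, unit-free, and
decaying toward 0 for arrhythmic signals. When no period is supplied it is
estimated from the reference autocorrelation. Note that for an ideal
antiphase pair this index is near 0 by symmetry (the correlogram averages
out over a full cycle); it measures rhythm strength, not phase.

The coordination peak lag is the positive local maximum nearest lag 0
(height > 0, prominence ≥ 0.05): for alternating pairs the shallow ripple
on the anticorrelated trough at lag 0 must not be mistaken for a peak.

The rhythmicity index is the height of the first positive-lag
autocorrelogram local maximum with prominence ≥ 0.05 (0 if none exists —
the floor suppresses the O(1/√N) noise ripple of arrhythmic envelopes);
the rhythm period estimate is its lag, and "rhythmic" means index > 0.2.

## Frequency modes and distribution comparison

Instantaneous cycle frequencies (1/period) are pooled and smoothed with a
fixed-bandwidth Gaussian kernel (default 0.02 Hz, Silverman fallback) on a
1 mHz grid, rescaled to peak 1 to match the conventional peak-normalized
frequency-distribution graphs. Modes are local maxima with prominence at
least 0.2 of the peak, ascending. The estimator is invariant to sample
order and duplication. Distributions are compared with the two-sample
Kolmogorov–Smirnov test (exact sup-ECDF distance, asymptotic p-value).

## Soma positions

DV = d·sin α / H and ML = d·cos α / W exactly, reported ×100 as percent of
cord height and hemicord width. Analysis operates on one hemicord
(left-side cells are mirrored); values slightly outside [0, 1] from
measurement noise are clamped with a warning, not dropped. Density maps use
a separable Gaussian product kernel (default bandwidth 0.05 fraction units,
50×50 grid) with reflection boundary correction — mirroring each point at 0
and 1 — because plain truncation biases border cells low by the lost kernel
mass (≈ 31 % at an edge) no matter how many cells are sampled; maps are
renormalized to integrate to exactly 1 over the unit square.

Hotelling's T² follows the textbook two-sample form with pooled covariance
and the F(2, n₁+n₂−3) reference distribution. Cells from all sections of a
group are pooled by default; a per-embryo mode (testing embryo mean
positions) is available since the appropriate experimental unit is
debatable. A singular pooled covariance raises with advice rather than
returning a misleading p.

## Behavior

Swim cycles are flexion-to-flexion by default (extension-to-extension is a
flag — which convention the field uses varies). A cycle is a missed
alternation when the LH→RH phase leaves the symmetric half-cycle window
[90°, 270°]; the window is a declared operationalization of "failure to
alternate". The miss ratio divides the missed count by the mean cycle
period (units 1/s), so faster swimmers are not mechanically favoured. The
phase machinery is literally the same function used for root pairs.

The vestibulospinal measurement rotates the end-frame paw position 90° CCW
about the image centre ((x, y) → (−y, x) in centred coordinates), applies
the operator's manual overlay translation, and reports the Euclidean
distance to the start-frame paw. A measurement taken at the 200 ms fallback
frame (no extension elicited) carries a flag.

## Synthetic data

The generators are phenomenological — no conductance-based CPG model. A
reference onset train comes from a fixed-period or two-state Markov process
(defaults: T = 4 s fixed; slow/fast 6.25 s / 3.7 s with switch probability
0.1 per cycle; multiplicative period jitter CV 0.05, a post-stabilization
rhythm). Each root's onsets are the reference shifted by its phase offset
(LL2 and RL5 at 180°, LL5 at 0° — the ideal locomotor pattern). Bursts of
duration duty·T (duty 0.4) are rendered as 50–450 Hz band-limited noise
under a Tukey envelope (amplitude 1, ±10 % per-burst variation) over
baseline noise sd 0.1 (SNR 10), at 1 kHz. Extra bursts are injected with
probability 0.05 per cycle into the extensor roots (RL5 : LL5 weighted
0.7 : 0.3), placed inside the target root's own silent gap. Everything is
reproducible from the seed, and the returned ground truth (onsets, periods,
regimes, extra-burst times, lapse labels, cluster labels) suffices to
compute every downstream metric without re-detection.

Position tables draw (ML, DV) from a two-component Gaussian mixture —
central (0.50, 0.35) weight 0.75, medial (0.15, 0.40) weight 0.25, SD 0.08,
rejection-truncated to the unit square; these are invented fixture values
with the right qualitative geometry, not measurements. Raw (d, α, H, W) are
produced by exactly inverting the normalization for uniformly drawn section
sizes, so normalization round-trips to machine precision.

Swim bouts place RH flexions at ~0.5 of each LH cycle (phase ≈ 180°) and at
~0.05 during lapse runs (phase ≈ 18°), entered with a per-cycle probability
and lasting a configurable run length; extensions fall midway between
flexions. By construction the generator's lapse labels coincide exactly
with cycles scored as missed alternations.

What the generators do *not* emulate: slow amplitude drift and electrode
artefacts, within-burst unit structure, deleting/duplicated video events,
section-to-section anatomical covariates. Passing tests therefore certify
the estimators under clean quasi-periodic statistics, not robustness to
every recording pathology.

## Problem sizes and numerical choices

Simulated recordings in the tests run 60 cycles (240 s) for phase recovery
and 600 s for frequency-mode recovery, at the 1 kHz simulator rate —
enough cycles that circular means settle well inside the ±10–15° bands and
mode positions within ±0.015 Hz. Calibration checks use 2000 null
replicates (Hotelling type-I error) and 200 seeded bouts (lapse-count
binomial coverage). Reports serialize with sorted keys and repr-exact
floats, so identical seed + config reproduce identical bytes.

## Known limitations

* The hysteresis detector assumes a unimodal baseline; strongly bimodal
  baselines (e.g. long tonic episodes) shift the median and MAD.
* The CCC definition is one of several in circulation; values are
  comparable within this package, not across packages.
* The asymptotic KS p-value is conservative for heavily tied samples.
* Fixed-bandwidth KDE mode counts are bandwidth-dependent; the 0.02 Hz
  default resolves modes ≥ ~0.05 Hz apart at realistic cycle counts.
* Density maps assume the unit-square normalization is adequate; no
  section-shape registration beyond H/W scaling is attempted.
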