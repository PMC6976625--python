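"""Model/Results front-ends tying the analysis stages into three studies.

Each class follows the fit-then-inspect pattern: a model is built from data,
``fit()`` runs the full analysis chain and returns a results object carrying
the estimates, their test statistics and a ``summary()`` table, plus a
``to_report()`` dict suitable for deterministic JSON export.

* :class:`FictiveLocomotionAnalysis` — envelopes, burst trains and timing
  metrics per ventral root; circular phase statistics and cross-correlogram
  CCC for the six root pairs; autocorrelation rhythmicity and
  cycle-frequency modes per root and pooled.
* :class:`SomaDistribution` — normalized (ML, DV) coordinates, per-group
  density maps and marginals, and a two-sample Hotelling's T² per axial
  level.
* :class:`SwimAnalysis` — per-bout swim metrics and a rank-based group
  comparison of mean cycle period and miss ratio.
"""

from __future__ import annotations

import itertools
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import __version__ as _pkg_version
from .burst import BurstConfig, BurstTrain, FrequencySample, burst_metrics, detect_bursts
from .rhythm import (
    TestResult,
    autocorr_rhythmicity,
    circular_stats,
    cross_correlogram_ccc,
    frequency_modes,
    ks_two_sample,
    pair_phases,
)
from .spatial import density_maps, hotelling_t2, normalize_positions
from .behavior import SwimBout, swim_metrics
from .trace import Envelope, EnvelopeConfig, Trace, envelope

__all__ = [
    "FictiveLocomotionAnalysis",
    "FictiveLocomotionResults",
    "SomaDistribution",
    "SomaDistributionResults",
    "SwimAnalysis",
    "SwimAnalysisResults",
    "compare_frequency_distributions",
]

#: The six analyzed root pairs (reference, target): left/right alternating,
#: ipsilateral flexor/extensor alternating, diagonal synchronous.
ROOT_PAIRS = (
    ("RL2", "LL2"),
    ("RL5", "LL5"),
    ("LL2", "LL5"),
    ("RL2", "RL5"),
    ("RL2", "LL5"),
    ("LL2", "RL5"),
)


class FictiveLocomotionAnalysis:
    """Fictive-locomotion rhythm analysis of one multi-root recording.

    Parameters
    ----------
    traces
        Mapping of channel label (RL2/LL2/RL5/LL5, any subset) to Trace.
    env_cfg, burst_cfg
        Preprocessing and detector settings (defaults as documented there).
    max_lag_s
        Correlogram half-width in seconds.
    analysis_window_s
        Optional (start, stop) interval in seconds; by default the full
        record is analyzed (callers mirroring a long acquisition typically
        pass the final, rhythm-stabilized stretch).
    """

    def __init__(
        self,
        traces: dict[str, Trace],
        env_cfg: EnvelopeConfig | None = None,
        burst_cfg: BurstConfig | None = None,
        max_lag_s: float = 10.0,
        analysis_window_s: Optional[tuple[float, float]] = None,
    ) -> None:
        known = {"RL2", "LL2", "RL5", "LL5"}
        bad = set(traces) - known
        if bad:
            raise ValueError(
                f"unmappable channels {sorted(bad)}; expected labels from {sorted(known)}"
            )
        if not traces:
            raise ValueError("at least one channel is required")
        self.traces = dict(traces)
        self.env_cfg = env_cfg or EnvelopeConfig()
        self.burst_cfg = burst_cfg or BurstConfig()
        self.max_lag_s = max_lag_s
        self.analysis_window_s = analysis_window_s

    def _windowed(self, tr: Trace) -> Trace:
        if self.analysis_window_s is None:
            return tr
        a, b = self.analysis_window_s
        i0 = max(0, int(round((a - tr.t0) * tr.rate)))
        i1 = min(len(tr), int(round((b - tr.t0) * tr.rate)))
        if i1 - i0 < 2:
            raise ValueError("analysis window leaves fewer than 2 samples")
        return Trace(
            samples=tr.samples[i0:i1], rate=tr.rate, channel=tr.channel,
            t0=tr.t0 + i0 / tr.rate,
        )

    def fit(self) -> "FictiveLocomotionResults":
        envelopes: dict[str, Envelope] = {}
        trains: dict[str, BurstTrain] = {}
        channel_stats: dict[str, dict] = {}
        warnings_log: list[str] = []
        for ch, tr in self.traces.items():
            env = envelope(self._windowed(tr), self.env_cfg)
            train = detect_bursts(env, self.burst_cfg)
            envelopes[ch] = env
            trains[ch] = train
            if train.empty_reason:
                warnings_log.append(f"{ch}: {train.empty_reason}")
            metrics = burst_metrics(train)
            stats: dict = {
                "n_bursts": len(train),
                "threshold": train.threshold,
                "mean_cycle_period_s": float(np.mean(metrics["cycle_periods"]))
                if metrics["cycle_periods"].size
                else float("nan"),
                "mean_burst_duration_s": float(np.mean(metrics["burst_durations"]))
                if metrics["burst_durations"].size
                else float("nan"),
                "frequencies": metrics["frequencies"],
            }
            try:
                stats["rhythmicity"] = autocorr_rhythmicity(env)
            except ValueError as exc:
                stats["rhythmicity"] = None
                warnings_log.append(f"{ch}: rhythmicity skipped ({exc})")
            if len(metrics["frequencies"]) >= 5:
                stats["modes"] = frequency_modes(metrics["frequencies"])
            else:
                stats["modes"] = None
                warnings_log.append(f"{ch}: too few cycles for frequency modes")
            channel_stats[ch] = stats

        pair_stats: dict[tuple[str, str], dict] = {}
        for ref, tgt in ROOT_PAIRS:
            if ref not in trains or tgt not in trains:
                continue
            entry: dict = {}
            ps = pair_phases(trains[ref], trains[tgt])
            entry["n_phases"] = len(ps)
            entry["n_skipped"] = ps.n_skipped
            if len(ps) >= 2:
                entry.update(circular_stats(ps))
                entry["phases"] = ps
            else:
                warnings_log.append(f"{ref}/{tgt}: too few matched cycles for phases")
            try:
                cc = cross_correlogram_ccc(
                    envelopes[ref], envelopes[tgt], max_lag_s=self.max_lag_s
                )
                entry["ccc_index"] = cc["ccc_index"]
                entry["peak_lag_s"] = cc["peak_lag_s"]
                entry["correlogram"] = cc["corr"]
            except ValueError as exc:
                warnings_log.append(f"{ref}/{tgt}: correlogram skipped ({exc})")
            pair_stats[(ref, tgt)] = entry

        pooled = FrequencySample(
            frequencies=np.concatenate(
                [channel_stats[ch]["frequencies"].frequencies for ch in sorted(trains)]
            )
            if trains
            else np.empty(0),
            channel="pooled",
            pooled=True,
        )
        pooled_modes = (
            frequency_modes(pooled) if len(pooled) >= 5 else None
        )
        return FictiveLocomotionResults(
            model=self,
            envelopes=envelopes,
            trains=trains,
            channel_stats=channel_stats,
            pair_stats=pair_stats,
            pooled_frequencies=pooled,
            pooled_modes=pooled_modes,
            warnings=warnings_log,
        )


class FictiveLocomotionResults:
    """Fitted fictive-locomotion analysis of one preparation."""

    def __init__(
        self, model, envelopes, trains, channel_stats, pair_stats,
        pooled_frequencies, pooled_modes, warnings,
    ) -> None:
        self.model = model
        self.envelopes = envelopes
        self.trains = trains
        self.channel_stats = channel_stats
        self.pair_stats = pair_stats
        self.pooled_frequencies = pooled_frequencies
        self.pooled_modes = pooled_modes
        self.warnings = warnings

    def pair_table(self) -> pd.DataFrame:
        """One row per root pair: n, mean phase, R, circular SD, Rayleigh p, CCC."""
        rows = []
        for (ref, tgt), e in self.pair_stats.items():
            rows.append(
                {
                    "pair": f"{ref}/{tgt}",
                    "n": e.get("n_phases", 0),
                    "n_skipped": e.get("n_skipped", 0),
                    "mean_deg": e.get("mean_deg", float("nan")),
                    "R": e.get("R", float("nan")),
                    "circ_sd_deg": e.get("circ_sd_deg", float("nan")),
                    "rayleigh_p": e["rayleigh"].pvalue if "rayleigh" in e else float("nan"),
                    "ccc_index": e.get("ccc_index", float("nan")),
                    "peak_lag_s": e.get("peak_lag_s", float("nan")),
                }
            )
        return pd.DataFrame(rows)

    def channel_table(self) -> pd.DataFrame:
        rows = []
        for ch, s in self.channel_stats.items():
            rhythm = s.get("rhythmicity") or {}
            modes = s.get("modes")
            rows.append(
                {
                    "channel": ch,
                    "n_bursts": s["n_bursts"],
                    "mean_cycle_period_s": s["mean_cycle_period_s"],
                    "mean_burst_duration_s": s["mean_burst_duration_s"],
                    "rhythmicity_index": rhythm.get("index", float("nan")),
                    "rhythm_period_s": rhythm.get("period_estimate_s", float("nan")),
                    "modes_hz": list(modes["modes_hz"]) if modes else [],
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Fictive locomotion analysis", "=" * 27]
        lines.append(self.channel_table().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        lines.append("")
        lines.append(self.pair_table().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        if self.pooled_modes is not None:
            modes = ", ".join(f"{m:.3f}" for m in self.pooled_modes["modes_hz"])
            lines.append(f"\npooled frequency modes [Hz]: {modes}"
                         f"  (n = {len(self.pooled_frequencies)} cycles)")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def to_report(self) -> dict:
        channels = {}
        for ch, s in self.channel_stats.items():
            modes = s.get("modes")
            channels[ch] = {
                "n_bursts": s["n_bursts"],
                "threshold": s["threshold"],
                "mean_cycle_period_s": s["mean_cycle_period_s"],
                "mean_burst_duration_s": s["mean_burst_duration_s"],
                "rhythmicity": s.get("rhythmicity"),
                "modes_hz": list(map(float, modes["modes_hz"])) if modes else None,
                "frequencies_hz": s["frequencies"].frequencies,
            }
        pairs = {}
        for (ref, tgt), e in self.pair_stats.items():
            pairs[f"{ref}/{tgt}"] = {
                "n": e.get("n_phases", 0),
                "n_skipped": e.get("n_skipped", 0),
                "mean_deg": e.get("mean_deg"),
                "R": e.get("R"),
                "circ_sd_deg": e.get("circ_sd_deg"),
                "rayleigh_p": e["rayleigh"].pvalue if "rayleigh" in e else None,
                "ccc_index": e.get("ccc_index"),
                "peak_lag_s": e.get("peak_lag_s"),
            }
        return {
            "schema": "cpgkit/fl-report/1",
            "version": _pkg_version,
            "channels": channels,
            "pairs": pairs,
            "pooled_modes_hz": list(map(float, self.pooled_modes["modes_hz"]))
            if self.pooled_modes
            else None,
            "pooled_n": len(self.pooled_frequencies),
            "warnings": list(self.warnings),
        }


def compare_frequency_distributions(
    a: FictiveLocomotionResults, b: FictiveLocomotionResults
) -> TestResult:
    """Two-sample KS test between the pooled cycle-frequency samples of two fits."""
    return ks_two_sample(a.pooled_frequencies, b.pooled_frequencies)


class SomaDistribution:
    """Spatial-distribution analysis of soma positions, compared between groups.

    Built from a position table (raw polar columns or precomputed
    percentages; see :func:`cpgkit.spatial.normalize_positions`).  Sections
    from multiple embryos are pooled per group by default;
    ``per_embryo=True`` collapses each embryo to its mean position and
    tests embryo means instead.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        group_col: str = "genotype",
        level_col: str = "level",
        grid_size: int = 50,
        bandwidth: float = 0.05,
        per_embryo: bool = False,
    ) -> None:
        self.table = normalize_positions(table)
        self.group_col = group_col
        self.level_col = level_col
        self.grid_size = grid_size
        self.bandwidth = bandwidth
        self.per_embryo = per_embryo

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "SomaDistribution":
        return cls(table, **kwargs)

    def _points(self, df: pd.DataFrame) -> np.ndarray:
        if self.per_embryo:
            g = df.groupby("embryo_id")[["ml_frac", "dv_frac"]].mean()
            return g.to_numpy(dtype=float)
        return df[["ml_frac", "dv_frac"]].to_numpy(dtype=float)

    def fit(self) -> "SomaDistributionResults":
        levels: dict[str, dict] = {}
        warnings_log: list[str] = []
        for level, df_level in self.table.groupby(self.level_col, sort=True):
            entry: dict = {"groups": {}, "hotelling": None}
            groups = sorted(df_level[self.group_col].unique())
            for grp in groups:
                df_grp = df_level[df_level[self.group_col] == grp]
                entry["groups"][grp] = {
                    "n_cells": int(len(df_grp)),
                    "density": density_maps(
                        df_grp, grid_size=self.grid_size, bandwidth=self.bandwidth
                    ),
                    "mean_ml_pct": float(df_grp["ml_pct"].mean()),
                    "mean_dv_pct": float(df_grp["dv_pct"].mean()),
                }
            if len(groups) >= 2:
                a, b = groups[:2]
                pa = self._points(df_level[df_level[self.group_col] == a])
                pb = self._points(df_level[df_level[self.group_col] == b])
                try:
                    entry["hotelling"] = hotelling_t2(pa, pb)
                    entry["compared"] = (a, b)
                except ValueError as exc:
                    warnings_log.append(f"{level}: Hotelling skipped ({exc})")
            else:
                warnings_log.append(
                    f"{level}: single group '{groups[0]}', test skipped"
                )
            levels[str(level)] = entry
        return SomaDistributionResults(model=self, levels=levels, warnings=warnings_log)


class SomaDistributionResults:
    def __init__(self, model, levels, warnings) -> None:
        self.model = model
        self.levels = levels
        self.warnings = warnings

    def test_table(self) -> pd.DataFrame:
        rows = []
        for level, e in self.levels.items():
            ht: Optional[TestResult] = e["hotelling"]
            rows.append(
                {
                    "level": level,
                    "groups": "/".join(e.get("compared", ())) or None,
                    "T2": ht.statistic if ht else float("nan"),
                    "p": ht.pvalue if ht else float("nan"),
                    "n": sum(g["n_cells"] for g in e["groups"].values()),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Soma distribution analysis", "=" * 26]
        lines.append(self.test_table().to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def to_report(self) -> dict:
        levels = {}
        for level, e in self.levels.items():
            ht = e["hotelling"]
            levels[level] = {
                "groups": {
                    g: {
                        "n_cells": v["n_cells"],
                        "mean_ml_pct": v["mean_ml_pct"],
                        "mean_dv_pct": v["mean_dv_pct"],
                    }
                    for g, v in e["groups"].items()
                },
                "hotelling": {
                    "T2": ht.statistic,
                    "p": ht.pvalue,
                    "n": ht.n,
                }
                if ht
                else None,
            }
        return {
            "schema": "cpgkit/positions-report/1",
            "version": _pkg_version,
            "levels": levels,
            "warnings": list(self.warnings),
        }


class SwimAnalysis:
    """Swim-bout metrics per animal with a rank-based group comparison."""

    def __init__(self, bouts: dict[str, Sequence[SwimBout]]) -> None:
        if not bouts:
            raise ValueError("at least one group of bouts is required")
        self.bouts = {g: list(v) for g, v in bouts.items()}

    def fit(self) -> "SwimAnalysisResults":
        per_bout: dict[str, list[dict]] = {}
        warnings_log: list[str] = []
        for grp, bouts in self.bouts.items():
            per_bout[grp] = []
            for bout in bouts:
                try:
                    m = swim_metrics(bout)
                except ValueError as exc:
                    warnings_log.append(f"{grp}/{bout.bout_id}: skipped ({exc})")
                    continue
                per_bout[grp].append(
                    {
                        "bout_id": bout.bout_id,
                        "mean_cycle_period_s": float(
                            np.mean(list(m["mean_cycle_period_s"].values()))
                        ),
                        "missed_alternations": m["missed_alternations"],
                        "miss_ratio_per_s": m["miss_ratio_per_s"],
                        "n_cycles": m["n_cycles"],
                    }
                )
        comparisons: dict[str, TestResult] = {}
        groups = sorted(per_bout)
        if len(groups) >= 2:
            a, b = groups[:2]
            for metric in ("mean_cycle_period_s", "miss_ratio_per_s"):
                xa = [r[metric] for r in per_bout[a]]
                xb = [r[metric] for r in per_bout[b]]
                if len(xa) >= 2 and len(xb) >= 2:
                    res = _stats.mannwhitneyu(xa, xb, alternative="two-sided")
                    comparisons[metric] = TestResult(
                        name="mann_whitney_u",
                        statistic=float(res.statistic),
                        pvalue=float(res.pvalue),
                        n={"n1": len(xa), "n2": len(xb)},
                    )
        return SwimAnalysisResults(
            model=self, per_bout=per_bout, comparisons=comparisons, warnings=warnings_log
        )


class SwimAnalysisResults:
    def __init__(self, model, per_bout, comparisons, warnings) -> None:
        self.model = model
        self.per_bout = per_bout
        self.comparisons = comparisons
        self.warnings = warnings

    def bout_table(self) -> pd.DataFrame:
        rows = []
        for grp, items in self.per_bout.items():
            for r in items:
                rows.append({"group": grp, **r})
        return pd.DataFrame(rows)

    def group_means(self) -> pd.DataFrame:
        df = self.bout_table()
        return df.groupby("group")[
            ["mean_cycle_period_s", "missed_alternations", "miss_ratio_per_s"]
        ].mean()

    def summary(self) -> str:
        lines = ["Swim analysis", "=" * 13]
        lines.append(self.group_means().to_string(float_format=lambda v: f"{v:.4f}"))
        for metric, t in self.comparisons.items():
            lines.append(f"{metric}: U = {t.statistic:.1f}, p = {t.pvalue:.4g}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def to_report(self) -> dict:
        return {
            "schema": "cpgkit/swim-report/1",
            "version": _pkg_version,
            "bouts": self.per_bout,
            "comparisons": {
                k: {"U": t.statistic, "p": t.pvalue, "n": t.n}
                for k, t in self.comparisons.items()
            },
            "warnings": list(self.warnings),
        }
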