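import numpy as np
import pytest

from cpgkit import (
    BurstTrain,
    FrequencySample,
    autocorr_rhythmicity,
    circular_stats,
    cross_correlogram_ccc,
    frequency_modes,
    ks_two_sample,
    pair_phases,
    phases_from_onsets,
)
from cpgkit.rhythm import PhaseSample

from conftest import make_envelope, random_bumpy_envelope


def train_from_onsets(onsets, dur=0.5, channel="RL2"):
    onsets = np.asarray(onsets, dtype=float)
    events = np.column_stack([onsets, onsets + dur, np.ones_like(onsets)])
    return BurstTrain(events=events, channel=channel)


class TestPairPhases:
    def test_identical_trains_give_zero_phase(self):
        a = train_from_onsets([0, 4, 8, 12])
        ps = pair_phases(a, a)
        assert ps.phases == pytest.approx([0, 0, 0])

    def test_half_period_shift_gives_180(self):
        a = train_from_onsets([0, 4, 8, 12])
        b = train_from_onsets([2, 6, 10], channel="LL2")
        ps = pair_phases(a, b)
        assert ps.phases == pytest.approx([180, 180, 180])
        assert ps.pair == ("RL2", "LL2")

    def test_one_second_shift_on_four_second_cycles_gives_90(self):
        a = train_from_onsets([0, 4, 8, 12, 16])
        b = train_from_onsets([1, 5, 9, 13])
        assert pair_phases(a, b).phases == pytest.approx([90, 90, 90, 90])

    def test_cycles_without_target_are_skipped_and_counted(self):
        a = train_from_onsets([0, 4, 8, 12])
        b = train_from_onsets([1, 9])  # nothing in cycle [4, 8)
        ps = pair_phases(a, b)
        assert ps.phases == pytest.approx([90, 90])
        assert ps.n_skipped == 1

    def test_disjoint_spans_warn_and_return_empty(self):
        a = train_from_onsets([0, 4, 8])
        b = train_from_onsets([100, 104])
        with pytest.warns(UserWarning):
            ps = pair_phases(a, b)
        assert len(ps) == 0


class TestCircularStats:
    def test_concentrated_sample(self):
        s = circular_stats(PhaseSample(phases=np.full(10, 180.0)))
        assert s["mean_deg"] == pytest.approx(180.0)
        assert s["R"] == pytest.approx(1.0)
        assert s["circ_sd_deg"] == pytest.approx(0.0, abs=1e-6)

    def test_antipodal_sample_has_undefined_mean(self):
        s = circular_stats(PhaseSample(phases=np.array([0.0, 180.0] * 5)))
        assert s["R"] == pytest.approx(0.0, abs=1e-12)
        assert s["mean_undefined"]
        assert np.isnan(s["mean_deg"])

    def test_wraparound_mean_is_zero_not_180(self):
        s = circular_stats(PhaseSample(phases=np.array([359.0, 1.0])))
        assert s["mean_deg"] == pytest.approx(0.0, abs=1e-9) or s[
            "mean_deg"
        ] == pytest.approx(360.0, abs=1e-9)

    def test_von_mises_mean_recovery(self):
        # concentrated sample around the alternating-pair phase
        rng = np.random.default_rng(42)
        phases = np.rad2deg(rng.vonmises(np.deg2rad(196.0), 4.0, size=500)) % 360.0
        s = circular_stats(PhaseSample(phases=phases))
        assert abs(s["mean_deg"] - 196.0) <= 5.0
        assert s["rayleigh"].pvalue < 1e-6

    def test_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        phases = np.rad2deg(rng.vonmises(1.0, 2.0, size=80)) % 360.0
        s = circular_stats(PhaseSample(phases=phases))
        rad = np.deg2rad(phases)
        assert s["mean_deg"] == pytest.approx(np.rad2deg(pg.circ_mean(rad)) % 360, abs=1e-8)
        assert s["R"] == pytest.approx(float(pg.circ_r(rad)), abs=1e-10)
        z, p = pg.circ_rayleigh(rad)
        assert s["rayleigh"].pvalue == pytest.approx(p, rel=1e-6, abs=1e-12)

    def test_simulation_pvalue_close_to_approx_for_moderate_n(self):
        rng = np.random.default_rng(11)
        phases = rng.uniform(0, 360, size=30)
        s_apx = circular_stats(PhaseSample(phases=phases), rayleigh_method="approx")
        s_sim = circular_stats(
            PhaseSample(phases=phases), rayleigh_method="simulation", n_sim=40000, seed=1
        )
        assert s_sim["rayleigh"].pvalue == pytest.approx(s_apx["rayleigh"].pvalue, abs=0.02)

    def test_requires_two_phases(self):
        with pytest.raises(ValueError):
            circular_stats(PhaseSample(phases=np.array([10.0])))


class TestCrossCorrelogram:
    def test_self_correlation(self, rng):
        env = random_bumpy_envelope(rng, 4000)
        out = cross_correlogram_ccc(env, env, max_lag_s=2.0)
        center = out["corr"].coefficients[out["corr"].lags == 0]
        assert center == pytest.approx(1.0, abs=1e-9)
        assert out["peak_lag_s"] == 0.0
        assert out["ccc_index"] > 0

    def test_negated_partner_gives_minus_one_at_zero_lag(self, rng):
        env = random_bumpy_envelope(rng, 4000)
        flipped = make_envelope(env.samples.max() - env.samples, rate=env.rate)
        out = cross_correlogram_ccc(env, flipped, max_lag_s=2.0)
        center = out["corr"].coefficients[out["corr"].lags == 0]
        assert center == pytest.approx(-1.0, abs=1e-9)

    def test_antiphase_sinusoids_match_analytic_cosine(self):
        # two 0.5 Hz sinusoids 180 deg apart: corr(lag) = -cos(2 pi f lag)
        rate, f, dur = 100.0, 0.5, 500.0
        t = np.arange(0, dur, 1 / rate)
        a = make_envelope(1 + np.sin(2 * np.pi * f * t), rate=rate)
        b = make_envelope(1 + np.sin(2 * np.pi * f * t + np.pi), rate=rate)
        out = cross_correlogram_ccc(a, b, max_lag_s=2.5, cycle_period_s=2.0)
        lags_s = out["corr"].lags
        expected = -np.cos(2 * np.pi * f * lags_s)
        assert np.max(np.abs(out["corr"].coefficients - expected)) <= 1e-3
        assert abs(abs(out["peak_lag_s"]) - 1.0) <= 0.02  # half the 2 s period

    def test_independent_noise_envelopes_have_small_ccc(self):
        rng = np.random.default_rng(99)
        vals = []
        for _ in range(100):
            a = random_bumpy_envelope(rng, 3000)
            b = random_bumpy_envelope(rng, 3000)
            out = cross_correlogram_ccc(a, b, max_lag_s=1.0, cycle_period_s=1.0)
            vals.append(out["ccc_index"])
        assert np.mean(np.abs(vals)) < 0.1

    def test_zero_variance_rejected(self):
        flat = make_envelope(np.ones(1000))
        bumpy = make_envelope(np.abs(np.sin(np.arange(1000) / 10)))
        with pytest.raises(ValueError):
            cross_correlogram_ccc(flat, bumpy, max_lag_s=1.0)


class TestAutocorrRhythmicity:
    def test_white_noise_is_arrhythmic(self):
        rng = np.random.default_rng(0)
        env = make_envelope(np.abs(rng.standard_normal(20_000)))
        out = autocorr_rhythmicity(env, max_lag_s=10.0)
        assert out["index"] < 0.1
        assert not out["rhythmic"]

    def test_periodic_bursts_recover_period(self):
        from cpgkit import envelope

        from conftest import square_burst_trace

        trace, _, _ = square_burst_trace(n_bursts=15, period_s=4.0, seed=8)
        out = autocorr_rhythmicity(envelope(trace))
        assert abs(out["period_estimate_s"] - 4.0) <= 0.1
        assert out["index"] > 0.5
        assert out["rhythmic"]

    def test_constant_envelope_rejected(self):
        with pytest.raises(ValueError):
            autocorr_rhythmicity(make_envelope(np.full(1000, 2.0)))


class TestFrequencyModes:
    def test_degenerate_sample_single_mode(self):
        fs = FrequencySample(frequencies=np.full(50, 0.25))
        out = frequency_modes(fs)
        assert out["density"].max() == pytest.approx(1.0)
        assert out["modes_hz"].size == 1
        assert out["modes_hz"][0] == pytest.approx(0.25, abs=0.002)

    def test_bimodal_mixture_recovers_both_centers(self):
        rng = np.random.default_rng(21)
        f = np.concatenate(
            [rng.normal(0.16, 0.02, 1000), rng.normal(0.27, 0.02, 1000)]
        )
        out = frequency_modes(FrequencySample(frequencies=f[f > 0]))
        assert out["modes_hz"].size == 2
        assert abs(out["modes_hz"][0] - 0.16) <= 0.01
        assert abs(out["modes_hz"][1] - 0.27) <= 0.01

    def test_single_cluster_single_mode(self):
        rng = np.random.default_rng(22)
        f = rng.normal(0.22, 0.02, 1500)
        out = frequency_modes(FrequencySample(frequencies=f[f > 0]))
        assert out["modes_hz"].size == 1
        assert abs(out["modes_hz"][0] - 0.22) <= 0.01

    def test_invariant_to_order_and_duplication(self):
        rng = np.random.default_rng(23)
        f = rng.normal(0.2, 0.03, 200)
        f = f[f > 0]
        base = frequency_modes(FrequencySample(frequencies=f))
        shuffled = frequency_modes(FrequencySample(frequencies=rng.permutation(f)))
        doubled = frequency_modes(FrequencySample(frequencies=np.concatenate([f, f])))
        assert np.array_equal(base["modes_hz"], shuffled["modes_hz"])
        assert np.array_equal(base["modes_hz"], doubled["modes_hz"])
        assert base["density"] == pytest.approx(doubled["density"])

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            frequency_modes(FrequencySample(frequencies=np.array([0.2, 0.2, 0.2, 0.2])))


class TestKsTwoSample:
    def test_identical_samples(self):
        a = FrequencySample(frequencies=np.linspace(0.1, 0.5, 50))
        res = ks_two_sample(a, a)
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_shifted_uniforms_match_ecdf_oracle(self):
        rng = np.random.default_rng(31)
        xa = rng.uniform(0, 1, 100)
        xb = rng.uniform(0.5, 1.5, 100)
        res = ks_two_sample(xa, xb)
        # brute-force sup |ECDF_a - ECDF_b| over the pooled sample
        pooled = np.concatenate([xa, xb])
        d = max(
            abs(np.mean(xa <= v) - np.mean(xb <= v)) for v in pooled
        )
        assert res.statistic == pytest.approx(d, abs=1e-12)
        assert res.statistic == pytest.approx(0.5, abs=0.12)
        assert res.pvalue < 1e-3

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(32)
        pvals = np.array(
            [
                ks_two_sample(rng.normal(size=150), rng.normal(size=150)).pvalue
                for _ in range(400)
            ]
        )
        grid = np.linspace(0.01, 0.99, 99)
        ecdf = np.array([(pvals <= g).mean() for g in grid])
        assert np.max(np.abs(ecdf - grid)) < 0.1


class TestPhaseSampleInvariants:
    def test_rejects_out_of_range_phases(self):
        with pytest.raises(ValueError):
            PhaseSample(phases=np.array([0.0, 360.0]))
        with pytest.raises(ValueError):
            PhaseSample(phases=np.array([-1.0]))

    def test_phases_from_onsets_handles_target_on_boundary(self):
        ps = phases_from_onsets([0.0, 4.0, 8.0], [0.0, 4.0])
        assert ps.phases == pytest.approx([0.0, 0.0])
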