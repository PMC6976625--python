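import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpgkit import (
    PositionFieldConfig,
    density_maps,
    gen_positions,
    hotelling_t2,
    normalize_position,
    normalize_positions,
)
from cpgkit.spatial import density_modes


class TestNormalizePosition:
    def test_origin_maps_to_zero(self):
        assert normalize_position(0.0, 45.0, 400.0, 300.0) == (0.0, 0.0)

    def test_vertical_soma_at_full_height(self):
        dv, ml = normalize_position(400.0, 90.0, 400.0, 300.0)
        assert dv * 100 == pytest.approx(100.0)
        assert ml * 100 == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_30_degrees(self):
        dv, ml = normalize_position(2.0, 30.0, 4.0, 8.0)
        assert dv * 100 == pytest.approx(25.0)
        assert ml * 100 == pytest.approx(100 * 2 * np.sqrt(3) / 2 / 8)  # ~21.65 %

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            normalize_position(1.0, 30.0, 0.0, 300.0)
        with pytest.raises(ValueError):
            normalize_position(1.0, 30.0, 400.0, -1.0)
        with pytest.raises(ValueError):
            normalize_position(-1.0, 30.0, 400.0, 300.0)

    def test_round_trip_with_generator_inverse_transform(self):
        table, _ = gen_positions(PositionFieldConfig(seed=9, n=500))
        out = normalize_positions(table)
        assert np.max(np.abs(out["dv_frac"] - table["dv_frac_true"])) <= 1e-12
        assert np.max(np.abs(out["ml_frac"] - table["ml_frac_true"])) <= 1e-12

    def test_clamping_warns_but_keeps_cells(self):
        df = pd.DataFrame(
            {
                "d_um": [450.0],
                "alpha_deg": [90.0],
                "H_um": [400.0],
                "W_um": [300.0],
            }
        )
        with pytest.warns(UserWarning, match="clamped"):
            out = normalize_positions(df)
        assert out["dv_frac"].iloc[0] == 1.0


class TestDensityMaps:
    def test_single_point_peaks_at_its_cell_and_integrates_to_one(self):
        out = density_maps(np.array([[0.3, 0.7]]))
        step = 1.0 / out["map2d"].shape[0]
        iy, ix = np.unravel_index(np.argmax(out["map2d"]), out["map2d"].shape)
        assert abs(out["grid"][ix] - 0.3) <= step
        assert abs(out["grid"][iy] - 0.7) <= step
        assert out["map2d"].sum() * step * step == pytest.approx(1.0, abs=1e-6)
        assert out["marginal_ml"].sum() * step == pytest.approx(1.0, abs=1e-9)

    def test_two_cluster_sample_has_two_maxima_near_cluster_means(self):
        rng = np.random.default_rng(17)
        n = 1500
        pts = np.concatenate(
            [
                rng.normal([0.50, 0.35], 0.06, size=(n, 2)),
                rng.normal([0.15, 0.40], 0.05, size=(n // 3, 2)),
            ]
        )
        pts = pts[(pts >= 0).all(axis=1) & (pts <= 1).all(axis=1)]
        out = density_maps(pts, grid_size=50, bandwidth=0.05)
        modes = density_modes(out["map2d"], min_frac=0.2)
        assert len(modes) == 2
        found = sorted((out["grid"][c], out["grid"][r]) for r, c in modes)
        step = 1.0 / 50
        tol = step + out["bandwidth"]
        assert abs(found[0][0] - 0.15) <= tol and abs(found[0][1] - 0.40) <= tol
        assert abs(found[1][0] - 0.50) <= tol and abs(found[1][1] - 0.35) <= tol

    def test_uniform_sample_is_approximately_flat(self):
        rng = np.random.default_rng(18)
        pts = rng.uniform(0, 1, size=(10_000, 2))
        out = density_maps(pts, bandwidth=0.1)
        assert np.max(np.abs(out["map2d"] - 1.0)) <= 0.15

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            density_maps(np.empty((0, 2)))


def oracle_t2(A, B):
    """Direct matrix-formula evaluation with explicit loops and inverse."""
    A, B = np.asarray(A, float), np.asarray(B, float)
    n1, n2 = len(A), len(B)
    m1 = np.array([sum(A[:, j]) / n1 for j in range(2)])
    m2 = np.array([sum(B[:, j]) / n2 for j in range(2)])
    S = np.zeros((2, 2))
    for x in A:
        S += np.outer(x - m1, x - m1)
    for x in B:
        S += np.outer(x - m2, x - m2)
    S /= n1 + n2 - 2
    d = m1 - m2
    return (n1 * n2 / (n1 + n2)) * float(d @ np.linalg.inv(S) @ d)


class TestHotellingT2:
    def test_identical_groups(self, rng):
        A = rng.normal(size=(20, 2))
        res = hotelling_t2(A, A.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_matches_matrix_oracle_on_small_groups(self, rng):
        A = rng.normal([0.4, 0.3], 0.1, size=(5, 2))
        B = rng.normal([0.5, 0.35], 0.1, size=(5, 2))
        res = hotelling_t2(A, B)
        assert abs(res.statistic - oracle_t2(A, B)) <= 1e-10

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        A = rng.normal([0.4, 0.3], 0.1, size=(25, 2))
        B = rng.normal([0.45, 0.33], 0.12, size=(30, 2))
        res = hotelling_t2(A, B)
        ref = pg.multivariate_ttest(A, B)
        assert res.statistic == pytest.approx(float(ref["T2"].iloc[0]), rel=1e-9)
        assert res.pvalue == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        sx=st.floats(0.5, 3.0),
        sy=st.floats(0.5, 3.0),
        theta=st.floats(0, np.pi),
        tx=st.floats(-5, 5),
        ty=st.floats(-5, 5),
    )
    def test_affine_invariance(self, seed, sx, sy, theta, tx, ty):
        """T2 and p are unchanged by a common affine map of both groups."""
        rng = np.random.default_rng(seed)
        A = rng.normal([0.3, 0.4], 0.1, size=(12, 2))
        B = rng.normal([0.4, 0.5], 0.1, size=(15, 2))
        c, s = np.cos(theta), np.sin(theta)
        M = np.array([[c, -s], [s, c]]) @ np.diag([sx, sy])
        t = np.array([tx, ty])
        base = hotelling_t2(A, B)
        mapped = hotelling_t2(A @ M.T + t, B @ M.T + t)
        assert mapped.pvalue == pytest.approx(base.pvalue, abs=1e-8)

    def test_power_increases_with_mean_shift(self):
        rng = np.random.default_rng(55)
        shifts = [0.0, 0.05, 0.1, 0.2]
        reps = 250
        rates = []
        for shift in shifts:
            rejections = 0
            for _ in range(reps):
                A = rng.normal([0.5, 0.35], 0.08, size=(30, 2))
                B = rng.normal([0.5 + shift, 0.35], 0.08, size=(30, 2))
                rejections += hotelling_t2(A, B).pvalue < 0.05
            rates.append(rejections / reps)
        assert all(b >= a - 0.03 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > 0.9

    def test_small_groups_and_singular_covariance_rejected(self):
        with pytest.raises(ValueError):
            hotelling_t2(np.zeros((2, 2)), np.zeros((5, 2)))
        degenerate = np.tile([0.5, 0.5], (6, 1))
        with pytest.raises(ValueError):
            hotelling_t2(degenerate, degenerate)
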