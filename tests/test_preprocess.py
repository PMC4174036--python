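"""Time-series conditioning contracts: discard, detrend, band-pass, nuisance."""

import numpy as np
import pytest

from bnec.preprocess import (
    NuisanceRegressors,
    bandpass,
    detrend,
    discard_initial_volumes,
    regress_nuisance,
    standardize,
)

from conftest import make_ts


class TestDiscard:
    def test_132_minus_5_gives_127_per_segment(self, rng):
        ts = make_ts(
            rng.normal(size=(264, 2)),
            segments=[("s1", 0, 132), ("s2", 132, 264)],
        )
        out = discard_initial_volumes(ts, 5)
        assert out.values.shape == (254, 2)
        assert out.segment_bounds == [("s1", 0, 127), ("s2", 127, 254)]
        np.testing.assert_array_equal(out.values[:127], ts.values[5:132])

    def test_zero_is_identity(self, rng):
        ts = make_ts(rng.normal(size=(10, 2)))
        np.testing.assert_array_equal(discard_initial_volumes(ts, 0).values, ts.values)

    def test_discarding_whole_segment_is_an_error(self, rng):
        ts = make_ts(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="cannot discard"):
            discard_initial_volumes(ts, 5)


class TestDetrend:
    def test_pure_line_removed_exactly(self):
        t = np.arange(50, dtype=float)
        ts = make_ts(np.column_stack([2 * t + 3, -0.5 * t + 1]))
        out = detrend(ts)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_constant_column_becomes_zero(self):
        ts = make_ts(np.full((20, 1), 4.2))
        np.testing.assert_allclose(detrend(ts).values, 0.0, atol=1e-10)

    def test_idempotent(self, rng):
        ts = make_ts(rng.normal(size=(60, 3)), segments=[("a", 0, 30), ("b", 30, 60)])
        once = detrend(ts)
        twice = detrend(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_matches_least_squares_projection_oracle(self):
        # ramp + sinusoid: residual must equal the explicit LS projection
        t = np.arange(127, dtype=float)
        y = 0.03 * t + np.sin(2 * np.pi * 0.05 * t * 2.0)
        ts = make_ts(y[:, None])
        out = detrend(ts).values[:, 0]
        X = np.column_stack([np.ones_like(t), t])
        resid_oracle = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(out, resid_oracle, atol=1e-9)

    def test_per_segment_means_vanish(self, rng):
        ts = make_ts(
            rng.normal(size=(40, 2)) + 5.0, segments=[("a", 0, 25), ("b", 25, 40)]
        )
        out = detrend(ts)
        for _, block in out.segments():
            assert np.abs(block.mean(axis=0)).max() < 1e-10


class TestBandpass:
    @pytest.mark.parametrize(
        "freq, low, high, check",
        [
            (0.04, 0.01, 0.08, lambda r: r >= 0.9),  # in band
            (0.20, 0.01, 0.08, lambda r: r <= 0.1),  # above band
        ],
    )
    def test_fft_amplitude_ratio(self, freq, low, high, check):
        tr = 2.0
        t = np.arange(400) * tr
        x = np.sin(2 * np.pi * freq * t)
        out = bandpass(make_ts(x[:, None], tr=tr), low, high).values[:, 0]
        # FFT amplitude oracle at the tone's bin (interior window avoids edges)
        win = slice(50, 350)
        f = np.fft.rfftfreq(300, d=tr)
        k = np.argmin(np.abs(f - freq))
        ratio = np.abs(np.fft.rfft(out[win]))[k] / np.abs(np.fft.rfft(x[win]))[k]
        assert check(ratio)

    def test_zero_input_zero_output(self):
        out = bandpass(make_ts(np.zeros((100, 2))), 0.01, 0.08)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_linearity(self, rng):
        x = rng.normal(size=(127, 1))
        y = rng.normal(size=(127, 1))
        fx = bandpass(make_ts(x), 0.01, 0.08).values
        fy = bandpass(make_ts(y), 0.01, 0.08).values
        fxy = bandpass(make_ts(2.0 * x - 3.0 * y), 0.01, 0.08).values
        np.testing.assert_allclose(fxy, 2.0 * fx - 3.0 * fy, atol=1e-8)

    @pytest.mark.parametrize("low,high", [(0.1, 0.05), (0.01, 0.3), (-0.01, 0.08)])
    def test_invalid_cutoffs_rejected(self, low, high):
        with pytest.raises(ValueError, match="cutoffs"):
            bandpass(make_ts(np.zeros((50, 1))), low, high)

    def test_inband_energy_preserved_on_white_noise(self, rng):
        tr = 2.0
        x = rng.normal(size=(2000, 1))
        out = bandpass(make_ts(x, tr=tr), 0.01, 0.08).values[:, 0]
        f = np.fft.rfftfreq(2000, d=tr)
        band = (f >= 0.02) & (f <= 0.06)  # well inside the passband
        pin = np.abs(np.fft.rfft(x[:, 0]))[band] ** 2
        pout = np.abs(np.fft.rfft(out))[band] ** 2
        assert pout.sum() / pin.sum() > 0.8


class TestNuisance:
    def test_exact_linear_combination_removed(self, rng):
        R = rng.normal(size=(100, 2))
        y = 3.0 * R[:, 0] - 2.0 * R[:, 1]
        out = regress_nuisance(
            make_ts(y[:, None]), NuisanceRegressors(R, ["r1", "r2"])
        )
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self, rng):
        R = rng.normal(size=(127, 3))
        ts = make_ts(rng.normal(size=(127, 4)))
        out = regress_nuisance(ts, NuisanceRegressors(R, list("abc")))
        for j in range(4):
            for k in range(3):
                ip = out.values[:, j] @ R[:, k]
                bound = 1e-8 * np.linalg.norm(out.values[:, j]) * np.linalg.norm(R[:, k])
                assert abs(ip) <= max(bound, 1e-8)

    def test_duplicated_regressor_equals_single_copy(self, rng):
        # minimum-norm solution oracle: residual = (I - X X^+) y
        R = rng.normal(size=(80, 1))
        y = rng.normal(size=(80, 2))
        single = regress_nuisance(make_ts(y), NuisanceRegressors(R, ["r"]))
        doubled = regress_nuisance(
            make_ts(y), NuisanceRegressors(np.column_stack([R, R]), ["r", "r2"])
        )
        X = np.column_stack([np.ones(80), R, R])
        oracle = y - X @ np.linalg.pinv(X) @ y
        np.testing.assert_allclose(doubled.values, single.values, atol=1e-8)
        np.testing.assert_allclose(doubled.values, oracle, atol=1e-8)

    def test_never_increases_column_variance(self, rng):
        R = rng.normal(size=(127, 4))
        ts = make_ts(rng.normal(size=(127, 3)))
        out = regress_nuisance(ts, NuisanceRegressors(R, list("abcd")))
        assert np.all(out.values.var(axis=0) <= ts.values.var(axis=0) + 1e-12)

    def test_row_count_mismatch_is_an_error(self, rng):
        R = rng.normal(size=(50, 1))
        with pytest.raises(ValueError, match="regressor rows"):
            regress_nuisance(make_ts(rng.normal(size=(60, 1))), NuisanceRegressors(R, ["r"]))


class TestStandardize:
    def test_unit_moments_per_segment(self, rng):
        ts = make_ts(
            rng.normal(loc=3, scale=9, size=(80, 3)),
            segments=[("a", 0, 50), ("b", 50, 80)],
        )
        out = standardize(ts)
        for _, block in out.segments():
            assert np.abs(block.mean(axis=0)).max() < 1e-12
            np.testing.assert_allclose(block.var(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_already_standard_input_unchanged(self, rng):
        ts = standardize(make_ts(rng.normal(size=(100, 2))))
        again = standardize(ts)
        np.testing.assert_allclose(again.values, ts.values, atol=1e-10)

    def test_constant_column_names_node_and_subject(self, rng):
        vals = rng.normal(size=(30, 2))
        vals[:, 1] = 3.0
        ts = make_ts(vals, labels=["PCC", "MPFC"], segments=[("sub07", 0, 30)])
        with pytest.raises(ValueError, match="MPFC.*sub07"):
            standardize(ts)
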