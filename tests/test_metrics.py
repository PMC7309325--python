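"""Evaluation formulary: alignment, errors, ICC, rank tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import respvol as rv
from respvol.metrics import (
    AlignmentError,
    align,
    compare_methods,
    dunn_test,
    icc,
    icc_matrix,
    kruskal_wallis,
    match_breaths,
    tidal_volume_error,
    volume_waveform_error,
)
from respvol.volume import Breath, VolumeWaveform


def make_wave(t, cum):
    return VolumeWaveform(times=np.asarray(t), values=np.diff(cum, prepend=cum[0]),
                          cumulative=np.asarray(cum, dtype=float))


@pytest.fixture
def sine_pair():
    t = np.arange(0, 60, 1 / 16)
    ref = make_wave(t, 200 * (1 - np.cos(2 * np.pi * t / 4)) / 2)
    return ref


class TestAlign:
    def test_identical_zero_difference(self, sine_pair):
        pair = align(sine_pair, sine_pair, offset=0.0)
        np.testing.assert_allclose(pair.reference, pair.estimate)

    def test_constant_shift_cancelled_by_offset(self, sine_pair):
        t = sine_pair.times
        delayed = make_wave(t + 0.5, sine_pair.cumulative)
        pair = align(sine_pair, delayed, offset=-0.5)
        np.testing.assert_allclose(pair.reference, pair.estimate, atol=1e-9)

    def test_disjoint_ranges_rejected(self, sine_pair):
        t = sine_pair.times
        other = make_wave(t + 1000.0, sine_pair.cumulative)
        with pytest.raises(AlignmentError):
            align(sine_pair, other)


class TestTidalVolumeError:
    def test_identical_zero(self):
        e, per = tidal_volume_error([500.0, 400.0], [500.0, 400.0])
        assert e == 0.0

    def test_ten_percent_uniform(self):
        vv = np.array([500.0, 430.0, 610.0])
        e, per = tidal_volume_error(1.1 * vv, vv)
        assert e == pytest.approx(10.0)
        np.testing.assert_allclose(per, 10.0)

    def test_hand_computed_mixed(self):
        e, _ = tidal_volume_error([550.0, 450.0], [500.0, 500.0])
        assert e == pytest.approx(10.0)

    def test_scale_invariance(self):
        vd = np.array([550.0, 450.0])
        vv = np.array([500.0, 500.0])
        e1, _ = tidal_volume_error(vd, vv)
        e2, _ = tidal_volume_error(7.3 * vd, 7.3 * vv)
        assert e1 == pytest.approx(e2)

    def test_validation(self):
        with pytest.raises(ValueError):
            tidal_volume_error([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            tidal_volume_error([1.0], [0.0])


class TestVolumeWaveformError:
    def test_identical_zero(self, sine_pair):
        pair = align(sine_pair, sine_pair)
        assert volume_waveform_error(pair) == 0.0

    def test_doubled_waveform_is_hundred_percent(self, sine_pair):
        t = sine_pair.times
        doubled = make_wave(t, 2 * sine_pair.cumulative)
        assert volume_waveform_error(align(sine_pair, doubled)) == pytest.approx(100.0)

    def test_zero_estimate_is_hundred_percent(self, sine_pair):
        t = sine_pair.times
        flat = make_wave(t, np.zeros_like(t))
        assert volume_waveform_error(align(sine_pair, flat)) == pytest.approx(100.0)

    def test_scale_invariance(self, sine_pair):
        t = sine_pair.times
        est = make_wave(t, 1.37 * sine_pair.cumulative)
        e1 = volume_waveform_error(align(sine_pair, est))
        ref2 = make_wave(t, 5 * sine_pair.cumulative)
        est2 = make_wave(t, 5 * 1.37 * sine_pair.cumulative)
        assert e1 == pytest.approx(volume_waveform_error(align(ref2, est2)))

    def test_zero_reference_rejected(self):
        t = np.arange(0, 5, 1 / 16)
        flat = make_wave(t, np.zeros_like(t))
        with pytest.raises(ValueError):
            volume_waveform_error(align(flat, flat))


class TestICC:
    def test_identical_nonconstant_is_one(self, sine_pair):
        assert icc(align(sine_pair, sine_pair)) == pytest.approx(1.0)

    def test_matches_pingouin_oracle(self, rng):
        # independent oracle: pingouin's two-way absolute-agreement
        # single-measures ICC on 20 random paired series
        pingouin = pytest.importorskip("pingouin")
        for _ in range(20):
            n = int(rng.integers(20, 60))
            base = rng.normal(0, 1, n)
            a = base + rng.normal(0, 0.3, n)
            b = 0.9 * base + rng.normal(0.2, 0.3, n)
            data = np.column_stack([a, b])
            df = pd.DataFrame({
                "targets": np.repeat(np.arange(n), 2),
                "raters": np.tile(["x", "y"], n),
                "scores": data.ravel(),
            })
            res = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                           ratings="scores")
            expected = float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
            assert icc_matrix(data) == pytest.approx(expected, abs=1e-10)

    def test_absolute_agreement_penalizes_bias(self, sine_pair):
        t = sine_pair.times
        biased = make_wave(t, sine_pair.cumulative + 300.0)
        assert icc(align(sine_pair, biased)) < 0.5
        assert icc(align(sine_pair, sine_pair)) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(7)
        n = 10_000
        t = np.arange(n, dtype=float)
        a = make_wave(t, np.cumsum(rng.normal(size=n)) * 0 + rng.normal(size=n))
        b = make_wave(t, rng.normal(size=n))
        pair = align(a, b)
        assert abs(icc(pair)) < 0.05

    def test_constant_waveforms_rejected(self):
        t = np.arange(0, 5, 1 / 16)
        flat = make_wave(t, np.full_like(t, 3.0))
        with pytest.raises(ValueError):
            icc(align(flat, flat))

    def test_symmetric_in_waveforms(self, rng):
        a = rng.normal(0, 1, 50)
        b = a + rng.normal(0, 0.5, 50)
        assert icc_matrix(np.column_stack([a, b])) == pytest.approx(
            icc_matrix(np.column_stack([b, a]))
        )


class TestKruskalWallis:
    def test_identical_groups(self):
        g = [np.ones(5), np.ones(5), np.ones(5)]
        h, p = kruskal_wallis(g)
        assert h == 0.0 and p == 1.0

    def test_exact_rank_hand_computation(self):
        groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
        h, p = kruskal_wallis(groups)
        # ranks are 1..9 with group means 2, 5, 8; N=9
        expected = 12 / (9 * 10) * 3 * ((2 - 5) ** 2 + 0 + (8 - 5) ** 2)
        assert h == pytest.approx(expected)

    def test_matches_scipy_with_ties(self, rng):
        groups = [np.round(rng.normal(i, 1, 12), 1) for i in range(3)]
        h, p = kruskal_wallis(groups)
        ref = stats.kruskal(*groups)
        assert h == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(i, 1, 10) for i in range(3)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2)

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 50)
        b = rng.normal(2, 1, 50)
        _, p = kruskal_wallis([a, b])
        assert p < 0.01

    def test_matches_permutation_oracle(self):
        # permutation null of H on a small fixed dataset
        rng = np.random.default_rng(3)
        groups = [rng.normal(0.8 * i, 1, 6) for i in range(3)]
        h_obs, p_chi2 = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            h_p, _ = kruskal_wallis(list(parts))
            if h_p >= h_obs:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        assert p_chi2 == pytest.approx(p_perm, abs=0.05)


class TestDunnAndCompare:
    def test_pairwise_count_and_bonferroni(self, rng):
        groups = [rng.normal(i, 1, 15) for i in range(3)]
        table = dunn_test(groups, ["a", "b", "c"])
        assert len(table) == 3
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-15).all()
        assert (table["p_adjusted"] <= 1.0).all()

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(11)
        errs = {
            "adaptive": rng.normal(8, 2, 50),
            "temporal": rng.normal(12, 2, 50),
            "spatial": rng.normal(16, 2, 50),
        }
        res = compare_methods(errs)
        assert res.p_value < 1e-6
        assert (res.pairwise["p_adjusted"] < 0.01).all()

    def test_identical_everything(self):
        res = compare_methods([np.full(5, 2.0), np.full(4, 2.0)])
        assert res.h == 0.0 and res.p_value == 1.0


class TestMatchBreaths:
    def _b(self, t0, t1, ml=300.0):
        return Breath(0, 0, t0, t1, ml)

    def test_overlap_pairing(self):
        ref = [self._b(0, 2), self._b(4, 6), self._b(8, 10)]
        est = [self._b(0.3, 2.2), self._b(8.1, 9.8)]
        r, e, unmatched = match_breaths(ref, est)
        assert [x.valley_time for x in r] == [0, 8]
        assert unmatched == 1

    def test_empty_inputs(self):
        r, e, unmatched = match_breaths([], [self._b(0, 1)])
        assert r == [] and unmatched == 1
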