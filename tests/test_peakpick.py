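import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msikit.datamodel import MeanSpectrum, mean_spectrum
from msikit.peakpick import (
    Peak,
    PeakSet,
    deisotope,
    detect_peaks,
    peak_extent,
    peak_intensity,
    reduce_to_peaks,
    winsorize_mean,
)

from conftest import make_dataset


def ms(values, mz=None):
    values = np.asarray(values, dtype=float)
    if mz is None:
        mz = 100.0 + np.arange(values.size)
    return MeanSpectrum(mz=mz, mu=values)


def brute_force_peaks(x, z_t):
    """O(d^2)-style oracle: checks every channel's neighbourhood directly.

    Returns (l, apex, r) triples, 1-based, with valley truncation.
    """
    x = np.asarray(x, dtype=float)
    d = x.size
    apexes = []
    for c in range(d):
        if c > 0 and x[c - 1] == x[c]:
            continue  # not the leftmost channel of its plateau
        e = c
        while e + 1 < d and x[e + 1] == x[c]:
            e += 1
        if (c == 0 or x[c - 1] < x[c]) and (e == d - 1 or x[e + 1] < x[c]):
            if x[c] > z_t:
                apexes.append(c)
    extents = []
    for a in apexes:
        half = x[a] / 2.0
        l = a
        while l > 0 and x[l - 1] >= half:
            l -= 1
        r = a
        while r < d - 1 and x[r + 1] >= half:
            r += 1
        extents.append([l, r])
    for t in range(len(apexes) - 1):
        if extents[t][1] >= extents[t + 1][0]:
            seg = x[apexes[t] + 1 : apexes[t + 1]]
            valley = apexes[t] + 1 + int(np.argmin(seg))
            extents[t][1] = min(extents[t][1], valley)
            extents[t + 1][0] = max(extents[t + 1][0], valley + 1)
    return [(l + 1, a + 1, r + 1) for a, (l, r) in zip(apexes, extents)]


class TestWinsorize:
    def test_caps_at_second_highest(self):
        out = winsorize_mean(ms([10.0, 5.0, 3.0, 1.0]), z_w=2)
        np.testing.assert_array_equal(out.mu, [5.0, 5.0, 3.0, 1.0])

    def test_rank_one_is_identity(self):
        mu = ms([4.0, 2.0, 9.0])
        np.testing.assert_array_equal(winsorize_mean(mu, 1).mu, mu.mu)

    def test_ties_at_rank_cap_at_tied_value(self):
        values = np.array([7.0, 7.0, 7.0, 2.0, 9.0])
        out = winsorize_mean(ms(values), z_w=3)
        cap = np.sort(values)[::-1][2]  # brute-force rank on the multiset
        np.testing.assert_array_equal(out.mu, np.minimum(values, cap))

    def test_never_increases_and_idempotent(self):
        rng = np.random.default_rng(2)
        values = rng.gamma(2.0, size=50)
        once = winsorize_mean(ms(values), z_w=5)
        assert np.all(once.mu <= values)
        twice = winsorize_mean(once, z_w=5)
        np.testing.assert_array_equal(once.mu, twice.mu)

    def test_out_of_range_rank(self):
        with pytest.raises(ValueError):
            winsorize_mean(ms([1.0, 2.0]), z_w=3)


class TestDetectPeaks:
    def test_threshold_filters_lower_maximum(self):
        ps = detect_peaks(ms([0.0, 1.0, 0.0, 5.0, 0.0]), z_t=2.0)
        assert len(ps) == 1 and ps.peaks[0].apex == 4

    def test_lower_threshold_keeps_both(self):
        ps = detect_peaks(ms([0.0, 1.0, 0.0, 5.0, 0.0]), z_t=0.5)
        assert [p.apex for p in ps.peaks] == [2, 4]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        values = np.round(rng.gamma(2.0, size=120), 2)
        lo = detect_peaks(ms(values), z_t=1.0)
        hi = detect_peaks(ms(values), z_t=2.5)
        assert set(hi.apex_channels()) <= set(lo.apex_channels())

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        values=st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=60),
        z_lo=st.integers(min_value=0, max_value=20),
        z_gap=st.integers(min_value=1, max_value=20),
    )
    def test_threshold_monotonicity_property(self, values, z_lo, z_gap):
        # integer intensities exercise plateaus; higher threshold -> subset
        mu = ms(np.asarray(values, dtype=float))
        lo = detect_peaks(mu, float(z_lo))
        hi = detect_peaks(mu, float(z_lo + z_gap))
        assert set(hi.apex_channels()) <= set(lo.apex_channels())
        got = [(p.l, p.apex, p.r) for p in lo.peaks]
        assert got == brute_force_peaks(np.asarray(values, float), float(z_lo))

    def test_matches_oracle_on_random_spectra(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            values = np.round(rng.gamma(2.0, size=80), 1)  # ties exercise plateaus
            z_t = float(np.percentile(values, 60))
            got = [(p.l, p.apex, p.r) for p in detect_peaks(ms(values), z_t).peaks]
            assert got == brute_force_peaks(values, z_t)


class TestPeakExtent:
    def test_half_height_run(self):
        mu = ms([1.0, 4.0, 6.0, 10.0, 7.0, 4.0, 2.0])
        assert peak_extent(mu, apex=4) == (3, 4, 5)

    def test_isolated_spike(self):
        assert peak_extent(ms([0.0, 10.0, 0.0]), apex=2) == (2, 2, 2)

    def test_even_run_takes_lower_middle(self):
        mu = ms([10.0, 9.0, 8.0, 6.0, 1.0])  # run channels 1..4
        l, v, r = peak_extent(mu, apex=1)
        assert (l, r) == (1, 4)
        assert v == 2  # lower middle of {1,2,3,4}


class TestPeakIntensity:
    def test_hand_sum(self):
        spectrum = np.array([1.0, 4.0, 6.0, 10.0, 7.0, 4.0, 2.0])
        peak = Peak(l=3, r=5, v=4, apex=4, mz_v=103.0, height=10.0)
        assert peak_intensity(spectrum, peak) == 6.0 + 10.0 + 7.0

    def test_zero_spectrum(self):
        peak = Peak(l=1, r=3, v=2, apex=2, mz_v=101.0, height=1.0)
        assert peak_intensity(np.zeros(5), peak) == 0.0

    def test_single_channel_peak(self):
        peak = Peak(l=2, r=2, v=2, apex=2, mz_v=101.0, height=1.0)
        assert peak_intensity(np.array([3.0, 7.0, 1.0]), peak) == 7.0


class TestReduceToPeaks:
    def test_disjoint_partition_conserves_tic(self):
        rng = np.random.default_rng(9)
        ds = make_dataset(rng.gamma(2.0, size=(5, 6)))
        peaks = [
            Peak(l=1, r=3, v=2, apex=2, mz_v=float(ds.mz[1]), height=1.0),
            Peak(l=4, r=6, v=5, apex=5, mz_v=float(ds.mz[4]), height=1.0),
        ]
        out = reduce_to_peaks(ds, PeakSet(peaks=peaks, z_t=0.0))
        np.testing.assert_allclose(
            out.intensities.sum(axis=1),
            ds.intensities.astype(np.float64).sum(axis=1),
            rtol=1e-6,
        )

    def test_matches_per_pixel_bruteforce(self, small_phantom):
        ds, _ = small_phantom
        mu = mean_spectrum(ds)
        ps = detect_peaks(mu, z_t=float(np.percentile(mu.mu, 90)))
        assert len(ps) > 0
        out = reduce_to_peaks(ds, ps)
        assert out.n_channels == len(ps)
        for row in [0, 17]:
            for k, p in enumerate(ps.peaks):
                expected = float(
                    ds.intensities[row, p.l - 1 : p.r].astype(np.float64).sum()
                )
                assert abs(out.intensities[row, k] - expected) <= 1e-3 * max(expected, 1)

    def test_empty_peakset_raises(self):
        ds = make_dataset([[1.0, 2.0]])
        with pytest.raises(ValueError):
            reduce_to_peaks(ds, PeakSet(peaks=[], z_t=0.0))


def _peak(mz_v, height, channel=None):
    # place each synthetic peak on its own channel so extents stay disjoint
    c = channel if channel is not None else int(round((mz_v - 499.0) * 100))
    return Peak(l=c, r=c, v=c, apex=c, mz_v=mz_v, height=height)


class TestDeisotope:
    def test_removes_satellite_one_spacing_up(self):
        ps = PeakSet(peaks=[_peak(500.000, 100.0), _peak(501.003, 40.0)], z_t=0.0)
        out = deisotope(ps, tol=0.01)
        assert [p.mz_v for p in out.peaks] == [500.000]

    def test_equal_height_tie_keeps_lower_mass(self):
        ps = PeakSet(peaks=[_peak(500.000, 50.0), _peak(501.003, 50.0)], z_t=0.0)
        out = deisotope(ps, tol=0.01)
        assert [p.mz_v for p in out.peaks] == [500.000]

    def test_no_peaks_within_spacing_is_identity(self):
        ps = PeakSet(peaks=[_peak(500.0, 10.0), _peak(505.0, 20.0)], z_t=0.0)
        out = deisotope(ps, tol=0.01)
        assert len(out) == 2

    def test_higher_satellite_shields_monoisotopic(self):
        # the satellite outranks a *different* lower peak but cannot remove
        # an already-kept higher peak below it
        ps = PeakSet(
            peaks=[_peak(500.000, 100.0), _peak(501.003, 40.0), _peak(502.006, 10.0)],
            z_t=0.0,
        )
        out = deisotope(ps, tol=0.01, max_iso=3)
        assert [p.mz_v for p in out.peaks] == [500.000]

    def test_recovers_planted_monoisotopic_channels(self, small_phantom):
        # threshold between the noise floor and the weakest planted signal
        ds, truth = small_phantom
        mu = mean_spectrum(ds)
        ps = detect_peaks(mu, z_t=0.8)
        out = deisotope(ps, tol=0.15)
        planted_mono = sorted(
            truth.matrix_peak_channels
            + [c for group in truth.region_peak_channels for c in group]
        )
        mono_mz = set(np.round(ds.mz[np.array(planted_mono) - 1], 3))
        surviving = {round(p.mz_v, 3) for p in out.peaks}
        # satellites sit 1.00335 Da above planted channels and must be gone
        sat_mz = {
            round(m + 1.0, 1) for m in mono_mz
        }
        assert not any(round(p.mz_v, 1) in sat_mz for p in out.peaks)
        assert mono_mz <= surviving
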