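import numpy as np
import pytest

from icpshape.core import Recording, Subsequence
from icpshape.segmentation import (
    Extremum,
    FilterSpec,
    SegmentationParams,
    design_lowpass,
    find_extrema,
    prune_minima,
    segment,
    segment_recording,
    smooth,
    znormalize,
)


class TestSmooth:
    def test_dc_preserved(self):
        rec = Recording(np.full(12_000, 10.0), fs=10.0)
        out = smooth(rec, FilterSpec())
        ripple = 10 ** (0.001 / 20) - 1
        assert np.max(np.abs(out.samples - 10.0)) <= 10.0 * ripple * 1.01

    def test_cardiac_tone_strongly_attenuated(self):
        # same design code path at fs=10 Hz keeps the filter short
        fs = 10.0
        t = np.arange(int(1800 * fs)) / fs
        rec = Recording(np.sin(2 * np.pi * 1.1 * t), fs=fs)
        out = smooth(rec, FilterSpec(f_pass=0.05, f_stop=0.1))
        core = slice(rec.n_samples // 3, 2 * rec.n_samples // 3)
        atten = np.sqrt(np.mean(out.samples[core] ** 2)) / np.sqrt(np.mean(rec.samples[core] ** 2))
        assert 20 * np.log10(atten) <= -60

    def test_length_preserved_and_aligned(self):
        fs = 10.0
        t = np.arange(int(3600 * fs)) / fs
        x = np.sin(2 * np.pi * t / 900)  # deep-passband tone
        out = smooth(Recording(x, fs=fs), FilterSpec())
        assert out.n_samples == x.size
        core = slice(x.size // 4, 3 * x.size // 4)
        # group-delay compensated: peak positions unchanged
        assert np.max(np.abs(out.samples[core] - x[core])) < 0.01

    def test_invalid_band(self):
        rec = Recording(np.zeros(100), fs=100.0)
        with pytest.raises(ValueError):
            smooth(rec, FilterSpec(f_pass=0.2, f_stop=0.1))

    def test_recording_shorter_than_filter(self):
        rec = Recording(np.zeros(100), fs=100.0)
        with pytest.raises(ValueError, match="taps"):
            smooth(rec, FilterSpec())


class TestFindExtrema:
    def test_single_period_sinusoid(self):
        t = np.linspace(0, 1, 1000, endpoint=False)
        x = np.sin(2 * np.pi * t)
        ext = find_extrema(x)
        kinds = [e.kind for e in ext]
        assert kinds == ["max", "min"]
        assert abs(ext[0].index - 250) <= 1
        assert abs(ext[1].index - 750) <= 1

    def test_alternation_and_neighbor_property(self, rng):
        x = np.cumsum(rng.normal(size=500))
        ext = find_extrema(x)
        for a, b in zip(ext, ext[1:]):
            assert a.kind != b.kind
        for e in ext:
            if e.kind == "min":
                assert x[e.index - 1] >= x[e.index] and x[e.index + 1] >= x[e.index]

    def test_plateau_first_sample_wins(self):
        x = np.array([0.0, 1.0, 1.0, 1.0, 0.0, -1.0, -1.0, 0.0])
        ext = find_extrema(x)
        assert (ext[0].index, ext[0].kind) == (1, "max")
        assert (ext[1].index, ext[1].kind) == (5, "min")

    def test_monotone_warns_empty(self):
        with pytest.warns(UserWarning):
            assert find_extrema(np.arange(10.0)) == []


class TestPruneMinima:
    def _ext(self, triples):
        return [Extremum(i, v, k) for i, v, k in triples]

    def test_duration_rule_removes(self):
        # min at t=0 s, max at t=20 s, eta_dur = 1 min
        fs = 1.0
        ext = self._ext([(0, 10.0, "min"), (20, 14.0, "max"), (200, 9.0, "min")])
        b = prune_minima(ext, SegmentationParams(eta_dur=1.0, eta_mag=0.5), fs,
                         n_samples=1000)
        assert 0 not in b[1:-1] or 0 == b[0]
        assert 200 in b

    def test_magnitude_rule_removes(self):
        fs = 1.0
        ext = self._ext([(100, 10.0, "min"), (400, 10.3, "max"), (900, 9.0, "min")])
        b = prune_minima(ext, SegmentationParams(eta_dur=1.0, eta_mag=0.5), fs,
                         n_samples=2000)
        assert 100 not in b
        assert 900 in b

    def test_wide_gaps_kept(self):
        fs = 1.0
        ext = self._ext([(400, 10.0, "min"), (700, 14.0, "max"), (1200, 9.5, "min")])
        b = prune_minima(ext, SegmentationParams(eta_dur=1.0, eta_mag=1.0), fs,
                         n_samples=2000)
        assert 400 in b and 1200 in b

    def test_endpoints_always_present(self):
        with pytest.warns(UserWarning, match="no surviving minima"):
            b = prune_minima([], SegmentationParams(), 100.0, n_samples=500)
        assert list(b) == [0, 499]

    def test_merge_keeps_larger_max(self):
        # removing the middle minimum merges its flanking maxima; the
        # surviving (larger) one then governs the next candidate
        fs = 1.0
        ext = self._ext([
            (100, 5.0, "min"), (200, 9.0, "max"), (230, 8.9, "min"),
            (300, 7.0, "max"), (700, 5.0, "min"),
        ])
        params = SegmentationParams(eta_dur=1.0, eta_mag=0.5)
        b = prune_minima(ext, params, fs, n_samples=1000)
        assert 230 not in b  # duration rule vs the max at 200 (30 s < 1 min)
        assert 100 in b and 700 in b  # survivors judged against the merged max


class TestSegmentAndZnorm:
    def test_boundary_pairs(self, short_recording):
        subs = segment(short_recording, [0, 100, 250])
        assert [(s.i, s.j) for s in subs] == [(0, 100), (100, 250)]
        assert subs[0].raw.size == 101
        # shared boundary sample
        assert subs[0].raw[-1] == subs[1].raw[0]

    def test_tiling_telescopes(self, short_recording):
        bounds = [0, 37, 501, 1203, short_recording.n_samples - 1]
        subs = segment(short_recording, bounds)
        assert sum(s.j - s.i for s in subs) == bounds[-1] - bounds[0]

    def test_too_few_boundaries(self, short_recording):
        with pytest.raises(ValueError):
            segment(short_recording, [5])

    def test_znormalize_hand_case(self):
        sub = Subsequence("r", 0, 2, np.array([1.0, 2.0, 3.0]), fs=1.0)
        znormalize(sub)
        assert np.allclose(sub.z, [-1.22474487, 0.0, 1.22474487], atol=1e-8)
        assert sub.mu == pytest.approx(2.0)
        assert sub.sigma == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_znormalize_centering_and_scale(self, rng):
        raw = rng.normal(5, 3, 400)
        sub = znormalize(Subsequence("r", 0, 399, raw, fs=1.0))
        assert abs(sub.z.mean()) < 1e-9
        assert abs(sub.z.std() - 1) < 1e-9

    def test_degenerate_constant_flagged(self):
        sub = znormalize(Subsequence("r", 0, 2, np.array([5.0, 5.0, 5.0]), fs=1.0))
        assert sub.degenerate
        assert sub.z is None

    def test_scale_translation_invariance(self, rng):
        raw = rng.normal(size=256)
        a = znormalize(Subsequence("r", 0, 255, raw, fs=1.0))
        b = znormalize(Subsequence("r", 0, 255, 3.7 * raw + 11.0, fs=1.0))
        assert np.allclose(a.z, b.z, atol=1e-9)


class TestRoundTrip:
    def test_noiseless_boundaries_recovered(self, clean_three_segment):
        rec, gt = clean_three_segment
        subs, bounds, smoothed = segment_recording(
            rec, FilterSpec(), SegmentationParams(eta_dur=0.5, eta_mag=0.5)
        )
        taps = design_lowpass(rec.fs, FilterSpec())
        tol = taps.size // 2  # group delay in samples
        for b in gt.boundaries:
            assert np.min(np.abs(bounds - b)) <= tol
        # tiling is exact
        assert bounds[0] == 0 and bounds[-1] == rec.n_samples - 1
        assert sum(s.j - s.i for s in subs) == rec.n_samples - 1

    def test_pruning_monotone_in_thresholds(self, clean_three_segment):
        rec, _ = clean_three_segment
        smoothed = smooth(rec, FilterSpec())
        ext = find_extrema(smoothed)
        counts_dur = []
        for eta_dur in (0.25, 0.5, 1.0, 2.0):
            b = prune_minima(ext, SegmentationParams(eta_dur=eta_dur, eta_mag=0.5),
                             rec.fs, n_samples=rec.n_samples)
            counts_dur.append(len(b))
        assert counts_dur == sorted(counts_dur, reverse=True)
        counts_mag = []
        for eta_mag in (0.25, 0.5, 1.0, 2.0):
            b = prune_minima(ext, SegmentationParams(eta_dur=0.5, eta_mag=eta_mag),
                             rec.fs, n_samples=rec.n_samples)
            counts_mag.append(len(b))
        assert counts_mag == sorted(counts_mag, reverse=True)
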