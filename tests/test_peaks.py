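"""Peak/boundary overlap, metagene profiles, boundary-associated calls."""

import numpy as np
import pytest

import boundarykit as bk
from boundarykit.peaks import PeakSet
from boundarykit.tads import TAD, Boundary


def mk_bounds(bins, bs=10_000):
    return [Boundary("chrS", int(b), bs) for b in bins]


def mk_tads(edges, bs=10_000):
    return [TAD("chrS", s, e, bs) for s, e in zip(edges[:-1], edges[1:])]


def brute_assign(intervals, bounds, tads, flank, bs=10_000):
    """Quadratic-scan oracle for peak category assignment."""
    cats = []
    for s, e in intervals:
        on_b = any(s < (b.bin + 1) * bs + flank and e > b.bin * bs - flank
                   for b in bounds)
        in_t = any(s < t.end_bin * bs and e > t.start_bin * bs for t in tads)
        cats.append("boundary" if on_b else ("tad" if in_t else "gap"))
    return cats


class TestAssignPeaks:
    def test_no_peaks(self):
        ps = PeakSet("f", np.empty((0, 2), dtype=int), np.empty(0, dtype=int))
        st = bk.assign_peaks(ps, mk_bounds([5]), mk_tads([0, 5, 10]))
        assert st.boundary_fraction == 0.0
        assert not st.boundary_flags.any()

    def test_all_peaks_in_one_boundary_bin(self):
        iv = np.array([[50_000 + k * 100, 50_000 + k * 100 + 50] for k in range(10)])
        ps = PeakSet("f", iv, iv[:, 0])
        st = bk.assign_peaks(ps, mk_bounds([5]), mk_tads([0, 5, 10]))
        assert st.boundary_fraction == 1.0
        assert st.boundary_flags.tolist() == [True]

    def test_fractions_sum_to_one(self, rng):
        iv = np.sort(rng.integers(0, 990_000, size=(200, 1)), axis=0)
        iv = np.hstack([iv, iv + rng.integers(100, 5000, size=(200, 1))])
        ps = PeakSet("f", iv, iv[:, 0])
        bounds = mk_bounds([10, 40, 70])
        tads = mk_tads([0, 10, 40, 70, 100])
        st = bk.assign_peaks(ps, bounds, tads)
        assert st.boundary_fraction + st.intra_tad_fraction + st.gap_fraction \
            == pytest.approx(1.0)

    @pytest.mark.parametrize("flank", [0, 5000])
    def test_matches_brute_force(self, rng, flank):
        starts = rng.integers(0, 495_000, size=500)
        iv = np.stack([starts, starts + rng.integers(50, 8000, size=500)], axis=1)
        ps = PeakSet("f", iv, starts)
        bins = np.sort(rng.choice(np.arange(1, 50), size=30, replace=False))
        bounds = mk_bounds(bins)
        tads = mk_tads([0, *bins.tolist(), 50])
        st = bk.assign_peaks(ps, bounds, tads, flank=flank)
        cats = brute_assign(iv, bounds, tads, flank)
        assert st.boundary_fraction == pytest.approx(cats.count("boundary") / 500)
        assert st.intra_tad_fraction == pytest.approx(cats.count("tad") / 500)
        for k, b in enumerate(bounds):
            expect = any(
                s < (b.bin + 1) * 10_000 + flank and e > b.bin * 10_000 - flank
                for s, e in iv)
            assert st.boundary_flags[k] == expect

    def test_chrom_mismatch_rejected(self):
        ps = PeakSet("f", np.array([[0, 100]]), np.array([0]), chrom="chr2")
        with pytest.raises(ValueError, match="chr"):
            bk.assign_peaks(ps, mk_bounds([5]), mk_tads([0, 5, 10]))


class TestMetageneProfile:
    def test_constant_track_rpm(self):
        track = np.full(100, 3.0)
        prof = bk.metagene_profile(track, np.array([50]), 10)
        assert np.allclose(prof, 3.0 * 1e6 / 300.0)

    def test_single_anchor_identity(self, rng):
        track = rng.poisson(5.0, size=200).astype(float)
        prof = bk.metagene_profile(track, np.array([100]), 7)
        scale = 1e6 / track.sum()
        assert np.allclose(prof, track[93:108] * scale)

    def test_truncated_windows_dropped(self, rng):
        track = rng.poisson(5.0, size=100).astype(float)
        p_all = bk.metagene_profile(track, np.array([2, 50]), 10)
        p_mid = bk.metagene_profile(track, np.array([50]), 10)
        assert np.allclose(p_all, p_mid)  # anchor at 2 is truncated, dropped
        with pytest.raises(ValueError):
            bk.metagene_profile(track, np.array([2]), 10)

    def test_boundary_enriched_track_ratio(self, small_sim):
        """Centre/edge profile ratio recovers amplitude/background."""
        _, arch, _ = small_sim
        targets = np.stack([arch.true_boundaries, arch.true_boundaries + 1], axis=1)
        track = bk.simulate_signal_track(arch, targets, 12.0, 2.0, seed=8)
        prof = bk.metagene_profile(track, arch.true_boundaries, 20)
        ratio = prof[20] / np.mean([prof[:5].mean(), prof[-5:].mean()])
        assert ratio == pytest.approx(6.0, rel=0.35)


class TestClassifyBA:
    def test_uniform_profile_not_ba(self):
        flag, ratio = bk.classify_ba(np.full(51, 2.0))
        assert ratio == pytest.approx(1.0)
        assert flag is False

    def test_zero_flank_warns(self):
        prof = np.zeros(51)
        prof[25] = 5.0
        with pytest.warns(UserWarning):
            flag, ratio = bk.classify_ba(prof)
        assert flag is None and np.isnan(ratio)

    def test_designed_separation(self, small_sim):
        """3x boundary-enriched factor is flagged; 1x (flat) factor is not."""
        _, arch, _ = small_sim
        targets = np.stack([arch.true_boundaries, arch.true_boundaries + 1], axis=1)
        enriched = bk.simulate_signal_track(arch, targets, 9.0, 3.0, seed=21,
                                            name="enriched")
        flat = bk.simulate_signal_track(arch, targets, 3.0, 3.0, seed=22,
                                        name="flat")
        anchors = arch.true_boundaries
        f1, r1 = bk.classify_ba(bk.metagene_profile(enriched, anchors, 25), 1.2)
        f2, r2 = bk.classify_ba(bk.metagene_profile(flat, anchors, 25), 1.2)
        assert f1 is True and r1 > 1.2
        assert f2 is False

    def test_monotone_in_boundary_fraction(self, small_sim):
        """More boundary placement never lowers the enrichment ratio call."""
        _, arch, _ = small_sim
        ratios = []
        for frac in (0.0, 0.3, 0.6, 0.9):
            spec = bk.FactorSpec("f", n_peaks=300, boundary_fraction=frac)
            peaks = bk.simulate_peaks(arch, [spec], seed=31)["f"]
            cov = np.zeros(arch.n_bins)
            np.add.at(cov, peaks[:, 2] // arch.config.bin_size, 1.0)
            prof = bk.metagene_profile(cov, arch.true_boundaries, 25)
            ratios.append(bk.classify_ba(prof, 1.2)[1])
        assert all(a < b for a, b in zip(ratios, ratios[1:]))


class TestBoundaryGroups:
    def test_factor_everywhere_ctcf_nowhere(self):
        g = bk.boundary_groups(np.zeros(6, bool), np.ones(6, bool))
        assert g["proportions"]["-CTCF+f"] == 1.0

    def test_toy_counts(self):
        anchor = np.array([1, 1, 0, 0, 1, 0], bool)
        test = np.array([1, 0, 1, 0, 0, 1], bool)
        g = bk.boundary_groups(anchor, test)
        assert g["sizes"] == {"+CTCF+f": 1, "+CTCF-f": 2, "-CTCF+f": 2, "-CTCF-f": 1}

    def test_designed_ctcf_independent_factor(self):
        """The +f vs -f insulation difference is confined to the -CTCF
        stratum when the factor only deepens CTCF-free boundaries."""
        rng = np.random.default_rng(5)
        n = 120
        anchor = rng.random(n) < 0.5
        test = rng.random(n) < 0.5
        iss = rng.normal(1.0, 0.1, n)
        iss[anchor] += 1.0               # CTCF dominates where present
        iss[~anchor & test] += 0.8       # factor matters only without CTCF
        g = bk.boundary_groups(anchor, test, insulation=iss)
        assert g["IS_tests"]["-CTCF"]["q"] < 0.01
        assert g["IS_tests"]["+CTCF"]["q"] > 0.05


class TestIntervalOverlap:
    def test_subset_is_one(self):
        a = np.array([[10, 20], [30, 40]])
        b = np.array([[0, 100]])
        assert bk.interval_overlap_fraction(a, b)["a_in_b"] == 1.0

    def test_disjoint_zero(self):
        a = np.array([[10, 20]])
        b = np.array([[20, 30]])  # half-open: no shared bp
        assert bk.interval_overlap_fraction(a, b)["a_in_b"] == 0.0

    def test_matches_brute_force(self, rng):
        def sample():
            s = rng.integers(0, 100_000, size=300)
            return np.stack([s, s + rng.integers(1, 500, size=300)], axis=1)
        a, b = sample(), sample()
        got = bk.interval_overlap_fraction(a, b)
        brute_ab = np.mean([
            any(s < be and e > bs for bs, be in b) for s, e in a])
        brute_ba = np.mean([
            any(s < ae and e > as_ for as_, ae in a) for s, e in b])
        assert got["a_in_b"] == pytest.approx(brute_ab)
        assert got["b_in_a"] == pytest.approx(brute_ba)


class TestRankFactors:
    def prof(self, center):
        p = np.ones(11)
        p[5] = center
        return p

    def stat(self, name, center):
        s = bk.FactorBoundaryStats(name, 1, 0, 0, 0, np.zeros(1, bool))
        s.profile = self.prof(center)
        return s

    def test_single_factor(self):
        assert bk.rank_factors({"x": self.stat("x", 2.0)}) == ["x"]

    def test_ties_alphabetical(self):
        stats = {n: self.stat(n, 3.0) for n in ("b", "a", "c")}
        assert bk.rank_factors(stats) == ["a", "b", "c"]

    def test_designed_amplitudes(self, small_sim):
        _, arch, _ = small_sim
        targets = np.stack([arch.true_boundaries, arch.true_boundaries + 1], axis=1)
        stats = {}
        for name, amp, seed in (("low", 2.0, 41), ("mid", 4.0, 42), ("high", 6.0, 43)):
            track = bk.simulate_signal_track(arch, targets, amp, 0.5, seed=seed,
                                             name=name)
            s = bk.FactorBoundaryStats(name, 1, 0, 0, 0, np.zeros(1, bool))
            s.profile = bk.metagene_profile(track, arch.true_boundaries, 20)
            stats[name] = s
        assert bk.rank_factors(stats) == ["high", "mid", "low"]
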