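"""Boundary detection, insulation score, domain score, TAD comparison."""

import numpy as np
import pytest

import boundarykit as bk
from boundarykit.tads import (
    TAD,
    Boundary,
    BinSignalTrack,
    classify_tad,
)


def brute_bin_signal(arr, w):
    n = arr.shape[0]
    out = np.full(n, np.nan)
    for i in range(w - 1, n - w):
        vals = []
        for r in range(i - w + 1, i + 1):
            for c in range(i + 1, i + w + 1):
                vals.append(arr[r, c])
        out[i] = np.mean(vals)
    return out


class TestBinSignal:
    def test_constant_matrix(self):
        sig = bk.bin_signal(np.full((30, 30), 4.0), w=3)
        inner = sig.values[5:-5]
        assert np.allclose(inner, 4.0)

    def test_zero_junction_between_blocks(self):
        n = 20
        a = np.zeros((n, n))
        a[:10, :10] = 1.0
        a[10:, 10:] = 1.0
        sig = bk.bin_signal(a, w=3)
        assert sig.values[9] == 0.0  # rectangle straddling the junction

    def test_matches_brute_force(self, rng):
        a = rng.poisson(8.0, size=(50, 50)).astype(float)
        a = np.triu(a) + np.triu(a, 1).T
        sig = bk.bin_signal(a, w=5)
        brute = brute_bin_signal(a, 5)
        assert np.allclose(sig.values, brute, equal_nan=True)

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError):
            bk.bin_signal(np.ones((10, 10)), w=5)


def call(oe, w=5, **kw):
    sig = bk.bin_signal(oe, w=w)
    return sig, *bk.detect_boundaries(sig, oe, **kw)


def oe_of(m):
    bal = bk.ice_balance(m)
    return bk.observed_over_expected(bal, bk.expected_by_distance(bal))


class TestDetectBoundaries:
    def test_uniform_matrix_no_boundaries(self):
        with pytest.warns(UserWarning):
            _, bounds, tads = call(np.ones((60, 60)))
        assert bounds == []
        assert len(tads) == 1 and tads[0].n_bins == 60

    def test_single_planted_boundary_recovered(self):
        cfg = bk.SimulationConfig(n_bins=100, tad_size_range=(50, 50),
                                  insulation_depths=(0.1,), depth=1e6, seed=4)
        arch = bk.plant_architecture(cfg)
        _, bounds, tads = call(oe_of(bk.simulate_contact_map(arch)),
                               chrom="chrS", bin_size=10_000)
        assert len(bounds) == 1
        assert abs(bounds[0].bin - 50) <= 1
        assert [t.n_bins for t in tads] == [bounds[0].bin, 100 - bounds[0].bin]

    def test_tads_tile_chromosome(self, called_tads):
        _, bounds, tads = called_tads
        edges = [tads[0].start_bin] + [t.end_bin for t in tads]
        assert edges[0] == 0 and edges[-1] == 300
        for a, b in zip(tads, tads[1:]):
            assert a.end_bin == b.start_bin
        assert sorted(b.bin for b in bounds) == [t.start_bin for t in tads[1:]]

    def test_min_size_enforced(self, called_tads):
        _, _, tads = called_tads
        assert min(t.n_bins for t in tads) >= 3

    def test_qvalues_bounded(self, called_tads):
        _, bounds, _ = called_tads
        for b in bounds:
            assert 0 <= b.pvalue <= 1 and 0 <= b.qvalue <= 1


class TestInsulationScore:
    def track(self, vals, w=5):
        return BinSignalTrack(values=np.asarray(vals, dtype=float), window_w=w)

    def setup_pair(self, n=40, b=20):
        tads = [TAD("c", 0, b, 10_000), TAD("c", b, n, 10_000)]
        bounds = [Boundary("c", b, 10_000)]
        return bounds, tads

    def test_constant_signal_zero(self):
        bounds, tads = self.setup_pair()
        iss = bk.insulation_score(self.track(np.full(40, 2.0)), bounds, tads)
        assert iss[0] == 0.0

    def test_single_dip_depth(self):
        vals = np.full(40, 5.0)
        vals[19] = 5.0 - 1.7  # dip at the boundary bin edge
        bounds, tads = self.setup_pair()
        iss = bk.insulation_score(self.track(vals), bounds, tads)
        assert iss[0] == pytest.approx(1.7)

    def test_edge_boundary_nan(self):
        bounds = [Boundary("c", 0, 10_000)]
        tads = [TAD("c", 0, 40, 10_000)]
        iss = bk.insulation_score(self.track(np.ones(40)), bounds, tads)
        assert np.isnan(iss[0])

    def test_monotone_in_planted_depth(self):
        """Deeper planted insulation (lower depth) gives higher scores:
        Spearman |rho| between (1 - depth) and IS >= 0.8 over the sweep."""
        from scipy.stats import spearmanr
        depths, scores = [], []
        for k, depth in enumerate(np.arange(0.1, 0.95, 0.1)):
            cfg = bk.SimulationConfig(n_bins=200, tad_size_range=(100, 100),
                                      insulation_depths=(float(depth),),
                                      depth=2e6, seed=100 + k)
            arch = bk.plant_architecture(cfg)
            oe = oe_of(bk.simulate_contact_map(arch))
            sig = bk.bin_signal(oe, w=5)
            b = arch.true_boundaries[0]
            tads = [TAD("c", 0, b, 10_000), TAD("c", b, 200, 10_000)]
            bounds = [Boundary("c", int(b), 10_000)]
            iss = bk.insulation_score(sig, bounds, tads)
            depths.append(1.0 - depth)
            scores.append(iss[0])
        rho = spearmanr(depths, scores).statistic
        assert abs(rho) >= 0.8 and rho > 0


def brute_domain_score(arr, s, e):
    intra = 0.0
    total = 0.0
    n = arr.shape[0]
    for i in range(s, e):
        for j in range(n):
            if j < i and s <= j < e:
                continue  # symmetric intra pair counted once
            v = arr[i, j]
            total += v
            if s <= j < e:
                intra += v
    return intra / total if total else np.nan


class TestDomainScore:
    def test_isolated_block_is_one(self):
        a = np.zeros((20, 20))
        a[:10, :10] = 2.0
        assert bk.domain_score(a, (0, 10)) == 1.0

    def test_zero_intra_is_zero(self):
        a = np.ones((20, 20))
        a[5:10, 5:10] = 0.0
        assert bk.domain_score(a, (5, 10)) == 0.0

    def test_no_contacts_nan(self):
        assert np.isnan(bk.domain_score(np.zeros((10, 10)), (2, 5)))

    def test_brute_force_all_intervals(self, rng):
        a = rng.poisson(3.0, size=(30, 30)).astype(float)
        a = np.triu(a) + np.triu(a, 1).T
        for s in range(0, 28, 3):
            for e in range(s + 2, 30, 4):
                assert bk.domain_score(a, (s, e)) == pytest.approx(
                    brute_domain_score(a, s, e))

    def test_in_zero_one(self, small_oe, called_tads):
        bal, _ = small_oe
        _, _, tads = called_tads
        for t in tads:
            d = bk.domain_score(bal, t)
            assert 0.0 <= d <= 1.0


def brute_classify(a, a_all, b_all, tol=10_000, ro=0.8, dis=0.2):
    """Independent re-statement of the classification rules."""
    def ov(x, y):
        return max(0, min(x[1], y[1]) - max(x[0], y[0]))

    la = a[1] - a[0]
    if any(abs(a[0] - b[0]) <= tol and abs(a[1] - b[1]) <= tol
           and ov(a, b) / la > ro and ov(a, b) / (b[1] - b[0]) > ro
           for b in b_all):
        return "invariant"
    for b in b_all:
        if (b[1] - b[0]) > la and ov(a, b) / la > ro:
            if any(o != a and ov(o, b) / (o[1] - o[0]) > ro for o in a_all):
                return "merged"
    if sum(ov(a, b) / (b[1] - b[0]) > ro for b in b_all) >= 2:
        return "split"
    if max((ov(a, b) / la for b in b_all), default=0.0) <= dis:
        return "disappeared"
    return "rearranged"


def tadify(intervals):
    return [TAD("c", s // 10_000, e // 10_000, 10_000) for s, e in intervals]


class TestCompareTadSets:
    def test_identity_all_invariant(self):
        iv = [(0, 500_000), (500_000, 1_200_000), (1_200_000, 2_000_000)]
        cmp_ = bk.compare_tad_sets(tadify(iv), tadify(iv))
        assert cmp_.tad_class == ["invariant"] * 3
        assert cmp_.boundary_class == ["conserved"] * 2

    def test_fusion_case(self):
        a = [(0, 500_000), (500_000, 1_000_000)]
        b = [(0, 1_000_000)]
        cmp_ = bk.compare_tad_sets(tadify(a), tadify(b))
        assert cmp_.tad_class == ["merged", "merged"]
        assert cmp_.boundary_class == ["disappeared"]

    def test_fission_case(self):
        a = [(0, 1_000_000), (1_000_000, 1_500_000)]
        b = [(0, 500_000), (500_000, 1_000_000), (1_000_000, 1_500_000)]
        cmp_ = bk.compare_tad_sets(tadify(a), tadify(b))
        assert cmp_.tad_class[0] == "split"

    def test_empty_b_all_disappeared(self):
        a = [(0, 500_000), (500_000, 1_000_000)]
        with pytest.warns(UserWarning):
            cmp_ = bk.compare_tad_sets(tadify(a), [])
        assert cmp_.tad_class == ["disappeared"] * 2

    def test_random_perturbations_match_dual_classifier(self, rng):
        """200 randomized jitter/fusion/fission/deletion cases agree with an
        independently coded brute-force classifier."""
        bs = 10_000
        for _ in range(200):
            edges = np.cumsum(rng.integers(5, 15, size=6)) * bs
            edges = np.concatenate([[0], edges])
            a_iv = list(zip(edges[:-1].tolist(), edges[1:].tolist()))
            mode = rng.choice(["jitter", "fusion", "fission", "deletion"])
            if mode == "jitter":
                b_edges = edges.copy()
                b_edges[1:-1] += rng.integers(-2, 3, size=len(edges) - 2) * bs
                b_edges = np.unique(np.sort(b_edges))
            elif mode == "fusion":
                k = rng.integers(1, len(edges) - 1)
                b_edges = np.delete(edges, k)
            elif mode == "fission":
                k = rng.integers(0, len(a_iv))
                s, e = a_iv[k]
                if e - s >= 4 * bs:
                    mid = (s + e) // 2 // bs * bs
                    b_edges = np.sort(np.append(edges, mid))
                else:
                    b_edges = edges
            else:  # deletion: drop a whole TAD from B's coverage
                k = rng.integers(0, len(a_iv))
                b_edges = edges.copy()
                b_iv = [iv for i, iv in enumerate(a_iv) if i != k]
                b_edges = None
            if b_edges is not None:
                b_iv = list(zip(b_edges[:-1].tolist(), b_edges[1:].tolist()))
            b_iv = [iv for iv in b_iv if iv[1] > iv[0]]
            got = bk.compare_tad_sets(tadify(a_iv), tadify(b_iv)).tad_class
            want = [brute_classify(a, a_iv, b_iv) for a in a_iv]
            assert got == want

    def test_planted_boundary_ablation_fraction(self, rng):
        """Removing 40% of boundaries is reported as ~40% disappeared."""
        edges = np.concatenate([[0], np.cumsum(rng.integers(8, 15, size=50))]) * 10_000
        a_iv = list(zip(edges[:-1].tolist(), edges[1:].tolist()))
        internal = np.arange(1, len(edges) - 1)
        drop = rng.choice(internal, size=20, replace=False)
        b_edges = np.delete(edges, drop)
        b_iv = list(zip(b_edges[:-1].tolist(), b_edges[1:].tolist()))
        cmp_ = bk.compare_tad_sets(tadify(a_iv), tadify(b_iv))
        assert cmp_.disappeared_boundary_fraction == pytest.approx(0.4, abs=0.02)
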