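"""TopDom-style TAD boundary detection, insulation and domain scores.

For every 10-kb bin a *bin signal* is computed: the mean contact value of
the w x w rectangle of bin pairs straddling the edge just downstream of
the bin.  Boundaries sit at local minima of this curve; each candidate is
kept only if the contacts within the two flanking domains stochastically
dominate the cross-boundary contacts (one-sided Wilcoxon rank-sum,
Benjamini-Hochberg corrected), which filters dips that are not backed by
local interaction aggregation.  Surviving boundaries tile the chromosome
into TADs.

The insulation score of a boundary is the local maximum of the bin-signal
curve inside the adjacent domains minus the local minimum at the boundary
dip (windows bounded by w bins and by the domains themselves), so a deeper
dip means a larger score and stronger insulation.  The domain score of a
TAD is the fraction of all contacts involving the TAD that stay inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import ContactMatrix

__all__ = [
    "BinSignalTrack",
    "Boundary",
    "TAD",
    "TADComparison",
    "bin_signal",
    "detect_boundaries",
    "insulation_score",
    "domain_score",
    "compare_tad_sets",
]

DEFAULT_W = 5
DEFAULT_ALPHA = 0.05
MIN_TAD_BINS = 3
BOUNDARY_MATCH_BP = 10_000  # max boundary displacement for conservation
RECIPROCAL_OVERLAP = 0.8
DISAPPEARED_MAX_OVERLAP = 0.2


@dataclass
class BinSignalTrack:
    values: np.ndarray  # NaN within w of the ends and on masked bins
    window_w: int


@dataclass
class Boundary:
    chrom: str
    bin: int  # index of the first bin of the downstream TAD
    bin_size: int
    pvalue: float = np.nan
    qvalue: float = np.nan
    insulation_score: float = np.nan

    @property
    def interval(self) -> tuple[int, int]:
        return (self.bin * self.bin_size, (self.bin + 1) * self.bin_size)


@dataclass
class TAD:
    chrom: str
    start_bin: int
    end_bin: int  # half-open
    bin_size: int
    domain_score: float = np.nan

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin

    @property
    def size_bp(self) -> int:
        return self.n_bins * self.bin_size

    @property
    def interval_bp(self) -> tuple[int, int]:
        return (self.start_bin * self.bin_size, self.end_bin * self.bin_size)


def _matrix_and_mask(m) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(m, ContactMatrix):
        return m.counts, m.effective_mask()
    arr = np.asarray(m, dtype=float)
    return arr, np.zeros(arr.shape[0], dtype=bool)


def bin_signal(m, w: int = DEFAULT_W) -> BinSignalTrack:
    """Mean contact of the w x w upstream-by-downstream rectangle at each bin.

    signal[i] = mean of m[i-w+1..i, i+1..i+w]; NaN where the rectangle
    would leave the chromosome or touch a masked bin.
    """
    arr, mask = _matrix_and_mask(m)
    n = arr.shape[0]
    if w < 2:
        raise ValueError("window w must be >= 2")
    if w >= n / 2:
        raise ValueError(f"window w={w} too large for {n} bins")
    vals = np.full(n, np.nan)
    for i in range(w - 1, n - w):
        rows = slice(i - w + 1, i + 1)
        cols = slice(i + 1, i + w + 1)
        if mask[rows].any() or mask[cols].any():
            continue
        block = arr[rows, cols]
        if np.isnan(block).all():
            continue
        vals[i] = np.nanmean(block)
    return BinSignalTrack(values=vals, window_w=w)


def _local_minima(sig: np.ndarray, w: int) -> list[int]:
    """Leftmost indices achieving the minimum of each +-w neighbourhood."""
    n = len(sig)
    out = []
    for i in range(n):
        if np.isnan(sig[i]):
            continue
        lo, hi = max(0, i - w), min(n, i + w + 1)
        window = sig[lo:hi]
        if np.isnan(window).all():
            continue
        mn = np.nanmin(window)
        if sig[i] == mn:
            js = np.flatnonzero(window == mn) + lo
            if js[0] == i:  # ties broken by leftmost bin
                out.append(i)
    return out


def _boundary_test(arr: np.ndarray, i: int, w: int) -> float:
    """One-sided rank-sum p: flanking-domain contacts exceed cross contacts.

    Bin i is the last upstream bin; the candidate boundary lies between
    bins i and i+1.  "Within" pools the strict upper triangles of the two
    w x w flanking blocks; "cross" is the w x w rectangle between them.
    """
    n = arr.shape[0]
    up = np.arange(max(0, i - w + 1), i + 1)
    dn = np.arange(i + 1, min(n, i + w + 1))
    if len(up) < 2 or len(dn) < 2:
        return 1.0
    within = []
    for grp in (up, dn):
        sub = arr[np.ix_(grp, grp)]
        iu = np.triu_indices(len(grp), k=1)
        within.append(sub[iu])
    within = np.concatenate(within)
    cross = arr[np.ix_(up, dn)].ravel()
    within = within[~np.isnan(within)]
    cross = cross[~np.isnan(cross)]
    if within.size == 0 or cross.size == 0:
        return 1.0
    res = stats.mannwhitneyu(within, cross, alternative="greater")
    return float(res.pvalue)


def detect_boundaries(
    sig: BinSignalTrack,
    m,
    alpha: float = DEFAULT_ALPHA,
    min_size: int = MIN_TAD_BINS,
    chrom: str = "chr",
    bin_size: int = 10_000,
) -> tuple[list[Boundary], list[TAD]]:
    """Boundaries at statistically supported local minima; TADs tile the rest.

    Candidates failing the BH-adjusted rank-sum test at ``alpha`` are
    dropped; domains shorter than ``min_size`` bins are merged into the
    neighbour across their weaker (shallower-dip) boundary.
    """
    arr, _ = _matrix_and_mask(m)
    if isinstance(m, ContactMatrix):
        bin_size = m.bin_size
        chrom = m.chrom
    n = arr.shape[0]
    w = sig.window_w
    cand = _local_minima(sig.values, w)
    cand = [i for i in cand if w - 1 <= i < n - w]
    if not cand:
        warnings.warn("no boundary candidates; returning one chromosome-wide TAD")
        return [], [TAD(chrom, 0, n, bin_size)]

    pvals = np.array([_boundary_test(arr, i, w) for i in cand])
    qvals = stats.false_discovery_control(pvals, method="bh")
    kept = [(i, p, q) for i, p, q in zip(cand, pvals, qvals) if q <= alpha]
    if not kept:
        warnings.warn("no boundary passed testing; returning one chromosome-wide TAD")
        return [], [TAD(chrom, 0, n, bin_size)]

    boundaries = [
        Boundary(chrom, i + 1, bin_size, pvalue=p, qvalue=q) for i, p, q in kept
    ]
    boundaries.sort(key=lambda b: b.bin)

    # merge undersized TADs into the neighbour across the weaker boundary
    # (weaker = higher bin-signal at the dip, i.e. less insulated)
    def tads_from(bnds: list[Boundary]) -> list[TAD]:
        edges = [0] + [b.bin for b in bnds] + [n]
        return [TAD(chrom, s, e, bin_size) for s, e in zip(edges[:-1], edges[1:])]

    def dip_value(b: Boundary) -> float:
        v = sig.values[b.bin - 1]
        return v if np.isfinite(v) else np.inf

    while True:
        tads = tads_from(boundaries)
        small = [k for k, t in enumerate(tads) if t.n_bins < min_size]
        if not small or not boundaries:
            break
        k = small[0]
        left = boundaries[k - 1] if k > 0 else None
        right = boundaries[k] if k < len(boundaries) else None
        if left is None:
            boundaries.remove(right)
        elif right is None:
            boundaries.remove(left)
        else:
            # drop the weaker of the two separating boundaries
            boundaries.remove(left if dip_value(left) >= dip_value(right) else right)
    tads = tads_from(boundaries)
    return boundaries, tads


def insulation_score(
    sig: BinSignalTrack,
    boundaries: list[Boundary],
    tads: list[TAD],
) -> np.ndarray:
    """Outside-maximum minus inside-minimum of the bin signal per boundary.

    The inside window is the dip around the boundary; the outside windows
    reach up to w bins into the two adjacent domains.  Larger score =
    deeper dip = stronger insulation.  Chromosome-edge boundaries get NaN.
    Scores are also written onto the Boundary objects.
    """
    w = sig.window_w
    vals = sig.values
    n = len(vals)
    starts = {t.start_bin: t for t in tads}
    out = np.full(len(boundaries), np.nan)
    for k, b in enumerate(boundaries):
        if b.bin <= 0 or b.bin >= n:
            continue
        right = starts.get(b.bin)
        left = next((t for t in tads if t.end_bin == b.bin), None)
        if right is None or left is None:
            continue
        lwin = vals[max(left.start_bin, b.bin - w): b.bin]
        rwin = vals[b.bin: min(right.end_bin, b.bin + w)]
        both = np.concatenate([lwin, rwin])
        both = both[np.isfinite(both)]
        if both.size == 0:
            continue
        score = float(np.max(both) - np.min(both))
        out[k] = score
        b.insulation_score = score
    return out


def domain_score(m, tad: TAD | tuple[int, int]) -> float:
    """Fraction of all contacts involving the TAD that are intra-TAD.

    Each unordered bin pair counts once (diagonal included).  NaN when the
    TAD has no contacts at all.
    """
    arr, _ = _matrix_and_mask(m)
    if isinstance(tad, TAD):
        s, e = tad.start_bin, tad.end_bin
    else:
        s, e = tad
    n = arr.shape[0]
    if not 0 <= s < e <= n:
        raise ValueError(f"interval ({s}, {e}) outside matrix of {n} bins")
    inside = np.zeros(n, dtype=bool)
    inside[s:e] = True
    sub = np.nan_to_num(arr[s:e, s:e], nan=0.0)
    intra = np.triu(sub).sum()
    cross = np.nan_to_num(arr[s:e, :][:, ~inside], nan=0.0).sum()
    total = intra + cross
    if total == 0:
        return np.nan
    d = intra / total
    result = float(d)
    if isinstance(tad, TAD):
        tad.domain_score = result
    return result


@dataclass
class TADComparison:
    """Classification of condition-A TADs and boundaries against condition B."""

    tad_class: list[str]  # per A TAD: invariant|merged|split|disappeared|rearranged
    boundary_class: list[str]  # per A boundary: conserved|disappeared
    class_counts: dict = field(default_factory=dict)

    @property
    def disappeared_boundary_fraction(self) -> float:
        if not self.boundary_class:
            return np.nan
        return self.boundary_class.count("disappeared") / len(self.boundary_class)


def _overlap_bp(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def classify_tad(
    a: tuple[int, int],
    a_tads: list[tuple[int, int]],
    b_tads: list[tuple[int, int]],
    tol_bp: int = BOUNDARY_MATCH_BP,
) -> str:
    """Class of one A TAD (bp intervals) against the B TAD list.

    invariant: a B TAD matches both boundaries within ``tol_bp`` and has
    > 80% reciprocal overlap.  merged: a larger B TAD contains > 80% of
    this TAD and > 80% of another A TAD.  split: two or more B TADs are
    each > 80% contained in this TAD.  disappeared: the best overlap
    covers <= 20% of this TAD.  rearranged: anything else.
    """
    la = a[1] - a[0]
    best_frac = 0.0
    for b in b_tads:
        ov = _overlap_bp(a, b)
        lb = b[1] - b[0]
        best_frac = max(best_frac, ov / la)
        if (
            abs(a[0] - b[0]) <= tol_bp
            and abs(a[1] - b[1]) <= tol_bp
            and ov / la > RECIPROCAL_OVERLAP
            and ov / lb > RECIPROCAL_OVERLAP
        ):
            return "invariant"
    for b in b_tads:
        lb = b[1] - b[0]
        if lb <= la or _overlap_bp(a, b) / la <= RECIPROCAL_OVERLAP:
            continue
        for other in a_tads:
            if other == a:
                continue
            lo = other[1] - other[0]
            if _overlap_bp(other, b) / lo > RECIPROCAL_OVERLAP:
                return "merged"
    contained = sum(
        1 for b in b_tads if _overlap_bp(a, b) / (b[1] - b[0]) > RECIPROCAL_OVERLAP
    )
    if contained >= 2:
        return "split"
    if best_frac <= DISAPPEARED_MAX_OVERLAP:
        return "disappeared"
    return "rearranged"


def compare_tad_sets(
    set_a: list[TAD],
    set_b: list[TAD],
    tol_bp: int = BOUNDARY_MATCH_BP,
) -> TADComparison:
    """Classify every A TAD and A boundary against condition B.

    Boundaries (internal TAD edges) are conserved iff within ``tol_bp`` of
    some B boundary.  Empty B yields all-disappeared with a warning.
    """
    a_iv = [t.interval_bp for t in sorted(set_a, key=lambda t: t.start_bin)]
    b_iv = [t.interval_bp for t in sorted(set_b, key=lambda t: t.start_bin)]
    if not b_iv:
        warnings.warn("empty comparison set; everything classified disappeared")
        tad_class = ["disappeared"] * len(a_iv)
        bclass = ["disappeared"] * max(len(a_iv) - 1, 0)
    else:
        tad_class = [classify_tad(a, a_iv, b_iv, tol_bp) for a in a_iv]
        a_bounds = [iv[0] for iv in a_iv[1:]]
        b_bounds = np.array(sorted({iv[0] for iv in b_iv[1:]}))
        bclass = []
        for x in a_bounds:
            if b_bounds.size and np.min(np.abs(b_bounds - x)) <= tol_bp:
                bclass.append("conserved")
            else:
                bclass.append("disappeared")
    counts: dict[str, int] = {}
    for c in tad_class:
        counts[c] = counts.get(c, 0) + 1
    return TADComparison(tad_class=tad_class, boundary_class=bclass, class_counts=counts)
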