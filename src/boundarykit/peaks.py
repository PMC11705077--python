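"""Peak/boundary integration: boundary-associated factors and stratification.

Overlaps factor binding peaks with TAD boundary bins and TAD bodies,
computes boundary metagene profiles in reads-per-million, flags factors
whose boundary signal exceeds their intra-TAD flank signal (boundary-
associated factors), stratifies boundaries by anchor-factor (CTCF) x test-
factor status, and computes peak-peak overlap fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .tads import TAD, Boundary

__all__ = [
    "PeakSet",
    "FactorBoundaryStats",
    "assign_peaks",
    "metagene_profile",
    "classify_ba",
    "boundary_groups",
    "interval_overlap_fraction",
    "rank_factors",
]

BA_RATIO_THRESHOLD = 1.2
BA_CENTER_BINS = 1      # central window: boundary bin +- 1 bin
BA_FLANK_RANGE = (10, 20)  # flank window: bins 10..20 from the boundary, both sides


@dataclass
class PeakSet:
    """Binding intervals of one factor on one chromosome (0-based half-open)."""

    factor: str
    intervals: np.ndarray  # (n, 2) start/end bp
    summits: np.ndarray | None = None  # absolute bp
    chrom: str = "chrS"
    signal: np.ndarray | None = None

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=int).reshape(-1, 2)
        if iv.size and np.any(iv[:, 0] >= iv[:, 1]):
            raise ValueError("peak start must be < end")
        self.intervals = iv
        if self.summits is not None:
            s = np.asarray(self.summits, dtype=int)
            if iv.size and (np.any(s < iv[:, 0]) or np.any(s >= iv[:, 1])):
                raise ValueError("summits must fall inside their intervals")
            self.summits = s

    @classmethod
    def from_triplets(cls, factor: str, rows: np.ndarray, chrom: str = "chrS") -> "PeakSet":
        rows = np.asarray(rows, dtype=int).reshape(-1, 3)
        return cls(factor, rows[:, :2], rows[:, 2], chrom=chrom)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class FactorBoundaryStats:
    factor: str
    n_peaks: int
    boundary_fraction: float
    intra_tad_fraction: float
    gap_fraction: float
    boundary_flags: np.ndarray  # per boundary: >=1 overlapping peak
    profile: np.ndarray | None = None  # boundary metagene, RPM
    enrichment_ratio: float = np.nan
    is_ba: bool | None = None
    metadata: dict = field(default_factory=dict)


def _any_overlap(intervals: np.ndarray, regions: np.ndarray) -> np.ndarray:
    """Boolean per interval: overlaps >=1 bp of any (sorted, merged) region."""
    if len(intervals) == 0:
        return np.zeros(0, dtype=bool)
    if len(regions) == 0:
        return np.zeros(len(intervals), dtype=bool)
    starts, ends = regions[:, 0], regions[:, 1]
    # region index whose start is the last <= each peak end-1
    j = np.searchsorted(starts, intervals[:, 1] - 1, side="right") - 1
    hit = np.zeros(len(intervals), dtype=bool)
    # a peak may span several regions; scanning left from j is enough because
    # regions are merged (non-overlapping, sorted)
    for k, (s, e) in enumerate(intervals):
        jj = j[k]
        while jj >= 0 and ends[jj] > s:
            if starts[jj] < e:
                hit[k] = True
                break
            jj -= 1
    return hit


def _merge(regions: np.ndarray) -> np.ndarray:
    if len(regions) == 0:
        return regions.reshape(0, 2)
    r = regions[np.argsort(regions[:, 0])]
    out = [list(r[0])]
    for s, e in r[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=int)


def assign_peaks(
    peaks: PeakSet,
    boundaries: list[Boundary],
    tads: list[TAD],
    flank: int = 0,
) -> FactorBoundaryStats:
    """Assign every peak to boundary / intra-TAD / gap, boundary first.

    A peak is boundary-overlapping if it intersects a boundary bin widened
    by ``flank`` bp on each side; otherwise intra-TAD if it intersects a
    TAD body; otherwise a gap peak.  A boundary is flagged +factor iff at
    least one peak overlaps it.
    """
    if boundaries and peaks.chrom != boundaries[0].chrom:
        raise ValueError(
            f"chromosome mismatch: peaks on {peaks.chrom!r}, "
            f"boundaries on {boundaries[0].chrom!r}"
        )
    b_regions = _merge(
        np.array(
            [[b.interval[0] - flank, b.interval[1] + flank] for b in boundaries],
            dtype=int,
        ).reshape(-1, 2)
    )
    t_regions = _merge(
        np.array([t.interval_bp for t in tads], dtype=int).reshape(-1, 2)
    )
    on_boundary = _any_overlap(peaks.intervals, b_regions)
    in_tad = _any_overlap(peaks.intervals, t_regions) & ~on_boundary
    n = len(peaks)
    flags = np.zeros(len(boundaries), dtype=bool)
    for k, b in enumerate(boundaries):
        lo, hi = b.interval[0] - flank, b.interval[1] + flank
        if n:
            flags[k] = np.any((peaks.intervals[:, 0] < hi) & (peaks.intervals[:, 1] > lo))
    bf = on_boundary.mean() if n else 0.0
    tf = in_tad.mean() if n else 0.0
    return FactorBoundaryStats(
        factor=peaks.factor,
        n_peaks=n,
        boundary_fraction=float(bf),
        intra_tad_fraction=float(tf),
        gap_fraction=float(1.0 - bf - tf),
        boundary_flags=flags,
    )


def metagene_profile(
    track: np.ndarray,
    anchors: np.ndarray,
    flank_bins: int,
) -> np.ndarray:
    """Average RPM profile of a per-bin track around anchor bins.

    Windows of ``2 * flank_bins + 1`` bins centred on each anchor are
    averaged column-wise; windows truncated by a chromosome end are
    dropped.  Values are scaled to reads-per-million of the track total.
    """
    track = np.asarray(track, dtype=float)
    anchors = np.asarray(anchors, dtype=int)
    n = len(track)
    keep = (anchors >= flank_bins) & (anchors < n - flank_bins)
    if not keep.any():
        raise ValueError("all anchor windows are truncated by chromosome ends")
    rows = np.stack([track[a - flank_bins: a + flank_bins + 1] for a in anchors[keep]])
    total = track.sum()
    scale = 1e6 / total if total > 0 else 0.0
    return rows.mean(axis=0) * scale


def classify_ba(
    profile: np.ndarray,
    ratio_threshold: float = BA_RATIO_THRESHOLD,
    center_bins: int = BA_CENTER_BINS,
    flank_range: tuple[int, int] = BA_FLANK_RANGE,
) -> tuple[bool | None, float]:
    """Boundary-associated call from a boundary metagene profile.

    The factor is boundary-associated iff the mean profile over the
    central window (boundary +- ``center_bins``) exceeds
    ``ratio_threshold`` times the mean over the two intra-TAD flank
    windows (bins ``flank_range[0]..flank_range[1]`` from the boundary).
    Returns (flag, ratio); flag is None with a warning when the flank
    signal is zero.
    """
    profile = np.asarray(profile, dtype=float)
    c = len(profile) // 2
    lo, hi = flank_range
    if c - hi < 0:
        raise ValueError("profile too short for the requested flank window")
    center = profile[c - center_bins: c + center_bins + 1].mean()
    flank = np.concatenate(
        [profile[c - hi: c - lo + 1], profile[c + lo: c + hi + 1]]
    ).mean()
    if flank == 0:
        warnings.warn("zero flank signal; boundary-association undefined")
        return None, np.nan
    ratio = float(center / flank)
    return ratio > ratio_threshold, ratio


GROUP_LABELS = ("+CTCF+f", "+CTCF-f", "-CTCF+f", "-CTCF-f")


def boundary_groups(
    anchor_flags: np.ndarray,
    test_flags: np.ndarray,
    insulation: np.ndarray | None = None,
    domain_scores: np.ndarray | None = None,
) -> dict:
    """Four-way boundary stratification by anchor (CTCF) x test factor.

    Returns group sizes and proportions, per-group insulation-score and
    domain-score arrays, and two-sided rank-sum comparisons (+f vs -f
    within each anchor stratum, BH-adjusted) when metrics are supplied.
    """
    anchor_flags = np.asarray(anchor_flags, dtype=bool)
    test_flags = np.asarray(test_flags, dtype=bool)
    if anchor_flags.shape != test_flags.shape:
        raise ValueError("flag arrays must align")
    membership = {
        "+CTCF+f": anchor_flags & test_flags,
        "+CTCF-f": anchor_flags & ~test_flags,
        "-CTCF+f": ~anchor_flags & test_flags,
        "-CTCF-f": ~anchor_flags & ~test_flags,
    }
    n = len(anchor_flags)
    out: dict = {
        "sizes": {g: int(m.sum()) for g, m in membership.items()},
        "proportions": {g: float(m.mean()) if n else np.nan for g, m in membership.items()},
    }
    for label, metric in (("IS", insulation), ("domain_score", domain_scores)):
        if metric is None:
            continue
        metric = np.asarray(metric, dtype=float)
        out[label] = {g: metric[m][np.isfinite(metric[m])] for g, m in membership.items()}
        pvals, pairs = [], []
        for stratum, plus, minus in (
            ("+CTCF", "+CTCF+f", "+CTCF-f"),
            ("-CTCF", "-CTCF+f", "-CTCF-f"),
        ):
            a, b = out[label][plus], out[label][minus]
            if len(a) >= 3 and len(b) >= 3:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            else:
                p = np.nan
            pvals.append(p)
            pairs.append(stratum)
        finite = [p for p in pvals if np.isfinite(p)]
        qmap = dict(zip(
            [s for s, p in zip(pairs, pvals) if np.isfinite(p)],
            stats.false_discovery_control(finite, method="bh") if finite else [],
        ))
        out[f"{label}_tests"] = {
            s: {"p": p, "q": float(qmap.get(s, np.nan))} for s, p in zip(pairs, pvals)
        }
    return out


def interval_overlap_fraction(a: np.ndarray, b: np.ndarray) -> dict:
    """Fraction of A intervals with >=1 bp overlap in B (and the reverse)."""
    a = np.asarray(a, dtype=int).reshape(-1, 2)
    b = np.asarray(b, dtype=int).reshape(-1, 2)
    fa = float(_any_overlap(a, _merge(b)).mean()) if len(a) else np.nan
    fb = float(_any_overlap(b, _merge(a)).mean()) if len(b) else np.nan
    return {"a_in_b": fa, "b_in_a": fb}


def rank_factors(stats_by_factor: dict[str, FactorBoundaryStats]) -> list[str]:
    """Factors ordered by descending central boundary metagene value.

    Ties are broken alphabetically.
    """
    def central(s: FactorBoundaryStats) -> float:
        if s.profile is None:
            raise ValueError(f"factor {s.factor!r} has no metagene profile")
        p = np.asarray(s.profile, dtype=float)
        return float(p[len(p) // 2])

    return sorted(stats_by_factor, key=lambda f: (-central(stats_by_factor[f]), f))
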