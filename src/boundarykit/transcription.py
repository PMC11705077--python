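"""Transcription-boundary association: quantification, shuffles, strata.

Quantifies a nascent-transcription-like per-bin track over intervals in
reads-per-million, builds length-matched shuffled controls inside
container intervals, stratifies intervals into low/medium/high tertiles of
nonzero signal (zero-signal intervals form their own "none" class), and
tests group differences of boundary metrics (insulation score, intra-TAD
frequency, domain score) by rank-sum with BH adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SignalQuant",
    "quantify_signal",
    "shuffle_within",
    "stratify_levels",
    "associate",
]


@dataclass
class SignalQuant:
    interval: tuple[int, int]
    raw: float
    rpm: float


def quantify_signal(
    intervals: np.ndarray,
    track: np.ndarray,
    bin_size: int = 10_000,
) -> list[SignalQuant]:
    """Sum of the track over each bp interval, scaled to reads per million.

    Bins partially covered by an interval contribute proportionally to the
    overlapped base pairs.  The library total is the full track sum, so
    RPM is invariant to rescaling the track.
    """
    track = np.asarray(track, dtype=float)
    n = len(track)
    chrom_len = n * bin_size
    total = track.sum()
    scale = 1e6 / total if total > 0 else 0.0
    out = []
    for s, e in np.asarray(intervals, dtype=int).reshape(-1, 2):
        if not 0 <= s < e <= chrom_len:
            raise ValueError(f"interval ({s}, {e}) outside chromosome of {chrom_len} bp")
        b0, b1 = s // bin_size, (e - 1) // bin_size
        raw = 0.0
        for b in range(b0, b1 + 1):
            ov = min(e, (b + 1) * bin_size) - max(s, b * bin_size)
            raw += track[b] * ov / bin_size
        out.append(SignalQuant(interval=(int(s), int(e)), raw=raw, rpm=raw * scale))
    return out


def shuffle_within(
    query_intervals: np.ndarray,
    container_intervals: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Length-matched random placement of queries inside containers.

    For each query an equal-length interval is placed uniformly at random
    inside a uniformly chosen length-feasible container.  Infeasible
    queries are skipped with a warning; the result never leaves the
    containers.
    """
    rng = np.random.default_rng(seed)
    queries = np.asarray(query_intervals, dtype=int).reshape(-1, 2)
    containers = np.asarray(container_intervals, dtype=int).reshape(-1, 2)
    clens = containers[:, 1] - containers[:, 0]
    out = []
    for s, e in queries:
        length = e - s
        feasible = np.flatnonzero(clens >= length)
        if feasible.size == 0:
            warnings.warn(f"no container fits a query of {length} bp; skipped")
            continue
        c = containers[rng.choice(feasible)]
        start = int(rng.integers(c[0], c[1] - length + 1))
        out.append((start, start + length))
    return np.asarray(out, dtype=int).reshape(-1, 2)


def stratify_levels(quants: list[SignalQuant] | np.ndarray) -> tuple[list[str], tuple]:
    """Tertile labels L/M/H over nonzero RPM values; zeros labelled "none".

    Values below the lower tertile cut are L, above the upper cut H, M in
    between (so all-equal values are all M).  With fewer than three
    nonzero values everything is "none" with a warning.  Labels are
    invariant to monotone transforms of the signal.
    """
    if len(quants) and isinstance(quants[0], SignalQuant):
        vals = np.array([q.rpm for q in quants])
    else:
        vals = np.asarray(quants, dtype=float)
    nz = vals[vals > 0]
    if nz.size < 3:
        warnings.warn("fewer than 3 nonzero values; no strata assigned")
        return ["none"] * len(vals), (np.nan, np.nan)
    lo, hi = np.quantile(nz, [1 / 3, 2 / 3])
    labels = []
    for v in vals:
        if v == 0:
            labels.append("none")
        elif v < lo:
            labels.append("L")
        elif v > hi:
            labels.append("H")
        else:
            labels.append("M")
    return labels, (float(lo), float(hi))


def associate(groups: dict[str, np.ndarray]) -> list[dict]:
    """Pairwise two-sided rank-sum comparisons of a metric across groups.

    ``groups`` maps label -> metric values (e.g. insulation scores of
    boundaries stratified by transcription level).  Emits one row per
    unordered pair with p, BH-adjusted q, median difference, and fold
    change of means; pairs with a group of n < 3 get NaN statistics.
    """
    labels = sorted(groups)
    rows = []
    pvals = []
    for i, ga in enumerate(labels):
        for gb in labels[i + 1:]:
            a = np.asarray(groups[ga], dtype=float)
            b = np.asarray(groups[gb], dtype=float)
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if len(a) < 3 or len(b) < 3:
                p = np.nan
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            med_diff = float(np.median(a) - np.median(b)) if len(a) and len(b) else np.nan
            mb = b.mean() if len(b) else np.nan
            fold = float(a.mean() / mb) if len(a) and len(b) and mb else np.nan
            rows.append({"group_a": ga, "group_b": gb, "n_a": len(a), "n_b": len(b),
                         "p": p, "median_diff": med_diff, "fold_change": fold})
            pvals.append(p)
    finite_idx = [k for k, p in enumerate(pvals) if np.isfinite(p)]
    if finite_idx:
        qs = stats.false_discovery_control([pvals[k] for k in finite_idx], method="bh")
        qmap = dict(zip(finite_idx, qs))
    else:
        qmap = {}
    for k, row in enumerate(rows):
        row["q"] = float(qmap.get(k, np.nan))
    return rows
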