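"""Co-occupancy clustering of factors by consensus NMF.

Peak summits from all factors are chain-merged at <= 1 kb into candidate
cis-regulatory elements (CREs); the binary CRE x factor occupancy matrix
(rows with fewer than two factors dropped) is factorized by non-negative
matrix factorization at a range of ranks.  Rank is selected by consensus
statistics over random restarts: factors are co-clustered by the argmax
row of the coefficient matrix H, the restart-averaged connectivity matrix
gives the cophenetic correlation (agreement with average-linkage
clustering of the consensus distances) and the dispersion coefficient
mean(4 * (C - 1/2)^2); the most stable rank wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .peaks import PeakSet

__all__ = [
    "CRESet",
    "NMFResult",
    "ConsensusStats",
    "build_cres",
    "nmf_factorize",
    "rank_selection",
    "assign_groups",
]

CRE_MERGE_BP = 1000
NMF_MAX_ITER = 500
NMF_REL_TOL = 1e-6
DEFAULT_RESTARTS = 30


@dataclass
class CRESet:
    """Merged-summit cis-regulatory elements."""

    intervals: np.ndarray  # (n, 2) bp span of member summits
    member_summits: list[np.ndarray]
    member_factors: list[list[str]]

    @property
    def n_cres(self) -> int:
        return len(self.intervals)


def build_cres(
    peak_sets: dict[str, PeakSet], merge_bp: int = CRE_MERGE_BP
) -> tuple[CRESet, np.ndarray, list[str]]:
    """Single-linkage merge of all summits at <= ``merge_bp``; occupancy matrix.

    Consecutive summits (pooled over factors, sorted) closer than or equal
    to ``merge_bp`` join the same CRE.  V[c, f] = 1 iff factor f
    contributed >= 1 summit to CRE c; rows with fewer than two factors are
    dropped (single-factor elements carry no co-occupancy information).
    Returns (cres, V, factor_names).  The merge is independent of input
    order.
    """
    factors = sorted(peak_sets)
    pos_list, fac_list = [], []
    for f in factors:
        ps = peak_sets[f]
        if ps.summits is None:
            raise ValueError(f"peak set {f!r} has no summits")
        pos_list.append(np.asarray(ps.summits, dtype=int))
        fac_list.extend([f] * len(ps.summits))
    pos = np.concatenate(pos_list) if pos_list else np.empty(0, dtype=int)
    fac = np.array(fac_list)
    order = np.argsort(pos, kind="stable")
    pos, fac = pos[order], fac[order]

    intervals, summits, members = [], [], []
    v_rows = []
    fidx = {f: k for k, f in enumerate(factors)}
    start = 0
    for i in range(1, len(pos) + 1):
        if i < len(pos) and pos[i] - pos[i - 1] <= merge_bp:
            continue
        chunk_pos, chunk_fac = pos[start:i], fac[start:i]
        intervals.append((int(chunk_pos[0]), int(chunk_pos[-1]) + 1))
        summits.append(chunk_pos.copy())
        members.append(sorted(set(chunk_fac)))
        row = np.zeros(len(factors), dtype=int)
        for f in set(chunk_fac):
            row[fidx[f]] = 1
        v_rows.append(row)
        start = i
    v = np.array(v_rows, dtype=float).reshape(-1, len(factors))
    multi = v.sum(axis=1) >= 2
    if not multi.any():
        warnings.warn("no CRE is occupied by more than one factor")
    cres = CRESet(
        intervals=np.array(intervals, dtype=int).reshape(-1, 2)[multi],
        member_summits=[s for s, m in zip(summits, multi) if m],
        member_factors=[f for f, m in zip(members, multi) if m],
    )
    return cres, v[multi], factors


@dataclass
class NMFResult:
    w: np.ndarray
    h: np.ndarray
    rank: int
    error: float
    n_restarts: int
    seed: int
    error_trace: np.ndarray = field(repr=False, default=None)


def _mu_nmf(v: np.ndarray, k: int, rng: np.random.Generator,
            max_iter: int = NMF_MAX_ITER, rel_tol: float = NMF_REL_TOL,
            init: tuple[np.ndarray, np.ndarray] | None = None):
    """Multiplicative-update NMF for squared Frobenius error."""
    eps = 1e-12
    n, m = v.shape
    if init is not None:
        w, h = init[0].copy(), init[1].copy()
    else:
        w = rng.uniform(0.1, 1.0, size=(n, k))
        h = rng.uniform(0.1, 1.0, size=(k, m))
    prev = float(np.linalg.norm(v - w @ h) ** 2)
    trace = []
    for _ in range(max_iter):
        h *= (w.T @ v) / (w.T @ w @ h + eps)
        w *= (v @ h.T) / (w @ (h @ h.T) + eps)
        err = float(np.linalg.norm(v - w @ h) ** 2)
        trace.append(err)
        if prev - err <= rel_tol * max(prev, eps):
            break
        prev = err
    return w, h, trace[-1], np.array(trace)


def nmf_factorize(
    v: np.ndarray,
    k: int,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> NMFResult:
    """Best-of-restarts multiplicative-update NMF (squared Frobenius)."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("occupancy matrix is empty")
    if np.any(v < 0):
        raise ValueError("matrix must be non-negative")
    if not 1 <= k < v.shape[1]:
        raise ValueError(f"rank k={k} must satisfy 1 <= k < {v.shape[1]} factors")
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k, r]))
        w, h, err, trace = _mu_nmf(v, k, rng)
        if best is None or err < best.error:
            best = NMFResult(w=w, h=h, rank=k, error=err,
                             n_restarts=n_restarts, seed=seed, error_trace=trace)
    return best


@dataclass
class ConsensusStats:
    rank: int
    consensus: np.ndarray  # factor x factor, entries in [0, 1], diagonal 1
    cophenetic: float
    dispersion: float


def _connectivity(h: np.ndarray) -> np.ndarray:
    groups = np.argmax(h, axis=0)  # per factor; ties -> lower index via argmax
    return (groups[:, None] == groups[None, :]).astype(float)


def rank_selection(
    v: np.ndarray,
    rank_range: range | list[int],
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> tuple[list[ConsensusStats], int]:
    """Consensus statistics per rank and the chosen (most stable) rank.

    For each rank, every restart's coefficient matrix assigns factors to
    their argmax component; connectivity matrices are averaged into the
    consensus C.  The cophenetic coefficient is the Pearson correlation
    between the condensed distances 1 - C and the cophenetic distances of
    their average-linkage dendrogram; the dispersion coefficient is
    mean(4 * (C - 1/2)^2).  Chosen rank = argmax cophenetic, dispersion as
    tie-breaker.
    """
    if n_restarts < 2:
        raise ValueError("consensus statistics require n_restarts >= 2")
    v = np.asarray(v, dtype=float)
    stats_out: list[ConsensusStats] = []
    for k in rank_range:
        cs = []
        for r in range(n_restarts):
            rng = np.random.default_rng(np.random.SeedSequence([seed, k, r]))
            _, h, _, _ = _mu_nmf(v, k, rng)
            cs.append(_connectivity(h))
        c = np.mean(cs, axis=0)
        np.fill_diagonal(c, 1.0)
        dist = squareform(1.0 - c, checks=False)
        if np.allclose(dist, dist[0] if dist.size else 0.0):
            rho_c = 1.0  # degenerate: all distances equal, clustering is exact
        else:
            link = hierarchy.linkage(dist, method="average")
            coph = hierarchy.cophenet(link)
            rho_c = float(pearsonr(dist, coph)[0])
        rho_d = float(np.mean(4.0 * (c - 0.5) ** 2))
        stats_out.append(ConsensusStats(rank=k, consensus=c,
                                        cophenetic=rho_c, dispersion=rho_d))
    # cophenetic coefficients within float noise of each other are ties;
    # the dispersion coefficient then decides
    chosen = max(stats_out, key=lambda s: (round(s.cophenetic, 6), s.dispersion)).rank
    return stats_out, chosen


def assign_groups(h: np.ndarray, factors: list[str] | None = None) -> dict:
    """Map each factor to its maximal-coefficient component.

    Ties break to the lower component index; an all-zero column is left
    unassigned (None) with a warning.
    """
    h = np.asarray(h, dtype=float)
    k, m = h.shape
    names = factors if factors is not None else [f"f{j}" for j in range(m)]
    out = {}
    for j, name in enumerate(names):
        col = h[:, j]
        if np.all(col == 0):
            warnings.warn(f"factor {name!r} has an all-zero coefficient column")
            out[name] = None
        else:
            out[name] = int(np.argmax(col))
    return out
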