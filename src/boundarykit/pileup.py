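"""Aggregate domain analysis and boundary pile-ups on O/E maps.

ADA rescales each TAD's O/E submatrix (TAD plus a flank proportional to
its length) to a common pixel grid by bilinear interpolation and averages
the grids NA-aware.  Boundary pile-ups average fixed-size windows centred
on boundary bins without rescaling and quantify the two on-diagonal
(intra-TAD) blocks against the off-diagonal (inter-TAD) block, excluding
the one-bin centre cross.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .tads import TAD, Boundary

__all__ = ["PileupGrid", "QuadrantStats", "aggregate_domains", "boundary_pileup"]

ADA_FLANK_FRAC = 0.5
ADA_PIXELS = 99
PILEUP_FLANK_BP = 500_000


@dataclass
class PileupGrid:
    grid: np.ndarray
    n_anchors: int
    flank: float  # fraction of TAD length (ADA) or bp (boundary pile-up)


@dataclass
class QuadrantStats:
    upstream_intra: float
    downstream_intra: float
    inter: float

    @property
    def intra(self) -> float:
        return 0.5 * (self.upstream_intra + self.downstream_intra)

    @property
    def inter_intra_ratio(self) -> float:
        return self.inter / self.intra if self.intra else np.nan


def _rescale(sub: np.ndarray, n_pixels: int) -> np.ndarray:
    """Bilinear rescale to n_pixels^2; identity when sizes already match."""
    m = sub.shape[0]
    if m == n_pixels:
        return sub.copy()
    coords = np.linspace(0.0, m - 1.0, n_pixels)
    rr, cc = np.meshgrid(coords, coords, indexing="ij")
    filled = np.nan_to_num(sub, nan=0.0)
    valid = np.isfinite(sub).astype(float)
    num = ndimage.map_coordinates(filled, [rr, cc], order=1, mode="nearest")
    den = ndimage.map_coordinates(valid, [rr, cc], order=1, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


def aggregate_domains(
    oe: np.ndarray,
    tads: list[TAD] | list[tuple[int, int]],
    flank_frac: float = ADA_FLANK_FRAC,
    n_pixels: int = ADA_PIXELS,
) -> PileupGrid:
    """Average rescaled O/E submatrices over TADs (plus proportional flanks).

    TADs whose flanked extent leaves the chromosome are skipped; raises if
    none remain.  Averaging is NA-aware per pixel.
    """
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    grids = []
    for t in tads:
        s, e = (t.start_bin, t.end_bin) if isinstance(t, TAD) else t
        flank = int(round(flank_frac * (e - s)))
        lo, hi = s - flank, e + flank
        if lo < 0 or hi > n:
            continue
        grids.append(_rescale(oe[lo:hi, lo:hi], n_pixels))
    if not grids:
        raise ValueError("no TAD fits within the chromosome after flanking")
    with np.errstate(invalid="ignore"):
        grid = np.nanmean(np.stack(grids), axis=0)
    return PileupGrid(grid=grid, n_anchors=len(grids), flank=flank_frac)


def boundary_pileup(
    oe: np.ndarray,
    boundaries: list[Boundary] | np.ndarray,
    flank_bp: int = PILEUP_FLANK_BP,
    bin_size: int = 10_000,
) -> tuple[PileupGrid, QuadrantStats]:
    """Fixed-window average around boundary bins plus quadrant means.

    Windows are (2F+1)^2 with F = flank_bp / bin_size; truncated windows
    are dropped (error if all are).  The quadrant means exclude the centre
    row/column: upstream-intra = upper-left block, downstream-intra =
    lower-right block, inter = upper-right (cross-boundary) block.
    """
    if flank_bp % bin_size:
        raise ValueError("flank_bp must be a multiple of bin_size")
    f = flank_bp // bin_size
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    if len(boundaries) and isinstance(boundaries[0], Boundary):
        bins = np.array([b.bin for b in boundaries], dtype=int)
    else:
        bins = np.asarray(boundaries, dtype=int)
    grids = []
    for b in bins:
        lo, hi = b - f, b + f + 1
        if lo < 0 or hi > n:
            continue
        grids.append(oe[lo:hi, lo:hi])
    if not grids:
        raise ValueError("all boundary windows are truncated by chromosome ends")
    with np.errstate(invalid="ignore"):
        grid = np.nanmean(np.stack(grids), axis=0)
    up = slice(0, f)
    dn = slice(f + 1, 2 * f + 1)
    qs = QuadrantStats(
        upstream_intra=float(np.nanmean(grid[up, up])),
        downstream_intra=float(np.nanmean(grid[dn, dn])),
        inter=float(np.nanmean(grid[up, dn])),
    )
    return PileupGrid(grid=grid, n_anchors=len(grids), flank=float(flank_bp)), qs
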