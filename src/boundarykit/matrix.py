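"""Contact-matrix container, ICE balancing, O/E transform, compartments.

The per-chromosome contact map is held dense (synthetic chromosomes and
single-chromosome analyses at 10-100 kb bins fit comfortably in memory).
Balancing follows the iterative-correction scheme: bins whose marginal
falls below a coverage quantile are masked, then row/column scaling is
iterated until the coefficient of variation of the unmasked marginals
drops below tolerance.  Compartments are the first principal component of
the Pearson correlation of the observed/expected map, oriented so the
gene-rich sign is positive (compartment A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "CompartmentTrack",
    "coverage_mask",
    "ice_balance",
    "expected_by_distance",
    "observed_over_expected",
    "call_compartments",
    "rebin",
]

MASK_QUANTILE = 0.02  # marginals below this quantile of nonzero marginals are masked
ICE_TOL = 1e-5
# plain iterative correction converges linearly; strongly decaying matrices
# need several hundred sweeps to push the marginal CV below 1e-5
ICE_MAX_ITER = 2000


@dataclass
class ContactMatrix:
    """Symmetric binned contact matrix for one chromosome."""

    chrom: str
    bin_size: int
    counts: np.ndarray
    state: str = "raw"  # "raw" | "balanced"
    bias: np.ndarray | None = None
    mask: np.ndarray | None = None  # True = low-coverage bin, excluded
    converged: bool = True

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.nanmin(c) < 0:
            raise ValueError("counts must be non-negative")
        if not np.allclose(c, c.T, equal_nan=True):
            raise ValueError("counts must be symmetric")
        self.counts = c
        if self.state == "balanced" and self.bias is None:
            raise ValueError("balanced matrix requires a bias vector")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def effective_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.zeros(self.n_bins, dtype=bool)
        return self.mask


def rebin(m: ContactMatrix, factor: int) -> ContactMatrix:
    """Coarsen a raw matrix by summing ``factor`` x ``factor`` bin blocks.

    A trailing partial block is dropped.  Used to move from TAD resolution
    (10 kb) to compartment resolution (100 kb).
    """
    if m.state != "raw":
        raise ValueError("rebin raw counts, then balance at the new resolution")
    n = (m.n_bins // factor) * factor
    c = m.counts[:n, :n].reshape(n // factor, factor, n // factor, factor).sum(axis=(1, 3))
    return ContactMatrix(chrom=m.chrom, bin_size=m.bin_size * factor,
                         counts=c, state="raw")


def coverage_mask(counts: np.ndarray, quantile: float = MASK_QUANTILE) -> np.ndarray:
    """Mask bins with marginal below ``quantile`` of nonzero marginals (and zeros)."""
    marg = counts.sum(axis=0)
    nz = marg[marg > 0]
    if nz.size == 0:
        return np.ones(len(marg), dtype=bool)
    thresh = np.quantile(nz, quantile)
    return marg < thresh


def ice_balance(
    m: ContactMatrix,
    tol: float = ICE_TOL,
    max_iter: int = ICE_MAX_ITER,
    mask_quantile: float = MASK_QUANTILE,
) -> ContactMatrix:
    """Iterative correction: equalize unmasked marginals by row/col scaling.

    Returns a new balanced matrix plus the accumulated per-bin bias vector
    (original counts ~ bias_i * bias_j * balanced counts, up to the global
    scale that keeps the mean marginal constant).  Masked rows/columns are
    zeroed; non-convergence sets ``converged=False`` and warns rather than
    raising.
    """
    if m.state == "balanced":
        raise ValueError("matrix is already balanced")
    mask = m.mask if m.mask is not None else coverage_mask(m.counts, mask_quantile)
    keep = ~mask
    if not keep.any():
        raise ValueError("all bins are masked; cannot balance")

    w = m.counts.copy()
    w[mask, :] = 0.0
    w[:, mask] = 0.0
    bias = np.ones(m.n_bins)
    converged = False
    for _ in range(max_iter):
        marg = w.sum(axis=0)
        mu = marg[keep].mean()
        if mu == 0:
            raise ValueError("unmasked matrix is empty; cannot balance")
        cv = marg[keep].std() / mu
        if cv <= tol:
            converged = True
            break
        s = np.ones(m.n_bins)
        s[keep] = marg[keep] / mu
        w /= s[:, None]
        w /= s[None, :]
        bias *= s
    else:
        marg = w.sum(axis=0)
        cv = marg[keep].std() / marg[keep].mean()
        converged = cv <= tol
    if not converged:
        warnings.warn(
            f"ICE did not reach CV <= {tol} in {max_iter} iterations", RuntimeWarning
        )
    bias[mask] = np.nan
    return ContactMatrix(
        chrom=m.chrom,
        bin_size=m.bin_size,
        counts=w,
        state="balanced",
        bias=bias,
        mask=mask,
        converged=converged,
    )


@dataclass
class ExpectedProfile:
    """Mean contact value per genomic distance (in bins)."""

    values: np.ndarray  # length n_bins; values[s] = mean over unmasked (i, i+s)
    n_bins: int

    def __post_init__(self) -> None:
        if len(self.values) != self.n_bins:
            raise ValueError("profile length must equal n_bins")


def expected_by_distance(m: ContactMatrix) -> ExpectedProfile:
    """Per-diagonal mean over unmasked bin pairs."""
    n = m.n_bins
    keep = ~m.effective_mask()
    vals = np.zeros(n)
    for s in range(n):
        i = np.arange(n - s)
        ok = keep[i] & keep[i + s]
        diag = m.counts[i[ok], i[ok] + s]
        vals[s] = diag.mean() if diag.size else 0.0
    return ExpectedProfile(values=vals, n_bins=n)


def observed_over_expected(m: ContactMatrix, e: ExpectedProfile) -> np.ndarray:
    """O/E matrix: counts[i, j] / expected[|i-j|]; NaN where undefined.

    Entries on masked bins or at distances with zero expectation are NaN.
    """
    if e.n_bins != m.n_bins:
        raise ValueError("expected profile shape does not match matrix")
    n = m.n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    ev = e.values[dist]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(ev > 0, m.counts / ev, np.nan)
    bad = m.effective_mask()
    oe[bad, :] = np.nan
    oe[:, bad] = np.nan
    return oe


@dataclass
class CompartmentTrack:
    """Per-bin PC1 of the O/E Pearson map with A/B labels."""

    pc1: np.ndarray  # NaN on masked bins
    label: np.ndarray  # 'A' | 'B' | 'NA'
    gene_density: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if len(self.pc1) != len(self.label):
            raise ValueError("pc1 and label lengths differ")


def call_compartments(oe: np.ndarray, gene_density: np.ndarray) -> CompartmentTrack:
    """A/B compartments from PC1 of the Pearson-correlated O/E matrix.

    Masked (all-NaN) bins are dropped, the Pearson correlation of the
    remaining O/E columns is eigendecomposed, and the leading eigenvector
    is oriented so it correlates positively with gene density (A = PC1 > 0
    = gene-rich).  Calling the routine on its own output is idempotent in
    sign.
    """
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    gene_density = np.asarray(gene_density, dtype=float)
    if len(gene_density) != n:
        raise ValueError("gene_density length must equal the number of bins")
    keep = ~np.all(np.isnan(oe), axis=0)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 unmasked bins; compartments undefined")
    sub = oe[np.ix_(keep, keep)]
    # residual NaNs (zero-expectation distances) are neutral at O/E = 1
    sub = np.where(np.isnan(sub), 1.0, sub)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)
    evals, evecs = np.linalg.eigh(corr)
    pc1_sub = evecs[:, -1]
    gd = gene_density[keep]
    if np.std(gd) > 0 and np.corrcoef(pc1_sub, gd)[0, 1] < 0:
        pc1_sub = -pc1_sub
    pc1 = np.full(n, np.nan)
    pc1[keep] = pc1_sub
    label = np.full(n, "NA", dtype="<U2")
    label[keep & (pc1 > 0)] = "A"
    label[keep & (pc1 <= 0)] = "B"
    return CompartmentTrack(pc1=pc1, label=label, gene_density=gene_density)
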