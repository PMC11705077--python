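"""Synthetic Hi-C / ChIP-seq data with planted ground truth.

Generates per-chromosome contact matrices with block-structured TADs of
tunable boundary insulation, an A/B compartment checkerboard, factor peak
sets enriched at boundary bins with planted co-occupancy groups, and
boundary-enriched signal tracks.  Every generator is deterministic given
its seed, so downstream callers (TAD caller, compartment caller, NMF
clustering, pile-ups) can be tested by parameter recovery.

Model
-----
Expected contacts decay with genomic distance as a power law,

    E[i, j] = A * (1 + |i - j|) ** (-alpha) * m(i, j) * c(i, j),

where ``m`` is the product of the insulation depths of every planted
boundary lying between bins i and j (1 inside a TAD, < 1 across
boundaries) and ``c`` is an optional compartment factor (> 1 for bins
sharing an A/B label, < 1 otherwise).  ``A`` is set so the expected total
count over the upper triangle equals the requested sequencing depth.
Counts are Poisson draws around E, symmetrized exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .matrix import ContactMatrix

__all__ = [
    "SimulationConfig",
    "FactorSpec",
    "PlantedArchitecture",
    "plant_architecture",
    "simulate_contact_map",
    "simulate_peaks",
    "simulate_signal_track",
]

# Compartment contact modulation, symmetric on the log scale so that PC1 of
# the correlation map is sign-balanced.
SAME_COMPARTMENT_FACTOR = 1.3
CROSS_COMPARTMENT_FACTOR = 1.0 / 1.3


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic chromosome.

    Parameters
    ----------
    n_bins:
        Number of bins on the chromosome.
    bin_size:
        Base pairs per bin.
    decay_exponent:
        Power-law exponent alpha of the distance decay (> 0).
    depth:
        Expected total read-pair count of the simulated matrix.
    tad_size_range:
        (min, max) TAD length in bins, inclusive.
    insulation_depths:
        Cross-boundary contact attenuation per boundary, each in (0, 1];
        1 means no insulation.  Cycled over boundaries in order.
    compartment_block_bins:
        Period of the A/B checkerboard in bins; 0 disables compartments.
    seed:
        Master seed for all draws derived from this config.
    """

    n_bins: int
    bin_size: int = 10_000
    decay_exponent: float = 1.0
    depth: float = 1e6
    tad_size_range: tuple[int, int] = (20, 100)
    insulation_depths: tuple[float, ...] = (0.3,)
    compartment_block_bins: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.tad_size_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid tad_size_range {self.tad_size_range}")
        if self.n_bins < 2 * hi:
            raise ValueError(
                f"n_bins={self.n_bins} must be at least twice the maximum "
                f"TAD size ({hi}) for the tiling to be feasible"
            )
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if not all(0 < d <= 1 for d in self.insulation_depths):
            raise ValueError("insulation depths must lie in (0, 1]")


@dataclass(frozen=True)
class FactorSpec:
    """Planted binding behaviour of one factor (RBP/TF-like)."""

    name: str
    n_peaks: int = 200
    boundary_fraction: float = 0.5
    group_id: int | None = None
    peak_width: int = 200
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")
        if not 0 <= self.boundary_fraction <= 1:
            raise ValueError("boundary_fraction must lie in [0, 1]")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class PlantedArchitecture:
    """Ground truth of one synthetic chromosome."""

    config: SimulationConfig
    true_boundaries: np.ndarray  # internal boundary bin indices, increasing
    true_tads: list[tuple[int, int]]  # half-open bin intervals, tiling
    boundary_depths: np.ndarray  # insulation depth per internal boundary
    compartment_label: np.ndarray  # per-bin 'A'/'B'
    factor_truth: dict = field(default_factory=dict)  # name -> truth record
    signal_truth: dict = field(default_factory=dict)  # track -> per-bin mean

    @property
    def n_bins(self) -> int:
        return self.config.n_bins

    def tad_id_per_bin(self) -> np.ndarray:
        """Index of the containing TAD for every bin."""
        ids = np.zeros(self.n_bins, dtype=int)
        for k, (s, e) in enumerate(self.true_tads):
            ids[s:e] = k
        return ids


def plant_architecture(config: SimulationConfig) -> PlantedArchitecture:
    """Draw a TAD tiling and compartment labels for one chromosome.

    TAD sizes are drawn uniformly within ``tad_size_range``; the final
    domain absorbs the remainder so the tiling covers ``[0, n_bins)``
    exactly.  Boundaries are the starts of all TADs except the first.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.tad_size_range
    sizes: list[int] = []
    remaining = config.n_bins
    while remaining > 0:
        if remaining <= hi or remaining < 2 * lo:
            # final domain absorbs the remainder (exceeds hi only when the
            # range is too narrow to split the tail)
            sizes.append(remaining)
            remaining = 0
            continue
        s = int(rng.integers(lo, hi + 1))
        s = min(s, remaining - lo)  # keep the next domain feasible
        sizes.append(s)
        remaining -= s
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(int)
    ends = np.cumsum(sizes).astype(int)
    tads = list(zip(starts.tolist(), ends.tolist()))
    boundaries = starts[1:]

    depth_cycle = np.array(config.insulation_depths, dtype=float)
    depths = depth_cycle[np.arange(len(boundaries)) % len(depth_cycle)]

    labels = np.full(config.n_bins, "A", dtype="<U1")
    if config.compartment_block_bins > 0:
        block = np.arange(config.n_bins) // config.compartment_block_bins
        labels[block % 2 == 1] = "B"

    return PlantedArchitecture(
        config=config,
        true_boundaries=boundaries,
        true_tads=tads,
        boundary_depths=depths,
        compartment_label=labels,
    )


def expected_contact_matrix(arch: PlantedArchitecture) -> np.ndarray:
    """Noise-free expectation E[i, j] of the planted contact model."""
    cfg = arch.config
    n = cfg.n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    base = (1.0 + dist) ** (-cfg.decay_exponent)

    # product of depths of crossed boundaries via cumulative log-depths
    cum = np.zeros(n)
    if len(arch.true_boundaries):
        log_d = np.zeros(n)
        log_d[arch.true_boundaries] = np.log(arch.boundary_depths)
        cum = np.cumsum(log_d)
    # |cum_i - cum_j| = -sum(log depth) over crossed boundaries (depths <= 1)
    insulation = np.exp(-np.abs(cum[:, None] - cum[None, :]))

    comp = np.ones((n, n))
    if cfg.compartment_block_bins > 0:
        same = arch.compartment_label[:, None] == arch.compartment_label[None, :]
        comp = np.where(same, SAME_COMPARTMENT_FACTOR, CROSS_COMPARTMENT_FACTOR)

    e = base * insulation * comp
    total = np.triu(e).sum()
    scale = cfg.depth / total if total > 0 else 0.0
    return e * scale


def simulate_contact_map(
    arch: PlantedArchitecture, config: SimulationConfig | None = None
) -> ContactMatrix:
    """Poisson-sample a symmetric contact matrix around the planted model.

    The upper triangle (diagonal included) is sampled and mirrored, so the
    returned matrix equals its transpose exactly and its upper-triangle sum
    has expectation ``config.depth``.
    """
    cfg = config if config is not None else arch.config
    if cfg != arch.config:
        raise ValueError("config does not match the architecture's config")
    e = expected_contact_matrix(arch)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    counts = rng.poisson(np.triu(e)).astype(float)
    counts = counts + np.triu(counts, 1).T
    return ContactMatrix(
        chrom="chrS", bin_size=cfg.bin_size, counts=counts, state="raw"
    )


def _boundary_bp_intervals(arch: PlantedArchitecture) -> np.ndarray:
    bs = arch.config.bin_size
    b = arch.true_boundaries
    return np.stack([b * bs, (b + 1) * bs], axis=1) if len(b) else np.empty((0, 2), int)


def simulate_peaks(
    arch: PlantedArchitecture,
    specs: list[FactorSpec],
    seed: int | None = None,
) -> dict[str, "np.ndarray"]:
    """Place factor peaks with planted boundary enrichment and co-occupancy.

    Each factor's number of boundary-resident peaks is Binomial(n_peaks,
    boundary_fraction); boundary peaks are centred at uniform positions
    inside boundary bins, the rest uniformly elsewhere.  Factors sharing a
    ``group_id`` draw their summits from one shared latent position pool
    (with independent per-factor dropout), which plants co-occupancy
    structure for NMF recovery.  Returns ``{name: array of (start, end,
    summit) rows}``; also records the truth in ``arch.factor_truth``.
    """
    if not specs:
        raise ValueError("specs must be nonempty")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate factor names")
    cfg = arch.config
    master = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([master, 2]))
    bs = cfg.bin_size
    chrom_len = cfg.n_bins * bs
    boundary_bins = arch.true_boundaries
    n_boundary_positions = len(boundary_bins) * bs

    def draw_positions(n: int, frac: float) -> np.ndarray:
        """n summit positions, ~frac of them inside boundary bins."""
        n_b = rng.binomial(n, frac) if 0 < frac < 1 else int(round(n * frac))
        if n_b > 0 and n_b > n_boundary_positions:
            raise ValueError(
                f"{n_b} boundary peaks requested but only "
                f"{len(boundary_bins)} boundary bins are available"
            )
        if n_b > 0:
            bins = boundary_bins[rng.integers(0, len(boundary_bins), n_b)]
            offs = rng.integers(0, bs, n_b)
            on = bins * bs + offs
        else:
            on = np.empty(0, dtype=int)
        off = rng.integers(0, chrom_len, n - n_b)
        if len(boundary_bins):
            # push strays out of boundary bins so boundary_fraction=0 is exact
            in_bnd = np.isin(off // bs, boundary_bins)
            while in_bnd.any():
                off[in_bnd] = rng.integers(0, chrom_len, int(in_bnd.sum()))
                in_bnd = np.isin(off // bs, boundary_bins)
        return np.sort(np.concatenate([on, off]))

    # shared pools per co-occupancy group
    pools: dict[int, np.ndarray] = {}
    for gid in sorted({s.group_id for s in specs if s.group_id is not None}):
        members = [s for s in specs if s.group_id == gid]
        size = max(s.n_peaks for s in members)
        frac = members[0].boundary_fraction
        pools[gid] = draw_positions(size, frac)

    out: dict[str, np.ndarray] = {}
    for s in specs:
        if s.group_id is not None:
            pool = pools[s.group_id]
            keep = rng.random(len(pool)) >= s.dropout
            summits = pool[keep]
        else:
            summits = draw_positions(s.n_peaks, s.boundary_fraction)
        half = s.peak_width // 2
        starts = np.clip(summits - half, 0, chrom_len - 1)
        ends = np.clip(summits + max(s.peak_width - half, 1), 1, chrom_len)
        peaks = np.stack([starts, ends, summits], axis=1).astype(int)
        out[s.name] = peaks
        arch.factor_truth[s.name] = {
            "spec": dataclasses.asdict(s),
            "summits": summits.copy(),
        }
    return out


def simulate_signal_track(
    arch: PlantedArchitecture,
    target_intervals: np.ndarray,
    amplitude: float,
    background: float,
    seed: int | None = None,
    name: str = "track",
) -> np.ndarray:
    """Per-bin Poisson counts: ``amplitude`` on target bins, ``background`` off.

    ``target_intervals`` are (start, end) half-open *bin* intervals.
    """
    if not amplitude >= background >= 0:
        raise ValueError("require amplitude >= background >= 0")
    cfg = arch.config
    master = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([master, 3]))
    mean = np.full(cfg.n_bins, float(background))
    for s, e in np.asarray(target_intervals, dtype=int).reshape(-1, 2):
        if not 0 <= s < e <= cfg.n_bins:
            raise ValueError(f"target interval ({s}, {e}) outside chromosome")
        mean[s:e] = amplitude
    arch.signal_truth[name] = mean
    return rng.poisson(mean).astype(float)
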