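"""Plain-text readers/writers for the pipeline's interchange formats.

Formats: triplet contact matrices (bin_i TAB bin_j TAB count, upper
triangle, 0-based bins) with a BED bin table; peaks as 6+1-column BED with
a summit-offset column; per-bin tracks as bedGraph; TADs/boundaries as BED
with score columns; truth tables as TSV.  All readers accept gzip
transparently via the ``.gz`` suffix.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ContactMatrix
from .peaks import PeakSet
from .tads import TAD, Boundary

__all__ = [
    "write_triplets", "read_triplets",
    "write_bins", "read_bins",
    "write_peaks_bed", "read_peaks_bed",
    "write_bedgraph", "read_bedgraph",
    "write_tads_bed", "read_tads_bed",
    "write_boundaries_bed", "read_boundaries_bed",
    "write_truth", "read_truth",
]


def _open(path, mode="rt"):
    path = Path(path)
    return gzip.open(path, mode) if path.suffix == ".gz" else open(path, mode)


def write_triplets(m: ContactMatrix, path) -> None:
    iu = np.triu_indices(m.n_bins)
    vals = m.counts[iu]
    nz = vals != 0
    with _open(path, "wt") as fh:
        for i, j, v in zip(iu[0][nz], iu[1][nz], vals[nz]):
            fh.write(f"{i}\t{j}\t{v:g}\n")


def read_triplets(path, n_bins: int, chrom: str = "chrS",
                  bin_size: int = 10_000) -> ContactMatrix:
    counts = np.zeros((n_bins, n_bins))
    with _open(path) as fh:
        for line in fh:
            i, j, v = line.split()
            i, j, v = int(i), int(j), float(v)
            counts[i, j] = v
            if i != j:
                counts[j, i] = v
    return ContactMatrix(chrom=chrom, bin_size=bin_size, counts=counts, state="raw")


def write_bins(n_bins: int, bin_size: int, path, chrom: str = "chrS") -> None:
    with _open(path, "wt") as fh:
        for b in range(n_bins):
            fh.write(f"{chrom}\t{b * bin_size}\t{(b + 1) * bin_size}\t{b}\n")


def read_bins(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "bin_id"])
    return df


def write_peaks_bed(ps: PeakSet, path) -> None:
    """6+1 column BED: name/score/strand plus summit offset from start."""
    with _open(path, "wt") as fh:
        for k, (s, e) in enumerate(ps.intervals):
            summit_off = (ps.summits[k] - s) if ps.summits is not None else -1
            sig = ps.signal[k] if ps.signal is not None else 0.0
            fh.write(f"{ps.chrom}\t{s}\t{e}\t{ps.factor}_{k}\t{sig:g}\t.\t{summit_off}\n")


def read_peaks_bed(path, factor: str | None = None) -> PeakSet:
    rows = []
    chrom = "chrS"
    name = factor
    with _open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            chrom = parts[0]
            s, e = int(parts[1]), int(parts[2])
            if name is None and len(parts) > 3:
                name = parts[3].rsplit("_", 1)[0]
            off = int(parts[6]) if len(parts) > 6 else -1
            rows.append((s, e, s + off if off >= 0 else (s + e) // 2))
    arr = np.asarray(rows, dtype=int).reshape(-1, 3)
    return PeakSet(name or "factor", arr[:, :2], arr[:, 2], chrom=chrom)


def write_bedgraph(track: np.ndarray, bin_size: int, path,
                   chrom: str = "chrS") -> None:
    with _open(path, "wt") as fh:
        for b, v in enumerate(track):
            fh.write(f"{chrom}\t{b * bin_size}\t{(b + 1) * bin_size}\t{v:g}\n")


def read_bedgraph(path, n_bins: int, bin_size: int) -> np.ndarray:
    track = np.zeros(n_bins)
    with _open(path) as fh:
        for line in fh:
            _, s, e, v = line.split()
            s, e, v = int(s), int(e), float(v)
            track[s // bin_size: (e + bin_size - 1) // bin_size] = v
    return track


def write_tads_bed(tads: list[TAD], path) -> None:
    with _open(path, "wt") as fh:
        for k, t in enumerate(tads):
            s, e = t.interval_bp
            fh.write(f"{t.chrom}\t{s}\t{e}\ttad_{k}\t{t.domain_score:g}\n")


def read_tads_bed(path, bin_size: int = 10_000) -> list[TAD]:
    out = []
    with _open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            t = TAD(parts[0], int(parts[1]) // bin_size, int(parts[2]) // bin_size,
                    bin_size)
            if len(parts) > 4:
                t.domain_score = float(parts[4])
            out.append(t)
    return out


def write_boundaries_bed(bounds: list[Boundary], path) -> None:
    """BED + insulation score, p, q columns."""
    with _open(path, "wt") as fh:
        for k, b in enumerate(bounds):
            s, e = b.interval
            fh.write(f"{b.chrom}\t{s}\t{e}\tboundary_{k}\t"
                     f"{b.insulation_score:g}\t{b.pvalue:g}\t{b.qvalue:g}\n")


def read_boundaries_bed(path, bin_size: int = 10_000) -> list[Boundary]:
    out = []
    with _open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            b = Boundary(parts[0], int(parts[1]) // bin_size, bin_size)
            if len(parts) > 6:
                b.insulation_score = float(parts[4])
                b.pvalue = float(parts[5])
                b.qvalue = float(parts[6])
            out.append(b)
    return out


def write_truth(arch, path) -> None:
    """Planted architecture as TSV (boundaries, depths, TADs, compartments)."""
    rows = []
    for k, (s, e) in enumerate(arch.true_tads):
        rows.append({"record": "tad", "idx": k, "a": s, "b": e, "value": ""})
    for k, (b, d) in enumerate(zip(arch.true_boundaries, arch.boundary_depths)):
        rows.append({"record": "boundary", "idx": k, "a": int(b), "b": int(b) + 1,
                     "value": f"{d:g}"})
    for b, lab in enumerate(arch.compartment_label):
        rows.append({"record": "compartment", "idx": b, "a": b, "b": b + 1,
                     "value": lab})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path) -> dict:
    """Reload a truth TSV to arrays equal to the in-memory architecture."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    tads = [(int(r.a), int(r.b)) for r in df[df.record == "tad"].itertuples()]
    bdf = df[df.record == "boundary"]
    boundaries = bdf.a.to_numpy(dtype=int)
    depths = bdf.value.to_numpy(dtype=float)
    cdf = df[df.record == "compartment"].sort_values("idx")
    labels = cdf.value.to_numpy(dtype="<U1")
    return {"true_tads": tads, "true_boundaries": boundaries,
            "boundary_depths": depths, "compartment_label": labels}
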