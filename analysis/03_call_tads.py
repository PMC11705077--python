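#!/usr/bin/env python
"""Call TAD boundaries, score insulation and domain scores.

Compares the called boundaries against the planted truth (F1 at a one-bin
tolerance) and summarizes insulation and domain scores.
"""

from pathlib import Path

import numpy as np

from boundarykit.io import read_boundaries_bed, read_tads_bed, read_truth
from boundarykit.pipeline import RunConfig, run_stage

RUN = Path(__file__).resolve().parents[1] / "results" / "run"


def main():
    cfg = RunConfig(outdir=str(RUN), seed=1)
    for stage in ("simulate", "balance", "call-tads"):
        run_stage(stage, cfg)

    bounds = read_boundaries_bed(RUN / "boundaries.bed", cfg.bin_size)
    tads = read_tads_bed(RUN / "tads.bed", cfg.bin_size)
    truth = read_truth(RUN / "truth.tsv")
    called = np.array([b.bin for b in bounds])
    true = truth["true_boundaries"]
    prec = np.mean([np.min(np.abs(true - c)) <= 1 for c in called])
    rec = np.mean([np.min(np.abs(called - t)) <= 1 for t in true])
    f1 = 2 * prec * rec / (prec + rec)
    print(f"called {len(called)} boundaries vs {len(true)} planted; "
          f"precision {prec:.2f}, recall {rec:.2f}, F1 {f1:.2f} (±1 bin)")
    iss = np.array([b.insulation_score for b in bounds])
    ds = np.array([t.domain_score for t in tads])
    print(f"insulation score: median {np.nanmedian(iss):.2f} "
          f"(IQR {np.nanpercentile(iss, 25):.2f}-{np.nanpercentile(iss, 75):.2f})")
    print(f"domain score: median {np.nanmedian(ds):.2f} over {len(tads)} TADs")


if __name__ == "__main__":
    main()
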