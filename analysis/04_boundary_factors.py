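#!/usr/bin/env python
"""Overlap factor peaks with boundaries; flag boundary-associated factors.

Reproduces the boundary-hotspot readouts on the synthetic dataset: the
fraction of each factor's peaks on boundaries vs intra-TAD regions, the
metagene enrichment ratio and boundary-associated flag, the factor
ranking, and the four-way CTCF-by-factor boundary stratification.
"""

from pathlib import Path

import pandas as pd

from boundarykit.pipeline import RunConfig, run_stage

RUN = Path(__file__).resolve().parents[1] / "results" / "run"


def main():
    cfg = RunConfig(outdir=str(RUN), seed=1)
    for stage in ("simulate", "balance", "call-tads", "annotate"):
        run_stage(stage, cfg)

    stats = pd.read_csv(RUN / "factor_stats.tsv", sep="\t")
    print("per-factor boundary overlap (ranked by boundary metagene):")
    for r in stats.itertuples():
        print(f"  {r.rank}. {r.factor}: {r.boundary_fraction:.1%} of peaks on "
              f"boundaries, {r.intra_tad_fraction:.1%} intra-TAD, "
              f"enrichment {r.enrichment_ratio:.1f}x, "
              f"boundary-associated={r.is_ba}")
    groups = pd.read_csv(RUN / "boundary_groups.tsv", sep="\t")
    print("\nfour-way boundary groups (anchor = CTCF):")
    print(groups.to_string(index=False))


if __name__ == "__main__":
    main()
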