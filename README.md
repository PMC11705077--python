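# boundarykit

Chromatin is partitioned into topologically associating domains (TADs):
self-interacting intervals of 0.2–1 Mb visible as blocks in Hi-C contact
maps, separated by boundary bins at which cross-contact drops. A growing
class of RNA-binding proteins and transcription factors binds
preferentially at these boundaries, and their co-occupancy and the local
transcriptional state correlate with how strongly a boundary insulates.
`boundarykit` is a toolkit for that integrative analysis — for
computational genomicists who have binned Hi-C matrices, ChIP-seq peak
sets and nascent-transcription tracks and want to connect them:

- **Hi-C core** — ICE matrix balancing (iterative correction until the
  marginal coefficient of variation falls below tolerance), distance-decay
  expectation, observed/expected (O/E) transformation, and A/B compartment
  calling from the first principal component of the Pearson-correlated
  O/E map (oriented so gene-rich = A = positive PC1).
- **TAD calling** — TopDom-style detection at 10-kb bins: for each bin the
  *bin signal* is the mean contact of the `w x w` rectangle straddling the
  bin edge; boundaries sit at local minima, filtered by a one-sided
  Wilcoxon rank-sum test (flanking-domain contacts vs cross-boundary
  contacts, Benjamini–Hochberg corrected). Per boundary an insulation
  score `IS = max(signal outside) − min(signal inside)`, per TAD a domain
  score `D = intra-TAD contacts / all contacts involving the TAD`.
- **Peak integration** — boundary/intra-TAD overlap fractions per factor,
  RPM metagene profiles around boundaries, boundary-associated-factor
  classification (central/flank enrichment ratio), four-way
  `±CTCF × ±factor` boundary stratification, peak–peak overlap fractions.
- **Co-occupancy NMF** — cis-regulatory elements from 1-kb summit
  merging, binary CRE×factor occupancy matrix, multiplicative-update NMF
  with consensus rank selection (cophenetic correlation and dispersion
  coefficients over restarts), argmax group assignment.
- **Aggregate maps** — rescaled aggregate domain analysis (ADA) and
  fixed-window boundary pile-ups with intra/inter quadrant contrast.
- **Transcription link** — RPM quantification over intervals, length-
  matched shuffled controls inside container intervals, L/M/H tertile
  stratification, rank-sum association tables.
- **Synthetic data** — a planted-truth generator (power-law distance
  decay, multiplicative cross-boundary insulation, compartment
  checkerboard, boundary-enriched peaks with shared co-occupancy pools,
  Poisson tracks) so every stage is testable by parameter recovery.

## Worked example

Run the numbered drivers under `analysis/` (each writes tables under
`results/` and prints what it found), or the equivalent CLI:

```sh
python analysis/01_simulate.py
python analysis/03_call_tads.py
python analysis/06_aggregate_maps.py
# same stages via the CLI:
boundarykit run-all --outdir results/run --seed 1
```

On the default simulated chromosome (1000 bins at 10 kb, ~13 TADs of
50–100 bins, boundary insulation depth 0.3, 2×10⁶ read pairs, seed 1)
this prints:

```
called 12 boundaries vs 12 planted; precision 0.92, recall 0.92, F1 0.92 (±1 bin)
insulation score: median 0.81 (IQR 0.78-0.88)
domain score: median 0.82 over 13 TADs

boundary pile-up over 12 anchors (flank 200 kb):
  intra-TAD O/E: upstream 1.13, downstream 1.11
  inter-TAD O/E: 0.39
  inter/intra ratio: 0.35 (planted insulation depth [0.3])
```

Reading: the caller recovers essentially all planted boundaries within one
bin; the pile-up's cross-boundary (inter) O/E of ~0.35 of the within-TAD
level recovers the planted attenuation of 0.3 after Poisson noise and
calling tolerance. `analysis/04_boundary_factors.py` then shows the two
factors planted with 50% boundary placement flagged boundary-associated
and ranked above the 10% factors, and `analysis/05_cooccupancy_nmf.py`
recovers the two planted co-occupancy groups at the chosen rank.

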