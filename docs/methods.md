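# Methods

## Synthetic contact model

One simulated chromosome is a tiling of TADs with sizes drawn uniformly
from `tad_size_range` (the final domain absorbs the remainder; if the
range is too narrow to split the tail, the last domain may exceed the
maximum by less than the minimum size). Expected contacts are

    E[i, j] = A * (1 + |i−j|)^(−α) * m(i, j) * c(i, j)

with `α = decay_exponent` (default 1.0, the contact-probability decay
regime typical of mammalian Hi-C at the 0.1–10 Mb scale), `m` the product
of the insulation depths of all planted boundaries between `i` and `j`
(each in (0, 1]; 1 = no insulation, default 0.3), and `c` a compartment
factor (1.3 for bins sharing an A/B label, 1/1.3 across labels —
symmetric on the log scale so PC1 of the correlation map is sign-balanced;
off by default, enabled by `compartment_block_bins > 0`). `A` is set so
the expected upper-triangle total equals `depth` (default 2×10⁶ pairs, a
realistic per-chromosome count for a moderately sequenced library at
10-kb bins). Counts are Poisson draws of the upper triangle, mirrored, so
matrices are exactly symmetric. Multiplicative cross-boundary insulation
was chosen as the simplest model under which insulation-score recovery is
monotone in the planted depth and therefore testable; Poisson (not
negative-binomial) noise suffices for the recovery properties tested —
over-dispersion is a possible extension, off by default.

Factor peaks: each factor's number of boundary-resident peaks is
Binomial(`n_peaks`, `boundary_fraction`); boundary peaks sit at uniform
positions inside boundary bins, the rest uniformly outside them. Factors
sharing a `group_id` draw summits from one shared latent pool with
independent per-factor dropout (default 0.1 in the pipeline), which plants
the co-occupancy block structure that the NMF stage must recover.
Transcription-like tracks are per-bin Poisson with `amplitude` on target
bins and `background` elsewhere (defaults 8 and 1, a strong but not
artifact-free boundary enrichment).

One simulation call produces one chromosome; multi-chromosome data are
concatenations with independent seeds. Every generator is deterministic
given its seed; all pipeline randomness descends from the single config
seed via `numpy.random.SeedSequence`.

### What the generator does not emulate

Restriction-fragment geometry and read-level artifacts, loops/dots and
stripes, nested sub-TAD hierarchy, copy-number and mappability biases,
over-dispersed counts, and realistic peak-width/signal distributions.
Passing recovery tests therefore shows the estimators are correct and
well-conditioned under the stated model, not that they are robust to
every artifact of real libraries.

## Normalization and compartments

Bins whose marginal falls below the 2nd percentile of nonzero marginals
(or is zero) are masked; the quantile rule is an explicit, reproducible
stand-in for the upstream low-quality-bin filtering that production Hi-C
pipelines apply implicitly. Iterative correction rescales rows/columns by
`marginal / mean(marginal)` until the unmasked marginal CV ≤ 1e−5
(`max_iter` 2000 — plain iterative correction converges linearly, and
realistic decayed 1000-bin matrices need several hundred sweeps to reach
that tolerance; non-convergence sets a flag and warns rather than
raising). The O/E transform divides each entry by the mean of its
diagonal over unmasked pairs, so every diagonal of the O/E map averages
exactly 1. Compartments are called at 100-kb bins only (raw counts are
re-binned 10×, then balanced at the coarse resolution): the leading
eigenvector of the Pearson correlation of the O/E columns, oriented by
positive correlation with gene density, A = positive PC1. TAD calling
uses 10-kb bins only, mirroring the standard resolutions for the two
structures.

## TAD calling

The bin signal at bin `i` is the mean of the `w × w` rectangle
`m[i−w+1..i, i+1..i+w]` (default `w = 5`, i.e. 50 kb — TopDom's common
default). Candidates are leftmost ties of local minima within ±`w` bins.
Detection runs on the **O/E matrix**: on balanced counts the within-domain
vs cross-boundary rank-sum comparison is confounded by distance decay
(near-diagonal contacts always dominate), whereas on O/E the test
isolates insulation. Each candidate's one-sided Mann–Whitney p (upper
triangles of the two flanking `w × w` blocks vs the cross rectangle) is
BH-adjusted; candidates with q > 0.05 are dropped. Domains shorter than 3
bins are merged across their weaker (shallower-dip) separating boundary.

The insulation score is `max − min` of the bin signal over windows
reaching up to `w` bins into the two adjacent domains: the minimum is the
dip at the boundary, the maximum the domain-interior level, so a larger
score means a deeper dip and stronger insulation. (Conventions differ in
the literature — some report the dip value itself, where *lower* means
stronger; this package's score is the dip *depth*. Tests assert the
monotone relation to planted depth, not a sign convention.) The search
windows are bounded by `w` and by the domains themselves — the window
extent is a declared choice, as is the exact statistical filter; with a
different filter the absolute boundary count shifts, which is why the
package's guarantees are recovery properties rather than counts.

Domain score: `D = Σ intra-TAD contacts / Σ contacts involving the TAD`,
each unordered pair counted once, diagonal included; `D ∈ [0, 1]`, NaN
for a contact-free TAD.

Two-condition comparison: a TAD is *invariant* iff some partner TAD
matches both boundaries within 10 kb and has > 80% reciprocal overlap;
*merged* iff a larger partner contains > 80% of it and > 80% of another
reference TAD; *split* iff ≥ 2 partners are each > 80% contained in it;
*disappeared* iff its best overlap covers ≤ 20%; *rearranged* otherwise,
evaluated in that order so the classes are exclusive and exhaustive.
Boundaries are conserved iff within 10 kb of a partner boundary.

## Peak integration

A peak is boundary-overlapping if it intersects the single boundary bin
(optionally ± a flank; default flank 0, the most conservative reading —
published overlap percentages depend on an unstated boundary width, so
they are not treated as exact targets). Boundary assignment takes
precedence over intra-TAD; category fractions over
{boundary, intra-TAD, gap} sum to 1. Metagene profiles average
RPM-normalized windows around boundary bins (truncated windows dropped).
A factor is boundary-associated iff its central window (± 1 bin) exceeds
`ratio_threshold` (default 1.2) times its flank window (bins 10–20 on
both sides) — the published criterion is qualitative ("highly enriched"),
so the threshold and windows are explicit, configurable, and recorded in
the outputs. Ranking is by the central profile value, ties alphabetical.
Group comparisons use two-sided rank-sum with BH adjustment.

## Consensus NMF

Summits pooled over factors are chain-merged at ≤ 1 kb (single linkage);
`V[c, f] = 1` iff factor `f` contributed a summit to CRE `c`; rows with
fewer than two factors are dropped. Factorization minimizes squared
Frobenius error by multiplicative updates (500 iterations max, relative
tolerance 1e−6, `eps = 1e−12` guards), best of `n_restarts` (default 30;
20 in the pipeline) with per-restart seeds derived from the master seed.
For rank selection each restart assigns factors to the argmax row of `H`;
the restart-averaged connectivity matrix `C` gives the cophenetic
coefficient (Pearson correlation between the condensed distances `1 − C`
and the cophenetic distances of their average-linkage dendrogram — the
standard consensus-clustering convention) and the dispersion coefficient
`mean(4 (C − ½)²)`. The chosen rank maximizes the cophenetic coefficient
with dispersion as tie-breaker; cophenetic values within 1e−6 are treated
as tied, since differences at float precision among fully stable ranks
are noise. Factors (columns), not CREs, are the clustered units — this is
what the factor-group heatmap readout needs. With a single restart the
consensus is trivially binary and the dispersion is 1 regardless of
structure; the API therefore requires ≥ 2 restarts.

## Aggregate maps

ADA: each TAD ± `flank_frac`·length (default 0.5) is bilinearly rescaled
to `n_pixels`² (default 99, matching common pile-up conventions; exact
identity when the submatrix already has that size) and averaged NA-aware
per pixel — masked-bin pixels are ignored rather than whole anchors
dropped, which keeps low-coverage synthetic runs usable. Boundary
pile-ups average fixed `(2F+1)²` windows (default flank 500 kb as a
library default; the pipeline uses 200 kb on the 1000-bin chromosome so
that windows fit between boundaries). Quadrant contrast excludes the
centre row/column: the two on-diagonal blocks are intra-TAD, the
upper-right block inter-TAD; the exact block geometry behind published
bar quantifications is unstated, so this one is declared.

## Transcription link

Interval RPM = overlap-weighted track sum × 1e6 / track total (scale-
free by construction). Shuffled controls place an equal-length interval
uniformly inside a uniformly chosen length-feasible container. L/M/H
strata are tertiles of nonzero RPM (values below the lower cut L, above
the upper cut H, otherwise M — so all-equal values are all M);
zero-signal intervals form the separate "none" class, supporting the
with/without-transcription dichotomy. Association tables report two-sided
rank-sum p with BH q, median difference, and the ratio of group means as
the fold change (the computation behind published fold-change phrasing
is unstated; both summaries are emitted).

## Problem sizes and determinism

The shipped analyses and acceptance script use one 1000-bin (10-Mb)
chromosome at 10-kb bins with 2×10⁶ pairs, a 400-bin compartment/pile-up
chromosome at 4×10⁶ pairs, 200-bin single-boundary chromosomes for the
insulation sweep, and 200-CRE × 12-factor occupancy matrices — sizes at
which every recovery property is already stable while a full run stays in
seconds. Stage outputs are flat text with fixed formatting; re-running
with the same config and seed reproduces byte-identical files, which the
manifest checksums verify and the resume logic exploits.

## Known limitations

No loop/stripe modelling or calling; no nested TAD hierarchy; a single
chromosome per matrix; the statistical filter and window defaults are
declared conventions rather than reproductions of any particular
published tool's internals, so absolute boundary counts on real data will
differ from other callers even where the recovered structure agrees.
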