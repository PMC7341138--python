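# Methods

## Coordinate and orientation conventions

All coordinates are 0-based half-open (BED convention). The TSS of a
minus-strand BED6 record is `end − 1`, the standard RefSeq-derived
reading; flipping the strand of a record maps the TSS start ↔ end−1 and
is an involution. Fragments are strand-less merged outer spans of read
pairs; the midpoint of a fragment `[s, e)` is `floor((s+e)/2)`, which is
deterministic for even lengths. Promoter matrices are strand-oriented:
rows of minus-strand genes are reversed so that positive offsets are
always downstream of transcription; the reversal is applied to the
finished row, so a minus-strand row equals the plus-strand row reversed,
exactly.

## Occupancy matrices

`coverage_fpm` computes per-bp containment counts over each TSS ± flank
window; `midpoint_matrix` counts fragment midpoints in sliding windows
(default 60 bp at a 10 bp step, giving 195 window centers at
−970…+970 for flank = 1000). Window membership is half-open
`[center − w/2, center + w/2)` so that windows at step = window tile
exactly; the window must be even so the center grid stays integral.

Both tracks are normalized to fragments per million ("FPM"), where the
denominator is the number of fragments whose *midpoint* falls inside
the captured region set (the union of promoter windows), not the
genome-wide total — captured-library normalization should not be
diluted by off-target fragments. The one midpoint-based rule is applied
to both track types and recorded in the run log; raw-count mode is
available (`normalize=False`) and matrices carry a normalization tag so
mismatched inputs are rejected downstream.

Mononucleosome size selection defaults to 140–160 bp (the ~150 bp
band); the bounds are parameters because gel excision windows vary.

## The sensitivity statistic

`sensitivity_matrix` computes `log2((L + c)/(H + c))` cell-wise with a
symmetric pseudocount `c = 1` FPM (default). The pseudocount keeps all
values finite and maps cells empty in both digests to exactly 0 rather
than NA, which keeps band means and cluster features defined everywhere.
Light and heavy digests are depth-normalized independently (each to its
own per-million) before the ratio. The statistic is antisymmetric in its
arguments and strictly increasing in the light value. Positive values
are MNase-sensitive fragments (MSFs), negative values MNase-resistant
(MRFs); `classify_msf_mrf` applies the sign rule, with an optional
neutral band for a nonzero threshold. The log ratio is computed on the
midpoint-window matrices (the objects the heatmaps display); a per-bp
coverage mode is available through the same function since any matched
pair of matrices is accepted.

## Sorting, quartiles, clustering

Max-signal sorts are descending by per-gene row maximum with ties broken
by gene id, so orders are total and reproducible. Quartiles cut the
ranked gene list into 4 contiguous groups; when n is not divisible by 4
the earlier (higher-key) quartiles take the extra genes — an arbitrary
but documented remainder rule. Q1 always holds the highest keys.

k-means (Lloyd's algorithm, Euclidean distance on raw sensitivity rows,
best of `n_init = 10` restarts, fixed seed) groups promoters with
similar profiles; `k` defaults to 6 but is a free parameter since
nothing in the data fixes it. Rows containing NA are mean-imputed per
column for the clustering only and flagged. A z-score feature option
exists for users who want shape- rather than magnitude-driven clusters.
The "dominant −1 sensitive" promoter set is identified post hoc as the
cluster whose mean profile peaks inside the −200..0 bp band.

## Region summaries and the paired test

The −1-nucleosome band is operationalized as window centers with
−200 ≤ center ≤ 0 (membership by center, since the window grid is the
analysis unit). `region_summary` takes the NA-ignoring per-gene mean
over the band; `paired_t_test` forms per-gene differences between two
conditions (one pair per gene — the conservative reading when pairing
across conditions), computes `t = mean(d)/(sd(d)/√n)` with the sample
(n−1) standard deviation, and a two-sided Student-t p-value. Degenerate
inputs follow explicit contracts: zero-variance differences with
nonzero mean report t = ±∞ with p = 0 and a flag; identical summaries
report an undefined t with p = 1. NA pairs are dropped listwise and
counted. The expression check uses Spearman correlation by default
(robust to the heavy right tail of expression values); Pearson is a
flag.

## The synthetic digestion model

Each synthetic promoter carries nucleosome dyads at the canonical
offsets {−350, −200, −100, +50, +200, +350} around an NFR at roughly
−50..+40, per-dyad occupancy weights ~ U(0.8, 1.2), and a per-dyad
release probability ~ U(0.30, 0.50) shared between the light and heavy
digests at baseline. Sharing the baseline release probability is a
structural requirement, not a simplification: with a common uniform
background in both digests, the expected light and heavy midpoint
densities can only be proportional at every position (the null
construct) if the per-dyad release probabilities are equal.

MNase sensitivity enters through per-condition multipliers on the light
release probability: in the treated condition the −1 dyad (−100 bp) of
top-expression-tier genes has its light release multiplied by the
effect size (default 2.0, clipped to 1; 0 disables the effect). This is
the minimal mechanism that makes light-enriched nucleosomes yield
positive log2(light/heavy), and it localizes the planted change the way
a fast stimulus response would.

Fragments are drawn per gene: a background fraction (default 0.10,
a realistic non-nucleosomal floor for MNase libraries) lands uniformly
in the 2 kb window; the rest choose a dyad with probability
∝ occupancy × effective release, get a midpoint jittered by N(0, 20 bp)
(typical positional fuzziness of mapped dyads), and a length from a
truncated normal(150, 20) on [50, 200] bp, matching a ~150 bp
mononucleosome band from a 50–200 bp size-selected library. Exactly
`depth` fragments are emitted per gene per digest (default 2000 in the
benchmark design). Expression values are drawn from disjoint log-spaced
decade ranges per tier (Q1: 100–1000 … Q4: 0–1) so tiers are strictly
ordered; TF peaks (90 bp, centered at −5, the NFR midpoint) are placed
on every other top-tier gene. Genes tile one synthetic chromosome at a
spacing of 2·flank + 1 kb so promoter windows never overlap; strands
are all "+" by default with an option to randomize (orientation code is
exercised by tests either way).

Randomness is counter-based: every stream is
`default_rng(SeedSequence(seed, spawn_key=(purpose, gene_index)))`, so
identical configs are byte-identical on re-run and any gene subset or
digest/condition can be regenerated in isolation. Truncated-normal
lengths use inverse-CDF sampling on a single uniform draw, which keeps
the stream layout independent of acceptance/rejection behavior.

What the simulator does *not* model: sequence-level effects (MNase's
A/T preference, GC bias), replicate-level biological variance,
overlapping or nested promoters, chromosome edges, and occupancy
structure beyond the six phased dyads — the 2 kb window outside
±350 bp carries only the uniform background. Passing tests therefore
demonstrate that the pipeline recovers planted structure under clean
positional statistics, not that it is robust to every artifact of real
libraries.

## Recovery benchmark

`run_synthetic_benchmark` simulates the planted design (default 500
genes × 2000 fragments/gene/digest — sizes chosen so the whole 50-seed
suite runs on a laptop in minutes), analyzes it, and scores recovery:

- **Detection / specificity**: paired t-tests of the −200..0 band,
  treated vs baseline, on the top and bottom expression quartiles, plus
  a matched null-effect run (same seed, effect 0; the baseline digests
  are stream-identical, so only the treated digests are re-simulated).
- **Localization**: the position of the planted shift is estimated from
  the top-quartile mean Δ-sensitivity profile as the midpoint of the
  half-maximum interval around the absolute maximum. A plain argmax is
  unreliable here by construction: the log ratio saturates over every
  window the shifted dyad dominates, so the Δ profile is flat-topped
  (≈ −130..−50 at the default effect) and the argmax lands anywhere on
  the plateau. The half-max midpoint recovers −90 (10–15 bp from the
  planted −100) across seeds.
- **Set recovery**: k-means (k = 2) on the Δ-sensitivity columns in the
  −1 nucleosome footprint (−160..−40 bp), scored by adjusted Rand index
  against the planted treated/untreated labels. The footprint
  restriction is deliberate: the full 195-column rows are dominated by
  shot noise in the low-count flank/NFR cells at the study depth, which
  buries the planted contrast (ARI ≈ 0.05 on full rows vs ≈ 0.5–0.7 on
  the footprint at the default design, and 1.0 under stronger
  structure).
- **Construct checks**: the fraction of planted genes called MSF in the
  band, and the mean |per-gene row-mean sensitivity| of the null run.

A note on the null construct's convergence: the per-gene row-mean
sensitivity under the null is unbiased and shrinks as depth^(−1/2), but
at depth 10⁴ its standard deviation is ≈ 0.03, driven by the ~110
window columns outside the dyad array that carry only background
(~30 midpoints each). Tail genes can therefore exceed 0.05 in absolute
value at that depth; the bound is reliably met from roughly 4× that
depth.

## Pipeline behavior

The config-driven run (`run_full_analysis` /
`PromoterNucleosomeModel.fit`) validates the whole manifest before any
compute and aborts naming the offending condition and stage. Replicate
fragment files listed for the same digest are pooled on load and the
pooling logged. The baseline condition (default "untreated") anchors
all differential tests; each treated time point is compared against it
pairwise. Every applied default — mononucleosome bounds, window/step,
normalization rule, pseudocount, quartile remainder rule, k-means
settings, sort orders — is written to the run log, and identical
configs reproduce all outputs byte-identically. Heatmap/profile
plotting is an optional helper over the results object; the tested
artifacts are the matrices and tables themselves.
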