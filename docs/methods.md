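# Methods

## The measurement model

A directional bisulfite tagmentation library reads each DNA molecule on
one of the two original strands. Conversion chemistry turns unmethylated
cytosines into uracil (sequenced as T) while 5-methyl-cytosine resists
conversion. On the original-top (OT) strand a CpG is therefore scored at
its C position (`C` methylated / `T` unmethylated); on the original-bottom
(OB) strand the evidence appears at the paired G (`G` / `A`). Any other
base, or a base below the quality floor (default Q20), is an ambiguous
call. Because CpG methylation in bulk somatic data is overwhelmingly
symmetric across strands, evidence from both strands pools by default onto
the forward-strand C coordinate (`merge_strands=True`); pooling is by
summing counts and recomputing the beta, never by averaging betas, so
coverage weighting stays exact. A `--stranded` mode keeps OB evidence at
the G coordinate for strand-resolved work.

Counting is fragment-level: one sequenced molecule contributes at most one
call per CpG. Where mates overlap, the higher-quality base wins and ties
go to read 1. Coordinate-and-strand duplicates are collapsed at ingest
(OT and OB fragments at identical coordinates are distinct molecules and
are not collapsed together). Fragments with mapping quality below 30 are
dropped. All internal coordinates are 0-based half-open; SAM and
Bismark-coverage inputs (1-based) are converted once at ingest.

Downstream analyses use only CpGs inside the supplied peak intervals with
at least 5 informative reads: methylation outside enrichment peaks is
shallow and unreliable in this assay class, and 5 reads is the minimum for
a beta value worth interpreting.

## Groups and the cluster-confidence model

CpGs inside peaks are classified by methylation and coverage:

| label | methylation | coverage |
|---|---|---|
| G1 | beta < 0.20 | > 50 reads |
| G2 | beta < 0.20 | 5–50 reads |
| G3 | 0.20 ≤ beta ≤ 0.80 | 5–50 reads |
| G4 | beta > 0.80 | 5–50 reads |
| UNGROUPED | beta ≥ 0.20 | > 50 reads |
| EXCLUDED | — | < 5 reads |

Boundary values go to the interval whose description names them
inclusively (beta = 0.20 and 0.80 are intermediate; coverage 5 and 50 are
the low-coverage band). UNGROUPED exists because accessibility and
methylation are anticorrelated in real chromatin: intermediate-to-high
methylation with very deep accessibility coverage essentially does not
occur there. The simulator draws coverage independently of methylation,
so synthetic data do populate UNGROUPED; this is a deliberate,
documented difference from real data (see below).

The confidence that a CpG belongs to its assigned cluster treats the
observed beta *b* from *n* reads as approximately normal with mean *b* and
variance *b*(1−*b*)/(*n*−1), and evaluates Φ((C_h−b)/s) − Φ((C_l−b)/s)
for the cluster's methylation bounds (C_l, C_h); the G1/G2 bounds are
(0, 0.2), G3 (0.2, 0.8), G4 (0.8, 1). Φ is evaluated with `math.erf`
directly — no tables, no Monte-Carlo in the production path. When
*b* ∈ {0, 1} the variance collapses; the probability is then 1 if *b* lies
in [C_l, C_h) and 0 otherwise, which is the point-mass limit of the same
formula. Coverage enters only through *n*: the model is one-dimensional in
beta.

**Accuracy.** Against a 30-digit normal CDF the erf evaluation is exact to
< 1e−6 everywhere. Against the discrete reality of binomial counts the
*normal approximation itself* is good to < 0.03 when it applies (interior
beta, bounds not clipping the lattice of k/(n−1)), but degrades at low
read counts: at n = 10 with the cluster bounds the true error reaches
0.03–0.3, worst when a bound falls next to an atom of the k/9 lattice or
when beta sits near the support edge (e.g. b = 0.9 against (0.8, 1.0),
where the excluded atom at 1.0 carries 39% of the mass). Membership
probabilities at coverages near the 5-read floor should be read as rough
confidence scores, not calibrated probabilities. This is a property of
the model, and it is asserted in the tests exactly where it holds.

## Motif analysis

PWMs are built from JASPAR count matrices with a pseudocount
(default 1): p = (count + pc) / (colsum + 4·pc), scored as
log₂(p/background) with a uniform background by default. The score
threshold for a target p-value comes from the exact distribution of the
score under the background model, computed by position-wise convolution on
a 0.01-bit grid — discretization error is at most one grid step per
position. The scanner evaluates every window on both strands (minus
strand via the reverse-complement matrix) and skips windows containing
non-ACGT bases; it is validated against exhaustive enumeration.

Hits are annotated with the 1-based motif offsets whose genomic sequence
(in motif orientation) carries a CpG, each mapped to its forward-strand C
coordinate; for a minus-strand hit starting at *s* with width *W*, a
forward CpG with C at *p* appears at offset *s* + *W* − 1 − *p*. For the
19-bp CTCF motif these are the C2/C12 positions. Per-offset beta vectors
are compared with a two-sample rank-sum test (normal approximation with
tie correction; `scipy.stats.mannwhitneyu`), and a paired signed-rank
variant serves the same-CpG-two-assays comparison. When one CpG maps to
several overlapping hits it contributes once per (hit, offset);
`unique_cpg=True` collapses to the best-scoring hit.

Per-molecule co-methylation of a CpG pair uses only fragments with
unambiguous calls at both positions, builds the MM/MU/UM/UU table, takes
expected counts from the table's own marginals, and reports the Pearson
chi-square with one degree of freedom (no continuity correction) together
with the observed and independence-expected MM fractions. Pairs pooled
over all hits genome-wide are the default; per-hit tables are available.
Degenerate tables (< 2 informative fragments, or a marginal at 0 or 1)
return undefined chi-square rather than a value.

## The synthetic-data generator

`simulate` builds a single-contig toy genome (default 200 kb): a CpG-free
random background (any G following a C is resampled) with
round(0.02 × length) CG dinucleotides planted at random positions, so CpG
density is controlled to the target. Fifty non-overlapping peaks
(width ~ N(400, 100²) bp) stand in for accessibility/occupancy intervals.

Each CpG draws a methylation class — low / intermediate / high with
weights 0.7 / 0.2 / 0.1 — and a true beta within the class range:
low ~ 0.2·Beta(1.5, 6) (mean ≈ 4%), high mirrored near 1, intermediate
0.2 + 0.6·Beta(2, 2). Bulk methylomes are strongly bimodal — CpGs in
accessible regions sit near zero methylation, closed-chromatin CpGs near
full methylation — and boundary-light laws keep the class of a CpG
identifiable from 5–50 reads; a uniform law would pile probability onto
the 20%/80% boundaries, where no finite coverage can resolve the class.

Fragments have truncated-normal lengths (180 ± 50 bp, clamped to
[50, 1000]) and are placed with starts uniform over the peak padded by the
fragment length, which makes expected coverage flat across the peak.
Depth targets are **sequenced-base** coverage: only min(2 × 50, length) bp
of a fragment are read by its two 50-bp mates, and the fragment count is
scaled accordingly (defaults: 60× inside peaks, 2× background). Strand is
OT/OB with probability ½. For every CpG whose informative base lies in
the fragment, a Bernoulli(true beta) state is drawn; designated CpG pairs
can be drawn jointly through a Gaussian copula with latent correlation
`cometh_rho`, which preserves both marginals exactly for any rho. Read
bases then follow the chemistry: unmethylated CpG cytosines convert with
probability 0.99, methylated ones fail to be protected with probability
0.01, non-CpG cytosines (and the OB-strand equivalents on G) always
convert, and a flat 0.001 per-base sequencing error is applied last.
Reads are emitted as an already-aligned proper-paired SAM with flags that
round-trip through the ingest-side strand inference; alignment itself is
out of scope. Truth tables (per-CpG class and beta; per-fragment origin,
strand and state draws, flagged by whether the informative base was
actually sequenced) are written beside the outputs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: coverage is independent of methylation (real
accessibility coverage anticorrelates with methylation, emptying
UNGROUPED), there is no PCR-duplicate structure beyond an optional flat
duplication rate, base qualities are flat, there are no indels or
alignment errors, CpG density has no island structure, and conversion
efficiency is position-independent.

## Numerical and design choices

- **Aggregation yardstick for recovery.** Estimated betas are compared to
  truth as an RMSE over CpGs with ≥ 20 reads, measured against the
  binomial floor aggregated as sqrt(mean b(1−b)/cov) — the RMS of the
  per-site sampling SD, which is the scale an RMSE is commensurable with.
  (The arithmetic mean of per-site SDs is strictly smaller on any
  heterogeneous methylome by Jensen's inequality and is exceeded even by
  an exact caller.) Because a single default-scale run yields only ~700
  qualifying CpGs, the validation experiment pools 12 replicate
  simulations at identical conditions; with default noise the ratio sits
  near 1.06, against 1.00 for noise-free chemistry.
- **Problem sizes.** Validation experiments run at the generator's
  standard scale (200 kb, 50 peaks, 60× peak depth; ~22k fragments per
  replicate); the grouping-recovery experiment uses 30× peak depth so
  grouped sites fall inside the 5–50 read band and label proportions are
  comparable to the mixture weights. Scanner validation uses 20 seeded
  2-kb sequences with motif widths 2–6, where exhaustive enumeration is
  exact and fast.
- **Quadrant threshold.** The 2×2 peak classification uses a single 0.5
  threshold per axis, ties to the high side; configurable.
- **Annotation precedence.** promoter > intragenic > intergenic, with the
  promoter window TSS ± 3 kb. The separate `intergenic_min_dist` knob
  (default 1 kb) does not change labels; it marks intergenic regions as
  distal when farther than that from any promoter window, since the two
  distance conventions are independent choices a user may want to vary.
- **Co-methylation calibration betas.** The calibration experiment uses
  marginals 0.3/0.4 with 600 pairs per replicate, keeping all four
  expected cells ≥ 70 so the chi-square's asymptotic level holds (measured
  4.8% at nominal 5%).
- **Determinism.** Every stochastic component takes a NumPy Generator
  seeded from the run seed; the analysis pipeline itself draws no random
  numbers, so reruns are byte-identical.

## Known limitations

- The cluster-confidence model is miscalibrated at low coverage (see
  above) and treats reads as independent; PCR duplicates that survive
  coordinate dedup would overstate *n*.
- The caller assumes gapless alignments; fragments whose mates carry
  indels are skipped (counted, not silently dropped).
- The exact-threshold DP assumes independent background positions; a
  Markov background is not implemented.
- The simulator's flat error model cannot probe quality-dependent calling
  artifacts.
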