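# Methods

This note documents the models and numerical choices behind `cnascanner`, in
the spirit of a software methods supplement: what is assumed, what the knobs
mean, and what a green test does and does not establish.

## Problem setting

High-coverage (~30x) single-cell whole-genome sequencing after amplification
(PTA or MDA) carries two confounders for copy-number inference: allelic
dropout (ADO), where one allele fails to amplify over a kilobase-scale
stretch and mimics a loss, and multiplicative depth waviness shared across
both alleles. The package infers, per cell and genomic segment, an integer
allele-specific copy-number state (a, b) from two signals: the read-depth
ratio (RDR, observed over GC-expected count per bin) and the phased B-allele
fraction (pBAF, haplotype-aggregated allele depths of germline heterozygous
SNPs per bin).

## ADO model and bin-size selection

Site-level BAF at gHETs is binarized: 0 iff |BAF − 0.5| < 0.2 (the boundary
value 0.2 counts as homozygous-looking; an explicit 1e-12 float tolerance
enforces this for values like 0.7). A two-state hidden Markov model with
Gaussian emission densities is fitted by Baum–Welch (hmmlearn) with 10
random restarts and tolerance 1e-4, seeded explicitly.

*Numerical choice.* With free emission variances, the Gaussian likelihood of
binary data is maximized by collapsing the states onto the support points
(means 0/1, variance at the floor), after which the fitted "transitions" are
merely observed switching rates and the hidden chain is unrecoverable. We
therefore tie each state's variance to its mean as the Bernoulli variance
m(1 − m), floored at 0.15. The floor caps the peak Gaussian density near 1 —
the probability-mass scale of binary data — and parameter recovery on chains
with stay-probabilities 0.95/0.90 is then accurate to ±0.01 at n = 10,000.

Decoding is by Viterbi (contiguous-run semantics); each maximal run of the
high-emission-mean state is an ADO event with length last − first + 1 over
its gHET positions. The bin size is the smallest ladder entry at or above
the empirical 95th percentile (sorted-sample value at 1-based index
⌈0.95 n⌉, so exactly the top 5% of a tie-free sample exceed it). With no
ladder, the percentile is rounded up at 1 kb granularity with a 10 kb
minimum; below 20 events a configurable default (100 kb) is used.

## GC normalization

Expected counts come from a robust lowess fit (frac 0.3, 3 robustness
iterations) of per-bin count against GC fraction, rescaled so fitted values
average exactly 1 over training bins; expected = mean count x model(GC).
This is a bin-level stand-in for nucleotide-resolution normalization; an
externally produced expected-count track can be injected via
`compute_rdr(..., expected=...)`. Bins with under 50% mappable bases are
masked. The stand-in is validated by its flatness properties (exact recovery
of a linear GC relation; residual |corr(RDR, GC)| < 0.05 on simulation), not
by equivalence to any nucleotide-level model.

## Joint segmentation

The multinomial read-split likelihood of a segment with observed/expected
sums (a, b) is a log(a/(a+b)) + b log(b/(a+b)) (0 log 0 = 0). The
multi-sample criterion adds, per breakpoint, a penalty G λ log(Σₖ Nₖ) with
Nₖ the cell's total observed reads. Merging is greedy from singleton bins:
at each step the adjacent pair whose merge lowers the criterion most is
merged (ties to the leftmost pair, so output is deterministic and invariant
to cell order); merging never crosses a chromosome boundary. Per-segment
sufficient statistics make each sweep O(boundaries x cells); a 1,500-bin,
40-cell genome segments in seconds. On instances small enough for brute
force (≤ 14 bins) the greedy optimum matches the exhaustive minimum in our
tests; only a within-1% guarantee is asserted, since greedy agglomeration
is not globally optimal in general.

*λ calibration.* Amplified single-cell counts are overdispersed relative to
the multinomial model, and the appropriate λ scales with that overdispersion.
`lambda="auto"` estimates φ from adjacent-bin Pearson statistics (median
across pairs, scaled by the χ²(1) median — robust to true changepoints) and
sets the per-breakpoint penalty at the upper tail of the φ·χ²(G) null
deviance (mean + 4 sd). Fixed numeric λ remains available.

*Allelic refinement.* The joint criterion uses depth only, so copy-neutral
LOH boundaries are invisible to it. Within each depth segment, the same
greedy merge is re-run per cell on haplotype counts (observed = count_b,
expected = count_a, half-count pseudocounts), placing breakpoints where the
haplotype fraction changes. This resolves an ambiguity in the method's
published description, which states both depth-only segmentation and
merging by "similar RDR and BAF"; without some allelic breakpoints, cnLOH
detection at flat depth is impossible.

## LOH test and segment BAF

Per segment (≥ 10 informative bins; smaller segments are marked
low-confidence and assumed non-LOH), the haplotype-specific shift swaps
allele labels (b → 1 − b) on bins whose GC exceeds the segment median, and a
two-sample KS test compares allelic imbalance |pBAF − 0.5| before and after.
LOH is called iff the distributions are indistinguishable (p ≥ α, default
0.05) *and* the segment is homozygous-looking (median |pBAF − 0.5| > 0.4).

*Known limitation.* |pBAF − 0.5| is exactly invariant under the label swap,
so the KS comparison is degenerate by construction (statistic 0, p = 1); it
is retained as a reported diagnostic and for interface stability, but the
decision rests on the homozygosity condition. At the package's depth regime
(~1,500 informative allele reads per bin) that condition separates LOH from
balanced segments essentially perfectly; the type-I error on balanced
segments is far below α (asserted ≤ α + 0.02 over 500 segments).

Segment BAF: pBAF folded to [0, 0.5] (minor-allele convention, collapsing
the 1/3 vs 2/3 phasing ambiguity), Gaussian KDE with Silverman bandwidth
computed **on the folded data** and reflected about both edges (computing
the bandwidth on the reflected sample triples the spread and oversmooths the
density into a single central blob — a bug the test suite guards against).
Peaks below the edge band (default 0.1) are dropout artifacts and removed;
the highest-density remaining peak is the segment BAF, the median folded
value is the fallback, and LOH segments get BAF 0. A non-LOH segment is
floored at BAF 0.01 so BAF = 0 iff LOH holds exactly.

## Scale factor and allelic copy numbers

Balanced bins are those with 0.45 < pBAF < 0.55 (exclusive; widened to
(0.4, 0.6) with a warning below 30 hits). A Gaussian mixture with 1..t
components (t = maximum hypothesised whole-genome duplications, default 2)
over their RDR values is selected by BIC and the most-populated component
kept — with a guard: components whose means differ by less than 1.4x are
treated as one cluster, since ploidy-driven RDR modes differ by integer
copy ratios (≥ 1.5x) while amplification waviness produces closer spurious
modes. Candidate scale factors are γ(θ) = 2θ / mean(balanced RDR).

Each segment is scored over states (a, b), a ≥ b ≥ 0, 0 < a + b ≤ 8
(LOH segments restricted to b = 0) with Gaussian terms for RDR (mean
(a+b)/γ) and BAF (mean min(a,b)/(a+b)). Scales matter here:

- per-bin RDR sigma is a MAD estimate from the balanced cluster, and the
  segment-level standard error uses an AR(1) effective-sample-size
  correction sqrt(((1+ρ)/(1−ρ))/n) with lag-1 autocorrelation ρ estimated
  from genomically adjacent balanced-bin pairs — amplification waviness is
  correlated across bins, and the naive σ/√n is anti-conservative enough to
  flip ploidy selection;
- per-segment BAF sigma is the cell's balanced-bin folded-pBAF MAD scaled
  by 1/√n_bins, floored at 0.02.

θ is selected by BIC with a penalty of one unit per scored segment per
hypothesised duplication, with segments under 5 bins excluded from the vote.
Both choices are deliberate: each extra duplication doubles every segment's
candidate state grid, harvesting a small noise-quantization gain per segment
that accumulates linearly in segment count (an O(log n) penalty loses to it
and mislabels diploid cells as tetraploid), and sub-5-bin boundary-overhang
fragments genuinely carry fractional states that only the finer grid fits.
Ties break to smaller θ. A fully balanced genome is unidentifiable across θ
by construction (RDR is scale-free), so parsimony decides; conditioning on
known WGD status is exposed as `force_theta`.

After state assignment, a minimum-description-length smoothing pass absorbs
short (≤ 10-bin) state islands flanked by identically-stated, bin-adjacent
runs unless the island's own state is decisively better (−2 Δlog-likelihood
> 6, a χ²(1)-tail-scale margin). Without it, depth excursions fragment one
event into differently labelled pieces that fail reciprocal-overlap
matching; genuine short CNAs survive because their BAF term makes the drop
large. Adjacent same-state segments then merge into calls; states other
than the baseline (θ, θ) are reported, and calls under 2 bins are dropped.

## Synthetic-diploid simulator: the stated world

The generator emulates a diploid chromosome assembled from two
independently amplified haploid sources, at binned-depth and per-SNP
resolution (raw read-level simulation is out of scope; every signal the
caller consumes is preserved). Defaults describe one PTA-like cell at
30x-equivalent depth on a 150 Mb chromosome with 100 kb bins:

| parameter | default | rationale |
|---|---|---|
| haploid coverage | 15x (read length 100) | 30x total, the depth regime of high-coverage scWGS |
| shared amplification CV | 0.14, AR(1) corr. length 300 kb | locus-level waviness affecting both alleles; gives ~0.06 CV at 1 Mb, matching published PTA uniformity |
| allele-specific CV | 0.04 | PTA maintains allelic balance; keeps >80% of diploid bins inside the balanced pBAF band |
| GC bias | quadratic, ±20%, peak at GC 0.45 | the nuisance the normalization stage must remove |
| ADO | 20 events/Mb/haplotype, log-normal lengths (median 2 kb, σ = 0.6) | PTA-like kilobase dropout, ~5% of each haplotype |
| gHETs | 5 per 10 kb, Poisson allele depths | stated SNP density |
| phase switches | Binomial(0.01) per site, depths swapped | reference-phasing error rate |
| CNA sizes | geometric ladder, 13 sizes, 200 kb–5 Mb | benchmark ladder; midpoint is exactly 1 Mb |

Amplification fields are unit-mean Gamma marginals obtained by quantile
transform of an AR(1) Gaussian field. Spiked events modify haplotype B:
losses zero its depth, gains add one or two independently drawn replicate
fields (noise adds rather than scales), cnLOH leaves total depth untouched
and re-labels B reads as A at gHET sites. Truth intervals never overlap and
avoid 3 Mb chromosome-end exclusion zones.

What the simulator does **not** model: real read alignment and mappability
structure, chimeric amplification artifacts, sequencing error in allele
assignment beyond Poisson resampling, cell-to-cell shared (clonal) events,
and replication-timing covariates. A green benchmark therefore establishes
that the algorithmic chain is correct and well-calibrated under realistic
noise magnitudes, not that real-data performance at a given depth is
guaranteed.

## Evaluation harness

A truth interval is a true positive when a same-type, same-cell call
overlaps it reciprocally by ≥ 50% (the matching rule of the benchmark
figures is not published; 50% reciprocal overlap is the field's common
default and is exposed as a flag). Matching is greedy one-to-one by
decreasing overlap. Precision with zero calls is defined as 1. Bootstrap
CIs resample cells. Size-matched FDR maps each call to its type's table row
with the largest size strictly smaller than the call (smallest row as the
conservative fallback) and averages. Clonality requires *identical* start
and end bin coordinates and type in ≥ 2 cells; off-by-one-bin boundaries
are private by design.

## Known limitations

- The LOH decision is effectively the homozygosity guard (see above); a
  future refinement could implement a depth-aware shift with genuine power.
- Ploidy selection on a fully balanced genome is decided by parsimony, not
  evidence; `force_theta` exists for externally known WGD status.
- The greedy merge is not globally optimal; only near-optimality is
  asserted, and pathological noise configurations can in principle trap it.
- Subclonal (fractional) copy numbers and cross-cell smoothing of calls are
  out of scope.
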