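# Methods

`epiedit` implements the downstream computational analysis of a targeted
DNA-demethylation (CRISPR-dCas9-TET1) experiment as a reusable pipeline:
per-read bisulfite amplicon methylation calling, beta-value differential
methylation on EPIC-like arrays, Fisher-based enrichment of CpG subsets
and of principal-component loading genes, and intersection of
methylation-derived gene sets with differential expression.  All inputs
can be generated synthetically with planted ground truth, so every stage
is testable end to end without access-controlled human data.

## Exact statistics

Every enrichment question reduces to a 2×2 contingency table
`[[a, b], [c, d]]` where `a` counts items in both sets.  The two-sided
Fisher exact p-value sums the hypergeometric pmf

    P(X = a) = C(r1, a) C(N − r1, c1 − a) / C(N, c1)

over all tables with the observed margins whose pmf does not exceed the
observed pmf by more than a relative tolerance of 1e−7 (the standard
pmf-comparison rule; the tolerance absorbs floating-point ties between
equally probable tables).  All factorials are evaluated through the
log-gamma function and probabilities exponentiated at the end, so the
test is stable at array-scale counts (N ≈ 10⁶).  Odds-ratio conventions:
`(a·d)/(b·c)`; if exactly one cross product is zero the ratio is flagged
infinite (direction follows the nonzero product); if both are zero it is
undefined and the direction is `none`.  No Haldane-style continuity
correction is applied.

False-discovery control uses the Benjamini–Hochberg step-up rule,
`q_(i) = min_{j≥i} p_(j)·n/j` capped at 1, returned in input order.
One-sided tests, mid-p variants and Storey-type q-value estimation are
out of scope.

## Bisulfite amplicon layer

Alignment is "three-letter": both the read and the amplicon reference are
C→T converted before a semi-global alignment (match +1, mismatch −1,
gap −2, free end gaps), which makes the placement independent of
methylation state.  Methylation is then called back from the *original*
read base at each CpG reference column: C → methylated (M), T →
unmethylated (U), anything else or a gap → missing.  A read whose best
score falls below 0.5 per base is unalignable; in that case the reverse
complement of the read is tried through the same converted-space pass
(equivalent to a G→A pass for reads sequenced from the opposite
orientation) and the better-scoring placement wins.

Per-read QC: the bisulfite conversion rate is estimated from non-CpG
reference cytosines (T = converted, C = unconverted), identity is the
match fraction over aligned non-C reference columns, and CpG coverage is
the fraction of design CpGs with an informative call.  Default
thresholds — conversion ≥ 0.95, identity ≥ 0.9, coverage ≥ 0.8 — are
exposed in the configuration; they are conventional amplicon-QC values,
chosen once, not tuned.  Reads are assumed primer-trimmed or
full-amplicon; the free end gaps absorb overhangs, so there is no
explicit primer-clipping stage.

Summaries report per-CpG and overall mean methylation in percent over
non-missing calls.  Pattern maps only reorder rows (default: per-read
mean methylation descending, ties broken lexicographically on the call
pattern).  Read classification uses the per-read methylated fraction:
≤ 0.1 fully demethylated, ≥ 0.9 fully methylated, otherwise
heterogeneous — the thresholds are parameters.

## Array layer

Beta values (fraction methylated, in [0, 1]) arrive normalized; array
preprocessing (normalization, probe filtering) is out of scope.
Differential methylation between two groups is the difference of
per-group means, `delta = mean(reference) − mean(treatment)`, so probes
hypomethylated in the treatment have `delta ≥ +threshold` (default 0.2).
Probes with any missing value in a compared group are excluded and
counted; no imputation is performed anywhere in the package.

PCA treats samples as observations and probes as features, centers but
does not scale, and decomposes by SVD.  Components with a null singular
value (the centering always produces one) are dropped; each retained
component's sign is fixed by making its largest-magnitude loading
positive, and loadings have unit norm.  Locus clustering is agglomerative
(average linkage by default, configurable) on Euclidean distances between
sample beta vectors over the complete-case probes of a region.

## Enrichment procedures

Region sets (binding sites, predicted sgRNA off-targets) are extended by
a symmetric flank (default 1000 bp, clipped at zero) without merging;
both binding-site and off-target handling use this same ±flank rule.
Off-target predictions keep the top 50 scoring regions per guide; ties at
the boundary are all kept (logged) rather than broken arbitrarily.
Probe membership is the half-open test `start ≤ pos < end`, counted once
across overlapping windows.

Subset enrichment builds `a = |subset ∩ focal|`, `b = |subset \ focal|`,
`c = |focal \ subset|`, `d` = rest of the background and applies the
two-sided Fisher test.  The background defaults to all probes that
survive the differential comparison (complete cases), exposed as an
argument.

Gene enrichment of component loadings ranks probes by absolute loading
("associated with" a component; signed rankings are available via a
flag), takes the top k (default 5000), and tests each gene with ≥ 1 hit
using `a` = hits, `b` = rest of the list, `c` = the gene's remaining
array probes, `d` = everything else — i.e. each gene is corrected for its
total probe count on the array.  The exact 2×2 construction is this
package's reading of that correction; alternates would shift absolute
p-values but not the planted-recovery behaviour verified in the tests.
BH-FDR runs across the tested genes; rows are ranked by q, then p, then
gene label.  Probes without gene annotation stay in backgrounds but never
form a tested gene; a probe annotated to several genes contributes one
hit to each.

## Integration with expression

Genes of a hypomethylated CpG set (via manifest annotation) are
sequentially intersected with differential-expression gene sets supplied
as plain gene lists.  Matching is case-sensitive exact with an optional
upper-casing flag, and no concordant-direction filter is applied by
default.  The bundled `simple_de` is a Welch two-sample test on log2
values with BH-FDR and an |log2FC| cutoff — adequate for the synthetic
Gaussian generator; count data from a real experiment should be analysed
with a dedicated negative-binomial engine and passed in as a gene list.

## Synthetic data generators

All generators require an explicit seed (never defaulted from the
clock); identical seeds give byte-identical outputs, including the
writers, which use a fixed float format and timestamp-free headers.

* **Amplicon reads** are drawn from a mixture of per-molecule methylation
  components (weight + per-CpG Bernoulli probabilities).  Unmethylated
  cytosines convert to T except with the conversion-failure probability
  (default scenarios use 0.005); uniform substitution errors are applied
  last.  The packaged TSDR-like design is an engineered stand-in, not the
  genomic sequence: its primer annealing sites are cytosine-free (hence
  trivially bisulfite-compatible with the standard human TSDR
  bisulfite primer pair)
  and its inter-primer region carries exactly 15 CpGs plus one non-CpG
  cytosine per repeat unit for conversion QC.  Simulated reads have a
  uniform base-quality and no PCR amplification bias, paired-end
  structure or indel errors — passing tests bound calling accuracy under
  substitution noise only.
* **Manifest**: probes spread over 22 synthetic chromosomes with random
  spacing (20–2000 bp), gene labels assigned in consecutive runs
  (sizes 1 + Poisson, mean 20 probes/gene, ~85% of probes annotated,
  ~1% carrying two labels).  The full-scale profile emits 865,859
  probes.  Probe chemistry (type I/II) is not modelled.
* **Beta matrices**: per-probe baselines from a bimodal Beta mixture
  (half low-methylated Beta(2,10), half high Beta(10,2)), planted sets
  add a signed delta to one group's mean, replicates add Gaussian noise
  (default sd 0.03, matching tight array replicates) clamped to [0, 1].
  Baselines of planted probes are pulled into the range where the full
  delta is expressible — a demethylation target must be methylated — so
  planted truth is never silently truncated by the clamp.
* **Region sets** anchor each window on a probe drawn without
  replacement with weight `odds` for probes of a designated set, giving
  direct control of membership odds for calibration studies; a scored
  listing with guide ids accompanies the windows.
* **Expression**: log2-scale Gaussian baselines with an additive group
  effect on the planted genes.

## Problem sizes and calibration results

The validation suite runs the exact-test comparison over every 2×2 table
with N ≤ 40 against an integer-arithmetic enumeration oracle (agreement
better than 1e−12 relative), BH-FDR against the literal quadratic
definition on 100 random vectors (n ≤ 1000), amplicon recovery on 5,000
reads, differential-set recovery on 10,000 probes with 200 planted
effects (sensitivity ≥ 0.99, null calls ≤ 1%), enrichment calibration
over 1,000 null and 200 planted seeds (type-I ≤ 7% at α = 0.05, power
≥ 90% at odds 3), and an end-to-end PCA → top-k → gene-enrichment
recovery of 10 planted signature genes.  The demo pipeline defaults to a
20,000-probe manifest and 2,000 reads so a complete run takes seconds;
the full-scale manifest remains available through the configuration.

## Known limitations

* The amplicon aligner is per-amplicon and semi-global; it is not a
  genome-wide bisulfite aligner and does not reposition CpGs across
  indels beyond what alignment columns give.
* Beta-value noise is additive Gaussian, not the heteroskedastic
  intensity-derived noise of real arrays; conclusions about threshold
  calibration on real data should account for that.
* `simple_de` assumes roughly Gaussian log-scale values; it is a
  convenience for synthetic data, not a count-model replacement.
* Gene annotation in the simulator is contiguous-run based; long-range
  regulatory annotation structure is not emulated.
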