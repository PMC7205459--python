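# Methods

## The estimator

Each unique transposon insertion site is treated as a clonal lineage. A
gene's read proportion $N$ is the summed reads at filtered sites inside its
interval divided by all filtered reads in the sample (intergenic reads
included — the proportion is of *total* transposon reads; a genic-only
denominator is available via `denominator="genic"`). With the population
expanding $d = 2^{g}$ fold between the input sampling and the
post-selection sampling, the per-gene fitness is

$$W = \ln(N_{t2} d / N_{t1}) \,/\, \ln((1-N_{t2}) d / (1-N_{t1})).$$

The score is the gene's log expansion relative to the log expansion of the
rest of the population. Key identities, all enforced by tests: $W(N,N)=1$
exactly; $W(N, N/d) = 0$ exactly; $W$ is strictly increasing in $N_{t2}$;
and for a rare gene whose lineages expand as $d^{w}$ against a reference
expanding as $d$, $W \to w$. For abundant genes ($N$ not $\ll 1$) the
denominator's $(1-N)$ terms make the score mildly nonlinear in $w$; this
is a property of the estimator, not of the implementation.

The exponent is parameterised as $g = g_{t2} - g_{t1}$ (default $11 - 1 =
10$): the input library is sampled after one untreated generation, the
selected culture after eleven generations, and the score normalises by the
expansion between those two sampling points.

## Processing order and edge cases

1. **Pooling.** Input-library replicates (default three) are pooled by
   site-wise read summation before anything else. Summing counts rather
   than averaging per-gene values is variance-optimal for multinomial
   counts and makes the subsequent filter see the full evidence for each
   site; per-replicate proportions are scale-invariant, so downstream
   numbers are unchanged where coverage is deep.
2. **Filtering.** Unique sites with fewer than `min_reads = 2` reads are
   dropped, per sample, after pooling. A position is one site regardless of
   read strand. No 5′/3′ terminal trimming of genes is applied.
3. **Proportions.** Reads are assigned to genes by interval lookup
   (1-based insertion point inside the gene's span; a read in two
   overlapping genes counts for both). tRNA/rRNA/transposon features are
   carried in the annotation but receive no proportion row and no score.
4. **Scoring.** Per non-essential gene: `ok` when observed at both
   timepoints; `no_data` ($W$ = NaN) when absent from the input library;
   `pseudocounted` when present at t1 but extinct at t2.

**Zero at t2.** An extinct gene's $N_{t2}$ is floored at
$c/(T + c)$ with $T$ the sample's filtered read total and $c = 0.5$ — the
Haldane–Anscombe half-count continuity correction for log-ratio estimators
with zero cells. A full unit pseudocount would raise the detection floor by
$\ln 2 / \ln d \approx 0.1$ and systematically overestimate lethal genes at
typical depth; the half count keeps the floor near
$(\ln d - \ln(T N_{t1}))/\ln d$, i.e. ~0.01–0.02 at $10^6$ reads. The
correction is exposed as `pseudocount` for users who prefer another value.
$W$ remains a conservative lower bound for these genes: at finite depth
nothing below the sampling floor is observable.

## Thresholds and profiling

Phenotype categories use fixed fitness boundaries: **strong** if any
condition has $W < 0.75$ or $W > 1.25$; else **moderate** if any condition
has $W < 0.9$ or $W > 1.1$; else **none**. Boundaries are strict
inequalities, advantages count as phenotypes, NA cells never trigger a
call, and essential genes (no insertions by construction) are tallied
separately. Two concentrations of one drug are always two independent
matrix columns.

Clustering uses agglomerative linkage on gene fingerprints: euclidean
distance with complete linkage by default (the common defaults of the
heatmap-style clustering tools this workflow uses), with correlation
distance ($1 - r$) and average/ward linkage as options. NA cells are
imputed to the neutral value 1.0 before distance computation so absent
evidence creates no artificial separation; a zero-variance profile under
the correlation metric is assigned the maximal distance 2 with a warning.
Genes are processed in lexicographic gene_id order, which fixes the tree
and leaf order across platforms; neighbor rankings break correlation ties
the same way. Neighbor correlations are Pearson, pairwise-complete over
conditions where both genes have data. Condition-axis clustering is
deliberately not performed (condition order is an experimental-design
statement, not a data inference).

## The synthetic-data generator

`simulate_experiment` draws a toy genome (gamma-distributed gene lengths,
non-overlapping genes, a configurable essential fraction flagged at
random), places `n_sites` unique insertion sites uniformly outside
essential genes, gives each site a log-normal($\mu=0$, $\sigma=1$) founding
abundance, and produces sequencing samples as multinomial draws of `depth`
reads over lineage masses. Input replicates are resampled from the library
unchanged (one neutral generation leaves proportions untouched); each
condition's sample first expands lineage $i$ by $2^{w_i g}$ with
$g = g_{t2} - g_{t1}$, matching the estimator's expansion window.
Intergenic lineages grow at $w = 1$ — the denominator treats the rest of
the population as the reference. No bottleneck is applied by default (the
experimental design selects inoculum sizes to avoid one); a `bottleneck`
founder count is available.

Default study-scale parameters: 1 generation at t1, 11 at t2, three input
replicates, essential fraction 0.15. Condition designs assign a designed
$w$ to a small fraction of genes (a few percent per class) with the rest
neutral, reflecting that a sub-inhibitory treatment perturbs a minority of
genes per condition; concentrating large fractions of the genome in unfit
classes depresses the population-average expansion and shifts all relative
scores upward — visible, and expected, if you design such a condition.

What the generator does **not** emulate: PCR amplification bias and
duplicate reads, mapping errors, site-level insertion-position effects
within genes, strand effects, chromosomal replication-origin coverage
gradients, and any real site-abundance distribution (the log-normal is a
configurable stand-in; the true library skew of any given experiment is
unknown). Passing recovery tests therefore demonstrate correctness of the
estimator under multinomial sampling noise, not robustness to those
artefacts.

## Numerical choices

- Neutral identity tolerance: 1e-12 relative (two `log` calls of equal
  arguments may differ in the last ulp).
- Gene intervals are 0-based half-open internally; GFF3's 1-based inclusive
  coordinates are converted exactly once at the I/O boundary.
- Site-abundance masses are stored as integers (≥ 1) after scaling the
  log-normal draw by 100, so libraries are exactly serialisable as read
  counts.
- All randomness flows through `numpy.random.default_rng` seeds;
  `simulate_experiment` derives stage seeds from one experiment seed via
  `SeedSequence`, so whole runs are byte-reproducible.

## Problem sizes used in validation

The recovery check runs 2,000 genes / 20,000 sites / $10^6$ reads per
sample — about 10 sites and 500 input reads per gene, a deliberately
moderate coverage at which class means of $\hat W$ sit within ±0.05 of the
designed values while per-gene noise is still visible. The end-to-end demo
uses 500 genes × 5 conditions at 200,000 reads. Both finish in seconds;
scaling to real-experiment size (~3,000 genes, 200,000 sites, 40
conditions) is linear in sites × conditions.

## Limitations

- No statistical significance or confidence intervals on $W$; the score is
  a point estimate and replicate concordance is the intended QC.
- Essentiality is taken from the annotation (or absence of insertions), not
  called from saturation statistics.
- Overlapping genes double-count shared reads in both numerators; the
  proportion-sum invariant $\sum_g N_g \le 1$ holds only for
  non-overlapping annotations.
- The multinomial depth model ignores overdispersion from library prep;
  real replicate scatter will exceed the simulated scatter at equal depth.
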