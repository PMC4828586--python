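# Methods

## The problem

Recurrent deletions at 22q11.2 are mediated by low-copy repeats (LCRs
A–D): most events span the ~3 Mb A–D interval (chr22:18.8–21.8 Mb,
hg19), a minority the nested ~1.5 Mb A–B interval (18.9–20.4 Mb).  In a
case-control screen for such a deletion, carriers are so rare (single
digits among thousands of samples) that every analysis step must respect
discreteness: the χ² Mantel–Haenszel statistic, mid-p corrections and
normal approximations are all unreliable here.  The package therefore
works with exact conditional distributions throughout.

## Exact stratified test

For stratum *k* with n1<sub>k</sub> group-1 samples, n2<sub>k</sub>
group-2 samples and m<sub>k</sub> carriers in total, conditioning on the
margins makes the group-1 carrier count

S<sub>k</sub> ~ Hypergeometric(n1<sub>k</sub> + n2<sub>k</sub>, m<sub>k</sub>, n1<sub>k</sub>)

under the null of no association.  Strata are independent, so the null
law of S = Σ<sub>k</sub> S<sub>k</sub> is the convolution of the
per-stratum pmfs.  Because m<sub>k</sub> is tiny, the support of S is at
most a few tens of integers and the convolution is computed exactly by
direct summation (`assoc._convolve`); per-stratum pmfs are evaluated via
the hypergeometric log-pmf and renormalised, which keeps the
computation overflow-safe for arbitrarily large cohorts.  Strata whose
carrier margin is zero have a degenerate pmf at 0 and are convolution
identities — they carry no information, which is why the test does not
suffer from the Simpson's-paradox pooling problem stratification is
meant to avoid.

p-values on the null pmf of S:

- one-sided ("greater"): P(S ≥ s_obs);
- two-sided, minimum-likelihood ("minlike"): Σ P(S = s) over all s with
  P(S = s) ≤ P(S = s_obs)·(1 + 1e-7).  The relative tolerance guards
  floating-point ties in symmetric tables.  A single stratum reduces
  the test exactly to Fisher's two-sided exact test (this is asserted
  against `scipy.stats.fisher_exact` in the suite, and the stratified
  case against R's `stats::mantelhaen.test(exact = TRUE)`).

The minlike rule, not the tail-doubling rule, reproduces classical
two-sided Fisher values: e.g. 2/804 vs 0/684 has upper tail 0.29 but
two-sided 0.50 because the opposite extreme is likelier than the
observed one.  When the observed total is the extreme of the support
and the opposite extreme is likelier, one- and two-sided p-values
coincide — the configuration of the bundled screen's meta-analyses.

### Sensitivity analysis

`loo_sensitivity` drops one study at a time (a study may own several
strata) and repeats the stratified test.  For the bundled screen, the
reported reproduction stratifies the remainder at study level (four
units); this reproduces the published bound max p ≤ 0.016, attained
when the largest study (NeuroX) is excluded.  Retaining the
within-NeuroX country stratification instead gives 0.027 when WTCCC2 is
excluded — a reminder that with counts this sparse the minlike
two-sided value is sensitive to how the remainder is stratified (the
one-sided value for that exclusion is 0.014).  Both stratifications are
available; the function is agnostic about which strata it is given.

## Call post-processing

- **Probe support**: calls with fewer than 10 SNPs are dropped
  (inclusive boundary: 10 is kept).
- **Sample QC**: exclude iff LRR_SD > 0.30, BAF_SD > 0.15 (strict
  inequalities), or CNV count > mean + 3·SD of the sample's own
  (study, group) cell.  Cell statistics are computed once on the
  pre-exclusion population (no iteration); SD is the n−1 sample SD, 0
  for a singleton cell.  Pooling across studies is available by flag
  (`pool_studies`).  Note the count rule is self-referential: a lone
  outlier in a cell of n samples has z at most (n−1)/√n, so the rule
  cannot fire in cells smaller than ~11.
- **Split-call merging**: within one (sample, chromosome, copy-number)
  group, sorted by start, neighbours both spanning > 100 kb (strict)
  merge when the gap (bases strictly between them, B.start − A.end − 1)
  is < 50% of the merged span; merged probe counts add; the scan
  iterates to a fixed point so chains of fragments re-join.  Merging is
  restricted to equal copy number because a split call necessarily
  shares its state.  Genuinely overlapping calls in a group coalesce
  unconditionally regardless of size — otherwise the output could not
  be guaranteed non-overlapping.  The greedy left-to-right scan is
  confluent with the any-order pairwise closure (the merge condition is
  monotone under interval growth); the suite certifies this against a
  random-order closure oracle.  Merged calls replace the visual review
  step of array workflows with a deterministic rule; the audit trail
  (per-sample exclusion reasons, provenance hashes) is the compensating
  control.
- **Carrier selection**: a sample is a carrier when some deletion call
  (copy number ≤ 1) covers ≥ 60% of the target region.  The denominator
  is the *region* length, not a reciprocal overlap — the question is
  whether the region is spanned.  An atypical distal deletion (e.g. a
  726 kb LCR B–D event) fails the 60% rule against the A–B region and
  is excluded from the primary analysis, matching the screen's intent
  of counting canonical-deletion carriers only.

## Population-frequency comparisons

With zero observed control carriers, the control frequency cannot
anchor a risk estimate, so an assumed population carrier frequency of
0.024% (~24 per 100 000) is used: expected control carriers n·f; an
exact upper binomial tail P(X ≥ x) for the case groups; and a fold
estimate, reported as the proportion ratio (x/n)/f (the odds ratio
variant agrees within 1% at these rarities and is also provided).  The
prevalence of early-onset disease with the deletion is the product
(disease prevalence per 100 000) × (early-onset share) × (carrier share
among early-onset cases), e.g. 140 × 4% × 0.5% = 0.028 per 100 000.

## Onset analyses

Early onset is onset strictly before 45 years (50 as a post-hoc
alternative); cases with missing onset are dropped from onset-stratified
analyses only.  The Mann–Whitney comparison of carrier vs non-carrier
onset ages uses the exact U distribution when |x|·|y| ≤ 10 000 with no
ties, otherwise the normal approximation with tie correction and no
continuity correction (two-sided p = min(1, 2·min(tail))); differences
from other software at large unbalanced sizes trace to the continuity
choice.  The published carrier/non-carrier onset medians and the
individual-level Mann–Whitney p cannot be recomputed here because
individual ages are not printed; the synthetic onset-model recovery
test covers this functionality instead.

## Synthetic cohorts

The generator emulates the screen's study conditions: the four study
sizes (593/726, 1592/4939, 740/1996, 6462/6202 cases/controls), case
carrier frequency 8/9387 with zero control carriers, onset ages
truncated-normal on (18, 95) years with Normal(42.1, 11.9) for carriers
and Normal(60.3, 12.8) for non-carriers (normality is a simulation
choice; only the moments are anchored in the screen), and 10% missing
onset among cases.  Other defaults are realistic rather than estimated:
~5 benign background CNVs per sample (Poisson, placed rejection-sampled
off the locus so planted truth is unambiguous), low QC-failure rates
(2%/1%/0.5% for LRR/BAF/count), and split-call artifacts off by default.
When splitting is enabled, fragment geometry is derived from the locus
and merge policy so that each fragment covers < 60% of the region while
both pass the 100 kb gate and the gap rule — carriers are then
recoverable only through merging, which makes split recovery a sharp
regression test.  Infeasible geometry (e.g. a span barely larger than
the region) raises at generation time.  QC-failing samples get metrics
drawn beyond the thresholds; planted count failures add +50 calls,
which stands out only when failure rates are low (see the
self-referential count rule above).

What the generator does **not** emulate: probe-level LRR/BAF signal,
GC waves, batch effects between genotyping arrays, relatedness, or
genuine population variation in deletion breakpoints.  Passing
end-to-end tests therefore demonstrates correctness of the
post-processing and statistics on well-formed call-level data, not
robustness of upstream CNV calling.

## Numerical and design choices

- Internal coordinates are 1-based inclusive (PennCNV convention); BED
  output converts to 0-based half-open at the boundary, with extra
  name/score/num_snps columns so the export round-trips losslessly.
- The declared `length=` field of rawcnv lines is advisory; coordinates
  are authoritative.
- Chromosome labels compare after stripping an optional `chr` prefix,
  case-insensitively.
- All thresholds quoted above are defaults of frozen dataclasses
  (`QcThresholds`, `MergePolicy`, `TargetRegion`, `OnsetPolicy`,
  `PopulationPrior`) and overridable per run; the YAML config mirrors
  them field by field.
- Determinism: one `numpy` generator seeded from the config; reports
  carry a config hash, seed and package version, and identical configs
  produce byte-identical fixtures and reports.
- Problem sizes in the test suite are scaled (e.g. quarter-scale
  cohorts, 200-seed calibration at zero background rate) so the whole
  suite completes in well under a minute while still exercising
  full-size counts where it matters (the bundled-count reproductions
  use the complete 9387/13 863 cohort sizes).

## Known limitations

- No VCF/SVTYPE input, no probe-intensity parsing, no GC-model
  correction — the package starts at call-level text.
- No asymptotic CMH statistic, Breslow–Day homogeneity test, or
  confidence intervals for the fold estimate and onset medians.
- The nested 1.5 Mb deletion class is not detected separately; a second
  run with the A–B region as target covers it.
- The minlike two-sided rule is discrete and can jump discontinuously
  with small count changes; for borderline decisions consult the
  one-sided value and the full null pmf, both of which every result
  object carries.
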