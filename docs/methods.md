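# Methods

## The analysis model

The pipeline treats a cross-sectional pediatric cohort as a set of
independent CpG-level regressions against age. For each probe *j* with
beta values β<sub>js</sub> ∈ [0, 1] over control subjects *s* with ages
a<sub>s</sub>:

* **Age association** is measured by Spearman's rank correlation
  ρ<sub>j</sub> = corr(rank(β<sub>j·</sub>), rank(a)), with mid-rank tie
  handling. The two-sided p-value uses the classical t-transform
  t = ρ·√((n−2)/(1−ρ²)) on n−2 degrees of freedom for n ≥ 10; for n ≤ 9 it
  is computed exactly by enumerating all n! orderings of the observed
  ranks. The switch point is fixed at 9/10 because full enumeration is
  cheap up to 9! and the t-approximation is accurate from n ≈ 10 upward;
  the intended cohort size (n = 22 controls) always uses the
  approximation, whose type-I rate at n = 22 is verified by simulation to
  sit within Monte-Carlo error of the nominal 0.05.
* **Effect size** is the oldest-minus-youngest difference
  δ<sub>j</sub> = β<sub>j,oldest</sub> − β<sub>j,youngest</sub>. This uses
  the two extreme-aged subjects only — deliberately, as the analysis is a
  screen for drift magnitude over the observed age span, not a slope
  estimate. Subjects tied at an extreme age are averaged; a missing
  extreme value falls back to the nearest-aged subject with data and
  flags the record.
* **Selection**: p < 0.05 and |δ| ≥ 0.10. Both cutoffs are uncorrected
  trend thresholds by design; the package applies no multiple-testing
  correction anywhere by default (a Benjamini–Hochberg helper exists for
  callers that want q-values). Direction (increasing/decreasing) is the
  sign of ρ, never of δ; probes where noise makes sign(ρ) ≠ sign(δ) are
  admitted, classified by ρ, and counted in a diagnostics field.

**DMR calling** is single-linkage chaining: per chromosome and direction,
sort selected CpGs by position and join consecutive CpGs while the gap is
≤ 15,000 bp (boundary inclusive). Maximal chains with ≥ 2 members are
DMRs. Chaining rather than a sliding window makes the result independent
of input order and idempotent (re-calling on a DMR's members reproduces
it). The two direction lists are never mixed. The plausibility of observed
chains is quantified by a null that redraws the same number of selected
probes uniformly from the manifest and measures the chance of ≥ 1 chain
and the expected chain count (exact pair enumeration for n = 2, seeded
Monte-Carlo otherwise). Both the per-pair and per-analysis probabilities
are reported, since "the chance of such association" is ambiguous between
them.

**Disease overlap** compares, per DMR, the per-subject mean beta over
member CpGs between controls and one disease group with the classical
pooled-variance two-sample Student t (two-sided). Pooled rather than
Welch because the variance model of a beta-average at matched loci is the
same in both groups under the null and the group sizes are small. Zero
pooled variance resolves by convention: p = 1 for equal means, p = 0
otherwise. Per-CpG t-tests are retained for the detailed table. The two
enrichment contrasts are two-tailed Fisher exact tests via the method of
small p-values — p is the sum of hypergeometric probabilities of all
same-margin tables no more probable than the observed one, computed with
exact integer weights so tail membership involves no floating-point
comparison. Contrast 1 (UC-associated vs CD-associated counts) places the
same DMR set in both arms; the run summary carries a note that the arms
are paired, so that p-value is a descriptive contrast, not a test on
independent samples.

**Microbiome linkage** intersects subjects present in both the beta
matrix and the genus relative-abundance table (mirroring a design where
only a subset of the methylation cohort is sequenced). Genus-age trends
use Pearson correlation at a relaxed p < 0.1 — explicitly trend-level at
n ≈ 10. A (DMR, genus) pair is linked when ≥ 2 member CpGs correlate with
the genus abundance at p < 0.1; the DMR-average correlation is reported
alongside. Abundances enter untransformed (the screening model treats
them as plain covariates); a log10(x + pseudocount) option exists but is
off by default, and no compositional correction (CLR, rarefaction) is
attempted — correlations with relative abundances are therefore subject
to closure effects, a known limitation.

**Compendium overlap** scores the intersection of two CpG sets drawn from
a common array universe with the hypergeometric upper tail
P(X ≥ k | N, |A|, |B|) and the expectation |A|·|B|/N. The universe
defaults to the post-filter probe count and is always printed with the
report. At the scale of a 450K screen (sets of ~600–1100 probes over
~390,000), expected overlaps are of order 1 and observed overlaps of 5–12
give tails between ~10⁻² and ~10⁻⁶ — many orders of magnitude larger than
astronomically small figures sometimes quoted for such overlaps, which no
hypergeometric model can produce at these sizes. The report always prints
the computed tail.

## Thresholds

| parameter | default | unit | role |
|---|---|---|---|
| `p_age` | 0.05 | two-sided p | Spearman age-screen cutoff |
| `delta` | 0.10 | beta fraction | minimum oldest-vs-youngest difference |
| `max_gap` | 15,000 | bp | chaining distance for DMRs |
| `min_cpgs` | 2 | count | minimum CpGs per DMR |
| `p_disease` | 0.05 | two-sided p | DMR-average t-test cutoff |
| `p_microbiome` | 0.1 | two-sided p | Pearson cutoff for trends and links |
| `min_link_cpgs` | 2 | count | member CpGs required to link a genus |

All seven live in one `Thresholds` block; the CLI accepts them from a
flat YAML file with flag overrides.

## The synthetic-data generator

`simulate_cohort` emulates the statistical structure the stages assume,
with machine-readable ground truth:

* **Cohort**: 22 controls with ages uniform on [3.5, 17.5] years and the
  extremes forced to exist, plus 10 UC and 10 CD subjects drawn from the
  same age law. The disease group sizes are the package's choice of a
  realistic pediatric biopsy cohort (the microbiome subset in such
  studies is of the same order); they are configurable.
* **Probes**: planted CpGs follow β = c + s·(age − midpoint) + ε with the
  slope set so the span effect |β(17.5) − β(3.5)| equals 0.25 by
  construction; centers are uniform on [0.25, 0.65] so values stay inside
  [0, 1] even with a disease shift. Noise ε is Gaussian (sd 0.03) with
  clipping to [0.02, 0.98] — chosen over Beta noise for transparent
  effect-size arithmetic; a moment-matched Beta mode is available.
  Planted probes sit in 40 regions (20 per direction) whose total span
  never exceeds 12 kb, so each fully recovered region is callable as a
  single DMR; null probes are spaced 20 kb apart, so no chance chain can
  form among them. That spacing is intentionally conservative: it makes
  the chance-DMR prediction exactly zero and pins any called DMR on
  planted structure.
* **Disease shifts**: half the planted regions carry a +0.15 beta offset
  in one disease group, assigned in a period-4 UC/CD/CD/UC pattern so
  disease is not confounded with the period-2 direction interleave of the
  region list. Shifts are age-independent, isolating the disease t-test
  from the age screen.
* **Genera**: 25 genera; abundance is exp(b<sub>g</sub> + 0.5·x)
  normalised per subject to sum to 1 (so columns are valid relative
  abundances). For the 5 coupled genera the latent signal is the convex
  combination x = c·(±z) + (1 − c)·ε of the standardized DMR-average beta
  z of the partner region and independent N(0, 1) noise — this is the
  package's definition of coupling strength c: c = 1 makes the genus a
  deterministic monotone function of region methylation, c = 0 decouples
  it. Signs alternate with period 4 so coupled genera trend both up and
  down with age. The mild exponent scale (0.5) keeps the link function
  near-linear, so Pearson correlation on the abundance scale retains most
  of the latent correlation.

What the generator does **not** emulate, hence what passing tests do not
show about real data: probe-type (I/II) chemistry differences, spatially
correlated noise and batch effects, cell-composition heterogeneity,
nonlinear age trajectories, compositional coupling between genera beyond
the shared normalisation, and read-count sampling noise in abundances.
Recovery rates measured here are upper bounds relative to real cohorts.

## Numerical and degenerate-input conventions

* Correlations require ≥ 3 complete pairs after listwise missing-data
  removal; constant vectors raise a degenerate-input signal that callers
  convert to "probe/genus skipped with a logged warning", never a run
  failure.
* Exact-p tail membership in the Spearman permutation path uses a 1e-12
  slack on |ρ| to absorb float jitter in ties; the Fisher tail uses exact
  integer weights and needs none.
* `percent` rounds half away from zero to one decimal via decimal
  arithmetic (so 82.608…% prints as 82.6 and 0.125% as 0.1, matching how
  such fractions are conventionally reported).
* BED output converts the internal 1-based inclusive spans to 0-based
  half-open intervals; score = round(1000·|mean ρ|) capped at 1000.
* Beta values outside [0, 1] are rejected with coordinates, never
  clipped; probes missing from the manifest are dropped with a count.

## Problem sizes used in tests and the reproduction script

The default synthetic study is 5,000 probes × 42 subjects. Calibration
experiments use 100 replicate cohorts of 2,000 probes (null) and 100
replicates of a minimal 40-probe cohort (linkage power); the joint-null
oracle simulates 10,000 probes. The exhaustive Fisher cross-check covers
all 135,750 tables with total ≤ 40; the Spearman enumeration check covers
vectors up to n = 8 (40,320 permutations each). These sizes give
Monte-Carlo standard errors comfortably below the tolerances being
asserted while keeping a full run on a single core in a few minutes.

## Known limitations

* The oldest-vs-youngest δ uses two subjects and is noisy by design; a
  regression-slope effect size would be more efficient but would change
  the screen's meaning.
* Contrast 1's Fisher p treats paired arms as independent (flagged in the
  summary); a McNemar-style test would be the strict alternative.
* Pearson on relative abundances ignores compositional constraints.
* The Spearman t-approximation is slightly conservative in the extreme
  tails at n = 22; exact enumeration is infeasible there and the screen
  threshold (0.05) is far from the affected region.
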