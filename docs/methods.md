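# Methods

`clonefish` re-implements, as a tested library, a single-cell clonality
analysis for childhood high-hyperdiploid B-cell acute lymphoblastic
leukemia (HHD-B-ALL, modal chromosome number > 50). The measurement it
models is sequential interphase FISH (seq-iFISH): three successive
hybridization rounds on the same nuclei count the eight chromosomes
typically gained in HHD (X, 4, 6, 10, 14, 17, 18, 21), so each nucleus
yields an integer copy-number vector. Everything downstream — subclone
encoding, heterogeneity statistics, gain-order inference, the
chr18→chr10 relapse predictor, survival validation and clonal-evolution
calls — operates on those per-cell vectors plus per-patient clinical
records.

## Subclone encoding and karyotype comparison

A nucleus is encoded as an 8-digit *subclone code*: per panel chromosome,
observed copies minus the constitutional baseline (autosomes 2; X is 1 in
males, 2 in females — sex is therefore required and the encoder refuses
to guess). Codes concatenate digits when all gains lie in 0–9 (e.g.
`11111012`); losses (−1) force an unambiguous comma-separated form.

The ISCN-subset karyotype parser extracts the same gain vector from
clinical karyotype strings so the cytogenetic major clone can be compared
with the FISH major subclone. Parsing rules, chosen to reproduce the
bundled discovery cohort's published concordance flags:

- the **first abnormal clone** (modal number ≠ 46 or any abnormality
  token) is the comparison clone; `46,XX`/`46,XY`-only strings and
  "High hyperdiploid by FISH" reports are uninformative (never a match);
- `+N`, `+N?` and `+?N` each add one gain; the X gain is the surplus of
  X copies in the sex-chromosome block over the constitutional count plus
  any `+X` tokens (handles `XXY`, `XXYY` and interleaved `54,X,+X,Y`);
- structural tokens (`add`, `del`, `dup`, `inv`, `ins`, `der`, `t(...)`),
  marker chromosomes (`+mar`, `+3mar`, `10mar`) and non-panel gains are
  ignored; clone-size brackets (`[15]`, `[cp7]`, `[56%]`) are stripped;
  modal-number ranges (`52-56`) are accepted.

On the bundled 22-case discovery cohort this yields exactly the 7
published concordant cases; most cytogenetic major clones differ from the
FISH major subclone, which is the finding that motivates single-cell
analysis.

## Cutoff calibration and filtering

iFISH miscounts a small fraction of nuclei even in euploid controls
(probe overlap → false losses ≈ 5% per chromosome; split signals → false
gains ≲ 0.37%). Per-chromosome, per-direction error rates p̂ are
estimated from pooled diploid controls, and the positivity cutoff is the
minimal count k\* with Pr[Binomial(n, p̂) ≥ k\*] < α, computed by exact
tail summation (no normal approximation); c\* = k\*/n. Defaults: α =
0.05 per chromosome/direction without multiplicity correction (a
Bonferroni option divides by the 8 × 2 tests). At the printed control
gain rate (p̂ = 0.0037, n = 200, α = 0.05) this gives k\* = 3, c\* = 1.5%.

Cell filtering keeps informative nuclei (signal in every channel) with at
least one chromosome **gain**; losses alone do not qualify a nucleus as a
hyperdiploid blast, and no-gain nuclei are treated as normal hematopoietic
cells. Samples need ≥ 200 informative hyperdiploid blasts to pass QC.
Clone-level filtering retains a subclone only if every non-zero aneusomy
it carries has a marginal sample frequency above that chromosome and
direction's cutoff; by default frequencies of retained clones stay
relative to all blasts, so the major-clone percentage is unaffected by
the filtering choice.

## Heterogeneity statistics

The clonal composition of a sample is the empirical distribution of
subclone codes over its blasts. Two summaries:

- **Shannon entropy** H = −Σ Pᵢ log₂ Pᵢ (bits, 0·log 0 ≡ 0), computed on
  the clone distribution of retained blasts before cutoff filtering.
  Base-2 logarithm throughout. The non-negative form with the minus sign
  is used (entropy is non-negative by definition).
- **PMC**, the percentage of the major clone; ties for the majority are
  broken by the lexicographically smallest code and flagged.

These are inversely related: sweeping the clone-frequency concentration
trades PMC against entropy, and the package asserts their negative rank
correlation as a property. Marginal per-chromosome gain rates are split
into trisomy (gain 1), tetrasomy (gain 2) and higher fractions; combined
fractions (e.g. the triple trisomy 4+10+17, or trisomy 18 irrespective of
other gains) count blasts gaining every chromosome of the set
simultaneously. Group contrasts use two-sided unpaired t-tests and
matched DX–REL contrasts paired t-tests (scipy).

## Chromosome-gain hierarchy

The acquisition order of gains is inferred from agglomerative clustering
of the cells × chromosomes gain matrix: Euclidean distances between raw
per-cell gain columns (pooled over the cohort, not frequencies), complete
linkage (scipy). A chromosome whose column separates from the remaining
set at a larger merge height sits nearer the base of the dendrogram and
is read as an earlier gain; ranks share a level at numerically equal
heights. Clone-by-sample frequency matrices are row-standardised
(population SD; constant rows zeroed and flagged) before clustering both
axes, matching the heatmap row-Z-score convention. Trees export to Newick
with branch lengths equal to merge-height differences.

## Risk predictor

Per-sample features are the eight per-chromosome gain percentages.

- **Ranking**: leave-one-out Random Forests (500 trees by default, fixed
  seed) collect Gini (mean-decrease-in-impurity) importances per fold;
  features are ranked by median importance.
- **Pair rules**: candidate two-chromosome rules are depth-2 axis-aligned
  threshold trees. The pair's score is the leave-one-out accuracy of a
  CART fit; the *reported thresholds* come from an exhaustive
  accuracy-maximizing two-threshold refit on the full data, taking the
  centroid of the near-optimal plateau (all threshold pairs within one
  misclassified sample of the optimum). The plateau centroid is used
  because the empirical-accuracy maximizer is an interval, and its centre
  estimates the underlying threshold with less variance than any single
  maximizer — CART's greedy second split, fitted on half the data, is
  noticeably noisier.
- **Deployed rule**: two steps — a sample with chromosome-18 gains
  ≤ 40% is unfavorable; otherwise chromosome-10 gains ≤ 40% is
  unfavorable; otherwise favorable. "Favorable" requires strictly
  exceeding both thresholds (boundary policy configurable); the rule
  trace records which step fired.
- **Stress test**: per repetition, every feature value x is perturbed to
  clip(x ± u, 0, 100) with u ~ Uniform(0, L) and an independent random
  sign, then reclassified; the mean correctly/incorrectly classified
  patients is reported per noise level L (default grid 0–30 in steps of
  5, 100 repetitions). At L = 0 the counts equal the noiseless confusion
  exactly, and a sample with margin m below a noise level L flips with
  probability 0.5 · (1 − m/L) — both are asserted in the tests.

## Survival analysis

Relapse-free survival runs from diagnosis to the first of relapse or
death; patients alive in remission are censored at last follow-up.
Kaplan–Meier curves (lifelines) are compared by log-rank; horizon
estimates read the step function at 5 and 10 years. Cox models (Efron
tie handling, Wald 95% CIs) enter age per 5-year increase, sex as a male
indicator, and treatment protocol as categories against a PETHEMA
reference; univariate mode fits one covariate at a time. Zero events or
non-convergence (separation) raise instead of returning garbage.

Continuous markers (PMC) are dichotomised by maximally-selected rank
statistics: candidate cutpoints are the observed values inside the inner
10–90% quantile range (preventing boundary cutpoints), each split is
scored by the standardized log-rank statistic, and the argmax is the
cutpoint. A maximum below 1.96 flags the cutpoint as unstable. No
selection-adjusted p-value is reported by default; downstream inference
should use the Kaplan–Meier/Cox comparison of the resulting groups.

## Clonal evolution (DX–REL pairs)

Matched diagnosis/relapse pairs are classified *shared* if any top-k
(default k = 3) diagnostic clone appears among the top-k relapse clones,
otherwise *replacement*. Major-clone membership additionally requires a
minimum frequency (default 5% of blasts): with a 5% per-chromosome
false-loss rate, single-loss variants of a true clone appear as distinct
minor codes and would otherwise fake shared patterns in small clone sets.
Both k and the floor are configurable, and a sensitivity table over
k ∈ {1, 2, 3, 5} is provided. Pair-level outputs include major-clone
persistence, shared frequency mass at each timepoint, per-chromosome
DX→REL gain-rate differences and a paired entropy test.

## Synthetic cohort generator

The single-cell data the analysis was designed around are not publicly
deposited, so the generator produces cohorts with the statistical
structure the pipeline assumes; every planted quantity is recorded in a
ground-truth ledger for recovery tests.

- **Clone trees**: the founder gains the first K chromosomes of the order
  21, 14, X, 18, 17, 10, 6, 4 (K uniform on 3–6), encoding early gains of
  21/14/X and late gains of 4/6; descendants derive from random existing
  clones by per-chromosome ±1 perturbations at the CIN rate (default
  0.05, gain-biased 0.8, digits clipped to [−1, 2]).
- **Planted group effects**: per patient, target %+18 and %+10 are drawn
  from the group means (favorable 60/60, unfavorable 25/25, SD 10) and
  planted exactly by assigning the gain to clones in decreasing-frequency
  order, splitting the boundary clone so the clone-mass marginal equals
  the target.
- **Heterogeneity coupling**: clone frequencies are symmetric Dirichlet;
  the per-patient concentration scales as (mean planted rate / 40)^3, so
  high-trisomy samples are more heterogeneous (higher entropy, lower
  PMC), reproducing the negative PMC-vs-trisomy-rate association as a
  generative property.
- **Observation model**: cells are drawn from the clone mixture, a
  configurable fraction (default 10%) are admixed normal diploids, then
  independent per-chromosome false gains (0.37%) and false losses (5%) —
  the diploid-control upper bounds — and optional signal dropout are
  applied.
- **Outcomes and survival**: group labels are the planted outcome; times
  are exponential with base hazard 0.0129/year (≈ 88% favorable RFS at 10
  years) and hazard ratio 11 for the unfavorable group, censored at a
  uniform 5–15-year follow-up horizon.
- **Matched pairs**: the `persistent` scenario keeps the diagnostic clone
  set and guarantees the DX major clone at least half the relapse mass;
  the `sweep` scenario regenerates relapse clones until code-disjoint
  from diagnosis. These pin the two evolution patterns by construction.

What the generator does **not** emulate: spatial/optical correlations
between FISH channels, probe-specific error rates (a single bound per
direction is used), clone phylogenies with convergent gains, treatment
effects, or competing risks. Passing tests therefore demonstrate that the
pipeline recovers planted effects under idealised independence
assumptions, not that it would do so on any real cohort.

## Numerical choices and problem sizes

Defaults: 500 cells/sample; 33 favorable / 17 unfavorable validation
patients; binomial cutoffs at α = 0.05 with n = 200 reference nuclei;
forest seeds fixed; stress tests 100 repetitions. The test suite checks
complete linkage against a brute-force agglomeration oracle (100 random
matrices, ≤ 6 leaves), binomial cutoffs against exact tail enumeration
over a (p̂, n, α) grid, Kaplan–Meier against hand product-limit fixtures,
planted Cox HR 3 recovery at n = 500 over 100 seeds, planted cutpoint 50
recovery over 50 seeds, and threshold/pair recovery over 50 seeds at
n = 200. All randomness descends from explicit seeds; cohort regeneration
from a fixed master seed is byte-identical.

## Known limitations

- The ISCN parser covers only the dialect needed for gain counting;
  structural variants are deliberately ignored, so a karyotype whose
  extra copies arrive via derivatives would undercount gains.
- Entropy and PMC are estimated from a finite cell sample; at 200 cells
  the entropy of a rich clone distribution is biased downward (the
  convergence test quantifies the decay of this error with cell count).
- The maximally-selected cutpoint is reported without a
  selection-adjusted significance level.
- With ~50 patients, single-cohort Cox hazard ratios for a strong
  predictor are heavy-tailed; the acceptance script reports the median
  across replicate cohorts for that reason.
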