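# clonefish

Single-cell interphase-FISH clonality analysis for childhood
high-hyperdiploid B-cell acute lymphoblastic leukemia (HHD-B-ALL).

## The problem

High hyperdiploidy — a modal chromosome number above 50, with
characteristic gains of chromosomes X, 4, 6, 10, 14, 17, 18 and 21 — is
the most common cytogenetic subgroup of childhood B-ALL and is usually
cured, yet a substantial minority of patients relapse even after reaching
minimal-residual-disease negativity. Conventional karyotyping averages
over the few blasts that divide in culture and misses the clonal
heterogeneity of the disease. Sequential interphase FISH (seq-iFISH)
counts all eight typically-gained chromosomes in the *same* nucleus over
three hybridization rounds, so each cell becomes an 8-digit *subclone
code* of per-chromosome gains relative to the constitutional baseline
(autosomes 2 copies; X: 1 in males, 2 in females), e.g. `11111012`.

`clonefish` is for analysts working with such per-cell copy-number
panels: it provides the full path from cell tables to risk calls —
binomial cutoff calibration on diploid controls, clonal-heterogeneity
statistics, chromosome-gain-order inference, a relapse risk predictor
with noise stress testing, survival validation, and diagnosis-relapse
clonal-evolution classification — plus a synthetic cohort generator that
makes every stage testable without access to patient data.

## The statistics at the core

- **Clonal heterogeneity.** For a sample with subclone frequencies
  $P_1,\dots,P_n$, Shannon entropy $H = -\sum_i P_i \log_2 P_i$ (bits)
  and the percentage of the major clone (PMC, $= 100\max_i P_i$)
  summarise heterogeneity; they are inversely related.
- **Positivity cutoffs.** With control error rate $\hat p$ per
  chromosome and direction, the cutoff is the minimal $k^\*$ with
  $\Pr[\mathrm{Bin}(n,\hat p) \ge k^\*] < \alpha$, computed by exact tail
  summation; an aneusomy is considered real only above $c^\* = k^\*/n$.
- **Gain hierarchy.** Complete-linkage agglomeration of Euclidean
  distances between per-cell gain columns; chromosomes separating at the
  largest merge heights (chromosome 21, then 14 and X) are read as the
  earliest gains, chromosomes 4 and 6 as late.
- **Risk predictor.** A two-step threshold rule on per-sample gain
  percentages: %+18 ≤ 40 → unfavorable; else %+10 ≤ 40 → unfavorable;
  else favorable. Candidate rules are ranked by leave-one-out
  Random-Forest Gini importance and depth-2 decision trees, and their
  robustness is measured by a uniform-noise injection stress test.
- **Survival.** Relapse-free survival (diagnosis to relapse or death) via
  Kaplan–Meier/log-rank and Cox models (age per 5-year increase, protocol
  against a PETHEMA reference); PMC is dichotomised by maximally-selected
  rank statistics.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Generate a small synthetic cohort (three favorable, two unfavorable
patients), run the pipeline, and classify:

```python
import clonefish as cf
from clonefish.pipeline import cohort_statistics, risk_classify

spec = cf.SyntheticCohortSpec(seed=7, n_favorable=3, n_unfavorable=2)
cohort = cf.generate_cohort(spec)
sexes = dict(zip(cohort.clinical.patient_id, cohort.clinical.sex))
stats = cohort_statistics(cohort.cells, sexes)   # filter blasts + summarise
calls, _ = risk_classify(stats)                  # chr18 -> chr10 rule
cols = ["sample_id", "n_blasts", "n_clones", "pmc", "entropy_bits",
        "pct_gain_18", "pct_gain_10", "risk_label"]
print(calls[cols].round(2).to_string(index=False))
```

```
sample_id  n_blasts  n_clones   pmc  entropy_bits  pct_gain_18  pct_gain_10  risk_label
    FAV01       446        77 23.32          4.38        60.31        51.35   favorable
    FAV02       455        61 23.74          4.06        41.98        56.26   favorable
    FAV03       460        49 30.22          3.51        49.35        42.61   favorable
    UNF01       443        55 27.54          3.89        22.80        41.53 unfavorable
    UNF02       446        61 24.66          3.95        26.23        24.44 unfavorable
```

Each of the 500 simulated nuclei per patient was filtered to informative
hyperdiploid blasts (~450 survive the 10% normal-cell admixture and
signal dropout), tabulated into subclone codes, and summarised: these
samples carry 49–77 distinct subclones with major clones at only 23–30%
of blasts — the high clonal heterogeneity typical of HHD — and the rule
classifies every patient by its planted %+18/%+10 group (the UNF01 call
fires at step 1, %+18 = 22.8 ≤ 40).

Two quantities computed from fixed published inputs rather than
simulation:

```python
k, c = cf.binomial_cutoff(0.0037, 200, 0.05)
# k*=3 (c*=1.5%): >= 3 of 200 nuclei must show an aneusomy at the
# 0.37% control false-gain rate before it counts as real

table, n = cf.karyotype_concordance(cf.load_discovery_cohort())
# 7/22 cases: the cytogenetic major clone matches the seq-iFISH major
# subclone in only a third of the bundled discovery cohort
```

A thin CLI wraps the same functions: `clonefish simulate`, `clonefish
calibrate`, `clonefish predict`, `clonefish stress`, `clonefish
concordance`.

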