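# cnarec

Copy-number-alteration (CNA) binning and a three-phase voting classifier for
predicting recurrence/metastasis in head-and-neck squamous cell carcinoma
(HNSCC) from segment-level genomic profiles.

## The problem

HNSCC patients recur after curative-intent treatment at high rates, and
clinical staging alone does not say who. Tumour genomes carry recurrent
copy-number gains and losses; the question this package addresses is whether
a small set of chromosomal regions, read from routine aCGH or SNP-array
segment calls, can stratify patients by recurrence/metastasis risk — and how
to handle the patients whose follow-up was too short for a recurrence to
have been observed.

## The method

Given per-patient CNA segment calls and clinical outcomes, the pipeline:

1. **Bins the genome** per chromosome by the cohort's mean alteration size,
   turning variable segments into a patients x bins ternary matrix
   (−1 loss / 0 neutral / +1 gain) comparable across cohorts;
2. **Selects features** per binary task by Gini importance (mean decrease in
   Gini impurity across a random forest) under a class-balanced bootstrap:
   the 6 most important bins, every replicate holding ≥ 32 cases;
3. **Derives the "unidentifiable" (UNID) class**: over 500 balanced
   train/test rounds of the recurrence (REC) vs non-recurrence (NOREC)
   classifier, patients misclassified in ≥ 50% of their held-out rounds are
   relabelled UNID — operationalising the observation that some patients are
   *systematically* misclassified because their genome looks like the
   recurrence class while their follow-up was too short;
4. **Trains three pairwise linear SVMs** (REC|NOREC, NOREC|UNID, REC|UNID),
   each on its own feature subset, combined by one-vs-one **voting** (two
   votes win; the cyclic tie falls to UNID);
5. **Evaluates** by repeated stratified splits with balanced binary tasks,
   reporting accuracy and per-class correct-prediction rates with empirical
   95% percentile intervals in the format `83.6% CI95% [66.7; 94.4]%`.

Because no raw cohort is deposited, the package ships a first-class
**synthetic cohort generator** that plants class-informative regions,
genome-wide background alterations, and an ambiguous short-follow-up
subpopulation, with full ground truth — every stage is testable offline.
See `docs/methods.md` for the model details and assumptions.

## Worked example

```python
import pandas as pd
from cnarec import (
    SimulationConfig, simulate_cohort, bin_scheme_from_cohort,
    assign_to_bins, CNARecurrenceModel, EvalConfig,
)

cohort, truth = simulate_cohort(SimulationConfig(seed=0))   # 104 patients, 40 REC
scheme = bin_scheme_from_cohort(cohort)                      # ~1.8 Mb bins
X = assign_to_bins(cohort, scheme)                           # 104 x ~184 ternary matrix

model = CNARecurrenceModel(X, pd.Series(cohort.outcomes()), scheme=scheme)
results = model.fit(seed=100)
report = results.evaluate(EvalConfig(n_iterations=200, n_repeats=1, seed=7))
print(report.to_text())
```

prints

```
accuracy: 90.9% CI95% [81.8; 100.0]%
correct prediction of patients without recurrence/metastasis: 95.6% CI95% [83.3; 100.0]%
correct prediction of patients with recurrence/metastasis: 87.3% CI95% [75.0; 100.0]%
correct prediction of patients unidentifiable: 77.5% CI95% [0.0; 100.0]%
```

i.e. on this synthetic cohort the three-phase model separates the planted
recurrence signal cleanly; the UNID rate is lowest — as expected, since UNID
is by construction the boundary stratum — and its interval is wide because
only a few UNID patients land in each test split. `results.summary()` lists
the derived class sizes and the per-phase feature bins with importances;
`results.unid_patients` recovered 5 of the 6 planted ambiguous patients here
(`truth.ambiguous_patients`).

A command-line interface mirrors the workflow
(`cnarec simulate | bin | select | train | evaluate | validate |
freq-profile`); `cnarec evaluate --preset published` runs the published
5000-iterations-x-2 protocol.

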