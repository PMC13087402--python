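# qsarkit

A QSAR/QSPR modelling toolkit for small-compound antioxidant and
antimicrobial studies — the regime where a handful of synthesized analogues
(tens of compounds) meet thousands of computed molecular descriptors and the
modelling question is which few descriptors explain the measured activity.

It covers the full workflow around a typical medicinal-chemistry panel such
as a series of 8-aminoquinoline sulfonamide hybrids:

- **Assay reduction** — percent inhibition from absorbance pairs,
  IC50 from two-fold dilution series, pIC50 = −log₁₀(IC50 in M), and MIC
  conversion from µg/ml to µM via molecular weight.
- **Feature selection** — constant/duplicate filtering, classical stepwise
  multiple linear regression (partial-F entry/removal), correlation-based
  feature subset (CFS) merit with best-first search, and pairwise
  intercorrelation checks against an |r| ≤ 0.9 independence cutoff.
- **QSAR regression** — ordinary least squares on the selected descriptors,
  `Y = m₁x₁ + … + mₙxₙ + b`, with training R², R²adj, RMSE, MAE and Lin's
  concordance correlation coefficient; leave-one-out and k-fold
  cross-validated Q² (PRESS-based); and Y-randomization as a
  chance-correlation control.
- **Applicability domain** — hat-matrix leverages against the critical
  leverage h\* = 3(p+1)/n and ±3σ standardized residuals (Williams plot).
- **QSPR classification** — an unpruned gain-ratio (C4.5/J48-style) decision
  tree over descriptor thresholds, with confusion-matrix metrics
  (accuracy, class-support-weighted precision/recall/F-measure) and
  stratified cross-validation.
- **Candidate screening** — apply stored equations and trees to designed
  candidate tables, rank per endpoint, and flag predicted improvements over
  experimental prototypes.

The two published antioxidant equations (%DPPH and SOD-mimic pIC50) and the
published two-level antimicrobial tree (X4sol at 7.564, VR2_Dzi at 11.729)
ship as ready-to-use fixtures, together with the eleven-compound study panel
of printed experimental endpoints (`qsarkit.reference`).

## Worked example

Fit and validate a four-descriptor model on a synthetic 11-compound panel
with a planted linear signal (the generator mimics the small-n/wide-p study
regime; `truth` records the planted coefficients):

```python
import numpy as np
from qsarkit import QSARRegression
from qsarkit.simulate import RegressionScenario, gen_regression

scen = RegressionScenario(n_compounds=11, n_descriptors=40, noise_sd=0.05, seed=42)
table, y, truth = gen_regression(scen)
sub = table.select_columns(truth["informative"])
res = QSARRegression(y, np.asarray(sub.values), names=list(sub.descriptor_names),
                     ids=list(sub.compound_ids), response_label="%DPPH",
                     name="dpph-demo").fit()
print(res.summary(seed=0))
ad = res.applicability_domain()
print(f"h* = {ad.h_star:.2f}; compounds in domain: {int(ad.in_domain.sum())}/{len(ad.ids)}")
```

prints

```
QSAR regression results — dpph-demo
==========================================================
%DPPH = 0.0681(ATS5s) - 74.5008(GATS1e) - 5.9897(Mor04p) - 12.0386(Mor24u) + 20.5227
----------------------------------------------------------
N                    11
descriptors (p)      4
R2                   1.0000
R2 adjusted          1.0000
RMSE (train)         0.0272
MAE (train)          0.0213
CCC (train)          1.0000
Q2 (LOO)             1.0000
RMSE (LOO)           0.0533
Q2 (5-fold)          1.0000
RMSE (5-fold)        0.0574
----------------------------------------------------------
thresholds: R2>0.6 pass, Q2>0.5 pass, MAE<0.6 pass, CCC>0.85 pass

h* = 1.36; compounds in domain: 11/11
```

The recovered equation sits within noise of the planted coefficients
(0.0685, −74.5372, −6.0133, −12.0745, intercept 20.4924); the critical
leverage 3(p+1)/n = 15/11 ≈ 1.36 bounds the applicability domain, and all
eleven compounds fall inside it. The threshold line applies the standard
QSAR acceptability criteria (R² > 0.6, Q² > 0.5, MAE < 0.6, CCC > 0.85).

A command-line surface mirrors the library
(`qsarkit simulate|select|fit|validate|yrand|ad|tree-fit|tree-apply|metrics|screen`);
see `qsarkit --help`.

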