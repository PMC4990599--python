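# romap — age-stratified ROMA ovarian-cancer risk scoring

`romap` computes the Risk of Ovarian Malignancy Algorithm (ROMA) from serum
HE4 and CA125, in two variants, and provides the full diagnostic-evaluation
toolkit needed to compare them: confusion-matrix metrics, empirical ROC
curves, AUC with DeLong standard errors and confidence intervals, the paired
DeLong test for correlated AUCs, Youden-index cutoff selection, and the
Mann–Whitney U test for group contrasts. A seeded synthetic-cohort generator
emulates a realistic 413-patient ovarian-tumor case-control series so every
stage of the pipeline can be exercised without patient data.

It is written for biostatisticians and gynecologic-oncology researchers who
want to batch-score marker panels from CSV files and evaluate risk
algorithms reproducibly from the command line or from Python.

## The model

Both variants share the logistic predictive-index form

    PI    = A + w_HE4 · ln(HE4) + w_CA125 · ln(CA125)
    risk% = 100 · exp(PI) / (1 + exp(PI))

with HE4 in pmol/l and CA125 in U/ml. The **standard ROMA** selects one of
two coefficient triples (A, w_HE4, w_CA125) by menopausal status. The
**age-stratified variant (ROMA P)** replaces that dichotomy with eight age
intervals, W1 (≤ 20 y) through W8 (≥ 81 y), whose triples step linearly and
component-wise from the youngest set (−12, 2.38, 0.063) to the oldest
(−8.09, 1.04, 0.732) — reflecting that benign HE4 rises with age, so the
weight on ln(HE4) falls while the weight on ln(CA125) grows. Because the
age gradient is absorbed into the coefficients, a single risk cutoff
(23.5 %) applies to the whole population, instead of separate premenopausal
(14.1 %) and postmenopausal (25 %) cutoffs. Patients aged ≤ 20 score
identically under both variants when premenopausal, as do patients ≥ 81
when postmenopausal, since the endpoint triples coincide with the
menopausal ones.

## Worked example

```python
from romap import PatientRecord, MenopausalStatus, score_roma_p, score_roma_standard, classify

p = PatientRecord("pt-001", age=55, menopausal_status=MenopausalStatus.POST,
                  he4=439.3, ca125=500.0)
sp = score_roma_p(p)
ss = score_roma_standard(p)
print(f"ROMA P : stratum={sp.stratum_or_group}  PI={sp.pi:.3f}  "
      f"risk={sp.percent:.1f}%  -> {classify(sp, 23.5).value}")
print(f"ROMA   : group={ss.stratum_or_group}  PI={ss.pi:.3f}  "
      f"risk={ss.percent:.1f}%  -> {classify(ss, 25.0).value}")
```

prints

```
ROMA P : stratum=W5  PI=2.793  risk=94.2%  -> high_risk
ROMA   : group=postmenopausal  PI=2.788  risk=94.2%  -> high_risk
```

A 55-year-old with HE4 = 439.3 pmol/l and CA125 = 500 U/ml is scored with
the W5 triple (−9.77, 1.61, 0.445); her predictive index of 2.79 maps to a
94.2 % risk, far above the 23.5 % cutoff, so she is called high-risk — as
she is under the standard postmenopausal scoring. A 34-year-old with
benign-range markers (HE4 = 47.3, CA125 = 32.3) lands in W3 at 9.2 % risk,
low-risk under the same single cutoff.

The same flows run from the shell:

```bash
romap simulate -o cohort.csv --seed 7            # synthetic 162/251 cohort
romap score    -i cohort.csv -o scored.csv       # per-patient risks, both variants
romap evaluate -i cohort.csv -o report --select-cutoff
romap compare-auc -i cohort.csv -o aucs.csv      # paired DeLong matrix
```

On the seed-7 cohort, `report.json` shows an overall ROMA P AUC of 0.960
with sensitivity 89.5 % and specificity 99.6 % at the 23.5 % cutoff, and a
Youden-optimal cutoff of 24.2 % — close to the published operating point.

## Layout

- `romap.model` — strata, coefficient sets, predictive index, logistic
  transform, both scorers, cutoff classification
- `romap.diagnostics` — confusion metrics, ROC/AUC, DeLong variance and
  paired test, Youden cutoff selection
- `romap.mwu` — Mann–Whitney U two-sample test
- `romap.cohort` — seeded synthetic cohort generator
- `romap.io` / `romap.cli` — CSV schema, batch scoring tables, evaluation
  reports, and the `romap` command-line interface

See `docs/methods.md` for the modelling and numerical choices.
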