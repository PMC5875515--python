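# plaqueqa

Quality-assurance software for verifying the air kerma strength of
**pre-assembled I-125 eye plaques** used in episcleral brachytherapy of
ocular melanoma.

Pre-loaded COMS and Eye Physics EP917 plaques arrive sterilized, so the
individual seeds cannot be re-assayed before treatment. A simple check is
still possible with a well-type dose calibrator: place the assembled plaque
in the well, read its apparent activity at four rotations (0°, 90°, 180°,
270°), and compare the averaged, unit-converted reading against the
NIST-traceable assay certificate. `plaqueqa` implements the bookkeeping and
statistics around that measurement: decay correction, the plaque calibration
factor, per-type reference statistics, action-limit flagging, plan-vs-assay
cross-checks, and an error-injection simulator for validating the flags.

## The statistic

For a plaque with four angle readings $A_1..A_4$ (mCi), measured on date
$t_m$ against a certificate of total air kerma strength $S_K^{assay}$ (U)
assayed on date $t_a$:

$$
\bar A = \tfrac14\sum_i A_i,\qquad
S_K^{meas} = \bar A \times 1.270\ \mathrm{U/mCi},\qquad
S_K^{dec} = S_K^{assay}\, 2^{-(t_m - t_a)/T_{1/2}},\qquad
F = \frac{S_K^{meas}}{S_K^{dec}}
$$

with $T_{1/2} = 59.4$ d for I-125. The *plaque calibration factor* $F$ is
well below 1 (≈0.35 for the EP917, ≈0.25 for COMS plaques) because the gold
shell and seed slots shield laterally directed primary radiation from the
well chamber. $F$ is stable enough within a plaque type that a deviation of
more than **±5%** from the established type mean (the action limit for batch
assays in AAPM low-energy source-calibration guidance) flags a plaque for
investigation before use. A four-reading spread above **4%** signals that
the plaque must be repositioned and remeasured.

## Worked example

The package bundles a ten-plaque EP917 verification worksheet
(`plaqueqa.datasets.ep917_worksheet()`). Evaluating it against the
established EP917 cohort mean factor of 0.353:

```python
from plaqueqa import evaluate_record, datasets

for record in datasets.ep917_worksheet():
    r = evaluate_record(record, datasets.EP917_MEAN_CAL_FACTOR)
    print(record.plaque_id, f"{r.measured_strength_u:6.2f} "
          f"{r.decayed_assay_strength_u:6.2f} {r.cal_factor:.3f} "
          f"{r.deviation_pct:+5.1f}%", sorted(f.name for f in r.flags))
```

```
1  25.78  75.07 0.343  -2.7% []
2  17.84  47.73 0.374  +5.9% ['ACTION_LIMIT']
3  13.44  37.87 0.355  +0.5% []
4  11.73  34.37 0.341  -3.3% []
5  14.21  40.26 0.353  -0.0% []
6  21.46  62.37 0.344  -2.5% []
7  23.13  68.50 0.338  -4.4% []
8  21.88  59.82 0.366  +3.6% []
9  19.77  54.18 0.365  +3.4% []
10 16.64  49.21 0.338  -4.2% []
```

Per row: measured strength (U), certificate strength decayed to the
measurement date (U), the calibration factor, and its deviation from the
type mean. Plaque 2 sits +5.9% above the mean and is flagged for
investigation; plaques 8–10 were measured a few days *before* their assay
dates, so their decayed strengths exceed the certificate values.

The same pipeline is available from the shell:

```sh
plaqueqa evaluate --input worksheet.csv --type-factors factors.csv --out-dir qa/
plaqueqa aggregate --input qa/evaluated_worksheet.csv --by plaque_type --out factors.csv
plaqueqa seed-contrib --method placement --input seed_table.csv
plaqueqa simulate --n 500 --seed 42 --error-mix unit_confusion=0.02 --out fixtures.csv
plaqueqa constancy --reading 102 --expected 100
```

`evaluate` exits nonzero when any plaque trips the action limit or a
plan-vs-assay cross-check, so it can gate a clinical workflow.

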