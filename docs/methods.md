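# Methods

## The verification model

A pre-assembled eye plaque is measured face-up in a well-type dose
calibrator at four rotations of the sample holder; the rotation average
cancels first-order geometry effects of plaque placement. The averaged
apparent activity (mCi) is converted to air kerma strength with the I-125
equivalence 1 mCi = 1.270 U, and divided by the certificate strength decayed
to the measurement date:

    F = (mean activity x u_per_mci) / (S_assay x 2^(-Δt / T_half))

`F` is a property of the plaque type, not the loading: placement
measurements across the EP917's 17 slots show every position contributing
≈1/17th of total activity (grand mean 5.9%, sd 0.3% across positions), so a
single per-type factor remains valid for partially loaded plaques. The
package therefore verifies a plaque by comparing its factor against the
established mean for its type and flagging deviations beyond an action
limit.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `half_life_days` | 59.4 | d | I-125 half-life; configurable for a user-supplied nuclide |
| `u_per_mci` | 1.270 | U/mCi | reproduces archived worksheet strengths; `1/0.787` differs only in the 4th digit and is available via config |
| `mci_per_u` | 0.787 | mCi/U | stated inverse; the pair must agree with 1 to within 0.3% |
| `reading_spread_limit` | 4 | % | spread of the four angle readings achievable by careful centering; above it the plaque must be repositioned and remeasured |
| `action_limit` | 5 | % | batch-assay action limit from AAPM low-energy source-calibration guidance |
| `cross_check_limit` | 5 | % | plan-vs-assay strength and factor agreement |
| `date_window_days` | 365 | d | assay-to-measurement gap beyond which a warning (not an error) is raised |

The conversion constants are deliberately *not* forced to be exact inverses:
1.270 × 0.787 = 0.99949, and the round-trip property is guaranteed only to
that consistency bound. Reading-spread uses 100·(max−min)/mean by default;
(max−min)/min is selectable (`spread_metric`).

## Precision policy

All chained arithmetic is carried in double precision; rounding (2 dp for
strengths in U, 3 dp for calibration factors, 1 dp for percentages) is
applied only when a worksheet is written with `presentation=True`. Archived
worksheets often printed fewer digits than they computed with, so
re-derived presentation values can differ from historical printouts by one
unit in the last place (±0.01 U on strengths, ±0.1 percentage point on
deviations); the test suite uses exactly those tolerances and no looser.

The per-type group mean that deviations are measured against is an explicit
input everywhere: `run_qa` falls back to the current worksheet's own mean
only when no reference file is supplied, and logs that the result is then an
internal-consistency check rather than a comparison against an established
reference.

## Aggregation conventions

Per-type statistics use the sample (n−1) standard deviation; the CV is
100·sd/mean and is reported absent for singleton groups. Cohort-level
summaries expose both conventions wherever the choice is ambiguous: the
pooled mean is plaque-count-weighted (with the unweighted type-mean average
alongside), and the "average CV" is the unweighted mean of per-type CVs
(with the count-weighted variant alongside). Deviation histograms use
half-open bins `[lo, hi)` whose edges are integer multiples of the bin
width, so zero always falls on an edge and counts always sum to the number
of inputs.

Seed-contribution uniformity averages the per-plaque *percentages* per
position (not activity-weighted), and the grand sd is taken over the 17
per-position averages, not over all raw fractions. The removal method's raw
fractions do not sum to 1 under measurement noise; renormalization is
optional and off by default so the raw measurement is preserved.

## The simulator

`plaqueqa.synthetic` emulates the measurement process, not the physics: a
true factor is drawn per plaque from a normal distribution with the type's
mean and CV (defaults: EP917 0.353 / 3.29%, COMS types per their group
statistics), certificate strengths are uniform on 30–120 U, assay-to-
measurement gaps uniform on −3..40 days, and the four readings get
independent multiplicative lognormal noise (σ = 0.015, keeping the
four-reading spread typically below the 4% limit). With noise at zero,
evaluation recovers the drawn factor to machine precision — the round-trip
test that anchors the pipeline.

The normal factor model is an assumption made for its closed-form
consequences, not a measured fact: it predicts a false-positive rate of
2·(1−Φ(5/3.29)) ≈ 12.9% for clean EP917 cohorts at the 5% limit, and the
simulated rate is checked against that formula within Monte-Carlo error.
The simulator does **not** model calibrator geometry, plaque collimation
physics, Styrofoam positioning, or correlated angle errors — so passing
tests show the *bookkeeping and flagging logic* is correct under the stated
noise model, not that a real calibrator achieves these numbers.

Error injection implements four clinically observed failure modes:

- `unit_confusion` — the certificate's mCi number is entered in the U
  field (strength × 0.787), shifting the factor by +27% (100·(1/0.787−1));
  the confusion in the opposite direction shifts it by −21% and is equally
  detectable at a 5% limit;
- `transcription` — two adjacent differing digits of the strength swapped;
- `wrong_plaque` — readings rescaled by another type's factor over this
  type's;
- `activity_mismatch` — readings rescaled by a configurable percentage
  (default −6.8%, the worst delivered-vs-ordered mismatch observed
  clinically).

Detection and false-positive rates are tabulated by evaluating paired
clean/corrupted cohorts against the configured type mean. Problem sizes in
the test suite and acceptance script (500-record noisy cohorts for
detection rates, 4000 noiseless records for the false-positive comparison)
were chosen so Monte-Carlo error is small against the quantities checked
while the whole suite runs in seconds.

## Known limitations

- The software reports a reading-spread violation as a flag; it cannot
  trigger the physical remeasurement the procedure calls for.
- Whether a flagged plaque is a true error or a statistical outlier is left
  to human investigation, as it must be.
- COMS seed capacities vary by institution and carrier; the shipped values
  are editable defaults and violations warn rather than reject.
- No DICOM, treatment-planning-system import, TG-43 dose calculation, or
  radiation-transport modelling; the scope is the strength verification
  worksheet and its statistics.
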