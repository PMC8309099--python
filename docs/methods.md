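# Methods

This note documents the models, numerical conventions and design choices
behind dissofit, and what the synthetic-data pipeline does and does not
establish about real dissolution data.

## Dissolution profiles

A profile is a cumulative %-released curve Q(t) at strictly increasing
sampling times in minutes, annotated with pH stages. Times are always
stored in minutes; hours appear only in derived reports. Release values up
to 110% are accepted because cumulative UV assays commonly overshoot 100%
slightly; larger values are treated as data errors. Replicates are distinct
profiles: averaging is always an explicit `mean_profile` call (pointwise
mean on an identical grid), never implicit on read.

Absorbance readings convert to release through a linear calibration
(`concentration = slope·A + intercept`, slope > 0) times dilution factor and
vessel volume over dose. No correction for drug withdrawn in sampling
aliquots is applied by default — the protocol being emulated does not state
replacement — but the standard cumulative correction
`C_i' = C_i + (v/V)·Σ_{j<i} C_j` is available via `sample_volume`.

## Profile comparison (f1/f2)

f1 and f2 are computed exactly as defined (see README), on the mean profile
when replicates are supplied. Alignment requires time points to match
within 1e-9 min; profiles on different schedules are never interpolated,
because the statistics are defined on a shared sampling schedule. The
default point-selection rule (`fda85`) keeps common points up to and
including the first at which the *reference* exceeds 85% released,
reflecting regulatory practice of not over-weighting the plateau; `all` is
available. f2 is not clamped: grossly divergent profiles can give negative
f2, reported as-is with an `equivalent = False` verdict. f1 has no upper
bound (values above 100 are legitimate when the test releases far more than
the reference early on). The equivalence rule is f1 ∈ [0, 15] and
f2 ∈ [50, 100], boundaries inclusive.

## Kinetic models

All four fits are ordinary least squares on the model's linearized scale —
the operational form of the classical "is the plot linear?" criterion —
with constant variance and no weighting:

| model | transform | restriction |
|---|---|---|
| zero order | Q vs t | none |
| first order | log10(100−Q) vs t | drops Q ≥ 100 |
| Higuchi | Q vs √t | Q ≤ 60% |
| Korsmeyer–Peppas | log10 Q vs log10 t | Q ≤ 60%, t > 0, Q > 0 |

The 60% truncation reflects the short-time validity of the square-root and
power laws; `truncate_to_60` keeps points with Q ≤ 60 and drops the first
point beyond together with everything after it. The first-order rate
constant is reported in natural-log units (k1 = −slope·ln 10, for
dQ/dt = k1(100−Q)); the base-10 regression slope is retained in
`transformed_slope` since both conventions circulate.

R² is the squared Pearson correlation on the transformed scale. A raw-scale
coefficient of determination of the back-transformed predictions
(`r_squared_raw`) is reported for diagnostics only. MPE — undefined in many
reports that use it — is fixed here as mean absolute relative error × 100
on the raw % scale with back-transformed predictions: scale-free and
comparable across models. Points with zero observed release are skipped
(with a warning) since relative error is undefined there.

Best-model selection: highest transformed-scale R²; ties within 1e-6 broken
by lowest MPE; remaining ties by parsimony (zero order, first order,
Higuchi, Korsmeyer–Peppas). Parsimony matters because the power law nests
both zero-order (n = 1) and Higuchi (n = 0.5) exactly: on noise-free data
the constrained model should win.

Mechanism bands for the exponent n: Fickian < 0.45 ≤ anomalous < 0.89 ≤
case II ≤ 1.0 < super case II. The case II band is deliberately the closed
interval [0.89, 1.0]: the 0.89 threshold is the cylindrical-geometry value,
and extending it through 1.0 matches how matrix-tablet studies in this
field label exponents like 0.94 as case II while reserving super case II
for n > 1. Degenerate inputs (zero variance in predictor or response) raise
a skip signal rather than crashing; `analyze_profile` records the reason in
`skipped_models`. Profiles with fewer than 4 points at ≤ 60% release
(configurable) skip the Higuchi and power-law fits entirely — the
"fast drug release" case in which only zero- and first-order models are
meaningful. Fits pool both pH stages into one curve by default, matching
how 24 h sustained-release kinetics are normally reported; per-stage
analysis is available by slicing profiles.

## Synthetic experiments

The generator's reference schedule is the two-stage protocol: samples every
15 min to 2 h (pH 1.2), then every 2 h to 24 h (pH 7.4) — 19 points.
Measurement noise is additive Gaussian on the % scale, homoscedastic, the
minimal assumption when no replicate SDs are available to calibrate
anything richer; the default sd is 1% release. Noise-free curves are
clipped at a cap (default 100%); noised values are kept within
[0, cap + 5·sd]. An optional monotone (running-maximum) projection enforces
the physical non-decrease of cumulative release. Replicate r of root seed s
draws from the independent stream (s, r), so adding replicates never
perturbs existing ones.

Two-stage simulations are continuous at the medium change (the change is a
buffer addition, not a tablet transfer). The default continuation is
*carry-over*: stage 2 resumes its own curve at the effective elapsed time
that reproduces the changeover release level, which has the desirable
property that identical stage specifications reproduce the single-stage
curve exactly for every model. An *additive* continuation (stage-2 clock
restarted at zero, release added on top) is provided as an option; a
zero-rate second stage yields a plateau under either convention.

What the generator does **not** emulate: heteroscedastic assay error
(relative noise grows near the detection limit), inter-tablet variability
beyond iid noise, pH-dependent solubility of the drug, or mechanistic
matrix-erosion dynamics. Passing tests therefore demonstrate correctness of
the estimators under the stated statistical model, not robustness to every
real-data pathology.

### Identifiability at realistic noise

A brute-force study over the four models at sustained-release-like
parameters (k0 = 0.07 %/min, k1 = 0.0035 /min, kH = 2.2 %/√min, power law
k = 1.5, n = 0.75) on the 19-point schedule with 1% noise shows that
single-run model selection is reliable for zero-order data (≈100%
re-selection over 200 seeds) but not for the others (first order ≈14%,
Higuchi ≈78%, power law ≈87%). Two structural causes: the log10(100−Q)
transform amplifies additive noise by 1/((100−Q)ln 10) near complete
release, so the first-order fit is noisiest exactly on its own data; and
over the truncated ≤ 60% window the models mimic one another closely (a
Higuchi line fits noise-free first-order data there with R² ≈ 0.993, and
the power law nests two competitors exactly). Raw-scale R² or MPE-based
selection variants do not repair this. Rate-constant *estimation* is much
better behaved: 500 noisy Higuchi runs at kH = 6.5 %/√min recover the
constant with ≈3.2% mean absolute relative error. Practical consequence:
trust fitted constants from single runs, but base model discrimination on
replicate-averaged curves and report all fitted models — which is what the
reporting layer does.

## Formulation arithmetic

Lf = (API + vehicle)/(Avicel + Eudragit). Counting the matrix retardant
Eudragit RS PO as carrier is a deliberate convention: it enters the wet
mass alongside the cellulose carrier, and it is the only reading under
which the study's printed Lf column and the 20:1 carrier-to-coating design
note are simultaneously consistent for all ten compositions (e.g.
140/(135+45) = 0.78, not 140/135). Granulating water is process metadata
and never part of dosage-form mass. `infer_vehicle_mass` reconstructs the
unprinted vehicle mass as total minus named solids; it is the exact inverse
of `total_mass`. Percentages are rounded to 2 decimals only at the
reporting layer.

## QC metrics

Carr's index and angle of repose use the standard formulas. The
flowability bands follow the compendial (USP <1174>-style) tables, with one
deviation: the *excellent* band for the angle of repose extends to ≤ 30°
(compendially 25–30° is "good"), matching the scale applied in the source
study, which labels angles up to ~27° excellent. CI bands: ≤ 10 excellent,
(10, 15] good, (15, 20] fair, (20, 25] passable, (25, 31] poor, > 31 very
poor. Classification applies to replicate means, reported as mean ± SD.
Friability: fail on any fracture or weight loss > 1%; a final mass above
the initial one is clamped to zero loss as a weighing artifact. Hardness is
carried as mean ± SD only.

## Pipeline

`run_study` derives one seed per simulation entry from the root seed via
independent seed sequences, so stages can be re-run in isolation and the
same config + seed gives byte-identical reports. Rounding happens only at
serialization (2 decimals for percentages, f-factors and MPE; 3 for R² and
the exponent n). The manifest records package version, seed and SHA-256 of
every input file; failures write a failure manifest naming the stage along
with whatever partial outputs completed.

## Known limitations

- No bootstrap confidence intervals for f2, and no multivariate profile
  comparison.
- Only the four classical models; no Weibull, Hixson–Crowell or
  mixed-effects fitting.
- Model discrimination at 1% single-run noise is unreliable for three of
  the four models (see above); the package reports all fits rather than
  hiding this.
- The QC module classifies but does not propagate measurement uncertainty
  into the class labels.
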