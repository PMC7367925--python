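# Methods

This note documents the models, conventions and design choices behind
navitro, in the order a dataset moves through the pipeline.

## Concentration convention

All concentrations are stored as −log10 of the molar value. This single
internal convention is the backbone of the toolkit: points of departure
from assays with nanomolar and millimolar potencies live on one scale, and
µM/nM transcription mix-ups are confined to the I/O boundary, where
`neglog_to_conc` / `conc_to_neglog` round-trip to 1e−12 relative. Display
rounding is 2 significant figures; full precision is kept internally. The
standard test design is a 13-point series from 4 to 10 −log(M)
(100 µM → 0.1 nM) in 0.5-log steps.

## Plate-data format

One file is a long-format CSV (one row per well × endpoint) under a
`# key: value` metadata header. The dialect is deliberately strict because
the failure modes it guards against are spreadsheet-era ones: decimal
separator is `.` only, a decimal comma is an *error* (`LOCALE_COMMA`), and
cells like `Jun-05` — a number turned into a date by a spreadsheet — are
flagged (`SPREADSHEET_DATE_ARTIFACT`) rather than coerced. Non-numeric
cells are preserved verbatim through read/write so no information is lost
before a curator sees the report. Flags (`lab_error`, `outlier`,
`below_detection`) are additive annotations: flagged rows are always
written and only excluded at computation time. Mandatory metadata are test
method, lab, solvent and exposure time; a DMSO concentration other than the
0.1% convention produces a note. Cross-dataset validation warns when
metadata blocks are copy-pasted identically across distinct run ids.

Wells are letter-row + 1-based column (`A1`…`P24`); every plate carrying
treatment wells must carry solvent controls for the same endpoint
(`MISSING_CONTROL_LINK`), and (plate, well, endpoint) must be unique.

## Normalization and baseline QC

Responses are expressed in % of the per-plate solvent-control mean, after
subtracting the plate's blank mean when blanks are present. Controls
flagged `lab_error`/`outlier` do not enter the reference mean, so the mean
normalized control response is exactly 100% on every plate.

Baseline variance per plate is RSD = SD·100/µ over solvent-control
technical replicates, with replicate values also reported as x_norm = x/µ.
The SD is the sample SD (n−1): replicates are a small sample (typically
3–6), where the denominator choice matters; `ddof=0` is available. The
cross-plate summary is the unweighted mean of per-plate RSDs — weighting by
replicate count was considered and rejected as it lets a single large plate
dominate a robustness metric meant to describe typical plates.

Negative-control spread pools, per endpoint, the control-normalized
responses of designated no-effect compounds at their two lowest tested
concentrations, additionally required to lie below a per-compound cap in µM
(both conditions conjunctively — the cap protects against series that start
high). The summary reports the fraction inside [80%, 120%], the band a
well-behaved assay should mostly occupy.

## Curve fitting and BMC/PoD

The curve family is the four-parameter log-logistic model; in −log10(M)
units a declining endpoint is
`f(c) = bottom + (top − bottom)/(1 + 10^(hill·(log EC50 − c)))`, and an
induced endpoint flips the exponent's sign. 4PL is the field standard for
viability and reporter endpoints and admits a closed-form BMC inversion.
Fitting is bounded least squares (scipy's trust-region reflective):
bottom ∈ [−10, 50]%, top ∈ [50, 120]% for declining endpoints (wider top
for induction), hill ∈ (0, 10], and log EC50 within the tested range ± 1
log unit so that derived PoDs cannot extrapolate far beyond the series.
Start values come from the series ends and the mid-response point. A fit is
demoted to `fit_ok = False` when the optimizer fails or when the effect
*realised inside the tested window* is under 10% of control — the window
criterion matters because flat data can otherwise be "explained" by a steep
curve just outside the series.

No automatic statistical outlier rejection is performed by default; points
flagged in the data file are excluded before fitting, and expert visual
checking is encoded as a per-curve flag (`pending`/`passed`/`failed`).
Summary exports (the PoD matrix) refuse curves still pending, which turns
the visual-check policy into a mechanical gate rather than a convention.

The BMC at benchmark response BMR is the analytic inversion of the fitted
curve at 100 − BMR (decline) or 100 + BMR (induce). Censoring ("no effect
observed") occurs when the target response lies outside the fitted span or
when the inversion lands beyond the highest tested concentration; the
censor bound is that highest tested concentration in −log(M). The default
BMR is 25% and is recorded in every PoD result; it is a policy object, not
a constant, because the appropriate BMR is endpoint- and program-specific.

Cytotoxicity anchoring compares a functional PoD with the viability PoD of
the same system: ratio = 10^(PoD_func − PoD_viab). Cut-offs of 10× (specific)
and 3× (borderline) reflect the common observation that genuinely
pathway-mediated responses appear one to two orders of magnitude below
cytotoxic concentrations; both cut-offs are arguments. A censored
functional PoD gives "undetermined"; a censored viability PoD alone gives
"specific" with the ratio reported as a lower bound. For antagonist-mode
assays the reference agonist is co-applied at its fitted EC50
(`reference_ec50`); antagonist responses are normalized to the agonist-only
co-treatment control.

## Free-concentration model

The biokinetics module treats a culture medium as three compartments —
water, serum protein, serum lipid — with linear binding in the tested
range: `f_u = 1/(1 + K_p·C_p + K_l·C_l)`, phases in kg/L. All serum protein
is treated as albumin at 66.5 kDa (23 mg/mL ≡ 346 µM for undiluted FCS);
lipid is triacylglycerol at ~6000 mg/L per 100% FCS; media built from an
FCS percentage scale linearly, and charcoal-stripped serum keeps the
protein but contributes no lipid.

Two binding-constant routes are provided because programs differ in what
they have on record. `ppb_scaled` converts a measured plasma
protein-binding fraction into an albumin affinity via
K_p = (bound/unbound)/C_albumin,plasma with a 600 µM plasma reference;
`kow_regression` needs only logK_ow (log10 K_p = 0.71·logK_ow + 0.42,
K_l = K_ow). The routes can disagree substantially for drugs whose plasma
binding is stronger than their lipophilicity suggests (tolbutamide-class
sulfonylureas are the canonical case), which is why the method used is
recorded in every result. `auto` prefers the measured PPB.

Out of scope by construction: binding to plasticware and cells (warned
about permanently — for extreme hydrophobics plastic can claim on the order
of a third of the nominal amount), volatilization (compounds with
K_AW ≥ 0.03 are flagged volatile, [0.015, 0.03) borderline — half the
threshold, reproducing the judgement call usually made for HgCl₂ at 0.02),
hepatic clearance and any PBPK extrapolation. Serum-free media give
f_u = 1 exactly.

## Readiness scoring

The rubric is 13 categories with 62 sub-items; the shipped default is a
structural skeleton (ids, category names, uniform max scores) — the
authoritative sub-item texts belong to the published readiness scheme and
should be loaded from a config. Two raters' complete sheets are averaged
per sub-item; the discrepancy metric is the absolute difference of the two
*overall* percentages in percentage points (per-item discrepancies are also
reported for transparency), and ≥ 20 points blocks scoring until a third
sheet arrives, after which all three are averaged. Category and overall
percentages are points-weighted (sum of points over sum of maxima), not
category-averaged. Band boundaries are closed at the lower edge of the
better band: ≥ 85% high, ≥ 50% intermediate, < 50% low; both cut-offs are
arguments.

## Synthetic data generator

The generator emulates the standard battery design: 13-point half-log
series, triplicate wells, six solvent controls per plate, 384-well layout.
Raw signals are the true 4PL response times unit-mean multiplicative
lognormal noise (default CV 10% — baseline replicate variation in practice
sits below ~15%, so 10% is a realistic, slightly optimistic plate); test
fits use CV 5% where the check is about estimator behaviour rather than
robustness. Outliers are injected as 3× deviations carrying the `outlier`
flag. Per-plate random substreams derive from `(master_seed, plate_index)`,
so adding plates never reshuffles existing ones and a spec + seed is
byte-reproducible.

What the generator does *not* emulate — plate edge effects, signal drift,
pipetting autocorrelation, compound degradation — bounds what green tests
mean: they demonstrate the pipeline's statistical behaviour under its own
stated noise model, not performance on any particular laboratory's data.

## Problem sizes and numerics

Property tests run at the scale where the property is informative and the
suite stays fast: 1000 random curves for the closed-form-vs-root-finding
BMC check (agreement to 1e−9 in −log(M)), 1000 random vectors for the RSD
brute-force check (1e−9), 100 randomized datasets for format round-trips,
200 seeded runs for 4PL parameter recovery (median |ΔlogEC50| < 0.2 at CV
5%, bias < 0.05, plateaus within ±5 points). Dilution-series enumeration
uses a 1e−9 tolerance on the floor computation so inclusive endpoints land
exactly. Degenerate inputs (zero control mean, < 2 replicates, < 4 distinct
concentrations, flat curves) raise typed errors rather than returning NaN.

## Known limitations

Antagonist-mode normalization conventions vary between programs; the
default here (percent of agonist-only co-treatment) is one defensible
choice and is documented in outputs rather than hidden. The `kow_regression`
coefficients are a generic serum-albumin sorption regression; compounds
with specific high-affinity binding sites will be mispredicted, which the
dual-route design surfaces rather than solves. The readiness rubric
aggregation applies the discrepancy rule at the overall level; applying it
per category would be stricter and can be emulated by scoring categories as
separate methods.
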