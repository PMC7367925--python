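# navitro

A toolkit for running the data side of an in vitro test battery: a strict
plain-text plate-data format with full metadata, solvent-control
normalization and baseline-variance QC, four-parameter log-logistic (4PL)
concentration–response fitting with benchmark-concentration (BMC) and
point-of-departure (PoD) derivation in a unified −log10(M) convention,
free-concentration (biokinetics) prediction in arbitrary culture media, and
fit-for-purpose test-method readiness scoring.

It is written for groups coordinating animal-free hazard-assessment methods
(NAMs) across several laboratories — reporter-gene batteries, viability
panels, functional assays — where the recurring failure modes are not the
assays themselves but spreadsheet corruption, lost outlier flags, µM/nM
mix-ups, unanchored functional hits, and free-vs-nominal concentration
confusion between serum-containing and serum-free media.

## The models at the core

**Concentration convention.** Everything internal is −log10(M): a value of
6.0 is 1 µM, 5.6 ≈ 2.5 µM. Conversions happen only at the I/O boundary.

**Concentration–response.** Responses in % of solvent control are fitted
with the 4PL model (here for a declining endpoint; `c` in −log10(M)):

    f(c) = bottom + (top − bottom) / (1 + 10^(hill · (log EC50 − c)))

The BMC at a benchmark response BMR (e.g. 25% change from control) is the
closed-form inversion of the fitted curve; when the curve never reaches the
BMR within the tested series the result is censored ("no effect observed"
up to the highest tested concentration). A functional PoD is anchored
against the viability PoD of the same system via the specificity ratio
10^(PoD_func − PoD_viab) (≥ 10× = specific, 3–10× borderline, < 3×
cytotoxicity-confounded).

**Biokinetics.** A three-compartment mass balance predicts the unbound
fraction in a culture medium from its albumin and lipid content:

    f_u = 1 / (1 + K_protein · C_protein + K_lipid · C_lipid)

with phase concentrations in kg/L (albumin from µM via MW 66.5 kDa; 100%
FCS ≡ 346 µM albumin and ~6000 mg/L triacylglycerol). Binding constants
come either from measured plasma protein binding (`ppb_scaled`) or from
lipophilicity alone (`kow_regression`: log10 K_protein = 0.71·logK_ow +
0.42, K_lipid = K_ow).

**QC.** Baseline variance is the per-plate relative standard deviation of
solvent-control technical replicates, RSD = SD·100/µ, plus the pooled
spread of negative-control compounds at their two lowest tested
concentrations (expected mostly within 80–120% of control).

**Readiness.** A 13-category / 62-sub-item rubric scored by two independent
experts; sheets are averaged per sub-item unless the overall percentages
differ by ≥ 20 points (third scorer required), and percentages map to
traffic-light bands (≥ 85% high, ≥ 50% intermediate, < 50% low).

## Worked example

```python
from navitro import (Curve4PL, SyntheticSpec, PoDPolicy, generate_plate,
                     validate_dataset, normalize_to_controls, fit_4pl,
                     derive_pod, plate_baseline_profile, demo_registry,
                     free_fraction, medium_from_fcs)

truth = Curve4PL(top=100, bottom=0, log_ec50=6.0, hill=1.5,
                 visual_check_flag="passed")
spec = SyntheticSpec(seed=1, n_plates=3, noise_cv=0.05,
                     true_curves={("tolbutamide", "viability"): truth})
ds = generate_plate(spec)
print("validation errors:", len(validate_dataset(ds, demo_registry()).errors))
qc = plate_baseline_profile(ds, "viability")
print(f"average solvent-control RSD: {qc.average_rsd_percent:.1f}%")
rows = [r for r in normalize_to_controls(ds, "viability")
        if r["role"] == "treatment" and not r["flags"]]
fit = fit_4pl([r["conc_neglog_molar"] for r in rows],
              [r["response_percent"] for r in rows], "decline")
print(f"fitted 4PL: top={fit.top:.1f}% bottom={fit.bottom:.1f}% "
      f"log EC50={fit.log_ec50:.2f} hill={fit.hill:.2f}")
pod = derive_pod(fit, PoDPolicy(bmr_percent=25.0), "tolbutamide", "viability")
print(f"PoD (BMC25): {pod.pod_neglog_molar:.2f} -log(M)")
res = free_fraction(demo_registry()["tolbutamide"],
                    medium_from_fcs("fcs_10", 10.0), "kow_regression")
print(f"free fraction in 10% FCS medium: {res.f_unbound:.2f}")
```

prints

```
validation errors: 0
average solvent-control RSD: 3.5%
fitted 4PL: top=98.1% bottom=0.1% log EC50=5.99 hill=1.55
PoD (BMC25): 6.32 -log(M)
free fraction in 10% FCS medium: 0.71
```

The generated plates pass format validation; three plates of 5%-CV controls
show a 3.5% baseline RSD; the fit recovers the designed curve (EC50 1 µM,
i.e. 5.99 in −log(M)); the PoD at BMR 25% sits at 6.32 −log(M) ≈ 0.48 µM
(for unit-normalized hill 1.5 the BMC25 lies log10(3)/1.5 ≈ 0.32 log above
the EC50); and a strongly protein-bound drug keeps 71% of its nominal
concentration free in a 10% FCS medium.

A CLI mirrors the library: `navitro chem convert --neglog 5.6 --unit uM`,
`navitro data validate plate.csv --registry registry.csv`,
`navitro qc baseline plate.csv --endpoint viability`,
`navitro fit plate.csv --endpoint viability --bmr 25`,
`navitro freeconc --compound tolbutamide --fcs-percent 10 --nominal-um 100`,
`navitro readiness score --rubric rubric.yaml --sheets a.yaml --sheets b.yaml`.

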