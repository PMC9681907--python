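# tacropk

Population pharmacokinetics of tacrolimus in adult liver-transplant
recipients, built around routine therapeutic drug monitoring (TDM) data:
whole-blood trough concentrations (`C0`, ng/ml) paired with the total
daily dose (`DD`, mg/day) and the day's clinical covariates.

Tacrolimus shows nonlinear kinetics in this population. The package
implements and compares the two modeling strategies used to study it:

* **Michaelis–Menten (MM) dose–trough model.** The daily dose is the
  dependent variable,

  `DD = Vm · C0 / (f · Km_i + C0)`,  `f = 10 / min(POD, 10)`

  with `Vm` (mg/day) the maximum steady-state dose rate, `Km_i` (ng/ml)
  the trough at the half-maximal dose rate after covariate adjustment
  (postoperative day, hematocrit, bilirubin, recipient CYP3A5 genotype,
  triazole-antifungal co-therapy), and `f` an early-postoperative time
  factor. Inter-subject variability on `Km` is exponential; the
  residual error is combined (proportional + additive).

* **Theory-based one-compartment plasma model.** Whole blood and plasma
  are linked by saturable erythrocyte binding,

  `Cwb = Cp + Cp · HCT · Bmax / (Cp + KD)`,  Bmax = 418 µg/L, KD = 3.8 µg/L,

  and the plasma trough follows a one-compartment model with first-order
  absorption (`Ka` fixed at 4.48 h⁻¹) parameterized by `CL_pl/F` and
  `V_pl/F`, with covariates on clearance (AST, daily dose via an Emax
  relation, CYP3A5, antifungals) and a postoperative-day effect on the
  volume.

Around the models sits a complete, tested pipeline: a synthetic TDM
cohort generator with dose-titration feedback toward the 8–12 ng/ml
target window, FOCE-I-family estimation (linearized, Laplace, and
adaptive Gauss–Hermite objectives over shared conditional modes),
stepwise covariate selection (ΔOFV 3.84 forward / 6.63 backward, ≥20%
effect rule), diagnostics (subject bootstrap, prediction- and
variability-corrected VPC, NPDE with the global test, MDPE/MAPE/F20/F30
prediction errors), and a Monte Carlo starting-dose table stratified by
genotype × antifungal co-therapy × hematocrit band × bilirubin band.

## Worked example

```bash
tacropk --seed 42 simulate-cohort --n-subjects 176 --truth mm_final --out demo/cohort.csv
tacropk --seed 42 fit demo/cohort.csv --model mm_final --method agq --out demo/fit
tacropk --seed 42 dose-table --out demo/doses
```

The first command writes a 176-subject cohort (≈900 trough rows) whose
covariates, genotype frequencies and titrated dose trajectories emulate
an early-post-transplant TDM service, plus a `cohort.truth.json` sidecar
with the generating random effects. The fit prints

```
OFV 2432.039 (converged=True); wrote demo/fit.csv
```

and the parameter table starts

```
parameter,estimate,rse_percent,ci95_lo,ci95_hi
tv_vm,6.67232,3.0614,6.27196,7.07268
tv_km,6.34673,10.5689,5.032,7.66146
th_km~pod:power,0.310586,13.3163,0.229523,0.391648
```

— the refit recovers the generating values (`Vm` 6.62 mg/day, `Km` 6.46
ng/ml) at this cohort size, with η-shrinkage on `Km` of ~12%. The dose
table contains one row per stratum, e.g.

```
cyp3a5,taf,hct_band,tbil_band,dose_lo_mg,dose_hi_mg,median_dose_mg,fraction_feasible
*1 carrier,1,20-30,5.1-17.1,1.75,5.25,3.75,1
```

meaning that for a CYP3A5-expressing recipient on a triazole antifungal
with hematocrit 20–30% and normal bilirubin, starting daily doses of
1.75–5.25 mg (median 3.75) put the simulated day-7 steady-state trough
in the 8–12 ng/ml window for the central 95% of subjects.

Other subcommands: `stepwise`, `bootstrap`, `vpc`, `npde`, `run-all`;
`--config` accepts a YAML file with run settings (LOQ, simulation
counts, target window, dose grid).

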