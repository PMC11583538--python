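# pneumodose

Dosimetric evaluation of post-therapy pneumonitis (PTP) after thoracic
radio(chemo)therapy with or without immune checkpoint inhibition (ICI).

Radiation pneumonitis is classically confined to the irradiated volume, but
when PD-1/PD-L1 inhibitors are combined with thoracic radiotherapy the
inflammatory reaction may spill beyond the high-dose region. Quantifying that
requires mapping the pneumonitis — delineated on a follow-up diagnostic CT —
back onto the planning CT where the dose distribution lives, and then asking
how much of the pneumonitis volume received how much biologically weighted
dose. `pneumodose` implements that workflow end to end for physicists and
clinician-scientists running retrospective dose-volume analyses:

1. **Contour propagation** — the follow-up CT is deformably registered onto
   the planning CT with a multi-resolution Thirion demons algorithm, and the
   PTP mask is warped into the planning frame. The gross tumor volume (GTV) is
   subtracted so solid tumor never counts as pneumonitis.
2. **EQD2 conversion** — the planned physical dose `D` (delivered in `N`
   equal fractions, voxel fraction dose `d = D/N`) is converted to the
   equivalent dose in 2-Gy fractions under the linear-quadratic model,

   `EQD2 = D · (d + α/β) / (2 + α/β)`,  with `α/β = 3 Gy` for lung.

3. **Dose-volume analytics** — cumulative DVH and its area under the curve
   (AUC, Gy·%); V20 and V40 (volume receiving ≥ 20 / ≥ 40 Gy); mean EQD2;
   the volume split into low dose (LD, < 20 Gy), intermediate dose
   (ID, 20–40 Gy) and high dose (HD, ≥ 40 Gy); total-lung mean dose (MLD)
   and V20.
4. **Cohort statistics** — Mann-Whitney-U tests for numeric variables
   (exact by enumeration for small tie-free samples), Pearson chi-square for
   categorical ones, significance at p < 0.05, and one-to-one matched pairs
   across treatment groups minimizing the total absolute planning-target-
   volume (PTV) difference, per definitive/palliative stratum.

Because real patient cohorts of this kind are not publicly available, the
package ships a first-class synthetic module: analytic thorax phantoms with a
known smooth deformation, a conformal dose with configurable penumbra, a
two-lobe pneumonitis region with a calibrated overlap with the high-dose
region, and simulated cohorts — so every stage is validated against exact
ground truth.

## Worked example

```bash
pneumodose phantom --seed 4 --out phx/        # synthetic patient + ground truth
pneumodose evaluate --patient-dir phx/ --out out/
pneumodose cohort-sim --n 16 --effect 900 --seed 7 --out cohort.csv
pneumodose cohort --records cohort.csv --out tables/
```

prints

```
phantom written to phx (achieved HD overlap 0.453)
PHANTOM-004: V_ptp=28.1 cm^3, mean EQD2=37.6 Gy, AUC=3757.4 Gy*%
32 simulated records written to cohort.csv
cohort tables written to tables
```

The phantom line reports the calibrated fraction of the pneumonitis region
inside the ≥ 40 Gy (EQD2) volume. The evaluate line is the per-patient
result after registration, GTV subtraction and EQD2 conversion: pneumonitis
volume, its mean EQD2, and the DVH AUC. `tables/summary_all.csv` holds the
group comparison (mean / SD / median / min / max per variable per group with
the test and p-value), e.g.

```
variable,group,n,mean,sd,median,min,max,test,p_value,significant
v_ptp_cm3,RCT_ICI,16,32.468750,23.545722,30.125000,6.875000,89.250000,MWU,0.235105,False
v_ptp_cm3,RCT,16,48.031250,34.876105,48.687500,7.875000,111.375000,MWU,0.235105,False
```

alongside per-stratum summaries and the PTV-matched pair lists. The same
workflow is available as library calls (`evaluate_patient`, `run_cohort`,
`generate_phantom_pair`, …).

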