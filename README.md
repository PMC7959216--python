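# fontanstress

Atrial and diastolic ventricular function from chamber volume–time curves
under pharmacological stress, for single-ventricle (Fontan) physiology.

Patients with a Fontan circulation have no subpulmonary pump: systemic
venous return crosses the lungs passively, and circulatory performance
hinges on how well the single ventricle *fills*. That makes diastolic
ventricular function and the function of the pulmonary-venous atrium — its
reservoir, conduit and booster-pump roles — central quantities, and their
*reserve* under low-dose dobutamine stress a candidate marker of occult
dysfunction. This package is for researchers analysing such data (or
prototyping such analyses): it provides

- **`fontanstress.synthetic`** — a physiologically consistent generator of
  paired rest/stress ventricular + atrial volume–time curves with known
  ground truth, plus CPET breath series and follow-up event times;
- **`fontanstress.curves`** — extraction of the functional parameter set
  from one cycle of volume samples, BSA indexing (Haycock) and stress
  reserves;
- **`fontanstress.outcomes`** — peak VO2 (final-30-s mean, gated on
  maximal effort, RER ≥ 1.05), VE/VCO2 slope, and the composite clinical
  endpoint (death, transplant listing, qualifying arrhythmia,
  reintervention) with first-event timing;
- **`fontanstress.stats` / `fontanstress.report`** — the cohort battery:
  paired Wilcoxon (exact for small n), rank-sum, χ²/Fisher, Spearman ρ,
  Benjamini–Hochberg FDR control, univariable Cox models and Kaplan–Meier
  event-free survival, assembled into three report tables.

## The quantities

From each cycle: EDV, ESV, SV = EDV − ESV, EF = 100·SV/EDV; early filling
volume (volume gained over the first ⅓ of diastole); late filling volume
(gain from atrial-contraction onset to end-diastole); early/late peak
filling rates from the spline derivative, their ratio E/A; deceleration
time, extrapolating the 70–30% band of the early-filling downslope to zero
rate. From the atrial curve: maximal/minimal volume, cyclic volume change
V_max − V_min, early (reservoir) and late (booster-pump) emptying volumes,
and the conduit volume

    V_conduit = SV − (V_early-emptying + V_late-emptying),

i.e. ventricular filling that occurs while venous return equals
atrioventricular flow. Reserve(x) = x_stress − x_rest. All volumes are
indexed to body surface area (Haycock: 0.024265·kg^0.5378·cm^0.3964).

## Worked example

```python
import fontanstress as fs

params = fs.CyclePhysioParams.closed_loop(
    edv=130.0, esv=64.0, e_fill_volume=52.9, a_fill_volume=13.1,
    systole_fraction=0.38, e_peak_time_frac=0.225, e_width_frac=0.45,
    a_onset_frac=0.71, a_width_frac=0.29, heart_rate=71.4, a_min_volume=34.0)
vcurve, acurve, truth = fs.generate_cycle(params, n_frames=30)
vf, af, landmarks = fs.extract_features(vcurve, acurve)
```

`examples/single_cycle_extraction.py` prints (abridged):

```
parameter                           extracted      truth
EDV (mL)                               130.00     130.00
Early filling volume (mL)               48.07      47.59
Late filling volume (mL)                12.07      12.10
Early peak filling rate (mL/s)         451.41     451.26
Deceleration time (ms)                  96.38      96.57
Atrial early emptying (mL)              23.71      23.72
Atrial late emptying (mL)               14.07      14.09
Conduit volume (mL)                     28.28      28.19
```

— from only 30 frames per cycle the extractor recovers the generative
truth to a fraction of a millilitre, and the conduit volume obeys its
defining identity exactly.

At cohort scale, `examples/cohort_statistics.py` generates the default
57-patient paired cohort and runs the battery:

```
parameter                                    rest             stress        p    p(BH)
End-diastolic volume            85.8 (69.2-105.9)   76.1 (60.6-94.3)   0.0000   0.0000
Early filling volume              13.9 (7.8-18.4)    12.1 (5.7-15.2)   0.0000   0.0000
Late (atrial) filling volume      10.3 (7.8-12.8)    10.8 (8.4-14.0)   0.0001   0.0001
Atrial cyclic volume change      21.7 (15.7-28.7)   24.7 (18.7-31.9)   0.0000   0.0000
Stroke volume                    39.9 (32.4-52.8)   39.5 (34.2-52.8)   0.1550   0.1647

ECC stratum, atrial early-emptying reserve vs peak VO2: rho=0.74 (target 0.66),
BH-adjusted p=0.007, n=18
5-year event-free survival: 81% (95% CI 68-89%)
```

Cells are median (IQR) in mL/m²; EDV falls under stress while stroke
volume does not change, atrial cyclic volume change and both filling
phases shift in their configured directions, and the copula-induced
correlation between atrial early-emptying reserve and peak VO2 surfaces in
the ECC stratum.

The other examples cover the cohort generator
(`examples/synthetic_cohort.py`) and CPET/endpoint reduction
(`examples/cpet_and_events.py`). A thin CLI mirrors the file-based
pipeline:

```bash
fontanstress simulate --seed 1 --out study/
fontanstress extract  --curves study/curves.csv --patients study/patients.csv --out features.csv
fontanstress analyze  --features features.csv --patients study/patients.csv --out report/
fontanstress report   --tables report/
```

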