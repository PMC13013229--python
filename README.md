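# dpdquant

Quantitative [99mTc]Tc-DPD SPECT/CT marker extraction for transthyretin
cardiac amyloidosis (ATTR-CM), with a verifiable digital thorax phantom and
cohort-level treatment-response statistics.

In ATTR-CM, misfolded transthyretin deposits in the myocardium take up
bone-avid tracers such as [99mTc]Tc-DPD. Quantitative SPECT/CT turns that
uptake into candidate biomarkers of disease burden and treatment response.
`dpdquant` computes a 26-marker panel from a thoracic SPECT volume (voxel
values in SUV, or Bq/mL plus dose metadata) and coregistered CT-grid
anatomical masks (myocardium, LV, RV, LA, RA, vertebrae T7–T11, right
paraspinal muscle, inferior vena cava), and provides the statistical
machinery to analyse paired pre/post cohorts of such panels.

## The marker panel

For each cardiac structure *S* ∈ {LV, RV, LA, RA, myocardium}, with
*D(S)* the mask expanded by 10 mm (spill-out / coregistration margin):

- **SUV metrics** (15): SUV<sub>max</sub>, SUV<sub>mean</sub>,
  SUV<sub>peak</sub> over *D(S)*. SUV<sub>peak</sub> is the mean uptake in a
  1 mL sphere (r ≈ 6.20 mm) placed over all in-mask voxel centers to
  maximize the contained uptake.
- **Retention index** (1):
  RI = SUV<sub>peak</sub>(myocardium) / SUV<sub>peak</sub>(T9) ×
  SUV<sub>peak</sub>(paraspinal muscle, restricted axially to the T7–T11
  span).
- **Amyloid activity** (5): SUV<sub>mean</sub>(*D(S)*) × volume(*D(S)*)
  in SUV·mL — a total-uptake integral.
- **Amyloid-affected volume** (5): after target-to-background normalization
  TBR = SUV / mean SUV(IVC), the volume in mL of voxels in *D(S)* with
  TBR ≥ 1.

Cohort statistics mirror the standard treatment-response workflow:
Shapiro–Wilk-gated paired tests (paired *t* / Wilcoxon signed-rank),
normality-gated group comparisons (t / Mann–Whitney U, chi-square / Fisher),
Kaplan–Meier + log-rank + Cox models stratified by the *sign* of each
marker's change (Δ ≥ 0 vs Δ < 0), and inter-rater agreement via ICC(2,1).
All p values are unadjusted and exploratory.

## Worked example

```python
import dpdquant as dq

spec = dq.default_thorax(psf_fwhm_mm=8.0, noise=dq.NoiseModel("gaussian", 0.1), seed=1)
volume, structures, truth = dq.generate_phantom(spec)
panel = dq.extract_panel(volume, structures)
print(panel["SUVmax_MYOCARDIUM"], truth.panel["SUVmax_MYOCARDIUM"])
```

Running `python examples/extract_phantom_markers.py` prints (abridged):

```
marker                             measured      truth
SUVmax_MYOCARDIUM                     11.98      12.00
SUVpeak_MYOCARDIUM                    11.20      12.00
RETENTION_INDEX                        2.43       2.40
AMYLOID_ACTIVITY_MYOCARDIUM         2990.33    2991.16
```

The phantom's myocardial wall has true uptake SUV 12; under a simulated
8 mm FWHM point-spread function SUV<sub>max</sub> and SUV<sub>peak</sub>
drop slightly (resolution loss), while amyloid activity — an uptake
*integral* over the 10-mm-expanded region — barely moves because spill-out
stays inside the expanded mask. With `psf_fwhm_mm=0` and no noise every
marker reproduces the analytic truth exactly.

`examples/simulate_treatment_cohort.py` and `examples/reader_agreement.py`
demonstrate the paired-test table, the survival stratification by Δ sign
and the ICC workflow. A thin CLI wraps the same functions:

```bash
dpdquant phantom --out fixture/ --seed 1
dpdquant extract --spect fixture/spect_suv.nii --mask-dir fixture/masks --out markers.csv
dpdquant cohort-stats --cohort cohort.csv --out-dir stats/ --survival
dpdquant reader-icc --readings readings.csv --out icc.json
```

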