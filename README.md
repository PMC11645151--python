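# nephrokit

Quantitative kidney phenotyping for deep-phenotyping studies of type 1
diabetes (T1D) and healthy controls: dynamic ¹¹C-acetate PET kinetic
modelling, multiparametric kidney MRI map estimation, renal clearance and
Gomez intraglomerular hemodynamics, hyperinsulinemic-euglycemic clamp
metrics, and the cohort statistics that tie them together. A synthetic-data
module generates every input with known ground truth, so the full pipeline
is testable by parameter recovery without any imaging data on disk.

Intended users: imaging physicists and renal physiologists analysing
research kidney PET/MRI studies, and analysts reproducing clamp/clearance
phenotyping endpoints.

## Models

**PET kinetics.** Tissue tracer concentration follows the one-tissue
compartment model

    dC_t/dt = K₁·C_a(t) − k₂·C_t(t),
    C_PET(t) = (1 − v_b)·C_t(t) + v_b·C_a(t),

with K₁ the uptake rate (mL plasma/min/mL tissue), k₂ the clearance rate
(min⁻¹; with ¹¹C-acetate a surrogate for TCA-cycle CO₂ production, i.e.
oxidative metabolism), and v_b the blood volume fraction. The arterial
input C_a comes from an aorta ROI, metabolite-corrected and scaled to a
venous sample. Blood flow is F = K₁/E with extraction fraction E = 0.52.
`OneTissueModel(tac, aif).fit()` solves the weighted nonlinear
least-squares problem against an exact analytic convolution;
`VoxelwiseKineticModel` produces K₁/k₂ parametric maps by linear ridge
regression with a spatial constraint (smoothed-prior ridge).

**MRI.** R2\* (s⁻¹, BOLD oxygen availability) and ADC (mm²/s) are
log-linear monoexponential fits S(x) = S₀e^(−rate·x); FSOC is the drop in
R2\* after furosemide; total kidney volume from label masks.

**Renal physiology.** GFR and RPF from timed iohexol/PAH urinary
clearance periods (clearance = U·V̇/P̄, RPF = C_PAH/e_PAH); the Gomez
framework then yields filtration fraction, RBF, glomerular oncotic and
intraglomerular pressures, and afferent/efferent arteriolar resistances;
RVR = MAP/RBF.

**Metabolic and statistics.** Clamp M-value (steady-state glucose
infusion rate), NEFA suppression, DXA muscle mass; metabolomics
imputation (20% of per-metabolite minimum) and duplicate averaging;
Welch/Mann-Whitney/χ²/Fisher comparisons, covariate-adjusted
least-squares means, Spearman correlation, asymptotic two-sample
Kolmogorov-Smirnov, sqrt-scale regression for right-skewed outcomes,
noncentral-t power, and the 500–5000 genes / <50% mitochondrial
single-cell QC filter.

## Worked example

```python
import numpy as np
from nephrokit.petkinetics import PKParameters, OneTissueModel, simulate_tac
from nephrokit.petkinetics import DEFAULT_FRAME_SCHEDULE
from nephrokit.synth import gen_aif
from nephrokit.renal import gomez_profile

aif, _ = gen_aif()                       # gamma-variate arterial input
truth = PKParameters(K1=0.18, k2=0.18, vb=0.10)
tac = simulate_tac(truth, aif, DEFAULT_FRAME_SCHEDULE)
res = OneTissueModel(tac, aif).fit()
print(res.summary())
```

```
One-tissue compartment model fit
================================
  method          : nls
  K1  (mL/min/mL) : 0.18000
  k2  (1/min)     : 0.18000
  vb  (fraction)  : 0.10000
  F   (mL/min/mL) : 0.34615  (extraction fraction 0.52)
  residual norm   : 2.214e-12
  converged       : True
```

The fit recovers the generating parameters (K₁ = 0.18 mL/min/mL uptake,
k₂ = 0.18 min⁻¹ oxidative turnover, 10% blood volume) and converts K₁ to
a blood flow of 0.346 mL/min/mL tissue.

```python
profile = gomez_profile(gfr=147.0, rpf=600.0, map_pressure=93.0,
                        hct=0.42, total_protein=7.0)
print(profile.summary())
```

```
Gomez hemodynamic profile
=========================
  GFR       :   147.0000 mL/min
  RPF       :   600.0000 mL/min
  FF        :     0.2450
  RBF       :  1034.4828 mL/min
  delta_P_F :    24.2095 mmHg
  C_M       :     8.0296 g/dL
  pi_G      :    30.1482 mmHg
  P_GLO     :    64.3577 mmHg
  R_A       :  2206.1442 dyn*s/cm^5
  R_E       :  2173.5767 dyn*s/cm^5
  RVR       :     0.0899 mmHg*min/mL
```

A hyperfiltering participant (GFR 147 mL/min, filtration fraction 0.245)
shows elevated intraglomerular pressure (64.4 mmHg) with a low renal
vascular resistance — the hemodynamic signature the framework is designed
to expose.

A command-line surface mirrors the library:
`nephrokit pet-fit`, `nephrokit mri-maps`, `nephrokit hemo`,
`nephrokit cohort`, `nephrokit simulate`.

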