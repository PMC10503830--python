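# qmripd

Quantitative-MRI pharmacodynamic response analysis for stroma-modifying
cancer therapies.

When a drug such as a pegylated hyaluronidase degrades the hyaluronan-rich
tumor stroma, the change shows up within a day in quantitative MRI: water
content falls (lower ADC and T1) while perfusion, permeability, vascular
and extracellular space rise (higher iAUC, k<sup>trans</sup>, v<sub>p</sub>,
v<sub>e</sub>). `qmripd` turns multi-visit DW-, variable-flip-angle and
DCE-MRI acquisitions into those six parameter maps, decides per tumor and
per pixel whether the post-treatment change exceeds measurement
repeatability, and learns which baseline values predict that response —
the workflow an imaging-biomarker group needs for early-phase trials of
stroma-targeting agents.

## Models

* **ADC** — mono-exponential diffusion decay, S(b) = S₀·exp(−b·ADC);
  closed form for the two-point b = 0/450 s/mm² protocol, log-linear least
  squares for more b-values, replicates fitted independently and averaged.
* **T1** — spoiled gradient-echo signal
  S(α) = M₀ sin α (1−E₁)/(1−cos α·E₁), E₁ = exp(−TR/T1), fitted per voxel
  from the multi-flip-angle series (DESPOT1 linearization seeding a bounded
  profile search), with optional global flip-angle scale κ, per-volume
  intensity scales, and a spatial-smoothness penalty on R1 = 1/T1.
* **DCE** — SPGR inversion of each frame to T1(t), gadolinium
  concentration C(t) = (1/T1(t) − 1/T1_pre)/r₁, the AIF averaged over
  arterial voxels (or a biexponential population bolus), iAUC as the
  90-second post-arrival integral, and the extended Tofts model
  C_t(t) = v_p·C_p(t) + k^trans·(C_p ⊛ e^{−k^trans t / v_e})
  fitted by bounded multi-start least squares with an analytic Jacobian.
* **Repeatability** — RC = 2.77·√σ_w² with σ_w² the pooled one-way
  within-subject variance of replicate measurements; literature RCs are
  shipped for parameters without replicates (T1 0.27 s, iAUC ±32%,
  k^trans −45 %/+83 %, v_e 0.076, v_p 0.0062).
* **Response** — a tumor (or pixel) is a pharmacodynamic responder when
  its day-1 change beats the directional RC: below −RC for ADC and T1,
  above +RC for the rest. Baseline threshold rules maximizing balanced
  accuracy = (sensitivity + specificity)/2 are found by exhaustive
  cut-point search with exact McNemar p-values; the pixel-level analysis
  trains a class-balanced, per-patient-sampled decision stump and
  evaluates it by leave-one-patient-out cross-validation.

Because trial images are not redistributable, a seeded digital-phantom
module simulates the whole acquisition protocol (ellipsoidal tumors with
smooth heterogeneity, replicate DWI, four-angle VFA, a 48-frame DCE
series) with a programmed, optionally gated treatment effect — so every
stage is testable end to end against known ground truth.

## Worked example

```python
import numpy as np
from qmripd import (PhantomSpec, NoiseSpec, generate_phantom,
                    within_subject_variance, repeatability_coefficient)
from qmripd.io import RunConfig, write_phantom_study
from qmripd.pipeline import run_pipeline

# 1. Repeatability coefficient from baseline ADC replicate medians
reps = [(1.10e-3, 1.16e-3), (0.92e-3, 0.88e-3), (1.41e-3, 1.38e-3)]
var = within_subject_variance(reps)
print(f"sigma_w^2 = {var:.3e}   RC = {repeatability_coefficient(var):.2e} mm^2/s")

# 2. Noiseless digital phantom study through the full pipeline
spec = PhantomSpec(seed=1, noise=NoiseSpec(sigma_rel=0.0),
                   visits=("baseline", "day1"))
truth = generate_phantom(spec)
manifest = write_phantom_study(truth, "study")
result = run_pipeline(manifest, RunConfig(), output_dir="study/out")

day1 = result.labels[result.labels.visit == "day1"]
print(day1[["tumor_id", "parameter", "change", "label"]].to_string(index=False))
```

prints

```
sigma_w^2 = 1.017e-09   RC = 8.83e-05 mm^2/s
tumor_id parameter    change label
  tumor1       adc -0.000317     P
  tumor1        t1 -0.199362     N
  tumor1      iauc  0.657895     P
  tumor1    ktrans  0.800000     N
  tumor1        ve  0.139987     P
  tumor1        vp  0.014834     P
  tumor2       adc -0.000222     P
  tumor2        t1 -0.140146     N
  tumor2      iauc  0.637766     P
  tumor2    ktrans  0.800000     N
  tumor2        ve  0.196476     P
  tumor2        vp  0.026579     P
```

The RC line pools the three replicate pairs into a within-subject variance
and scales by 2.77, the factor that makes ±RC cover ~95 % of test-retest
differences. In the phantom run, each tumor's day-1 median change is
compared with its RC: the ADC decrease (absolute units) and the relative
iAUC rise (+66 % > +32 %) are responders (`P`), while the programmed
default effect leaves T1 (−0.20 s, inside the 0.27 s literature RC) and
k^trans (+80 %, inside the +83 % bound) as non-responders (`N`) — changes
smaller than measurement repeatability are never called responses.

The same pipeline is scriptable from the shell:

```sh
qmripd simulate --seed 1 --sigma-rel 0.02 --out study
qmripd run-all --manifest study/manifest.csv --out study/out
qmripd report --manifest study/manifest.csv --out study/report
```

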