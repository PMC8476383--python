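# myelinmap

Quantitative R1 relaxometry of brain myelination in infants and young
children.

Myelin raises the longitudinal relaxation rate R1 = 1/T1 of white matter,
so R1 mapping tracks brain maturation quantitatively where conventional
T1-/T2-weighted reading is subjective. `myelinmap` implements the full
analysis chain around a 3-T MP2RAGE acquisition:

* **MP2RAGE signal engine** — forward-simulates the steady-state
  longitudinal magnetization of the magnetization-prepared 2 rapid
  acquisition gradient echoes sequence, combines the two inversion-time
  images into the bias-robust uniform ratio
  `UNI = S1·S2/(S1² + S2²) ∈ [−0.5, 0.5]`, and inverts UNI to T1/R1 through
  a monotone lookup table. Includes a transmit-field (B1+) bias analysis.
* **Growth model** — fits the saturating-exponential myelination model

  ```
  R1(t) = R1∞ + A·e^(−t/τ),   A < 0
  ```

  per brain region by weighted nonlinear least squares (t = age in months,
  R1∞ = mature asymptote, R1∞ + A = value at birth, τ = myelination time
  constant), builds normative reference tables, and scores individual
  subjects as z-deviations from the norm.
* **Synthetic data** — seeded generators for tabular cohorts (ages 3–72
  months) and 3-D digital phantoms with paired inversion-time volumes,
  smooth ±10% transmit/receive bias fields and Gaussian noise, so the whole
  pipeline runs with exact ground truth and no data download.
* **ROI statistics & reliability** — per-label R1 mean ± SD from NIfTI
  label maps, intraclass correlation (two-way ANOVA, agreement/consistency,
  single/average) and Bland–Altman limits of agreement.
* **CLI** — `myelinmap` subcommands composing the stages with seeds and
  run manifests.

Intended users: researchers in pediatric neuroimaging and quantitative MRI
who need reproducible normative R1 curves and a testbed for MP2RAGE-based
relaxometry.

## Worked example

```python
import numpy as np
from myelinmap import (
    CohortSpec, generate_cohort, fit_growth, NormativeReference,
    reference_table, deviation_z, RegionObservation,
)

# 94-subject synthetic cohort drawn from the published growth curves
cohort = generate_cohort(CohortSpec(n_subjects=94, seed=42))
splenium = [o for o in cohort if o.region_key == "splenium"]
fit = fit_growth(splenium)
print(f"splenium: R1_inf = {fit.r1_inf:.3f} 1/s, A = {fit.amplitude:.3f} 1/s, "
      f"tau = {fit.tau:.1f} +/- {fit.tau_uncertainty:.1f} months")

reference = NormativeReference(params={"splenium": fit})
print(reference_table(reference))

patient = RegionObservation(subject_id="P01", age=25.3, region="splenium",
                            r1_mean=0.82, r1_sd=0.04, group="positive")
score = deviation_z(patient, fit)
print(f"patient z = {score.z:.2f} (flagged: {score.flagged})")
```

prints

```
splenium: R1_inf = 1.206 1/s, A = -0.773 1/s, tau = 12.2 +/- 0.6 months
           0mo  12mo  24mo
region
splenium  0.43  0.92   1.1
patient z = -7.15 (flagged: True)
```

The fitted splenium curve rises from R1 ≈ 0.43 1/s at birth toward
1.2 1/s with a time constant of about a year — the corpus callosum is
among the fastest-myelinating structures. The example patient, a
25-month-old with R1 = 0.82 ± 0.04 1/s, sits 7 standard deviations below
the normative curve and is flagged (|z| > 2.5), the signature of a
hypomyelinating disorder.

The same pipeline from the shell:

```sh
myelinmap simulate-cohort --n 94 --seed 42 --out cohort.csv
myelinmap fit-normative --cohort cohort.csv --out-dir fit/
myelinmap simulate-phantom --age 24 --seed 5 --out-dir phantom/
myelinmap t1map --ti1 phantom/ti1.nii --ti2 phantom/ti2.nii --out-dir maps/
myelinmap roi-stats --r1-map maps/r1_map.nii --labels phantom/labels.nii \
    --label-table phantom/labels.csv --out roi.csv
myelinmap b1-bias --b1-scale 1.1 --t1 0.9,1.4 --out bias.csv
```

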