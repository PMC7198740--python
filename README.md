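# vqmaps

Normal mean and standard-deviation statistical maps — and patient Z-score
maps — for ventilation/perfusion (V/Q) lung SPECT/CT.

## The problem

V/Q SPECT measures regional lung function: ⁹⁹ᵐTc-MAA uptake is
proportional to local perfusion, ⁸¹ᵐKr gas concentration to local
ventilation.  Quantifying these images is hard because normal uptake is
*not* uniform: in supine position gravity produces a posterior-to-anterior
perfusion gradient whose strength varies between subjects, attenuation
correction (AC vs NoAC) changes the apparent gradient, and counts are
only meaningful relative to the whole lung.  Simple thresholding of such
images cannot separate physiological heterogeneity from disease.

`vqmaps` implements the statistical-map approach: co-register a cohort of
normal V/Q SPECT/CT studies into one reference geometry using the CT,
normalize each SPECT to a whole-lung mean of 1000, and build voxel-wise
normal maps

```
I_mean(x)  = (1/n)     Σᵢ Iᵢ(x)
I_stdev(x) = sqrt( (1/(n-1)) Σᵢ [Iᵢ(x) − I_mean(x)]² )
```

(eight volumes: perfusion/ventilation × AC/NoAC × mean/SD).  A patient
scan is then scored voxel-by-voxel against the database:

```
Z(x) = [Patient(x) − I_mean(x)] / I_stdev(x)
```

after transporting the maps into the patient's geometry by the same
CT-driven registration.  Mismatched perfusion defects (the scintigraphic
signature of pulmonary embolism) appear as coherent Z < −1 regions on the
perfusion map with a silent ventilation map.

Regional summaries include relative lobar function (lobe counts / whole
lung counts) and the gravity-gradient metrics measured on four spherical
ROIs of the right lung:

```
PArd = (Anterior − Posterior) / Posterior   (%)
ISrd = (Superior − Inferior) / Inferior     (%)
```

Because clinical cohorts cannot ship with a package, `vqmaps` includes a
**digital thorax phantom**: synthetic normal V/Q SPECT/CT cases with a
known per-subject gravity gradient, AC/NoAC attenuation contrast, Poisson
counting noise with a SPECT-like reconstruction filter, inter-subject
anatomical deformation, ground-truth lung/lobe labels, and injectable
mismatched wedge defects.  Every stage of the pipeline is validated
against this ground truth; see `docs/methods.md` for the model and its
limits.

## Worked example

```python
from vqmaps import (PhantomConfig, generate_cohort, generate_case,
                    inject_defect, default_pe_defect)
from vqmaps.pipeline import build_database, map_gradient_metrics, score_patient
from vqmaps.zscore import region_summary

config = PhantomConfig(seed=11)
cohort = generate_cohort(config, 20)          # 20 synthetic normal subjects
db = build_database(cohort)                   # register, normalize, 8 maps

for modality in ("perfusion", "ventilation"):
    for ac in ("AC", "NoAC"):
        gm = map_gradient_metrics(db, modality, ac)
        print(f"{modality:12s} {ac:4s}  PArd {gm.pard:+6.1f} %  ISrd {gm.isrd:+5.1f} %")

patient = generate_case(config, 100)          # held-out normal subject
patient_pe, wedge = inject_defect(patient, default_pe_defect(patient, 0.2))
zmaps = score_patient(db, patient_pe)
s = region_summary(zmaps[("perfusion", "AC")], wedge.values)
print(f"mean perfusion Z in defect: {s['mean_z']:.2f} SD  (min {s['min_z']:.2f})")
```

prints

```
perfusion    AC    PArd  -35.5 %  ISrd  -0.2 %
perfusion    NoAC  PArd  -21.7 %  ISrd  -0.1 %
ventilation  AC    PArd   +9.7 %  ISrd  -0.1 %
ventilation  NoAC  PArd  +32.6 %  ISrd  -0.8 %
mean perfusion Z in defect: -18.12 SD  (min -33.97)
```

Read: perfusion is posterior-dominant (negative PArd) and attenuation
correction deepens the gradient (AC more negative than NoAC); ventilation
shows the opposite, smaller gradient; there is no systematic
superior-inferior gradient.  The simulated embolism (wedge at 20% of
normal perfusion) scores far below the −1 SD landmark on the perfusion
Z-map, while the same region on the ventilation Z-map stays near zero
(a mismatched defect).

A command-line interface mirrors the library:
`vqmaps simulate | segment | register | build-maps | quantify | zscore`
(each subcommand takes `--manifest`; see `--help`).

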