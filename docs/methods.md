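# Methods

This note records the models, parameter choices and numerical decisions
behind `vqmaps`, and what the phantom-based validation does and does not
demonstrate.

## Pipeline

1. **Lung segmentation** (`segmentation`): CT voxels below −400 HU,
   connected components, removal of components touching the volume
   border (outside-body air), the two largest components kept and
   labeled right/left by world-x centroid (RAS), binary closing with a
   2-voxel ball to fill vessel-sized holes.  All extrapulmonary voxels
   of the working CTs are set to 0 before registration.
2. **Reference selection**: the case whose total lung volume is closest
   to the cohort median (ties broken by smallest case id).  "Volume" is
   the left+right mask volume in mL.
3. **Registration** (`registration`): a rigid "box-based" stage aligns
   the lung-mask bounding-box centers (optionally refined by a short
   mean-squares Euler3D optimization), then a multi-resolution
   diffeomorphic-demons registration of the masked CTs (shrink factors
   4/2/1 with 60/40/15 iterations, field smoothing σ = 0.8 grid units).
   The same composed transform resamples the four SPECT reconstructions
   (linear interpolation) and label volumes (nearest neighbour).  No
   Jacobian intensity modulation is applied: the subsequent mean
   normalization removes the global scale that intensity-preserving
   resampling introduces (totals change by the lung-volume ratio), and
   local count non-conservation is accepted.
4. **Harmonic interior fill**: lung parenchyma is nearly homogeneous on
   CT, so image intensities carry no correspondence information inside
   the lungs; left to itself the demons update fills the interior with a
   poorly constrained diffusion of edge forces and texture noise.  After
   the demons loop the displacement inside the lung mask (eroded by one
   voxel) is replaced by the harmonic extension of the boundary-shell
   field (Laplace equation per component, coarse-grid relaxation plus a
   fine polish).  Any affine component of the true inter-subject warp is
   linear, hence harmonic, hence reproduced exactly; measured on
   phantoms this removes a systematic ~1 percentage-point compression of
   the map gradient and tightens its spread.
5. **Normalization** (`statmaps`): per case, the mean value inside the
   *reference* lung mask is stored and every voxel is multiplied by
   1000/stored_mean, so the in-mask mean is exactly 1000.  Normalizing by
   the mean (not the maximum) makes the scale insensitive to focal hot
   spots.  The factor is applied to all voxels, in and out of mask.
6. **Maps**: voxel-wise arithmetic mean and sample SD (n−1) over the
   registered, normalized cohort — eight volumes per cohort
   (perfusion/ventilation × AC/NoAC × mean/SD).
7. **Z-scoring** (`zscore`): the reference CT is registered onto the
   patient CT (same rigid+deformable scheme, database→patient
   direction), the mean and SD maps are transported with linear
   interpolation, the patient SPECT is normalized to in-lung mean 1000
   using the patient's own segmentation, and z = (patient − mean)/SD is
   evaluated on a validity mask.
8. **Quantification** (`quantify`): relative lobar function; PArd/ISrd
   from four spherical ROIs; Kolmogorov–Smirnov normality check;
   one-sample Student t comparison of individual gradients against the
   map measurement; seeded split-half validation (⌈n/2⌉ map-building /
   ⌊n/2⌋ held-out).

Registration quality gates: cohort members must reach lung Dice ≥ 0.90
against the reference (else excluded and logged); the database→patient
registration must reach Dice ≥ 0.85 (else an error).

## Digital thorax phantom

Anatomy: body = elliptic cylinder (semi-axes 135 × 105 mm, height
280 mm); lungs = two ellipsoids (46 × 70 × 100 mm semi-axes, centers at
x = ±68 mm); five lobes cut by fixed oblique planes in unit-sphere
coordinates (the right lung by two *parallel* planes), so every lobe
volume fraction has an exact spherical-cap/slab closed form.  Grid
64³ at 4.8 mm isotropic (SPECT-like); the CT shares the grid, with
−1000/+40/−780 HU for air/body/lung plus smooth ~25 HU texture when
noise is enabled.

Function: tracer activity is linear in the normalized
posterior-to-anterior position, A(x) = A₀·(1 + g·p(x)), where p runs
from −0.5 at a lung's most posterior voxel to +0.5 at its most anterior
(the gravity coordinate is normalized per lung, so "dependent region"
is defined within each lung).  Per subject, g is drawn from
Normal(g_pa, g_sigma) independently for perfusion and ventilation.

NoAC emulation: expected counts are multiplied by exp(−μ·depth) with
depth measured from the anterior *tangent plane* of the body — a planar
depth, chosen so the expected ROI activity has an exact closed form
(`analytic_pard` evaluates the exact ball average of (a+by)e^{μy},
with a series expansion for small μR to avoid cancellation).

Noise: Poisson counts around the expected activity followed by a
Gaussian reconstruction filter of 8 mm FWHM — the filter width used for
SPECT reconstructions at this voxel size — which leaves the expected
image smooth and the noise spatially correlated.  Expected in-lung
counts of the *reconstructed* AC image are calibrated to `count_budget`.
With `noise=False` the volumes are the exact unsmoothed activity
expectations (the deterministic limit used by the closed-form checks).

Inter-subject variation: per-axis affine scaling (±10%) plus a random
Gaussian-smoothed displacement field (amplitude 6 mm, correlation length
24 mm, gradient-clipped to keep the pull-back map invertible).  Anatomy
membership is evaluated analytically at the warped coordinates, so truth
labels carry no interpolation error.

Defects: a cone (apex at the hilum, configurable axis and half-angle)
multiplies expected *perfusion* counts by `defect_fraction` before noise
resampling; ventilation is untouched (a mismatched, PE-like defect).
Bronchial hot spots are off by default (Krypton-like ventilation).

### Key parameters (defaults)

| parameter | default | rationale |
|---|---|---|
| `grid_shape`, `voxel_size_mm` | 64³, 4.8 mm | SPECT-resolution grid; CT kept on the same grid to avoid multi-grid resampling |
| `g_pa_perf` | −0.85 | closed-form AC PArd ≈ −36%, the magnitude reported for attenuation-corrected perfusion |
| `g_pa_vent` | +0.17 | opposite-sign, smaller ventilation gradient (AC PArd ≈ +9%) |
| `g_sigma` | 0.15 | per-subject gradient spread; gives a per-case PArd SD of ~6 percentage points, the same order as clinical spreads |
| `atten_mu` | 0.003 /mm | effective in-tissue attenuation; reproduces the direction and rough size of the AC-vs-NoAC gradient shift |
| `count_budget` | 1e6 | typical total in-lung counts of a V/Q SPECT at desk scale |
| `recon_fwhm_mm` | 8 | reconstruction Gaussian filter |
| `deform_amp_mm`, `deform_scale_mm` | 6, 24 | mild, smooth inter-subject deformation |
| `affine_scale_range` | 0.1 | ±10% per-axis anatomical size variation |

The phantom does **not** emulate projection/sinogram physics, scatter,
collimator blur, respiratory motion, bronchial hot spots (unless
requested), airway anatomy, or realistic parenchymal texture; lungs are
smooth ellipsoids.  Passing tests therefore demonstrate that the
*pipeline* recovers known ground truth under controlled conditions —
they do not validate segmentation or registration accuracy on clinical
images.

## Numerical choices

- **ROI geometry**: spheres of radius 10 mm centered at 25%/75% of the
  right lung's AP extent (mid-SI, mid-LR) and of its SI extent (mid-AP,
  mid-LR), snapped to voxel centers, shifted toward the lung centroid
  and then shrunk (≥5 mm) until fully inside the mask; placement is
  deterministic.  Individual (non-registered) cases use ROIs on their
  own mask; maps use ROIs on the reference mask.
- **SD floor**: Z-map validity excludes lung voxels whose transported SD
  is below 5% of the in-lung median SD.
- **Identity short-circuit**: registering a volume to a bit-identical
  volume on the same grid returns the exact identity transform — the
  correct fixed point, which also makes warp-free cohorts exact.
- **KS normality**: tested against a normal law with estimated
  parameters; the p-value is liberal (Lilliefors situation) and a log
  message records the caveat.
- **t-test**: one-sample (the map measurement is a single number
  compared against n individual values); accepts printed (mean, sd, n)
  summaries, so published table rows can be checked directly.
- **Split-half**: ⌈n/2⌉ cases build maps, ⌊n/2⌋ are held out; the split
  is a seeded permutation.
- **Lobes are supplied** (phantom truth or user labels), never inferred;
  `attach_lobes` rejects maps with >1% of voxels outside the lung mask.
- Degenerate inputs raise distinct errors: empty masks, zero in-mask
  means, n < 2 cohorts, sub-5-sample KS, zero-SD t-tests, wedges that
  miss the lung, label volumes resampled with linear interpolation.

## Problem sizes

Validation uses 20-case cohorts at 64³ (database building takes ~1 min
on one CPU; a full patient scoring a few seconds).  The acceptance
script uses the same sizes.  Statistical checks that repeat the whole
pipeline (map-vs-individual agreement) use 10 seeded cohorts.

## Known limitations

- Linear interpolation during resampling attenuates the
  spatially-correlated counting noise of database cases by roughly 20%
  in SD, so the SD map slightly underestimates the noise of an
  unresampled patient scan and null Z-values are mildly over-dispersed
  (SD ≈ 1.2–1.5 instead of 1).  This matters most for the
  noise-dominated ventilation maps.
- A *normal* subject whose gravity gradient is 2σ from the population
  mean produces coherent |Z| > 3 regions at the AP extremes — inherent
  to normal-database scoring, and the reason the SD map is widest
  posteriorly.
- Counts are not conserved under resampling (no Jacobian modulation);
  totals scale with the lung-volume ratio, which the mean normalization
  removes.
- The demons similarity/stopping rules are this package's choices; no
  claim of equivalence with any commercial registration engine is made —
  the validation surface is ground-truth warp recovery on phantoms.
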