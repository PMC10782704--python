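# Methods

This note documents the models behind `pctqa`, the defaults and why they
were chosen, the numerical conventions, and the limits of what the synthetic
phantom can demonstrate.

## Geometry and volumes

A volume is a 3-D scalar grid with spacing and origin in mm; voxel
`(i, j, k)` is a **point sample** at `origin + index · spacing`.  Axes are
patient-LPS-like, but only internal consistency matters: every comparison is
intra-case.  Cross-grid comparisons resample the *evaluated* volume onto the
*reference* geometry (reference = planning CT and its dose), mirroring the
clinical direction of rigid dose transfer.  Masks resample with nearest
neighbour so they stay binary; out-of-field voxels after a rigid transform
are filled with 0 Gy (dose) or −1000 HU (CT-like) and flagged.  Structure
volume is voxel count × voxel volume; partial-volume effects are absorbed
into the DVH bin-width tolerance rather than modelled.

I/O is NRRD (preferred) and NIfTI-1 through SimpleITK.  Rigid transforms are
intrinsic z-y-x Euler rotations about the grid centre plus a translation;
composition with the inverse returns identity to ≤1e-9 mm.

## Synthetic phantom

The generator emulates the study conditions of a small-lesion brain-SRT
cohort, scaled down to desk size:

* **Anatomy** — an ~110 mm soft-tissue ellipsoid (40 HU) in a ~3 mm bone
  shell (1000 HU) in air (−1000 HU) on an 88³ grid at 1.25 mm isotropic
  (dose-grid convention; the clinical CT's 1.06 × 1.06 × 1.0 mm grid is
  supported via the resampling layer).  OARs: brainstem and spinal-cord
  cylinders, lens/optic-nerve/chiasm ellipsoids.  GTVs are spheres placed by
  rejection sampling with ≥3 mm clearance from OARs and each other; PTV =
  GTV dilated 2 mm by Euclidean-distance-transform thresholding (spacing
  independent).  1–4 lesions of 0.5–27.3 cm³; single-lesion cases sample the
  full range log-uniformly (median ≈ 3.7 cm³), multi-lesion cases cap each
  lesion at 10 cm³ so 2–4 lesions remain placeable in the scaled-down brain.
  CT texture: smooth low-frequency (σ = 4 voxels) plus fine Gaussian noise,
  total ~8 HU SD, body only.

* **Pseudo-CT** — `pct = max(ct + offset + noise, smooth(ct, σ) + offset)`
  inside the body, identical outside.  Defaults: offset −8 HU (CT-mean above
  pCT-mean), noise 10 HU, smoothing σ = 2 mm.  The smoothed floor raises the
  HU-min, emulating the low-energy smoothing bias of CNN-generated images.
  The floor clips the lower noise tail, so the realized mean deviation is
  ~3–5 HU — comfortably inside the <15 HU soft-tissue regime the defaults
  are meant to reproduce.  The smoothing magnitude is a free parameter; no
  measured value exists for it.

* **Dose** — analytic, not a beam model (treatment-planning dose calculation
  is out of scope; only *relative* CT-vs-pCT evaluation is exercised).  With
  `t` the signed distance to the PTV surface (positive outside, lightly
  smoothed so lattice-symmetric shells do not produce atomic DVHs) and
  δ = σ·√(ln 1.25):

      outside:  D = Dmax · exp(−((t + δ)/σ)²)
      inside:   D = Dmax · exp(−((δ·(1 + t/t_c))/σ)²)

  where `t_c` is the lesion's maximal interior depth.  The dose ramps from
  Dmax at the centre to exactly the prescription (= 0.8·Dmax, the
  "prescription at ~80% of maximum" SRT rule) at the PTV surface and falls
  as a Gaussian (σ = 3 mm, mimicking SRT's rapid falloff) beyond it.  The
  interior ramp is deliberate: a PTV-uniform dose would make D95%
  renormalization degenerate (V100% would be 100%, not ~95%).  A smooth 1%
  multiplicative modulation field emulates plan heterogeneity; disable it
  (`heterogeneity_sd=0`) for a strictly symmetric field.  Multi-lesion doses
  sum.

* **Pseudo-CT dose** — a seeded perturbation of the CT dose: global scale
  ~N(1, 0.004) and rigid shift ~N(0, 0.1 mm) per axis.  These defaults place
  the cohort in the qualitative regime the pipeline is designed to detect:
  local 1%/1 mm passing rates in the 80–95% band, mean |ΔTCP| below 1%, and
  near-perfect global 3%/2 mm rates.  The shift is the analog of rigid
  dose-transfer registration error; small lesions are the most sensitive to
  it, which the cohort reproduces.

Everything is bit-reproducible under `(config, seed)`.

## DVH conventions

Default bin width 0.01 Gy from 0 Gy; differential volumes in absolute cm³;
the cumulative fraction at edge `d` is the fraction of the structure at
≥ `d`.  All Dx% / D_vcc / Vx interpolation is linear on the cumulative
curve; Dmax/Dmin are voxel extremes (TPS convention), D\_0.1cm³ is the
absolute-volume interpolant.  Metrics from the binned curve agree with
direct sorting of voxel doses within one bin.  "Normal brain" is the brain
mask minus all GTVs, computed by set difference before the DVH.  PTV
Dmin/Dmax/Dmean are reported divided by the prescription; OAR metrics in Gy.
R100%/R50% count **body** volume at ≥100%/≥50% of the prescription over the
PTV volume.

## Gamma search

γ(r) minimises √(|e−r|²/Δd² + ΔD(e,r)²/ΔD_c²) over evaluated positions
within 3×Δd of the reference voxel, with trilinear interpolation of the
evaluated dose.  The implementation enumerates a dense 0.1 mm offset lattice
in shells of ascending spatial penalty with per-voxel early termination;
coarser requested resolutions add a halving local refinement.  A plain
coarse-to-fine scheme is not adequate here: with dose gradients of order
2 Gy/mm and 1–2% dose criteria, the agreement set is a sheet thinner than
0.1 mm in offset space, and a voxel-pitch scan steps over it (observed
errors up to ~0.5 γ against brute force).  Tests pin the search to a dense
brute-force lattice enumeration within 0.02 γ at every voxel.

Conventions (all config-exposed): the 10% low-dose threshold applies to the
**reference** voxel dose; global normalization uses the reference grid
maximum (not the prescription); local mode normalizes to the local reference
dose, so local γ ≥ global γ wherever the voxel is below the maximum.  A
`gamma_cap` (1.2 in cohort sweeps) bounds the search radius for speed; γ
values above the cap are upper bounds, pass/fail at γ ≤ 1 is unaffected.

## Radiomics

The 107 original-image features follow the IBSI-consistent definitions of
the standard reference feature set: fixed-bin-width discretization (25 HU,
relative to the masked minimum, no resampling), 13 unique directions at
distance 1 with symmetric GLCM accumulation and per-direction averaging
(GLCM, GLRLM), 26-connected zones (GLSZM), 26-neighbourhoods (NGTDM, GLDM),
and GLDM dependence counted as 1 + the number of neighbours within α = 0
grey levels.  Shape features are mesh-based (marching cubes at the 0.5
level); the maximum 2-D diameters are computed from surface-mesh vertices
projected onto the respective coordinate plane; principal axes come from the
eigenvalues of the physical voxel-coordinate covariance.  First-order
Entropy/Uniformity use the same fixed-width discretization; SD-type moments
use the population (N) divisor.

Structures with a single grey level or fewer than two voxels flag all
texture features degenerate (NaN), never silently dropped.  The paired
comparison removes a feature when any case yields a non-finite or degenerate
value in either image (alternative: median ± k·IQR screening).  On real
small organs this rule strikes the NGTDM and GLCM families first — the
qualitative outlier pattern the pipeline is built to surface.

## Radiobiology

EQD2 is applied per differential-DVH bin with the bin dose divided into the
plan's fraction count (uniform fractionation assumed), *before* EUD/Deff
condensation.  The tumour model is the EUD-based logistic
TCP = 1/(1 + (TCD50/EUD)^(4γ50)); the 4γ50 exponent gives the defining slope
property dTCP ≈ γ50/100 per 1% dose change at TCD50, and EUD = TCD50 gives
TCP = ½ exactly.  The organ model is LKB with Deff the 1/n power mean and
NTCP = Φ((Deff − TD50)/(m·TD50)); a uniform whole-organ dose at TD50 gives
NTCP = ½ exactly.  The power mean is evaluated in the log domain so serial
exponents (|a| ≫ 1) cannot overflow; its a→±∞ convergence to Dmax/Dmin goes
like v_max^(1/a), i.e. ~5% at |a| = 50 for a 15-bin uniform DVH and <1% only
for |a| ≳ 500 — the tests check the limits at tolerances the mathematics
actually supports.  `a = 0` (geometric mean) is not implemented and raises.

Shipped parameters: α/β = 3 Gy for all normal tissues; OAR TD50/m/n are
classic Burman-style values; tumour TCD50 = 24.5 Gy (EQD2), γ50 = 1.5,
a = −10 are **non-clinical placeholders** — the table is user-editable JSON/
YAML and validated for completeness.  Spinal-cord NTCP is excluded by
default (the LKB model is a poor predictor of cord tolerance under
stereotactic fractionation) and can be re-enabled.  Probabilities below
1×10⁻⁶ are printed as "<1e-6" rather than 0.

## Statistics

The Wilcoxon signed-rank test drops zero differences (Wilcoxon's rule;
Pratt handling by flag), uses mid-ranks for ties, and computes the two-sided
p exactly — P(|W⁺ − μ| ≥ |w⁺ − μ|) by dynamic programming over the doubled
rank multiset — whenever the nonzero count is ≤15; beyond that a normal
approximation with tie and continuity correction applies.  Tests verify the
exact branch against full 2ⁿ sign-pattern enumeration to 1e-12, ties
included.  Spearman is Pearson on mid-ranks (scipy), cross-checked against
an independent rank-Pearson computation; Shapiro–Wilk records why the
nonparametric test is used.  Stars: * <0.05, ** <0.01, *** <0.001.  Raw
p-values are reported uncorrected (matching the presentation style this
pipeline mirrors) with a Benjamini–Hochberg column alongside.  MAD is the
mean absolute paired difference.  The report builder is deterministic:
identical inputs produce byte-identical CSVs.

## Problem sizes

Defaults are sized so the full suite runs on a single CPU in minutes: 88³
phantom grids, a 20-case default cohort, 20³ grids for gamma-vs-brute-force
equivalence, and 50 replicates for the planted-effect recovery check.  These
are the package's reference conditions; all are config-exposed upward.

## Known limitations

* The dose model is analytic (Gaussian falloff + smooth heterogeneity), not
  a beam/arc calculation: absolute DVH/TCP values are not clinical, only
  CT-vs-pCT *differences* under controlled perturbations are meaningful.
* The pCT deviation model (offset + smoothed floor + noise; scaled/shifted
  dose) does not emulate bone-specific HU errors, MRI distortion, or
  CNN-specific artefacts; passing tests show the pipeline measures known
  deviations correctly, not that any particular pCT generator is safe.
* Radiomics reproduces the reference definitions but no third-party
  implementation is bundled to cross-check against; oracles are closed
  forms and hand-enumerated matrices on toy grids.
* DICOM/DICOM-RT parsing, deformable registration and plan optimization are
  out of scope by design.
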