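# Methods

## Scoring model

The package scores coronary calcification volume in CT two ways on the same
segmentation substrate.

**Clinical volume score (C-CS).** Lesions are maximal 26-connected components
of voxels with intensity ≥ 130 HU; the score is the voxel count times the
voxel volume (dx·dy·dz, with dz the slice increment). No sub-voxel
information is used, so every boundary voxel counts fully — the origin of the
density-dependent bias the corrected score addresses.

**Partial-volume-corrected score (PVC-CS).** Per lesion:

1. *Extended segmentation.* Voxels above 90 HU and 26-connected to the
   initial mask are candidates (grown through other candidates, so the
   extension is connected to the lesion in 3D). Candidates farther than
   d₁ from the initial boundary are discarded, where d₁ = max of the interior
   distance transform of the initial mask. This bound keeps noise chains and
   streak artifacts from annexing distant bright voxels.
2. *Background shell.* All non-calcification voxels within d₂ of the
   calcification volume (initial ∪ extension), d₂ = max interior distance of
   the calcification mask. Voxels belonging to another lesion's calcification
   are excluded so neighbouring calcium cannot contaminate the background
   sample; d₂ may be smaller or larger than d₁ and neither is assumed.
   Both transforms are Euclidean with anisotropic voxel spacing; all
   distances are voxel-center-to-voxel-center in mm. (Distance in "voxels"
   is ill-defined on anisotropic grids, so mm is used throughout.)
3. *Mixture threshold.* A two-component univariate Gaussian mixture is fitted
   by EM to the pooled calcification + background intensities of that lesion
   only (thresholds are never shared across lesions). The lower-mean
   component is the background; the threshold is
   μ_B + FWHM_B/2 = μ_B + √(2 ln 2)·σ_B.
4. *Fraction and volume.* The scored set is the supra-threshold subset of the
   calcification mask. With X_min/X_max its minimum/maximum intensity,
   PVC_i = (X_i − X_min)/(X_max − X_min) ∈ [0, 1], and the volume is
   Σ PVC_i · voxel volume. The max-intensity voxel always scores 1.

Assumptions: lesions are bright relative to a locally homogeneous background;
intensity is approximately proportional to the calcium fraction of a voxel
(valid for blur/averaging image formation at fixed density); each lesion's
pooled histogram is adequately described by two Gaussians.

### Design choices where the procedure was open

- **X_min.** "Minimum intensity of the segmented lesion" is ambiguous when
  the lesion is restricted to supra-threshold voxels. Default: the minimum
  over the scored (supra-threshold) set, so X_min ≥ threshold by
  construction. `RunConfig.xmin_mode` exposes `literal_lesion_min` (minimum
  over the whole calcification mask) and `threshold` as alternatives; the
  choice shifts all fractions by a common rescaling and changes volumes by a
  few percent on simulated phantoms.
- **EM initialization.** Background component from the background-mask sample
  moments, foreground from the calcification-mask moments, weights
  proportional to voxel counts — informative and deterministic. The EM makes
  no hard use of the mask labels afterwards; extension voxels are simply part
  of the pooled sample.
- **Single-intensity lesions** (X_max = X_min) score fraction 1 per voxel:
  every such voxel exceeded the detection threshold, which is positive
  evidence of calcium; the case is logged and flagged in `LesionScore.status`.
- **Degenerate intensity pools** (all values identical) cannot support a
  mixture; the lesion is reported with `status = "degenerate_intensities"`
  and its corrected volume falls back to the clinical volume rather than
  aborting the scan.
- **Minimum lesion size** defaults to 1 voxel; `min_lesion_voxels` supports
  the ≥3-voxel convention of Agatston-style workflows.

### Numerics

EM runs in double precision with log-sum-exp likelihood evaluation,
tolerance 1e-6 on the log-likelihood gain, at most 200 iterations, and a
0.5 HU floor on component standard deviations (a floored fit is flagged
`degenerate`, not rejected). Distance comparisons use a 1e-9 mm tolerance on
the ≤ tests. Ties for the "center" voxel of a mask (arg-max of the interior
distance map) need no resolution: only the maximum distance enters the
procedure.

## Phantom simulator

The generator emulates two physical calcium-scoring phantoms at their
catalog geometry:

- nine cylinders — large 98.2 mm³ (⌀5 × 5 mm), medium 21.2 mm³ (⌀3 × 3 mm),
  small 0.8 mm³ (⌀1 × 1 mm), each at 800/400/200 mg/cm³ hydroxyapatite —
  coplanar in the transverse plane, axes along z, in a 35 HU soft-tissue
  background; extension rings emulating patient girth enter only as noise
  (10/15/20 HU for none/M/L) since they are geometrically irrelevant to the
  insert signal;
- three artificial arteries (one per density) in a 50 HU blood-equivalent
  background, each carrying three circular-segment inserts of radius 2 mm and
  length 10 mm with cap heights 2.0/1.0/0.5 mm (62.8/24.6/9.1 mm³), stacked
  along z and mutually rotated ±60° about the artery axis. The 2 mm radius is
  inferred: it reproduces all three nominal volumes exactly. Motion
  translates the phantom transversely at 0/10/30 mm/s.

Image formation is image-domain only: anti-aliased analytic rasterization on
a grid supersampled 8× per axis (exact fractional z coverage, one-pixel edge
ramps in-plane; occupancy sums match analytic volumes to <0.1%), affine
HA→HU calibration (1.6 HU per mg/cm³, so 200/400/800 mg/cm³ → 320/640/1280 HU
at 120 kVp-like contrast), transverse box blur of width velocity × 0.2 s for
motion (the effective temporal aperture of a half-scan reconstruction at
0.4 s gantry rotation), isotropic in-plane Gaussian PSF (σ 0.6 mm default),
block-averaging to the reconstruction grid (0.4 mm in-plane, 3 mm slices —
the partial-volume step), and i.i.d. Gaussian noise. Repeated acquisitions
reposition the phantom rigidly by seed-controlled sub-voxel offsets
(±0.2 mm in-plane, ±1.5 mm along z, ±2° about the scan axis), emulating
slight repositioning between physical repeat scans. Sharp/soft
reconstruction kernels are surrogated as (σ 0.35 mm, noise 18 HU) vs
(σ 0.9 mm, noise 7 HU) applied to one shared noiseless master raster, like
two reconstructions of one acquisition.

What the generator does **not** model: projection-domain physics (no
sinograms, filtered backprojection, beam hardening, streaks), spectral/
dual-energy effects, ECG-phase-dependent motion, heterogeneous lesion
composition, or anatomy around the inserts. Consequently, passing simulation
tests demonstrates the scoring pipeline's behaviour under controlled partial
volume, noise, repositioning and motion — not performance on patient data,
where artifact structure and manual lesion identification add variability.
One visible artifact of the narrow desk-scale PSF: the 0.8 mm³ insert at
800 mg/cm³ is sometimes detected in simulation, whereas it stays invisible on
the physical scanner.

## Evaluation machinery

Volume ratios (measured/true), median and range over repeated acquisitions,
min–max scaling of paired volumes by the maximum soft-kernel score of the
same method (per-method scaling; clinical and corrected scores live on
different absolute scales), Bland–Altman bias with 1.96·SD limits of
agreement (sample SD, differences soft − sharp), and ICC(2,1) — two-way
random-effects, absolute agreement, single measurement — with the F-based
95% CI (Satterthwaite degrees of freedom). ICC(2,1) is the appropriate
variant because paired reconstructions act as random "raters" of one
underlying volume and reproducibility requires absolute agreement, not mere
consistency.

## Observed behaviour on simulated phantoms and problem sizes

With five repositioned repeats per configuration (the physical protocol's
repeat count), the clinical score inflates 800 and 400 mg/cm³ large/medium
inserts by ~1.8–2.7× while the corrected score stays within ~25% of truth;
at 30 mm/s the low-density artery nearly vanishes under clinical scoring
while the corrected score retains roughly two thirds of its static value;
and across 50 paired sharp/soft reconstructions of randomized single-insert
phantoms the corrected score shows smaller scaled bias and higher ICC than
the clinical score.

One claimed advantage does **not** reproduce: *relative* interscan range
(range/median of totals over repeats). On the cylinder phantom the corrected
totals vary ~5× more in relative terms than clinical totals. Two mechanisms:
(i) the coplanar 5 mm and 3 mm cylinders straddle two vs three slices in
opposite phase as the z offset varies, so their clinical-score fluctuations
partially cancel in the total; (ii) the intensity rescaling is genuinely
alignment-sensitive for low-density inserts, whose boundary voxels drop
below the 90 HU extension threshold when split across slices. Any stability
advantage of the corrected score holds for absolute scatter — clinical
totals are 2–3× larger, so equal absolute spread means smaller relative
spread for the clinical score. The corresponding simulation test asserts the
relative-range property and is expected to fail; it is retained unmodified
as an honest negative result.

Problem sizes were chosen for desk-scale runtimes: 80×80×3-voxel cylinder
phantom (~2 s per acquisition), 80×90×15-voxel segment phantom (~6 s),
24×24×9 mm randomized phantoms for the 50 kernel pairs (~1 s per pair); the
full simulation-backed test suite runs in about three minutes on one CPU.
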