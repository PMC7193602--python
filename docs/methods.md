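# Methods

## Spectral model and fitting

The dissolved-phase free induction decay is modelled as a sum of three
complex Lorentzians,

    s(t) = Σₖ Aₖ exp(iφₖ) exp(i2πfₖt) exp(−πwₖt),

with amplitude Aₖ (arbitrary units), frequency offset fₖ (Hz, relative to
the dissolved-phase carrier at gas + 17.51 kHz), full width at half maximum
wₖ (Hz) and phase φₖ (degrees). Fitting is nonlinear least squares on the
complex time-domain samples, which keeps the noise Gaussian and avoids the
Rician bias and baseline sensitivity of magnitude-spectrum fits. The
complex amplitudes enter the model linearly, so we use variable projection:
the optimizer searches only over (fₖ, wₖ) and the amplitudes/phases are
solved in closed form at every step. This is markedly more robust than the
full 4K-parameter search, which can stall for narrow lines; the noiseless
recovery suite (amplitude ratios 0.1–10, widths 20–200 Hz) passes at 1e-6
relative with the projected formulation.

Initialisation peak-picks the magnitude spectrum, ranking candidates by
prominence rather than height because the broad dissolved lines (FWHM
≈ 640 Hz at T2* ≈ 0.5 ms) are two orders of magnitude lower in peak height
than the narrow gas line while carrying comparable area. Components are
labelled by chemical-shift ordering (RBC > barrier > gas) with guard bands
(RBC 205–218, barrier 190–202, gas ±5 ppm); out-of-band fits are flagged in
`label_warnings`, not silently relabelled. The first FID sample is used
as-is (no dead-time model): the generator produces none, and a receiver
dead time would be an acquisition-specific correction upstream of this
package.

## Dixon separation

With the spectroscopic target ratio ρ and the masked complex sum
M = |M|e^{iφM}, the applied global phase is ψ − φM with ψ = arctan ρ, which
makes Σimag/Σreal = ρ exactly with both channel sums positive (resolving
the π ambiguity physically: aggregate compartment signals are
non-negative). "Ratio of image intensities" is interpreted as the ratio of
masked channel sums — this makes the closed form exact and is what the
steady-state spectrum itself measures; the mask used for phasing is the
thoracic mask resampled to the dissolved grid. Per-voxel negative values
after splitting are retained (they are noise) but counted. A single global
phase is applied; no voxelwise B0/phase correction is attempted.

## Maps

* Segmentation: lungs are the largest sub-Otsu-threshold connected
  component not touching the volume border, hole-filled. An external mask
  bypasses segmentation verbatim. On phantoms the Dice against the
  generator mask exceeds 0.95.
* Registration: 6-parameter rigid (SimpleITK Euler3D, mean-squares metric,
  geometry-centred initialisation). Physical FOV metadata drives
  resampling, so the 2× FOV dissolved grid lands on the central half of the
  ventilation grid; trilinear interpolation, value-preserving for constant
  images.
* Signal correction: each volume is divided by sin α · exp(−TE/T2*) of its
  own acquisition (gas: 15°, gas T2*; dissolved: 20°, 0.5 ms). The paper
  names the corrections without printing the formula; this is the standard
  small-excitation steady-state form, and both divisors are logged in the
  result provenance.
* Ventilation normalisation: division by the masked 99th percentile
  (configurable) with clipping to [0, 1]. The percentile itself is not
  printed in the source protocol; 99 is the clinical convention. Values
  below zero (noise) clip to 0.
* Ratio maps divide the Dixon channels by the corrected, un-normalised gas
  image (normalisation affects only the displayed ventilation map); this
  choice is recorded in provenance. Non-positive gas voxels inside the mask
  are excluded and counted.

## Binning

Healthy voxels are pooled across animals ("aggregate histogram"; an
equal-animal-weight variant is available), non-positive voxels excluded
with a count, and the Box-Cox exponent λ estimated by profile likelihood in
[−3, 3]. Thresholds sit at μ_t + k·σ_t with k = (−2, −1, 0, +1, +2) for the
6-bin ventilation and RBC:gas maps and k = (−2, …, +4) for the 8-bin
barrier:gas map, then map back through the inverse transform. These
multiples reproduce the established clinical 6/8-bin convention the
protocol mirrors and are config-exposed. Bin assignment uses half-open
intervals [tₖ, tₖ₊₁) with boundary values going to the higher bin.

Metrics: VDP = % of thoracic voxels in ventilation bin 1 (computed on the
thorax mask, since defects must not be excluded from their own
denominator); low-ventilation cluster = bin 2; RBC_defect % = RBC:gas bin 1
on the analysis mask; barrier_high % = the top three (purple) barrier bins.
RBC_defect is bin 1 only (not bins 1–2); the alternative is a one-line
change via `BinnedMap.bin_pct`. A defect-free subject still shows a ~2.3%
bin-1 floor (Φ(−2)) by construction — the binning measures deviation from
the healthy reference, not absolute pathology.

## Phantom generator

The generator emulates the study conditions rather than arbitrary images:

* Geometry: a supine rat thorax on a 64³ grid over a 50 mm FOV (axis 0
  left–right, axis 1 anterior–posterior with anterior at low index, axis 2
  superior–inferior). Two ellipsoidal lungs joined by a retrocardiac
  bridge, an anterior heart notch, a trachea/bronchi tree, and a body
  ellipsoid giving proton air–tissue contrast.
* Signals: ventilation is a smooth positive field (mean 1.0, CV 0.10 via
  Gaussian-filtered noise, 3σ-clipped); barrier and RBC are the gas field
  modulated by independent smooth fields (CV 0.15) and rescaled so the
  thoracic totals satisfy barrier:gas = 0.010 and rbc:gas = 0.0047, i.e.
  RBC:barrier = 0.47, the healthy control value. The realised
  post-lesion Σrbc/Σbarrier is reported as `true_rbc_barrier`.
* Lesions grow as compact regions from a deep seed voxel of their zone
  (anterior ≈ lowest 40% of the anterior–posterior extent, posterior the
  converse, peripheral = shallow Euclidean depth) until the requested
  fraction of the lung is covered, spilling beyond the zone only if
  exhausted. RBC defects scale the RBC channel; ventilation defects scale
  all xenon channels (unventilated lung receives no xenon); edema raises
  proton signal and zeroes all xenon signal. Lesion multipliers and extents
  are not printed in the source study; defaults (defect multiplier 0.2,
  barrier elevation 2.5) were chosen once to land the cohort metrics in the
  published ranges and are config-exposed, not claimed as ground truth.
* Measurement: circularly symmetric complex Gaussian noise per channel
  (thermal MR noise model; magnitude images take |·|), a global dissolved
  phase (default 37°) composing `e^{iφ}(barrier + i·rbc)`, and the FID via
  the exact forward model above with dissolved FWHM = 1/(πT2*) ≈ 637 Hz.
  Default noise SDs (proton 0.02, ventilation 0.02, dissolved 5e-4, FID
  0.05) correspond to SNR ~20–50, typical of the modality.
* Cohorts: per-animal metrics are drawn truncated-normal (within physical
  ranges) from group mean/SD tables defaulting to the published control /
  MCT-wk1 / MCT-wk2 values; `config_for_animal` converts a draw into a
  phantom configuration, injecting each defect percentage in excess of the
  2.3% binning floor as a lesion of that size. Histology tables are
  concentric-circle vessels whose wall thickness matches the drawn value.

What the phantom does **not** emulate: radial k-space sampling and
regridding artifacts (images are generated in image space), motion and
susceptibility artifacts near the heart, receiver dead time, B0
inhomogeneity, and deformable anatomy differences between animals. Passing
tests therefore validate the numerical pipeline and its statistical
behaviour under the stated noise model, not robustness to those
acquisition physics.

## Acquisition arithmetic

Effective RF-induced T1 = −TR/ln cos α (0.2411 s at 20°/15 ms, commonly
quoted rounded as ~0.25 s). TE₉₀ = 1/(4Δf) gives 221.3 µs for the in vivo
shifts; the operationally calibrated value (248 ± 5 µs) also absorbs the
timing origin within the 310 µs excitation pulse, so the closed form is not
asserted against it and `AcqParams.te_us` defaults to 248. Scan times:
gated scans count ⌈rays/rays-per-breath-hold⌉ 1 s breath cycles
(250/250/500 ms phases, 60/min); non-gated imaging is rays × NEX × TR. The
sinc off-resonance response uses the small-tip-angle approximation
(Fourier transform of the truncated envelope); the in vivo ≤10% gas
contamination figure depends on the unknown gas:dissolved signal ratio and
is not asserted — only the attenuation property is tested.

## Statistics

Mann-Whitney U uses exhaustive enumeration of all C(n, n₁) labelings of the
mid-ranked pooled data for combined n ≤ 20 (the study's group sizes are
8/9), which remains exact under ties; two-sided P = min(1, 2·min(P≤, P≥)).
Larger samples fall back to the tie-corrected normal approximation with
continuity correction. Kruskal-Wallis is tie-corrected with a χ² P;
post-hoc pairwise tests run only when the omnibus P < α, and all-identical
data return H = 0, P = 1. No multiplicity correction is applied (α = 0.05,
two-sided), matching the study design. On synthetic cohorts at the study's
effect size (0.47 ± 0.03 vs 0.40 ± 0.06, n = 8 vs 9) the exact test rejects
in roughly three quarters of replicates — a power estimate that is
reported, not asserted against any single published P value.

## Morphometry

Radii from perimeters via r = P/2π; medial wall thickness as
(r_ext − r_int)/r_ext (fraction) or r_ext − r_int in µm (absolute, the
default for cohort-style tables, since published summary values are in µm
while the defining formula is a fraction — both modes are kept). The
20–80 µm vessel filter applies to the external diameter 2·r_ext
(switchable); samples with fewer than 5 surviving vessels are flagged and
excluded from group statistics.

## Problem sizes and determinism

Default grids are 64³ for single-subject work and 40³ for the replicated
cohort-direction study in the test suite; reference pools then hold
10⁴–10⁵ voxels, ample for threshold stability. All randomness flows through
`numpy.random.default_rng` seeds carried in configs or function arguments;
identical (config, seed) pairs produce byte-identical phantoms.

## Known limitations

* Only rigid registration is provided; rodent deformable registration is
  out of scope.
* Single-timepoint gas exchange: no multi-delay replenishment modelling
  (spatial resolution was deliberately preferred over temporal dynamics).
* The Box-Cox domain requires positive voxels; heavily noise-dominated
  ratio maps with many negative Dixon voxels shrink the usable pool (the
  excluded count is reported).
* Reference distributions built from cohorts that themselves contain
  baseline defects absorb part of that floor, lowering measured defect
  percentages relative to generator truth while preserving group ordering.
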