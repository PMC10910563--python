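# Methods

This note documents the models implemented in `dectsim`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and the
numerical choices that affect results.

## Signal model

A detected measurement through an object with transmission
`T(E) = exp(-Σ_j (μ/ρ)_j(E) A_j)` is modeled as an energy-weighted compound
Poisson process: each energy bin contributes an independent Poisson photon
count with mean `I(E) T(E) η(E)`, weighted by the detector response `D(E)`.
The energy-integrating detector uses `D(E) = E`; a counting response
(`D(E) = 1`) exists for analytic oracles because it makes the signal exactly
Poisson. All energy integrals are rectangle-rule bin sums on the spectrum's
own grid with attenuation curves interpolated log-log onto it —
deterministic, reproducible, and accurate for these smooth integrands at
the chosen bin widths (1 keV for kV spectra, 10 keV for MV spectra).

The CT simulator samples this law exactly (per-bin Poisson draws); the
estimation module replaces it by a Gaussian with the matched first two
moments, which is the standard approximation for Fisher-information
analysis of energy-integrating systems. The Gaussian Fisher matrix carries
both the mean-sensitivity term and the variance-sensitivity term; the
latter matters at low flux, which is exactly the regime of a dose-matched
MV beam.

## Materials

Packaged tables (water, ICRU soft tissue, ICRU cortical bone, PMMA,
titanium, stainless steel, aluminum, xenon) are transcribed from the
standard NIST/XCOM compilations on the standard NIST energy grid
(1 keV–10 MeV, ~34 knots). Log-log interpolation between knots reproduces
the near-power-law behavior of photon cross sections. Densities: tissue
1.00 g/cm³, bone 1.85 g/cm³ (the study's stated values), PMMA 1.19,
commercially pure titanium 4.51, surgical stainless steel 8.00 (standard
reference values; the steel curve uses iron, whose attenuation is within a
few percent of 316 steel over this range). Knots below 10 keV for bone and
xenon are smooth power-law fill-ins; K-edge fine structure is not modeled.
Sub-10 keV energies carry negligible fluence after filtration, so this
affects nothing downstream. A file-based loader accepts user tables in the
same two/three-column text dialect for exact-number work with externally
produced data.

## Spectra and dose normalization

The study's spectra are generated, not measured:

* **kV beams** use the Kramers thin-target bremsstrahlung shape
  `(kVp − E)/E` filtered through aluminum (default 2.5 mm, a typical
  diagnostic inherent-plus-added filtration). Characteristic tungsten lines
  are omitted; they move the mean energy by ~1 keV and none of the
  package's conclusions depend on them.
* **MV beams** use the same thin-target falloff to the endpoint, hardened
  by 12 cm of water-equivalent filtration standing in for the flattening
  filter and monitor chain. The treatment beam ends at 6 MeV (mean ≈ 1.27
  MeV); the detuned imaging beam ends at 2.5 MeV (mean ≈ 0.61 MeV), below
  the 3 MV bound that defines "detuned" mode.

Dose is scored at 20 cm depth in water (center of a 40 cm cylinder) under
charged-particle equilibrium, `Dose = Σ I(E) e^{−μ_w(E)·20} (μ_en/ρ)_w(E) E`,
converted to µGy. Every spectrum is rescaled to a 1 µGy line dose (Model 1)
or to `dose/n_views` per view (Model 2), making all comparisons
dose-matched by construction. Dose allocation multiplies the high-energy
spectrum by `r` and the low-energy one by `1 − r`; because the moments are
linear in fluence, a full 99-point allocation sweep costs two moment
evaluations.

## Detector

The default detector emulates a high-DQE pressurized-xenon fan-beam
detector: `η(E) = 1 − exp(−(μ/ρ)_Xe(E) · x_eff)` with the effective mass
thickness calibrated once so `η(1 MeV) = 0.20`, the quoted MeV-range
efficiency of such detectors. The exact efficiency curve of any real
detector differs in the diagnostic range; a tabulated `η(E)` file can
replace the absorber model. Electronic noise, pile-up, and flat-panel
(EPID) behavior are out of scope.

## Single-line model defaults

40 cm of tissue plus 1–10 cm of bone along one ray; total dose 1 µGy
(≈1 mGy over a ~1000-view scan); allocation grid 1%–99% in 1% steps with
grid-argmax peaks (ties to smaller `r`, no sub-grid refinement, matching
the sweep resolution). The 2×2 Fisher matrix is inverted in closed form; a
condition number above 1e12 flags the system as singular and reports
SNR = 0 with unbounded variance instead of raising, so sweeps never abort.

With the packaged spectra the model reproduces the expected structure:
tissue SNR peaks at `r ≈ 0.89` for detunedMV–80kV and `r ≈ 0.51` for
140kV–80kV at 1 cm bone, optimal `r` falls as bone thickens for both
pairs, and the tissue-SNR ordering between the pairs reverses at 8 cm of
bone. Absolute SNR values depend on the exact spectral shapes and
efficiency curve and should be read as representative, not calibrated.

## Phantoms

The pelvis is parametric: an elliptical body (34×23 cm) of ICRU tissue, an
elliptical cortical-bone ring, two 2.2 cm-radius femoral heads, and a
bladder-like soft-tissue inset at 1.04 g/cm³ (≈ +40 HU) that provides the
low-contrast CNR signal. The implant variant replaces one femoral head
with a metal head (r = 1.4 cm), PMMA lining (to 1.8 cm), and a metal
acetabular shell (to 2.2 cm) on the medial side; titanium and steel
variants share identical anatomy elsewhere, so CNR/RMSE comparisons are
paired. ROIs are two fixed 1.3 cm circles, one in the inset (signal) and
one in plain tissue away from the implant (background). Geometry constants
live in a single module-level dict; generation is deterministic.

What the phantom does *not* emulate: anatomical texture, partial-volume
pixels (one material per pixel, by construction matching the label-based
Siddon projector), organ heterogeneity, and 3-D structure. Passing tests
therefore demonstrate the physics of the contrast/noise/artifact tradeoffs,
not clinical task performance. The soft-tissue inset differs from its
background only in density, so its HU contrast is nearly energy-flat; CNR
versus VMI energy is then governed mostly by the noise term, and peak CNR
tends toward the upper end of the energy grid rather than the interior
peaks a compositional lesion would produce.

## CT geometry and projection

Equiangular fan-beam, 47° fan, full 360° rotation. The source-to-isocenter
distance defaults to `(FOV/2)/sin(fan/2) ≈ 62.7 cm` so the fan exactly
subtends the 50 cm FOV — a geometric consistency requirement that fixes
the one free distance the study conditions leave open. Per-material path
lengths come from an exact-radiological-path grid traversal
(Siddon/Amanatides–Woo, numba-compiled); the per-material sums equal the
chord length through the grid to machine precision. Noise is sampled
per energy bin per ray and is reproducible under a seed. The per-view dose
is the total CT dose divided uniformly over views (no bowtie, no tube
current modulation).

## Decomposition

Iteratively reweighted Gauss–Newton on the Gaussian-weighted misfit with
analytic Jacobians; weights `σ²_i(A)` recomputed each iteration.
Initialization is water-equivalent (tissue thickness from the low-energy
log signal, zero bone): cheap and robust for every case tried.
Convergence: relative step norm < 1e-8 or 50 iterations; steps are clipped
at 100 g/cm². Singular normal equations fall back to the water-equivalent
solution and flag the ray. Raw signals below a 0.1-detected-photon floor
are clipped and counted (photon starvation behind steel). Negative basis
thicknesses are allowed under noise — clipping would bias the VMIs.
Noiseless roundtrips recover mass thicknesses to better than 1e-4 g/cm².

## Reconstruction and beam-hardening correction

Equiangular FFBP with cosine pre-weighting, the `(γ/sin γ)²` equiangular
ramp-kernel modification, FFT-domain filtering apodized by a sinc window
cut at 80% of Nyquist (window order configurable; order 1 default), and
`1/L²`-weighted backprojection. A noiseless monoenergetic disk
reconstructs to the true μ within 0.1% centrally; residual Gibbs ringing
around high-contrast bone is what limits noiseless VMI accuracy (~10 HU
RMS in material interiors at full resolution, zero mean bias).

Single-energy images are corrected in two steps. The water step builds the
polychromatic log-signal versus water-thickness curve (0–50 cm) from the
spectral model and fits a 4th-degree polynomial onto monoenergetic line
integrals at the reference energy (the detected-fluence-weighted mean
energy — a defensible scalar summary the study conditions leave
unspecified); this removes ≥95% of cupping on a 40 cm water cylinder. The
bone step thresholds the corrected image at +300 HU, reprojects the
bone-equivalent density map, converts it through the residual
bone-vs-water hardening error into an artifact-only sinogram and image,
and subtracts a scaled copy with the scale chosen on a 21-point grid
(0–2) minimizing soft-tissue-band variance. Threshold and grid are exposed
as parameters; both are conventional defaults rather than fitted values.
On bone-free phantoms the bone step is an exact no-op.

## Metrics

CNR uses population variance over ROI pixels (Eq. statistics over one
image, not over repeats). VMI CNR and RMSE are evaluated on a 40–350 keV
grid (1 keV steps full scale, 5 keV reduced). RMSE is taken against the
monoenergetic ground-truth HU map inside the body outline eroded by
3 pixels. Noiseless basis images give near-zero ROI variance, so CNR is
reported as an infinity flag in the degenerate case.

## Problem sizes

Full scale follows the study conditions: 512² phantom at 1 mm pixels,
1200×800 sinograms, 1 keV VMI grid. The reduced configuration
(`scale="test"`: 256² raster at ~2 mm, 360×256 sinograms, 5 keV VMI grid)
is the package's standard regression size; it preserves every qualitative
ordering (steel: MV-kV > kV-kV in CNR and RMSE; no implant: kV-kV > MV-kV
in CNR) across the seeds tried, while a full Model-2 variant runs in
minutes instead of hours. Reported absolute CNR/RMSE values scale with
geometry and should only be compared within a configuration.

## Known limitations

No scatter (single-source or cross-scatter), no motion, no electronic
noise, no bowtie or tube-current modulation, no cone-beam geometry, no
iterative or learned reconstruction, two-material basis only. The spectra
and efficiency curve are generator-based stand-ins with the correct
endpoints, dose normalization, and MeV-range efficiency; exact numerical
agreement with any specific published table requires loading that table
through the file interfaces.
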