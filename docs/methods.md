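# Methods

This note documents the optical model, the numerical choices and the
design decisions behind `refractsim`, in the spirit of a model-description
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Wavefronts and conventions

**Zernike basis.** Coefficients use the OSA/ANSI single-index ordering
with orthonormal normalization (`N_n^m = √(2(n+1)/(1+δ_m0))`), so the
total RMS wavefront error is the Euclidean norm of the coefficient
vector, in μm, bound to a pupil radius in mm. Piston and tilts are
accepted in files but dropped by image formation (piston is invisible;
tilt only translates the image).

**Refraction ↔ wavefront.** Prescriptions are minus-cylinder
`(S, C × α)`, TABO axis in (0°, 180°] (the horizontal axis is written 180,
as on a phoropter dial). Power vectors are `M = S + C/2`,
`J0 = −(C/2)cos 2α`, `J45 = −(C/2)sin 2α`; they add under thin-lens
stacking. The wavefront of an eye whose manifest refraction is
`(M, J0, J45)` has second-order coefficients

    c(2,0)  = −M  R²/(4√3),   c(2,2) = −J0 R²/(2√6),   c(2,−2) = −J45 R²/(2√6),

the standard aberrometric convention (a myope has positive defocus
coefficient). For this to be self-consistent with image formation, a
*physical* thin lens of power vector `(M, J0, J45)` placed at the pupil
must contribute the opposite-signed quadratic,

    W_lens(x, y) = +½ [ M (x²+y²) + J0 (x²−y²) + 2 J45 x y ]   (μm; x, y in mm),

so that a lens equal to the eye's manifest refraction nulls the
second-order wavefront exactly. This pair of signs is the package's fixed
convention; either global sign flip would reproduce the same images.

**Pupil rescaling.** When the entrance pupil is set smaller than the
measurement pupil, coefficients are rescaled analytically: within each
azimuthal group the radial polynomials satisfy
`R_n'(ερ) = Σ_n b_nn'(ε) R_n(ρ)` with
`b_nn'(ε) = 2(n+1) ∫₀¹ R_n'(ερ) R_n(ρ) ρ dρ`, evaluated exactly through
the monomial coefficients; the orthonormal normalization contributes
`√((n'+1)/(n+1))`. The transform is triangular in radial order (energy
only flows downward). Up-scaling is refused — it would extrapolate the
measurement. A dense least-squares refit of the same wavefront on the
smaller pupil serves as the independent oracle in the tests (agreement
below 10⁻⁸ μm).

## The optical scene

The reduced schematic eye (focal length 22.4 mm, index 1.33) fixes the
angular scale; all imagery lives in visual-angle coordinates (arcmin) and
conversion to retinal μm is a reporting utility. The design wavelength is
587 nm, monochromatic.

Phoropter lenses are thin sphero-cylinders at a common vertex distance
`d_v` (default 15 mm: a 12 mm spectacle vertex plus 3 mm cornea-to-pupil;
the automated sessions default to `d_v = 0` so that recovered corrections
are directly comparable to the eye's refraction). Each lens is
vertex-transposed per principal meridian, `F' = F/(1 − d_v F)`, then its
quadratic phase is added; the stack is transposed lens by lens.

The Jackson Cross Cylinder of power ±P is the sphero-cylinder
`S = +P, C = −2P` at its current minus-cylinder axis; its spherical
equivalent is exactly zero, flipping rotates the minus axis by 90° and
negates `(J0, J45)`, and an inactive JCC contributes a zero map (the
Heaviside gate in the total-phase sum).

Concentric-ring multifocal contact lenses are piecewise defocus phases
(`+½·add·r²` per annulus) in the pupil plane — no transposition and no
magnification, since the lens rides on the cornea and covers the pupil.
The two built-in designs bracket the centre-near concept: CL1 with rings
near (+2 D, 0–1.5 mm), intermediate (+1 D, 1.5–2.25 mm), distance (0 D,
2.25–3 mm); CL2 with near/distance/near (+2, 0, +2 D) on the same radii
and no intermediate zone. The ring radii are a design choice (the concept
figures in the source literature are schematic); both are fully
configurable.

## Image formation

The pupil patch is sampled with `n_pupil` points across the diameter
(default 256) and zero-padded by `pad_factor` (default 4), giving a PSF
pixel scale `Δθ = λ/(pad·2R)` rad — e.g. 0.126 arcmin at R = 2 mm. FFT
centering uses ifftshift/fftshift pairs with the grid origin at index
`n/2`, so the zero-phase PSF peaks exactly on the centre pixel; a custom
"same"-mode crop about that pixel makes a delta-function chart reproduce
the PSF bit-exactly. PSFs are normalized to unit sum, so convolution
conserves flux (checked to 10⁻⁶ in full mode). Doubling the padding
changes Strehl/VS by < 1%, which is the convergence guard for the
sampling choices; a direct O(N⁴) Fourier summation on a 32-sample pupil
is the small-instance oracle for the FFT path.

Anamorphic spectacle magnification is applied to the paraxial chart
before convolution as a rotate–scale–rotate affine with bilinear
resampling, using the principal-meridian SMs of the combined phoropter
power (the stack is summed in power-vector space first; for thin lenses
at one vertex this equals the per-lens product to first order).

Charts are "emission" rasters (ink bright on black) built from a 5×5
Sloan-style bitmap font — no system fonts, bit-reproducible. Letter
height is `5·10^logMAR` arcmin with 1/5-height strokes; the clock dial is
a 250-arcmin disc with twelve 5-arcmin-wide spokes at 30° spacing; the
dot pattern is a 5×5 grid of 2-arcmin dots spanning 50 arcmin. Stroke
and dot geometry beyond the stated angular extents are package defaults,
configurable per chart.

## Metrics

**Visual Strehl (VSOTF).** `VS = ∫CSF·Re(OTF) / ∫CSF·Re(OTF_DL)` with
the OTF from the unit-sum PSF and the diffraction-limited reference on
the same grid. The neural contrast-sensitivity weight is a log-parabola
(log-Gaussian in log₂ frequency) peaking at 4 cpd with a 1.43-octave
width, truncated at 60 cpd and zero at DC. The specific CSF shape is a
design choice (several published forms exist); VS(zero phase) = 1 by
construction and the qualitative orderings used by the procedures are
insensitive to the exact peak. Note that VS converges onto the Maréchal
approximation `exp[−(2πσ/λ)²]` only for very small aberrations
(σ ≲ λ/50): at larger defocus the CSF discounts exactly the high spatial
frequencies defocus destroys first, so VS sits above the raw Strehl
ratio (which itself tracks Maréchal to 2 % up to λ/14, as tested).

**Dial sharpness.** Each spoke is scored by the mean transverse gradient
magnitude in an annular region of interest (0.35–0.95 of the dial radius,
±7.5 arcmin across the spoke). The sharpest *orientation* is estimated by
a circular mean of the doubled spoke angles weighted by squared excess
score — the numerical analogue of the clinical "if two lines are equally
sharp the axis lies between them" — and the equality end point is the
minimum of the relative spread (std/mean) of the twelve scores.

**Image-pair similarity.** Zero-mean normalized cross-correlation,
clipped to [0, 1]. A useful exact property: at the correct cylinder with
the circle of least confusion (CLC) on the retina, the two JCC flips
produce transposed wavefronts whose PSFs are identical (the pure
crossed-cylinder PSF is separable with equal factors), so the flip pair
similarity is exactly 1; any residual spherical error breaks the symmetry
and the similarity collapses. This is what makes the end point
identifiable only when the CLC is controlled.

**Visual acuity.** An automated tumbling-E observer: at each 0.1-logMAR
chart level the rendered E is matched (NCC) against the four
diffraction-limited orientation templates; the level is "read" when the
true orientation wins by a margin δ. The chart is read top-down (large to
small) and the estimate is the smallest size with an unbroken run of
successes, which makes VA monotone in letter size by construction and
immune to isolated spurious-resolution matches under heavy defocus.
δ defaults to 0.05: the margin is the surrogate's sensitivity knob, and
this value keeps VA monotone in blur over 0–3 D on an aberration-free
eye (a 0.02 margin lets low-frequency cues "identify" unresolvable
letters). VA is a surrogate for ranking corrections, not a reproduction
of any published psychophysical acuity computation.

## Procedures

All patient judgements are replaced by deterministic surrogates: "which
flip is better" = higher VS; "flips equal" = VS difference ≤ 2·10⁻³;
"can you read it" = tumbling-E identification. Powers move in 0.25 D
quanta and axes in 10°-then-5° steps, mirroring clinical practice.

- **Fogging** adds +0.25 D steps until VA ≥ 0.50 logMAR *on the myopic
  side* of best focus (a probe step of extra plus must worsen VS — this
  distinguishes genuine fog from hyperopic blur). The full pipeline fogs
  by at least +1.25 D over its objective starting sphere so that both
  focal lines of cylinders up to −2 D sit in front of the retina; without
  that margin the dial's sharpest-line rule can pick the wrong meridian.
- **Clock dial**: sharpest-orientation → minus-cylinder axis by the rule
  of 30 (axis = orientation + 90°, snapped to the 5° clinical grid), then
  −0.25 D cylinder steps (with +0.25 D sphere per −0.50 D to keep the fog
  constant) until the spoke-score spread is minimized. A starting spread
  below 0.05 is reported as "no astigmatism".
- **JCC axis search**: the cross cylinder straddles the trial axis at
  ±45°; the axis rotates toward the preferred flip's minus cylinder,
  10° steps narrowing to 5°, terminating on flip equality or oscillation
  (then splitting the final step). The comparison is only meaningful with
  the CLC near the retina, so the pipeline re-seats the sphere (best-VS
  scan with the cylinder in place) between the dial and the JCC.
- **JCC power search**: the cross cylinder aligns with the trial axis
  (reinforce) or perpendicular (oppose); the cylinder moves one quantum
  toward the preferred flip. With CLC maintenance the sphere gains
  +0.25 D per accumulated −0.50 D of cylinder, which conserves the
  spherical equivalent exactly after every whole half-diopter pair — the
  0.25 D quantization leaves at most a 0.125 D transient in between. An
  A→B→A oscillation terminates at the better (by VS) of the two
  bracketing cylinders, flagged "bracketed".
- **Sphere refinement**: maximum plus to best VA — scan ±1.5 D in
  0.25 D steps, keep the most-plus sphere within one chart line
  (0.1 logMAR) of the best acuity found.
- **Full pipeline**: objective starting sphere (best-VS scan, the stand-in
  for an autorefractor) → fog → dial → re-seat sphere → JCC axis → JCC
  power (CLC maintained) → sphere refinement.

## Synthetic eyes

The fixture generator emulates the two subject archetypes the simulator
is exercised on, not real measured eyes:

- `P1_like`: second-order terms only, manifest refraction plano
  −0.75 × 180 — an eye whose fogged dial shows a clearly sharpest
  vertical line.
- `P2_like`: seeded Gaussian coefficients over radial orders 3–6 rescaled
  so RMS(orders ≥ 3) is exactly 1.44 μm, plus a mixed second-order
  component (−0.50 −1.00 × 45) for irregular astigmatism. The individual
  higher-order coefficients are synthetic; only the RMS summary is
  meaningful, and `load_s1_table` exists for supplying a real measured
  table instead.
- `custom`: a second-order eye from any prescription — the workhorse of
  the parameter-recovery battery.

What passing tests show, and what they do not: recovery of seeded
low-order eyes demonstrates that the engine plus automated observers is
self-consistent end to end (render → judge → converge to the generating
prescription). It does not demonstrate performance on real aberrated
eyes — higher-order aberrations make the Sturm interval asymmetric, the
dial equality ambiguous and the JCC end point pupil-size dependent, which
is precisely the regime the simulator is built to explore interactively.

## Problem sizes and determinism

Interactive/default grids are 256 pupil samples with 4× padding; the
automated sessions use 128 samples (their metrics change by < 1% under
grid doubling, per the convergence test). The recovery battery runs 20
eyes with prescriptions on clinical quanta (0.25 D, 5° axes, |S| ≤ 3 D,
|C| ≤ 2 D) at a 2.5 mm pupil radius; axis agreement is scored only when
|C| > 0.25 D, since the axis of a near-zero cylinder is clinically
indeterminate. All randomness flows through explicit seeds; the optics
contain no hidden RNG, so identical scenes render bit-identical images.

## Known limitations

Monochromatic, on-axis, thin-lens optics; no chromatic aberration,
accommodation, pupil dynamics, Stiles–Crawford apodization, photon noise,
cone-mosaic sampling or neural processing. The acuity and preference
surrogates are deliberate simplifications of human judgement; absolute VA
values should not be compared against clinical measurements, only used to
rank corrections within the simulator.
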