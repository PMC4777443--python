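# refractsim

Retinal-image simulation of subjective refraction.

`refractsim` computes the retinal image formed by an aberrated human eye
viewed through a virtual phoropter, a Jackson Cross Cylinder (JCC) and/or a
multifocal contact lens, and drives the classical subjective-refraction
procedures — fogging, the astigmatic clock dial, JCC axis and power
refinement, final sphere adjustment — as automated state machines on top of
that imaging engine. It is written for visual-optics researchers,
optometry educators and lens designers who want to *see* what a patient
sees at every step of a refraction, and to evaluate corrections (including
concentric-ring multifocal designs) with objective image-quality metrics.

## The model

A reduced schematic eye (focal length 22.4 mm, refractive index 1.33,
monochromatic λ = 587 nm) carries the subject's aberrometry as OSA-indexed
Zernike coefficients `c_j` (μm) over a measurement pupil of radius `R`
(mm). The total pupil-plane phase is

    W_T(x, y) = W_eye(x, y) + Σ W_lens(x, y) + S · W_JCC(x, y) [+ W_CL(x, y)]

where `W_eye = Σ c_j Z_j(ρ, θ)` (orthonormal Zernike polynomials, with
analytic coefficient rescaling when the entrance pupil is smaller than the
measurement pupil), each phoropter lens is a thin sphero-cylinder
vertex-transposed to the pupil plane per principal meridian
(`F' = F / (1 − d_v F)`), `S ∈ {0, 1}` gates the cross cylinder, and a
contact lens contributes a piecewise-quadratic phase per concentric zone.
The point-spread function is the intensity of the Fourier transform of the
complex pupil function,

    PSF = |ℱ( p(x, y) · e^(−i 2π W_T / λ) )|²,

and the retinal image is the convolution of the PSF with the paraxial
optotype after anamorphic spectacle magnification `SM = 1 / (1 − d_v F)`
per principal meridian. Image quality is summarized by the Visual Strehl
ratio (VSOTF): the CSF-weighted volume of `Re(OTF)` relative to the
diffraction-limited system on the same pupil. Refraction end points
("which image is better", "are the two flips equal", "can you read this
line") are decided by objective surrogates: VS comparison, normalized
cross-correlation of image pairs, and tumbling-E template identification.

Prescriptions use minus-cylinder notation `(S, C × α)` with TABO axes in
(0°, 180°], and the power-vector form `M = S + C/2`,
`J0 = −(C/2)·cos 2α`, `J45 = −(C/2)·sin 2α`. The wavefront convention is
the standard aberrometric one, `M = −4√3·c(2,0)/R²` — a myopic eye has a
positive defocus coefficient.

## Worked example

```python
from refractsim import SchematicEye
from refractsim.fixtures import make_eye
from refractsim.procedures import RefractionSession, clock_dial_procedure, fog

eye = SchematicEye(make_eye("P1_like", pupil_radius_mm=2.0), pupil_radius_mm=2.0)
session = RefractionSession(eye)
fog(session, target_logmar=0.50, min_added_d=1.25)
axis, cylinder = clock_dial_procedure(session)
print(f"{cylinder:+.2f} D x {axis:.0f}")
```

prints

```
-0.75 D x 180
```

The fixture eye has a pure −0.75 D astigmatism at axis 180. After fogging
(+1.25 D of plus sphere, so both focal lines sit in front of the retina)
the rendered clock dial shows the vertical spoke sharpest; by the rule of
30 the minus-cylinder axis is 90° away (180°), and stepping the cylinder
in −0.25 D increments until the twelve spoke-sharpness scores are most
nearly equal terminates exactly at the eye's astigmatism.

The `examples/` directory holds one short script per capability:

- `retinal_image_pipeline.py` — phase → PSF → retinal letter line (PNG out)
- `clock_dial_refraction.py` — the example above, with the fog log
- `jcc_full_refraction.py` — complete automated refraction vs ground truth
- `multifocal_defocus_curves.py` — CL1/CL2 through-focus VS curves (CSV out)
- `clc_position_effect.py` — why the circle of least confusion must stay
  on the retina during the JCC test

A thin CLI mirrors these entry points
(`refractsim simulate|clock-dial|session|defocus-curve|make-eye`).

## Limitations

Monochromatic optics only; no chromatic aberration, pupil dynamics,
accommodation, cone-mosaic sampling or neural-noise modelling; thin-lens
phoropter, centred optics, on-axis imagery. See `docs/methods.md` for the
full model description and design rationale.
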