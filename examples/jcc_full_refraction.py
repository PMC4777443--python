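"""Full automated subjective refraction of a random low-order eye.

Runs the complete routine — objective starting sphere, fogging, clock
dial, Jackson Cross Cylinder axis and power refinement with the circle of
least confusion held on the retina, final sphere adjustment — and compares
the result with the known ground-truth prescription.
"""

from refractsim import SchematicEye, SpheroCylinder
from refractsim.fixtures import make_eye
from refractsim.powers import axis_difference_deg
from refractsim.procedures import RefractionSession, run_full_refraction

truth = SpheroCylinder(-1.25, -1.00, 70.0)
eye = SchematicEye(
    make_eye("custom", refraction=truth, pupil_radius_mm=2.5)
)
session = RefractionSession(eye)
result = run_full_refraction(session, maintain_clc=True)

print(f"true refraction      : {truth}")
print(f"recovered refraction : {result}")
print(f"errors: sphere {result.sphere - truth.sphere:+.2f} D, "
      f"cylinder {result.cylinder - truth.cylinder:+.2f} D, "
      f"axis {axis_difference_deg(result.axis, truth.axis):.1f} deg")
print("steps taken:")
for step in session.history:
    if step.name in ("initial_sphere", "clock_dial_end", "jcc_axis_end",
                     "jcc_power_end", "refine_sphere", "final"):
        print(f"  {step.name:16s} trial = {step.trial}")
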