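"""Automated clock-dial astigmatism search.

Fogs an astigmatic eye, renders the 250-arcmin dial, finds the sharpest
spoke and adds minus cylinder until all twelve radii are equally clear.
"""

from refractsim import SchematicEye
from refractsim.fixtures import make_eye
from refractsim.procedures import RefractionSession, clock_dial_procedure, fog

eye = SchematicEye(
    make_eye("P1_like", pupil_radius_mm=2.0), pupil_radius_mm=2.0
)
session = RefractionSession(eye)
fog(session, target_logmar=0.50, min_added_d=1.25)
print(f"fogged to {session.trial} "
      "(plus sphere until both focal lines sit in front of the retina)")

axis, cylinder = clock_dial_procedure(session)
start = next(s for s in session.history if s.name == "clock_dial_start")
print(f"sharpest spoke at {start.info['sharpest']:.0f} deg -> "
      f"minus-cylinder axis {axis:.0f} deg (rule of 30)")
print(f"end point: {cylinder:+.2f} D x {axis:.0f} — the cylinder that "
      "makes all twelve radii equally sharp, i.e. the eye's astigmatism")
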