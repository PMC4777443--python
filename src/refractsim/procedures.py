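"""Automated subjective-refraction workflows.

Each clinical procedure is a scripted state machine driven by the rendering
engine, with the patient's judgement replaced by objective surrogates:

* "which image is better"  -> higher Visual Strehl of the two candidates;
* "are the two flips equal" -> normalized cross-correlation of the two
  rendered images above an equality threshold;
* "can you read this line"  -> tumbling-E template identification.

The session's trial correction is a single sphero-cylinder in the virtual
phoropter.  During JCC power refinement the circle of least confusion (CLC)
can be held on the retina by the classical bookkeeping rule: +0.25 D of
sphere for every accumulated -0.50 D of cylinder, which conserves the
spherical equivalent of the trial correction exactly in 0.25 D quanta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .eye_lenses import JCCState, MultifocalDesign, PhoropterState, SchematicEye
from .metrics import (
    TAU_EQUALITY,
    DialSharpness,
    dial_line_sharpness,
    estimate_va,
    identifies_e,
    image_pair_similarity,
    scene_visual_strehl,
)
from .optotypes import make_clock_dial, make_dot_pattern
from .powers import SpheroCylinder
from .scene import Scene

STEP_D = 0.25                  # clinical power quantum, D
AXIS_STEPS_DEG = (10.0, 5.0)   # coarse then fine JCC axis rotation
DIAL_EQUALITY_SPREAD = 0.05    # relative spread below which spokes are equal
VS_EQUALITY_TOL = 2e-3         # VS difference treated as "flips equal"


@dataclass
class SessionStep:
    name: str
    trial: SpheroCylinder
    info: dict = field(default_factory=dict)


@dataclass
class RefractionSession:
    """State of one automated refraction: eye, trial lens, history.

    The history is append-only; every logged step records the trial lens
    and the scalar metrics that drove the decision, so any rendered image
    can be regenerated bit-exactly from the logged scene parameters.
    """

    eye: SchematicEye
    trial: SpheroCylinder = SpheroCylinder()
    vertex_distance_m: float = 0.0
    jcc_power: float = 0.50
    contact_lens: MultifocalDesign | None = None
    n_pupil: int = 128
    pad_factor: int = 4
    history: list[SessionStep] = field(default_factory=list)

    def scene(self, jcc: JCCState | None = None) -> Scene:
        return Scene(
            eye=self.eye,
            phoropter=PhoropterState(
                (self.trial,), self.vertex_distance_m
            ),
            jcc=jcc,
            contact_lens=self.contact_lens,
            n_pupil=self.n_pupil,
            pad_factor=self.pad_factor,
        )

    def log(self, name: str, **info) -> None:
        self.history.append(SessionStep(name, self.trial, info))

    def set_trial(self, trial: SpheroCylinder) -> None:
        self.trial = trial.canonical()

    def vs(self, jcc: JCCState | None = None) -> float:
        return scene_visual_strehl(self.scene(jcc))


# ---------------------------------------------------------------------------
# fogging


def fog(
    session: RefractionSession,
    target_logmar: float = 0.50,
    max_added_d: float = 6.0,
    min_added_d: float = 0.0,
) -> RefractionSession:
    """Add plus sphere in +0.25 D steps until acuity is degraded to the
    fogging target *on the myopic side* of best focus (so that further plus
    only blurs more).  Raises if the target is unreachable within +6 D.

    ``min_added_d`` forces at least that much plus regardless of acuity;
    the full automated routine uses it (relative to the objective starting
    sphere) to guarantee that both astigmatic focal lines sit in front of
    the retina before the clock dial is read."""
    added = 0.0
    while True:
        scene = session.scene()
        va_reached = not identifies_e(scene, target_logmar - 0.1)
        vs_now = scene_visual_strehl(scene)
        probe = replace(
            session, trial=session.trial + SpheroCylinder(STEP_D)
        )
        myopic_side = probe.vs() < vs_now
        session.log(
            "fog", added_d=added, va_reached=va_reached,
            myopic_side=myopic_side, vs=vs_now,
        )
        if va_reached and myopic_side and added >= min_added_d - 1e-9:
            return session
        if added >= max_added_d:
            raise RuntimeError(
                "fogging target not reached within +6.00 D of added sphere"
            )
        session.set_trial(session.trial + SpheroCylinder(STEP_D))
        added += STEP_D


# ---------------------------------------------------------------------------
# clock dial


def clock_dial_procedure(
    session: RefractionSession,
    max_cylinder_d: float = -4.0,
    equality_spread: float = DIAL_EQUALITY_SPREAD,
    dial_bin_factor: int = 2,
) -> tuple[float, float]:
    """Astigmatism search on the clock-dial chart.

    Renders the dial, finds the sharpest spoke, converts its orientation to
    the minus-cylinder axis (rule of 30: axis = orientation + 90), then adds
    minus cylinder at that axis in 0.25 D steps until the 12 spoke-sharpness
    scores are most nearly equal.  Returns (axis_deg, cylinder_D) and leaves
    the winning cylinder in the trial."""
    if not any(s.name == "fog" for s in session.history):
        import warnings

        warnings.warn("clock dial run without prior fogging", stacklevel=2)
    chart = make_clock_dial(
        pixel_scale_arcmin=session.scene().psf_binned(dial_bin_factor)
        .pixel_scale_arcmin
    )

    def spread_at(trial: SpheroCylinder) -> DialSharpness:
        probe = replace(session, trial=trial)
        img = probe.scene().render(chart, bin_factor=dial_bin_factor)
        return dial_line_sharpness(img, chart)

    base = spread_at(session.trial)
    session.log(
        "clock_dial_start",
        spread=base.relative_spread,
        sharpest=base.sharpest_orientation,
        scores=base.scores,
    )
    if base.relative_spread < equality_spread:
        session.log("clock_dial_end", axis=0.0, cylinder=0.0)
        return 0.0, 0.0
    # rule of 30, interpolated: the score-weighted sharpest orientation
    # maps to the minus-cylinder axis 90 degrees away, snapped to the 5
    # degree clinical grid
    axis = round((base.weighted_orientation + 90.0) / 5.0) * 5.0 % 180.0
    start = session.trial
    best_c, best_spread = 0.0, base.relative_spread
    c = 0.0
    rising = 0
    while c > max_cylinder_d:
        c = round(c - STEP_D, 4)
        # +0.25 D sphere per -0.50 D cylinder keeps the fog constant
        s = start.sphere + STEP_D * np.floor(-c / 0.5 + 1e-9)
        d = spread_at(SpheroCylinder(s, c, axis).canonical())
        session.log(
            "clock_dial_step", cylinder=c, spread=d.relative_spread,
        )
        if d.relative_spread < best_spread:
            best_spread, best_c = d.relative_spread, c
            rising = 0
        else:
            rising += 1
            if rising >= 2:
                break
    s = start.sphere + STEP_D * np.floor(-best_c / 0.5 + 1e-9)
    session.set_trial(
        SpheroCylinder(s, best_c, axis if best_c else 0.0)
    )
    axis_out = session.trial.axis
    session.log("clock_dial_end", axis=axis_out, cylinder=best_c)
    return axis_out, best_c


# ---------------------------------------------------------------------------
# Jackson Cross Cylinder


def _flip_pair(session: RefractionSession, jcc: JCCState):
    """(VS with the JCC as placed, VS with it flipped)."""
    return session.vs(jcc), session.vs(jcc.flip())


def flip_pair_similarity(
    session: RefractionSession, jcc: JCCState, bin_factor: int = 2
) -> float:
    """Similarity of the two rendered flip images on a dot-pattern chart."""
    scene_a = session.scene(jcc)
    scene_b = session.scene(jcc.flip())
    chart = make_dot_pattern(
        pixel_scale_arcmin=scene_a.psf_binned(bin_factor).pixel_scale_arcmin
    )
    img_a = scene_a.render(chart, bin_factor=bin_factor)
    img_b = scene_b.render(chart, bin_factor=bin_factor)
    return image_pair_similarity(img_a, img_b)


def jcc_axis_step(
    session: RefractionSession, step_deg: float
) -> tuple[RefractionSession, int]:
    """One axis-refinement comparison.

    The JCC is placed with its principal meridians straddling the trial
    axis at +/-45 degrees; the trial cylinder axis rotates toward the minus
    cylinder of the preferred flip.  Returns the session and the decision
    (-1, 0, +1; 0 means the flips were judged equal)."""
    a = session.trial.axis
    jcc = JCCState(
        session.jcc_power, (a + 45.0) % 180.0, mode="axis-search"
    )
    vs_plus, vs_minus = _flip_pair(session, jcc)
    if abs(vs_plus - vs_minus) <= VS_EQUALITY_TOL:
        decision = 0
    else:
        decision = 1 if vs_plus > vs_minus else -1
    if decision:
        new_axis = (a + decision * step_deg) % 180.0
        session.set_trial(
            SpheroCylinder(
                session.trial.sphere, session.trial.cylinder, new_axis
            )
        )
    session.log(
        "jcc_axis_step", step=step_deg, decision=decision,
        vs_plus=vs_plus, vs_minus=vs_minus,
    )
    return session, decision


def jcc_axis_search(
    session: RefractionSession,
    steps_deg: tuple[float, ...] = AXIS_STEPS_DEG,
    max_iter: int = 36,
) -> RefractionSession:
    """Iterate axis steps with coarse-to-fine rotation until the two flips
    are equal or the finest step starts oscillating."""
    if session.trial.cylinder == 0:
        session.log("jcc_axis_search", note="no cylinder in trial; skipped")
        return session
    level = 0
    last_decision = 0
    for _ in range(max_iter):
        session, decision = jcc_axis_step(session, steps_deg[level])
        if decision == 0:
            break
        if last_decision and decision != last_decision:
            if level + 1 < len(steps_deg):
                level += 1
            else:
                # oscillating at the finest step: split back half a step
                half = steps_deg[-1] / 2.0
                session.set_trial(
                    SpheroCylinder(
                        session.trial.sphere,
                        session.trial.cylinder,
                        (session.trial.axis - decision * half) % 180.0,
                    )
                )
                break
        last_decision = decision
    session.log("jcc_axis_end", axis=session.trial.axis)
    return session


def jcc_power_step(
    session: RefractionSession,
    maintain_clc: bool = True,
    state: dict | None = None,
) -> tuple[RefractionSession, int]:
    """One power-refinement comparison.

    The JCC minus axis is aligned with the trial axis (calling for more
    minus cylinder) or perpendicular to it (calling for less); the trial
    cylinder moves one 0.25 D quantum toward the preferred flip.  With
    ``maintain_clc`` the sphere is compensated +0.25 D per accumulated
    -0.50 D of cylinder so the spherical equivalent is conserved."""
    if state is None:
        state = {"sphere0": session.trial.sphere, "cyl0": session.trial.cylinder}
    a = session.trial.axis
    jcc = JCCState(session.jcc_power, a, mode="power-search")
    vs_more, vs_less = _flip_pair(session, jcc)
    if abs(vs_more - vs_less) <= VS_EQUALITY_TOL:
        decision = 0
    else:
        decision = 1 if vs_more > vs_less else -1
    if decision:
        new_c = round(session.trial.cylinder - decision * STEP_D, 4)
        new_c = min(new_c, 0.0)
        new_s = session.trial.sphere
        if maintain_clc:
            delta = state["cyl0"] - new_c
            new_s = state["sphere0"] + STEP_D * np.floor(delta / 0.5 + 1e-9)
        session.set_trial(SpheroCylinder(new_s, new_c, a))
    session.log(
        "jcc_power_step", decision=decision,
        vs_more=vs_more, vs_less=vs_less, maintain_clc=maintain_clc,
    )
    return session, decision


def jcc_power_search(
    session: RefractionSession,
    maintain_clc: bool = True,
    tau_eq: float = TAU_EQUALITY,
    max_iter: int = 32,
) -> RefractionSession:
    """Iterate power steps until flip equality or an A->B->A oscillation
    (then keep the better of the two bracketing cylinders, flagged)."""
    state = {"sphere0": session.trial.sphere, "cyl0": session.trial.cylinder}
    seen: list[float] = [session.trial.cylinder]
    bracketed = False
    for _ in range(max_iter):
        session, decision = jcc_power_step(session, maintain_clc, state)
        if decision == 0:
            break
        c = session.trial.cylinder
        if len(seen) >= 2 and c == seen[-2]:
            # oscillation: compare the two bracketing corrections directly
            cands = sorted({seen[-1], c})
            scores = []
            for cc in cands:
                s = state["sphere0"]
                if maintain_clc:
                    s += STEP_D * np.floor(
                        (state["cyl0"] - cc) / 0.5 + 1e-9
                    )
                trial = SpheroCylinder(s, cc, session.trial.axis)
                scores.append(
                    scene_visual_strehl(
                        replace(session, trial=trial).scene()
                    )
                )
            best = cands[int(np.argmax(scores))]
            s = state["sphere0"]
            if maintain_clc:
                s += STEP_D * np.floor((state["cyl0"] - best) / 0.5 + 1e-9)
            session.set_trial(
                SpheroCylinder(s, best, session.trial.axis)
            )
            bracketed = True
            break
        seen.append(c)
    jcc = JCCState(session.jcc_power, session.trial.axis, mode="power-search")
    sim = flip_pair_similarity(session, jcc)
    session.log(
        "jcc_power_end",
        cylinder=session.trial.cylinder,
        bracketed=bracketed,
        flip_similarity=sim,
        equal=sim >= tau_eq,
    )
    return session


# ---------------------------------------------------------------------------
# sphere refinement


def refine_sphere(
    session: RefractionSession,
    window_d: float = 1.5,
    max_logmar: float = 1.2,
) -> RefractionSession:
    """Maximum plus to best visual acuity.

    Scans the sphere in 0.25 D steps around the current value and keeps the
    most-plus sphere whose acuity is within one chart step (0.1 logMAR) of
    the best found."""
    s0 = session.trial.sphere
    spheres = np.round(
        np.arange(s0 - window_d, s0 + window_d + 1e-9, STEP_D), 4
    )
    vas = []
    for s in spheres:
        probe = replace(
            session,
            trial=SpheroCylinder(
                float(s), session.trial.cylinder, session.trial.axis
            ),
        )
        vas.append(estimate_va(probe.scene(), max_logmar=max_logmar))
    vas = np.asarray(vas)
    best = vas.min()
    chosen = spheres[vas <= best + 0.1 + 1e-9].max()
    session.set_trial(
        SpheroCylinder(
            float(chosen), session.trial.cylinder, session.trial.axis
        )
    )
    session.log("refine_sphere", sphere=float(chosen), best_va=float(best))
    return session


def best_vs_sphere(
    session: RefractionSession, lo: float = -6.5, hi: float = 6.5
) -> float:
    """Sphere (0.25 D grid) maximizing the Visual Strehl of the scene —
    the objective starting point of the automated routine."""
    spheres = np.round(np.arange(lo, hi + 1e-9, STEP_D), 4)
    best_s, best_v = 0.0, -np.inf
    for s in spheres:
        probe = replace(
            session,
            trial=SpheroCylinder(
                float(s), session.trial.cylinder, session.trial.axis
            ),
        )
        v = probe.vs()
        if v > best_v:
            best_s, best_v = float(s), v
    return best_s


def clc_effect_comparison(
    eye: SchematicEye,
    fog_d: float = 1.25,
    n_pupil: int = 128,
) -> dict:
    """Compare JCC cylinder-power refinement with the circle of least
    confusion held on the retina versus left uncontrolled.

    Controlled arm: the sphere is first adjusted to best acuity (which
    places the CLC on or next to the retina), then the power search runs
    with the +0.25 D sphere per -0.50 D cylinder bookkeeping.
    Uncontrolled arm: the search starts in a fogged state (``fog_d`` of
    extra plus) and no spherical bookkeeping is applied, so the CLC sits
    well off the retina throughout.  Both results then receive a final
    sphere adjustment before their Visual Strehl is compared.

    Returns endpoint flip-pair similarities, final corrections and final
    VS for both arms.
    """
    out: dict = {}
    for arm, maintain in (("maintained", True), ("uncontrolled", False)):
        ses = RefractionSession(eye, n_pupil=n_pupil)
        if maintain:
            refine_sphere(ses)
        else:
            ses.set_trial(SpheroCylinder(fog_d, 0.0, 0.0))
        jcc_power_search(ses, maintain_clc=maintain)
        end = next(
            s.info for s in reversed(ses.history)
            if s.name == "jcc_power_end"
        )
        refine_sphere(ses)
        out[arm] = {
            "correction": ses.trial,
            "flip_similarity": end["flip_similarity"],
            "final_vs": ses.vs(),
        }
    return out


def run_full_refraction(
    session: RefractionSession,
    maintain_clc: bool = True,
    fog_target_logmar: float = 0.50,
) -> SpheroCylinder:
    """The complete automated routine: objective starting sphere, fogging,
    clock dial, JCC axis and power refinement, final sphere refinement.
    Returns the final trial correction."""
    session.set_trial(
        SpheroCylinder(best_vs_sphere(session), 0.0, 0.0)
    )
    session.log("initial_sphere", sphere=session.trial.sphere)
    fog(session, fog_target_logmar, min_added_d=1.25)
    clock_dial_procedure(session)
    # lift the fog: put the circle of least confusion back on the retina
    s_best = best_vs_sphere(
        session,
        session.trial.sphere - 4.0,
        session.trial.sphere + 1.0,
    )
    session.set_trial(
        SpheroCylinder(s_best, session.trial.cylinder, session.trial.axis)
    )
    session.log("unfog", sphere=s_best)
    if session.trial.cylinder:
        jcc_axis_search(session)
        jcc_power_search(session, maintain_clc=maintain_clc)
    refine_sphere(session)
    session.log("final", result=str(session.trial))
    return session.trial
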