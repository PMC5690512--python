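"""DVH-guided outer-loop plan autopiloting.

The autopilot wraps the inner fluence optimizer in a decision loop that
imitates a human planner working toward a reference plan.  Starting from the
reference plan's optimization parameters (a warm start), it alternates:

1. run the inner optimizer with the current per-structure weights,
2. compute fresh DVHs of the resulting dose and sample them at ``J`` fixed
   volume-fraction control points ("segments"),
3. check every segment against the reference plan's segment,
   ``|d_sj - d_sj_ref| < eps_s`` with ``eps_s`` set to a fixed fraction
   (default 3%) of the reference value, floored for near-zero reference
   doses,
4. if any segment violates its tolerance, nudge the violating structures'
   weights toward decreasing the discrepancy and reoptimize.

The loop stops when all segments are within tolerance or after a fixed
iteration cap (default 50).  A final refinement stage then lets each
structure's objective make a trial movement toward better target coverage or
OAR sparing; a trial is kept only if no DVH segment of any structure worsens
by more than a tolerance (default: one DVH bin width), so every accepted
move is Pareto-safe with respect to the segment set.

Weight updates are multiplicative and exponentiated in the aggregate signed
violation: an OAR overdosed relative to the reference (in the segment sense)
has its priority raised by ``exp(eta * V / D_rx)``; a target is updated
symmetrically on underdose.  Updates are clipped to a factor of e per
iteration, which keeps weights positive and the loop stable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dose_engine
from .dose_engine import OptimizerConfig, PlanParameters, compute_dose
from .dvh import (
    DEFAULT_RESOLUTION_GY,
    DEFAULT_SEGMENT_FRACTIONS,
    DVHCurve,
    SegmentVector,
    compute_dvh,
    sample_segments,
    write_dvh_file,
)
from .phantom import PlanningCase
from .reference import ReferenceCase
from .structures import GeometryError

__all__ = [
    "AutopilotConfig",
    "SegmentViolation",
    "IterationRecord",
    "AutopilotState",
    "TrialMove",
    "AutopilotResult",
    "check_constraints",
    "update_weights",
    "run_autopilot",
    "trial_refinement",
]

EXIT_CONVERGED = 0
EXIT_CAP_HIT = 2
EXIT_NO_REFERENCE = 3


@dataclass
class AutopilotConfig:
    epsilon_fraction: float = 0.03        # eps_s as a fraction of the reference segment dose
    epsilon_floor_gy: float = 0.1         # tolerance floor for near-zero reference doses
    max_outer_iterations: int = 50
    learning_rate: float = 300.0          # eta of the multiplicative weight update;
                                          # a violation of ~0.3% of the prescription
                                          # saturates the per-iteration clip
    weight_floor: float = 0.05            # weights never drop below this: a zeroed
                                          # priority would leave its structure's dose
                                          # entirely uncontrolled
    segment_fractions: tuple = DEFAULT_SEGMENT_FRACTIONS
    trial_step: float = 0.05              # relative objective-dose perturbation per trial
    trial_passes: int = 1
    worsen_tol_gy: float | None = None    # default: one DVH bin width
    dvh_resolution_gy: float = DEFAULT_RESOLUTION_GY
    output_dvh_resolution_gy: float = 0.01  # bin width of exported per-iteration files
    # endgame pattern search: when the gradient-style rule stalls this many
    # iterations without improving the worst excess, probe single-structure
    # weight moves (including currently satisfied structures) and keep those
    # that reduce the worst excess
    stall_patience: int = 4
    probe_initial_step: float = 0.5       # log-weight step of the pattern search
    probe_min_step: float = 0.01
    inner: OptimizerConfig = field(default_factory=OptimizerConfig)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.epsilon_fraction < 1.0):
            raise ValueError("epsilon_fraction must lie in (0, 1)")
        if self.max_outer_iterations < 1:
            raise ValueError("need at least one outer iteration")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.trial_step < 0:
            raise ValueError("trial step must be nonnegative")

    @property
    def worsening_tolerance_gy(self) -> float:
        return self.dvh_resolution_gy if self.worsen_tol_gy is None else self.worsen_tol_gy


@dataclass
class SegmentViolation:
    structure: str
    segment_index: int
    volume_fraction: float
    current_gy: float
    reference_gy: float
    epsilon_gy: float
    signed_excess_gy: float  # positive: overdosed vs reference beyond tolerance


@dataclass
class IterationRecord:
    iteration: int
    weights: dict[str, float]
    max_abs_deviation_gy: float
    max_abs_excess_gy: float
    n_violations: int
    inner_objective: float
    inner_converged: bool


@dataclass
class TrialMove:
    structure: str
    role: str
    accepted: bool
    objective_dose_before_gy: float
    objective_dose_after_gy: float
    segments_before: dict[str, np.ndarray]
    segments_after: dict[str, np.ndarray]


@dataclass
class AutopilotState:
    records: list[IterationRecord] = field(default_factory=list)
    params: PlanParameters | None = None
    fluence: np.ndarray | None = None
    segments: dict[str, SegmentVector] = field(default_factory=dict)
    curves: dict[str, DVHCurve] = field(default_factory=dict)
    converged: bool = False
    converged_iteration: int | None = None
    trial_moves: list[TrialMove] = field(default_factory=list)

    @property
    def iteration(self) -> int:
        return len(self.records)


@dataclass
class AutopilotResult:
    fluence: np.ndarray
    params: PlanParameters
    state: AutopilotState
    converged: bool
    exit_code: int

    @property
    def iterations(self) -> int:
        return self.state.converged_iteration or len(self.state.records)


# ---------------------------------------------------------------------------
# constraint checking (the stopping rule)
# ---------------------------------------------------------------------------

def segment_epsilon_gy(reference_gy: float, cfg: AutopilotConfig) -> float:
    return max(cfg.epsilon_fraction * reference_gy, cfg.epsilon_floor_gy)


def check_constraints(
    current: dict[str, SegmentVector],
    reference: dict[str, SegmentVector],
    cfg: AutopilotConfig,
) -> tuple[bool, list[SegmentViolation]]:
    """Check every DVH segment against its reference within per-segment tolerance.

    Satisfied iff ``|d_sj - d_sj_ref| < eps_sj`` for all structures and
    segments, with ``eps_sj = max(epsilon_fraction * d_sj_ref,
    epsilon_floor_gy)``; ties at exactly the tolerance count as violations.
    Each violation carries the signed excess beyond the tolerance band.
    """
    if set(current) != set(reference):
        raise ValueError(
            f"segment structures differ: {sorted(current)} vs {sorted(reference)}"
        )
    violations: list[SegmentViolation] = []
    for name in sorted(current):
        cur, ref = current[name], reference[name]
        if cur.volume_fractions.shape != ref.volume_fractions.shape or np.any(
            cur.volume_fractions != ref.volume_fractions
        ):
            raise ValueError(f"control points differ for structure {name!r}")
        for j, (dc, dr) in enumerate(zip(cur.doses_gy, ref.doses_gy)):
            eps = segment_epsilon_gy(dr, cfg)
            delta = dc - dr
            if abs(delta) >= eps:
                violations.append(
                    SegmentViolation(
                        structure=name,
                        segment_index=j,
                        volume_fraction=float(cur.volume_fractions[j]),
                        current_gy=float(dc),
                        reference_gy=float(dr),
                        epsilon_gy=float(eps),
                        signed_excess_gy=float(np.sign(delta) * (abs(delta) - eps)),
                    )
                )
    return not violations, violations


# ---------------------------------------------------------------------------
# weight update (the decision function)
# ---------------------------------------------------------------------------

def update_weights(
    params: PlanParameters,
    violations: list[SegmentViolation],
    cfg: AutopilotConfig,
    roles: dict[str, str],
    prescription_dose_gy: float,
    damping: dict[str, list] | None = None,
) -> PlanParameters:
    """Adjust structure weights toward decreasing the DVH discrepancy.

    Aggregate each structure's signed excesses into ``V_s`` (Gy; positive
    means overdosed relative to the reference).  OARs: ``w <- w * exp(eta *
    V_s / D_rx)`` (overdose raises priority).  Targets update symmetrically
    on underdose.  The exponent is clipped to [-1, 1] per iteration;
    structures without violations are left untouched.

    ``damping`` (optional, mutated in place) carries per-structure
    ``[step_scale, previous_sign]`` state: when a structure's aggregate
    violation changes sign between iterations its step scale is halved,
    which suppresses overshoot oscillation around the tolerance band.
    """
    new = params.copy()
    agg: dict[str, float] = {}
    for v in violations:
        agg[v.structure] = agg.get(v.structure, 0.0) + v.signed_excess_gy
    for name, V in agg.items():
        if name not in new.objectives:
            continue
        obj = new.objectives[name]
        scale = 1.0
        if damping is not None:
            state = damping.setdefault(name, [1.0, 0.0])
            if state[1] != 0.0 and np.sign(V) != state[1]:
                state[0] = max(state[0] * 0.5, 1.0 / 256.0)
            state[1] = float(np.sign(V))
            scale = state[0]
        sign = -1.0 if roles.get(name) == "target" else 1.0
        exponent = scale * np.clip(
            sign * cfg.learning_rate * V / prescription_dose_gy, -1.0, 1.0
        )
        obj.weight = float(max(obj.weight * np.exp(exponent), cfg.weight_floor))
    return new


# ---------------------------------------------------------------------------
# outer loop
# ---------------------------------------------------------------------------

def _plan_segments(
    dose: np.ndarray,
    case: PlanningCase,
    names: list[str],
    cfg: AutopilotConfig,
) -> tuple[dict[str, DVHCurve], dict[str, SegmentVector]]:
    curves = {
        n: compute_dvh(dose, case.structures[n].mask, cfg.dvh_resolution_gy, name=n)
        for n in names
    }
    segments = {n: sample_segments(c, cfg.segment_fractions) for n, c in curves.items()}
    return curves, segments


def reference_segments(
    reference: ReferenceCase, names: list[str], cfg: AutopilotConfig
) -> dict[str, SegmentVector]:
    return {
        n: sample_segments(reference.dvhs[n], cfg.segment_fractions) for n in names
    }


def run_autopilot(
    case: PlanningCase,
    reference: ReferenceCase,
    cfg: AutopilotConfig | None = None,
    output_dir: str | Path | None = None,
) -> AutopilotResult:
    """Drive the inner optimizer until the plan's DVH matches the reference.

    Warm-starts from the reference plan's parameters (and fluence when the
    beam layout matches), then alternates optimize / compare / update until
    every segment satisfies its tolerance or the iteration cap is reached.
    If the cap is hit, the best iterate (smallest worst-segment excess) is
    returned with a not-converged flag.  A trial-movement refinement pass
    runs afterwards in either case.  Deterministic for a fixed configuration.
    """
    cfg = cfg or AutopilotConfig()
    cfg.validate()
    for t in case.structures.targets:
        for o in case.structures.oars:
            if np.any(t.mask & o.mask):
                raise GeometryError(
                    f"target {t.name!r} and OAR {o.name!r} masks overlap"
                )
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    names = sorted(
        n
        for n in reference.dvhs
        if n in case.structures and case.structures[n].role != "external"
    )
    if not names:
        raise ValueError("reference carries no DVHs for the case's structures")
    ref_segs = reference_segments(reference, names, cfg)
    roles = {s.name: s.role for s in case.structures.structures}

    params = reference.params.copy()  # warm start: the reference plan's knobs
    x = None
    if reference.fluence is not None and reference.fluence.shape == (
        case.influence.n_beamlets,
    ):
        x = np.asarray(reference.fluence, dtype=float)

    state = AutopilotState()
    damping: dict[str, list] = {}
    best = None  # (max_abs_excess, fluence, params, segments, curves)
    probe: dict | None = None
    stall = 0
    move_names = sorted(params.objectives)

    def probe_queue(step):
        # coarse moves first, then a finer scale: stalled runs may need either
        # a large escape move or a sub-band nudge
        return [
            (n, s * scale)
            for scale in (step, step / 4.0)
            for n in move_names
            for s in (1.0, -1.0)
        ]

    for it in range(1, cfg.max_outer_iterations + 1):
        x, trace = dose_engine.optimize(params, case.influence, case.structures, x0=x,
                                        config=cfg.inner)
        dose = compute_dose(x, case.influence)
        curves, segs = _plan_segments(dose, case, names, cfg)
        satisfied, violations = check_constraints(segs, ref_segs, cfg)

        deviations = [
            abs(dc - dr)
            for n in names
            for dc, dr in zip(segs[n].doses_gy, ref_segs[n].doses_gy)
        ]
        max_excess = max((abs(v.signed_excess_gy) for v in violations), default=0.0)
        state.records.append(
            IterationRecord(
                iteration=it,
                weights={n: o.weight for n, o in params.objectives.items()},
                max_abs_deviation_gy=float(max(deviations)),
                max_abs_excess_gy=float(max_excess),
                n_violations=len(violations),
                inner_objective=trace.objectives[-1],
                inner_converged=trace.converged,
            )
        )
        if out is not None:
            coarse = [
                compute_dvh(dose, case.structures[n].mask,
                            cfg.output_dvh_resolution_gy, name=n)
                for n in names
            ]
            write_dvh_file(coarse, out / f"iter_{it:03d}.dvh")
        improved = best is None or max_excess < best[0] - 1e-9
        if best is None or max_excess < best[0]:
            best = (max_excess, x.copy(), params.copy(), segs, curves)
        if satisfied:
            state.converged = True
            state.converged_iteration = it
            break
        if it == cfg.max_outer_iterations:
            break
        if probe is not None and improved:
            # restart the probing round around the new best point
            probe["queue"] = probe_queue(probe["step"])
        if probe is None:
            stall = 0 if improved else stall + 1
            if stall < cfg.stall_patience:
                params = update_weights(
                    params, violations, cfg, roles, case.prescription.dose_gy,
                    damping=damping,
                )
                continue
            # the per-violator rule has stopped making progress: switch to a
            # pattern search over single-structure weight moves around the
            # best parameters found so far
            probe = {"step": cfg.probe_initial_step,
                     "queue": probe_queue(cfg.probe_initial_step)}
        if not probe["queue"]:
            probe["step"] = max(probe["step"] * 0.5, cfg.probe_min_step)
            probe["queue"] = probe_queue(probe["step"])
        move_name, delta = probe["queue"].pop(0)
        params = best[2].copy()
        params.objectives[move_name].weight = float(
            max(params.objectives[move_name].weight * np.exp(delta), cfg.weight_floor)
        )
        x = best[1].copy()

    if state.converged:
        state.fluence, state.params = x, params
        state.segments, state.curves = segs, curves
    else:
        # cap hit: fall back to the best iterate seen
        _, state.fluence, state.params, state.segments, state.curves = best

    trial_refinement(state, case, reference, cfg)

    if out is not None:
        _write_history(state, out)
        dose_engine.write_parameters(state.params, out / "final_parameters.yaml")
        write_dvh_file(
            [state.curves[n] for n in sorted(state.curves)], out / "final.dvh"
        )

    return AutopilotResult(
        fluence=state.fluence,
        params=state.params,
        state=state,
        converged=state.converged,
        exit_code=EXIT_CONVERGED if state.converged else EXIT_CAP_HIT,
    )


def trial_refinement(
    state: AutopilotState,
    case: PlanningCase,
    reference: ReferenceCase,
    cfg: AutopilotConfig,
) -> AutopilotState:
    """Post-convergence trial movements beyond the reference benchmark.

    Structures are visited in a fixed order (targets first, then OARs by
    descending weight).  Each trial perturbs that structure's objective dose
    (targets: raised by ``trial_step`` fraction for better coverage; OARs:
    lowered for better sparing), reoptimizes from the current fluence, and is
    accepted only if no DVH segment of any structure worsens by more than the
    worsening tolerance — worsening means a dose drop for target segments and
    a dose rise for OAR segments.  Rejected trials are reverted.  Updates
    ``state`` in place and returns it.
    """
    if cfg.trial_step == 0.0 or cfg.trial_passes < 1:
        return state
    names = list(state.segments)
    roles = {s.name: s.role for s in case.structures.structures}
    tol = cfg.worsening_tolerance_gy

    def order(params: PlanParameters) -> list[str]:
        targets = [n for n in names if roles.get(n) == "target"]
        oars = [n for n in names if roles.get(n) == "oar"]
        oars.sort(key=lambda n: (-params.objectives[n].weight, n))
        return [n for n in targets + oars if n in params.objectives]

    for _ in range(cfg.trial_passes):
        for name in order(state.params):
            trial = state.params.copy()
            obj = trial.objectives[name]
            before_dose = obj.dose_gy
            if roles.get(name) == "target":
                obj.dose_gy = before_dose * (1.0 + cfg.trial_step)
            else:
                obj.dose_gy = before_dose * (1.0 - cfg.trial_step)
            x_new, _ = dose_engine.optimize(
                trial, case.influence, case.structures, x0=state.fluence,
                config=cfg.inner,
            )
            dose = compute_dose(x_new, case.influence)
            curves, segs = _plan_segments(dose, case, names, cfg)
            worsened = False
            for n in names:
                delta = segs[n].doses_gy - state.segments[n].doses_gy
                if roles.get(n) == "target":
                    if np.any(delta < -tol):
                        worsened = True
                else:
                    if np.any(delta > tol):
                        worsened = True
            move = TrialMove(
                structure=name,
                role=roles.get(name, "oar"),
                accepted=not worsened,
                objective_dose_before_gy=before_dose,
                objective_dose_after_gy=obj.dose_gy,
                segments_before={n: state.segments[n].doses_gy.copy() for n in names},
                segments_after={n: segs[n].doses_gy.copy() for n in names},
            )
            state.trial_moves.append(move)
            if not worsened:
                state.params = trial
                state.fluence = x_new
                state.segments = segs
                state.curves = curves
    return state


def _write_history(state: AutopilotState, out: Path) -> None:
    names = sorted(state.records[0].weights) if state.records else []
    lines = [
        ",".join(
            ["iteration", "inner_objective", "max_abs_deviation_gy",
             "max_abs_excess_gy", "n_violations"]
            + [f"weight_{n}" for n in names]
        )
    ]
    for r in state.records:
        lines.append(
            ",".join(
                [str(r.iteration), f"{r.inner_objective:.8g}",
                 f"{r.max_abs_deviation_gy:.6f}", f"{r.max_abs_excess_gy:.6f}",
                 str(r.n_violations)]
                + [f"{r.weights[n]:.6g}" for n in names]
            )
        )
    (out / "history.csv").write_text("\n".join(lines) + "\n")
    if state.trial_moves:
        tlines = ["structure,role,accepted,objective_dose_before_gy,objective_dose_after_gy"]
        for m in state.trial_moves:
            tlines.append(
                f"{m.structure},{m.role},{int(m.accepted)},"
                f"{m.objective_dose_before_gy:.6f},{m.objective_dose_after_gy:.6f}"
            )
        (out / "trial_moves.csv").write_text("\n".join(tlines) + "\n")
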