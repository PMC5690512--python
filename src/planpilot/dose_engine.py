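"""Surrogate inner-loop fluence-map optimizer.

The commercial optimizer that the outer loop steers is modelled here as the
standard convex fluence-map-optimization problem: nonnegative beamlet
fluences ``x`` produce dose ``d = D x`` through a dose-influence matrix, and
the plan objective is a weighted sum of per-structure quadratic penalties

    F(x) = sum_s  w_s * mean_{v in s} pen(d_v)

with ``pen(d) = (d - d_obj)^2`` for targets (uniform-dose objective) and
``pen(d) = max(0, d - d_obj)^2`` for organs at risk (one-sided upper-dose
objective).  The per-structure weights ``w_s`` are the priorities the outer
loop adjusts.

Minimisation is a bound-constrained quasi-Newton fit (L-BFGS-B) of the
convex objective; the line search only accepts descent steps, so the
recorded objective trace is monotone nonincreasing.  The problem is convex,
so a warm start changes the path, not the solution.  The influence matrices
of scatter-heavy beam models make the objective severely ill-conditioned
(long, nearly flat valleys), which is why a curvature-aware method is used
rather than plain projected gradient descent.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import optimize as _sciopt

from .structures import StructureSet

__all__ = [
    "StructureObjective",
    "PlanParameters",
    "OptimizerConfig",
    "OptimizeTrace",
    "compute_dose",
    "optimize",
    "write_parameters",
    "read_parameters",
]

OBJECTIVE_KINDS = ("uniform", "max")


@dataclass
class StructureObjective:
    """One structure's optimization objective: priority weight, goal dose, penalty type."""

    weight: float
    dose_gy: float
    kind: str  # "uniform" (two-sided, targets) or "max" (upper penalty, OARs)

    def __post_init__(self) -> None:
        if self.kind not in OBJECTIVE_KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("objective weights must be nonnegative")
        if self.dose_gy < 0:
            raise ValueError("objective doses must be nonnegative")


@dataclass
class PlanParameters:
    """The optimizer knobs the outer loop turns: one objective per structure."""

    objectives: dict[str, StructureObjective]

    def validate(self) -> None:
        if not any(o.kind == "uniform" and o.weight > 0 for o in self.objectives.values()):
            raise ValueError("need at least one target (uniform) objective with positive weight")

    def copy(self) -> "PlanParameters":
        return PlanParameters({k: copy.copy(v) for k, v in self.objectives.items()})


@dataclass
class OptimizerConfig:
    rel_tol: float = 1e-12      # relative objective-decrease stopping tolerance
    grad_tol: float = 1e-10     # projected-gradient stopping tolerance
    max_iterations: int = 20000
    max_restarts: int = 20      # fresh-memory restarts to escape flat-valley stalls


@dataclass
class OptimizeTrace:
    objectives: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def n_iterations(self) -> int:
        return max(len(self.objectives) - 1, 0)


def compute_dose(x: np.ndarray, influence) -> np.ndarray:
    """Dose grid from beamlet fluences: ``dose = D x``, reshaped to the voxel grid."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("fluence must be nonnegative")
    D = influence.entries
    if x.shape != (D.shape[1],):
        raise ValueError(
            f"fluence length {x.shape} does not match beamlet count {D.shape[1]}"
        )
    return (D @ x).reshape(influence.grid_shape)


def _assemble(params: PlanParameters, D: np.ndarray, sset: StructureSet):
    """Collect (weight/n, rows-of-D, goal dose, one_sided) per active structure."""
    terms = []
    for name, obj in params.objectives.items():
        if obj.weight == 0.0:
            continue  # identical to omitting the structure
        if name not in sset:
            raise KeyError(f"objective references unknown structure {name!r}")
        idx = np.flatnonzero(sset[name].mask.ravel())
        if idx.size == 0:
            raise ValueError(f"structure {name!r} has an empty mask")
        terms.append((obj.weight / idx.size, idx, obj.dose_gy, obj.kind == "max"))
    return terms


def optimize(
    params: PlanParameters,
    influence,
    sset: StructureSet,
    x0: np.ndarray | None = None,
    config: OptimizerConfig | None = None,
) -> tuple[np.ndarray, OptimizeTrace]:
    """Minimise the weighted quadratic plan objective over nonnegative fluences.

    Returns the best iterate and the per-iteration objective trace; if the
    iteration cap is reached before the relative-decrease tolerance, the
    trace's ``converged`` flag is False and the best iterate is still
    returned.
    """
    params.validate()
    cfg = config or OptimizerConfig()
    D = influence.entries
    n_beamlets = D.shape[1]
    terms = _assemble(params, D, sset)

    all_idx = np.unique(np.concatenate([t[1] for t in terms]))
    Dsub = D[all_idx]  # only voxels that enter the objective matter
    remap = {v: i for i, v in enumerate(all_idx)}
    terms = [(c, np.array([remap[v] for v in idx]), d0, one) for c, idx, d0, one in terms]

    def f_and_grad_residual(d):
        f = 0.0
        r = np.zeros_like(d)
        for c, idx, d0, one_sided in terms:
            res = d[idx] - d0
            if one_sided:
                res = np.maximum(res, 0.0)
            f += c * float(res @ res)
            r[idx] += 2.0 * c * res
        return f, r

    if x0 is None:
        x = np.zeros(n_beamlets)
    else:
        x = np.asarray(x0, dtype=float).copy()
        if x.shape != (n_beamlets,):
            raise ValueError("warm-start fluence has the wrong length")
        if np.any(x < 0):
            raise ValueError("warm-start fluence must be nonnegative")

    def fun_and_grad(xv):
        f, r = f_and_grad_residual(Dsub @ xv)
        return f, Dsub.T @ r

    f0, _ = fun_and_grad(x)
    trace = OptimizeTrace(objectives=[f0])

    def record(xk):
        fk, _ = fun_and_grad(xk)
        trace.objectives.append(fk)  # the line search only accepts descent steps

    # restart with fresh quasi-Newton memory until no further progress: on the
    # nearly flat valleys of scatter-heavy influence matrices a single
    # L-BFGS-B run can stall far from the optimum
    x_cur = x
    f_prev = f0
    converged = False
    for _ in range(cfg.max_restarts):
        result = _sciopt.minimize(
            fun_and_grad,
            x_cur,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * n_beamlets,
            callback=record,
            options={
                "maxiter": cfg.max_iterations,
                "maxfun": 50 * cfg.max_iterations,
                "ftol": cfg.rel_tol,
                "gtol": cfg.grad_tol,
            },
        )
        x_cur = np.maximum(result.x, 0.0)
        f_cur, _ = fun_and_grad(x_cur)
        if f_cur < trace.objectives[-1]:
            trace.objectives.append(f_cur)
        converged = bool(result.success)
        if f_prev - f_cur <= cfg.rel_tol * max(abs(f_prev), 1.0):
            break
        f_prev = f_cur
    trace.converged = converged
    return x_cur, trace


# ---------------------------------------------------------------------------
# key-value serialization (same dialect as phantom specs)
# ---------------------------------------------------------------------------

def write_parameters(params: PlanParameters, path: str | Path) -> None:
    data = {
        name: {"weight": float(o.weight), "dose_gy": float(o.dose_gy), "kind": o.kind}
        for name, o in params.objectives.items()
    }
    Path(path).write_text(yaml.safe_dump({"objectives": data}, sort_keys=True))


def read_parameters(path: str | Path) -> PlanParameters:
    data = yaml.safe_load(Path(path).read_text())
    objectives = {
        name: StructureObjective(d["weight"], d["dose_gy"], d["kind"])
        for name, d in data["objectives"].items()
    }
    return PlanParameters(objectives)
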