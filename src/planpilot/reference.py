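"""Knowledge-based reference-plan retrieval.

A new case is matched against a library of previously planned cases.  The
library is first filtered on anatomical site, target volume, structure-name
set and prescribed dose; surviving candidates are then scored with a signed
radial contour-similarity metric:

For each structure a polar coordinate system is placed at the structure's
own centre of mass (per case).  Rays are cast at a fixed angular resolution
(default 2.5 deg, i.e. 144 rays) and the radii at which each ray crosses the
structure boundary are recorded — one crossing for a convex target
containing the origin, possibly several for concave organs.  The signed
difference at a crossing is ``r_reference - r_current``; a candidate is
rejected when any |signed difference| of any structure exceeds that
structure's threshold (small structures: a few mm; large structures such as
the skin contour: 5–15 mm).  Rays whose crossing counts differ between the
two cases cannot be matched pointwise and are treated as exceeding any
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon

from .dvh import DVHCurve
from .structures import (
    GeometryError,
    StructureSet,
    center_of_mass,
    structure_volume_cc,
)

__all__ = [
    "ReferenceCase",
    "SelectionConfig",
    "RayDifference",
    "StructureSimilarity",
    "SimilarityReport",
    "SelectionResult",
    "ray_intercepts",
    "signed_difference",
    "filter_candidates",
    "select_reference",
    "default_thresholds",
    "plot_overlay",
]

DEFAULT_ANGLE_RESOLUTION_DEG = 2.5


@dataclass
class Prescription:
    dose_gy: float
    fractions: int

    def __post_init__(self) -> None:
        if self.dose_gy <= 0:
            raise ValueError("prescription dose must be positive")


@dataclass
class ReferenceCase:
    """A previously planned case: geometry, prescription, optimizer knobs and DVHs."""

    case_id: str
    site: str
    structures: StructureSet
    prescription: Prescription
    params: "PlanParameters"  # noqa: F821 - forward ref, avoids import cycle
    dvhs: dict[str, DVHCurve]
    fluence: np.ndarray | None = None
    spec: object | None = None  # generating phantom spec, kept for synthetic cases

    def validate(self) -> None:
        unknown = set(self.dvhs) - set(self.structures.names)
        if unknown:
            raise ValueError(f"DVHs for structures not in the set: {sorted(unknown)}")


@dataclass
class SelectionConfig:
    angle_resolution_deg: float = DEFAULT_ANGLE_RESOLUTION_DEG
    target_volume_band: float = 0.25   # relative band on physical target volume
    dose_band: float = 0.10            # relative band on prescription dose
    small_volume_cc: float = 10.0      # below: "small structure" threshold applies
    small_threshold_mm: float = 2.0    # within the 1-3 mm range for small structures
    large_threshold_mm: float = 10.0   # within the 5-15 mm range for large structures


@dataclass
class RayDifference:
    angle_deg: float
    intercept_index: int
    signed_diff_mm: float


@dataclass
class StructureSimilarity:
    """Signed radial differences of one structure between current and reference case."""

    structure: str
    differences: list[RayDifference]
    mismatched_angles: list[float]   # rays whose crossing counts differ
    max_abs_mm: float                # inf when any ray is mismatched
    rms_mm: float


@dataclass
class SimilarityReport:
    case_id: str
    structures: dict[str, StructureSimilarity]
    accepted: bool
    rejection_reasons: list[str] = field(default_factory=list)

    @property
    def score_mm(self) -> float:
        """Worst structure's worst |signed difference| — the selection score."""
        if not self.structures:
            return float("inf")
        return max(s.max_abs_mm for s in self.structures.values())

    @property
    def rms_mm(self) -> float:
        diffs = [
            d.signed_diff_mm for s in self.structures.values() for d in s.differences
        ]
        if not diffs:
            return float("inf")
        return float(np.sqrt(np.mean(np.square(diffs))))


@dataclass
class SelectionResult:
    reference: ReferenceCase | None
    report: SimilarityReport | None
    candidate_reports: list[SimilarityReport]

    @property
    def found(self) -> bool:
        return self.reference is not None


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def ray_intercepts(contour: np.ndarray, origin, angle_deg: float) -> np.ndarray:
    """Radii (mm, sorted increasing) at which the ray from ``origin`` at
    ``angle_deg`` crosses the contour boundary."""
    poly = Polygon(np.asarray(contour, dtype=float))
    if not poly.is_valid or poly.area == 0:
        raise GeometryError("degenerate (zero-area or self-intersecting) contour")
    origin = np.asarray(origin, dtype=float)
    theta = np.deg2rad(angle_deg)
    u = np.array([np.cos(theta), np.sin(theta)])
    # long enough to leave the structure from any interior or nearby origin
    verts = np.asarray(contour, dtype=float)
    reach = 2.0 * float(np.max(np.hypot(*(verts - origin).T))) + 10.0
    ray = LineString([origin, origin + reach * u])
    hit = poly.exterior.intersection(ray)
    if hit.is_empty:
        return np.array([])
    pts: list[np.ndarray] = []
    for geom in getattr(hit, "geoms", [hit]):
        if isinstance(geom, Point):
            pts.append(np.array([geom.x, geom.y]))
        else:  # collinear overlap with an edge: keep its endpoints
            pts.extend(np.asarray(geom.coords))
    radii = np.hypot(*(np.array(pts) - origin).T)
    radii = np.unique(np.round(radii, 9))
    return np.sort(radii)


def signed_difference(
    current: StructureSet,
    reference: StructureSet,
    structure: str,
    angle_resolution_deg: float = DEFAULT_ANGLE_RESOLUTION_DEG,
) -> StructureSimilarity:
    """Signed radial contour difference of one structure between two cases.

    Origins are the per-case centres of mass of the structure, rays are cast
    at the given resolution (which must divide 360 evenly), crossings are
    matched by sorted radial index, and each matched crossing contributes
    ``r_reference - r_current``.
    """
    n_rays = 360.0 / angle_resolution_deg
    if abs(n_rays - round(n_rays)) > 1e-9:
        raise ValueError("angle resolution must divide 360 evenly")
    if structure not in current or structure not in reference:
        raise KeyError(f"structure {structure!r} missing from one of the cases")
    cur = current[structure]
    ref = reference[structure]
    o_cur = center_of_mass(cur.mask, current.voxel_size_mm)
    o_ref = center_of_mass(ref.mask, reference.voxel_size_mm)
    diffs: list[RayDifference] = []
    mismatched: list[float] = []
    for k in range(int(round(n_rays))):
        angle = k * angle_resolution_deg
        r_cur = ray_intercepts(cur.contour, o_cur, angle)
        r_ref = ray_intercepts(ref.contour, o_ref, angle)
        if len(r_cur) != len(r_ref):
            mismatched.append(angle)
            continue
        for j, (rc, rr) in enumerate(zip(r_cur, r_ref)):
            diffs.append(RayDifference(angle, j, float(rr - rc)))
    max_abs = float("inf") if mismatched else (
        max((abs(d.signed_diff_mm) for d in diffs), default=0.0)
    )
    rms = (
        float(np.sqrt(np.mean([d.signed_diff_mm**2 for d in diffs]))) if diffs else 0.0
    )
    return StructureSimilarity(structure, diffs, mismatched, max_abs, rms)


# ---------------------------------------------------------------------------
# library filtering and selection
# ---------------------------------------------------------------------------

def _normalize_name(name: str) -> str:
    return name.strip().lower().replace(" ", "").replace("_", "")


def _target_volume_cc(sset: StructureSet) -> float:
    return sum(
        structure_volume_cc(t.mask, sset.voxel_size_mm) for t in sset.targets
    )


def filter_candidates(library: list[ReferenceCase], case, config: SelectionConfig | None = None):
    """Keep candidates matching the query's site, target volume, structure names
    and prescribed dose (volume and dose within configured relative bands)."""
    if not library:
        raise ValueError("reference library is empty")
    cfg = config or SelectionConfig()
    q_names = {_normalize_name(n) for n in case.structures.names}
    q_vol = _target_volume_cc(case.structures)
    q_dose = case.prescription.dose_gy
    kept = []
    for cand in library:
        if cand.site != case.site:
            continue
        if {_normalize_name(n) for n in cand.structures.names} != q_names:
            continue
        if abs(_target_volume_cc(cand.structures) - q_vol) > cfg.target_volume_band * q_vol:
            continue
        if abs(cand.prescription.dose_gy - q_dose) > cfg.dose_band * q_dose:
            continue
        kept.append(cand)
    return kept


def default_thresholds(sset: StructureSet, config: SelectionConfig | None = None) -> dict[str, float]:
    """Per-structure acceptance thresholds from the small/large volume rule."""
    cfg = config or SelectionConfig()
    out = {}
    for s in sset.structures:
        vol = structure_volume_cc(s.mask, sset.voxel_size_mm)
        out[s.name] = (
            cfg.small_threshold_mm if vol < cfg.small_volume_cc else cfg.large_threshold_mm
        )
    return out


def select_reference(
    library: list[ReferenceCase],
    case,
    thresholds: dict[str, float] | None = None,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Pick the best admissible reference case, or an explicit no-reference result.

    Candidates surviving :func:`filter_candidates` are scored structure by
    structure with :func:`signed_difference`; any structure whose worst
    |signed difference| exceeds its threshold rejects the candidate.  Among
    accepted candidates the one with the smallest worst-structure score wins
    (ties: smaller RMS, then lexicographic case id).
    """
    cfg = config or SelectionConfig()
    if thresholds is not None and any(t <= 0 for t in thresholds.values()):
        raise ValueError("thresholds must be positive")
    thr = thresholds or default_thresholds(case.structures, cfg)
    candidates = filter_candidates(library, case, cfg)
    reports = []
    for cand in candidates:
        per_struct = {}
        reasons = []
        for name in sorted(case.structures.names):
            sim = signed_difference(
                case.structures, cand.structures, name, cfg.angle_resolution_deg
            )
            per_struct[name] = sim
            limit = thr.get(name, cfg.large_threshold_mm)
            if sim.mismatched_angles:
                reasons.append(
                    f"{name}: unmatched crossing counts at "
                    f"{len(sim.mismatched_angles)} ray(s)"
                )
            elif sim.max_abs_mm > limit:
                reasons.append(
                    f"{name}: max |signed difference| {sim.max_abs_mm:.2f} mm "
                    f"exceeds {limit:.2f} mm"
                )
        reports.append(
            SimilarityReport(cand.case_id, per_struct, accepted=not reasons,
                             rejection_reasons=reasons)
        )
    accepted = [(r, c) for r, c in zip(reports, candidates) if r.accepted]
    if not accepted:
        return SelectionResult(None, None, reports)
    best_report, best_case = min(
        accepted, key=lambda rc: (rc[0].score_mm, rc[0].rms_mm, rc[0].case_id)
    )
    return SelectionResult(best_case, best_report, reports)


def plot_overlay(case, reference: ReferenceCase, path: str | Path) -> None:
    """Write a contour-overlay figure of the current case and the chosen reference,
    the artifact that replaces a planner's visual coincidence check."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for sset, style, label in (
        (case.structures, "-", "current"),
        (reference.structures, "--", f"reference {reference.case_id}"),
    ):
        for s in sset.structures:
            ax.plot(s.contour[:, 0], s.contour[:, 1], style, lw=1.2,
                    label=f"{s.name} ({label})")
    ax.set_aspect("equal")
    ax.set_xlabel("x [mm]")
    ax.set_ylabel("y [mm]")
    ax.legend(fontsize=6, loc="upper right")
    fig.savefig(path, dpi=120)
    plt.close(fig)
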