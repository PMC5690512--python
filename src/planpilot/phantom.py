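"""Synthetic planning cases: phantom geometry, surrogate dose physics, reference libraries.

A phantom is a 2D axial-slice patient model on a regular voxel grid: a
circular external (body) contour, a central planning target volume (PTV) and
one to three organs at risk (OARs) whose proximity to the target is
controllable, so both easy and tight planning geometries can be produced
from a seed.  The data model keeps grid shape abstract, so a 3D extension is
a configuration change rather than a redesign.

Dose physics is a deliberately simple divergent pencil-beam model: each beam
direction carries a fan of beamlets; a beamlet deposits dose with
exponential depth attenuation along its axis and a lateral Gaussian
penumbra whose width grows slowly with depth.  The resulting dose-influence
matrix ``D`` (Gy per unit fluence, voxels x beamlets) is all any downstream
module sees of the "machine", mirroring how a treatment planning system's
optimizer consumes precomputed beamlet dose.

A reference library emulates previously treated patients: each library case
is the base phantom with its target/OAR contours perturbed by at most
``jitter_mm`` and a plan optimized to convergence on its own geometry, so
every reference DVH is achievable where it was planned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import dose_engine
from .dose_engine import (
    OptimizerConfig,
    PlanParameters,
    StructureObjective,
    compute_dose,
    read_parameters,
    write_parameters,
)
from .dvh import DEFAULT_RESOLUTION_GY, compute_dvh, read_dvh_file, write_dvh_file
from .reference import Prescription, ReferenceCase
from .structures import (
    DegenerateGeometryError,
    GeometryError,
    Structure,
    StructureSet,
    read_contours,
    write_contours,
)

__all__ = [
    "OARSpec",
    "PhantomSpec",
    "PencilBeamConfig",
    "InfluenceMatrix",
    "PlanningCase",
    "Prescription",
    "generate_phantom",
    "make_case",
    "default_plan_parameters",
    "generate_reference_library",
    "save_reference_case",
    "load_reference_case",
    "save_library",
    "load_library",
    "write_phantom_spec",
    "read_phantom_spec",
    "load_case",
    "save_case",
]


@dataclass
class OARSpec:
    """One organ at risk: a circle or axis-aligned ellipse placed relative to grid centre."""

    name: str
    center_offset_mm: tuple[float, float]
    size_mm: float | tuple[float, float]  # radius, or (semi-axis x, semi-axis y)
    shape: str = "circle"

    def semi_axes(self) -> tuple[float, float]:
        if self.shape == "circle":
            return float(self.size_mm), float(self.size_mm)
        if self.shape == "ellipse":
            a, b = self.size_mm
            return float(a), float(b)
        raise ValueError(f"unknown OAR shape {self.shape!r}")


@dataclass
class PencilBeamConfig:
    """Surrogate beam physics (documented defaults; roughly 6-MV-like in water)."""

    mu_per_mm: float = 0.004        # linear attenuation, ~4%/cm
    sigma0_mm: float = 6.0          # primary lateral penumbra sigma at the surface
    sigma_growth: float = 0.02      # penumbra growth per mm depth
    scatter_weight: float = 0.10    # broad scatter component relative to primary
    scatter_sigma_mm: float = 80.0  # lateral sigma of the scatter component
    source_distance_mm: float = 1000.0
    aperture_margin_mm: float = 8.0  # beamlet fan covers PTV radius + margin


@dataclass
class PhantomSpec:
    """Everything needed to rebuild a phantom case deterministically."""

    grid_shape: tuple[int, int] = (64, 64)
    voxel_size_mm: float = 2.0
    ptv_radius_mm: float = 12.0
    ptv_center_offset_mm: tuple[float, float] = (0.0, 0.0)
    oar_specs: list[OARSpec] = field(default_factory=list)
    beam_angles_deg: list[float] = field(
        default_factory=lambda: [i * 22.5 for i in range(16)]
    )
    beamlets_per_beam: int = 17
    external_radius_mm: float | None = None  # default: 0.45 x smaller grid extent
    prescription_dose_gy: float = 50.0
    fractions: int = 25
    seed: int = 0

    def validate(self) -> None:
        ny, nx = self.grid_shape
        if ny < 16 or nx < 16:
            raise ValueError("grid must be at least 16x16 voxels")
        if self.voxel_size_mm <= 0 or self.ptv_radius_mm <= 0:
            raise ValueError("voxel size and PTV radius must be positive")
        if self.beamlets_per_beam < 1:
            raise ValueError("need at least one beamlet per beam")
        if not self.beam_angles_deg:
            raise ValueError("need at least one beam angle")

    def resolved_external_radius(self) -> float:
        if self.external_radius_mm is not None:
            return self.external_radius_mm
        ny, nx = self.grid_shape
        return 0.45 * min(ny, nx) * self.voxel_size_mm


@dataclass
class InfluenceMatrix:
    """Dose-influence matrix: Gy per unit fluence, shape (n_voxels, n_beamlets)."""

    entries: np.ndarray
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if np.any(self.entries < 0):
            raise ValueError("influence entries must be nonnegative")
        if np.any(~self.entries.any(axis=0)):
            raise ValueError("every beamlet column must deposit dose somewhere")

    @property
    def n_beamlets(self) -> int:
        return self.entries.shape[1]


@dataclass
class PlanningCase:
    """A case to be planned: geometry plus the machine model and prescription."""

    case_id: str
    site: str
    structures: StructureSet
    influence: InfluenceMatrix
    prescription: Prescription
    spec: PhantomSpec | None = None


# ---------------------------------------------------------------------------
# geometry + physics generation
# ---------------------------------------------------------------------------

def _grid_centers(spec: PhantomSpec):
    ny, nx = spec.grid_shape
    xs = (np.arange(nx) + 0.5) * spec.voxel_size_mm
    ys = (np.arange(ny) + 0.5) * spec.voxel_size_mm
    X, Y = np.meshgrid(xs, ys)
    iso = np.array([nx * spec.voxel_size_mm / 2.0, ny * spec.voxel_size_mm / 2.0])
    return X, Y, iso


def _ellipse_mask(X, Y, center, semi_axes) -> np.ndarray:
    a, b = semi_axes
    return ((X - center[0]) / a) ** 2 + ((Y - center[1]) / b) ** 2 <= 1.0


def _pencil_beam_influence(
    spec: PhantomSpec, external_mask: np.ndarray, beam: PencilBeamConfig
) -> InfluenceMatrix:
    X, Y, iso = _grid_centers(spec)
    r = np.column_stack([X.ravel(), Y.ravel()])
    inside = external_mask.ravel()
    R_ext = spec.resolved_external_radius()
    half_aperture = spec.ptv_radius_mm + beam.aperture_margin_mm
    n_b = spec.beamlets_per_beam
    offsets = (
        np.linspace(-half_aperture, half_aperture, n_b) if n_b > 1 else np.array([0.0])
    )
    cols = []
    for angle in spec.beam_angles_deg:
        th = np.deg2rad(angle)
        s = np.array([np.cos(th), np.sin(th)])   # towards the source
        prop = -s                                 # propagation direction
        t = np.array([-np.sin(th), np.cos(th)])  # lateral axis
        rel = r - iso
        lat_iso = rel @ t
        along = rel @ prop
        # depth inside the circular body along the (near-parallel) beam
        chord = np.sqrt(np.maximum(R_ext**2 - lat_iso**2, 0.0))
        depth = np.clip(along + chord, 0.0, None)
        atten = np.exp(-beam.mu_per_mm * depth)
        sigma = beam.sigma0_mm + beam.sigma_growth * depth
        source = iso + beam.source_distance_mm * s
        rel_src = r - source
        for o in offsets:
            axis_pt = iso + o * t
            u = axis_pt - source
            u = u / np.hypot(*u)
            lat = np.abs(rel_src[:, 0] * u[1] - rel_src[:, 1] * u[0])
            kernel = np.exp(-0.5 * (lat / sigma) ** 2) + beam.scatter_weight * np.exp(
                -0.5 * (lat / beam.scatter_sigma_mm) ** 2
            )
            col = atten * kernel
            col[~inside] = 0.0
            cols.append(col)
    return InfluenceMatrix(np.column_stack(cols), spec.grid_shape)


def generate_phantom(
    spec: PhantomSpec, beam: PencilBeamConfig | None = None
) -> tuple[StructureSet, InfluenceMatrix, Prescription]:
    """Build the structure set, dose-influence matrix and prescription of a phantom.

    Deterministic for a fixed spec (the seed is carried along for library
    generation, which is where randomness lives).
    """
    spec.validate()
    beam = beam or PencilBeamConfig()
    X, Y, iso = _grid_centers(spec)
    vs = spec.voxel_size_mm
    R_ext = spec.resolved_external_radius()

    external = _ellipse_mask(X, Y, iso, (R_ext, R_ext))
    ptv_center = iso + np.asarray(spec.ptv_center_offset_mm)
    ptv = _ellipse_mask(X, Y, ptv_center, (spec.ptv_radius_mm, spec.ptv_radius_mm))
    if not ptv.any():
        raise GeometryError("PTV mask is empty on this grid")
    if np.any(ptv & ~external):
        raise GeometryError("PTV extends outside the external contour")

    structures = [
        Structure.from_mask("BODY", "external", external, vs),
        Structure.from_mask("PTV", "target", ptv, vs),
    ]
    for oar in spec.oar_specs:
        center = iso + np.asarray(oar.center_offset_mm)
        mask = _ellipse_mask(X, Y, center, oar.semi_axes())
        if not mask.any():
            raise GeometryError(f"OAR {oar.name!r} mask is empty on this grid")
        if np.any(mask & ~external):
            raise GeometryError(f"OAR {oar.name!r} extends outside the external contour")
        if np.any(mask & ptv):
            raise DegenerateGeometryError(
                f"OAR {oar.name!r} overlaps the PTV; planning geometry is degenerate"
            )
        structures.append(Structure.from_mask(oar.name, "oar", mask, vs))

    sset = StructureSet(voxel_size_mm=vs, structures=structures)
    sset.validate()
    influence = _pencil_beam_influence(spec, external, beam)
    rx = Prescription(spec.prescription_dose_gy, spec.fractions)
    return sset, influence, rx


def make_case(
    spec: PhantomSpec,
    case_id: str = "case",
    site: str = "phantom",
    beam: PencilBeamConfig | None = None,
) -> PlanningCase:
    sset, influence, rx = generate_phantom(spec, beam)
    return PlanningCase(case_id, site, sset, influence, rx, spec=spec)


def default_plan_parameters(sset: StructureSet, rx: Prescription) -> PlanParameters:
    """Sensible starting objectives: uniform prescription dose on the target,
    an upper goal at a fifth of the prescription on every OAR."""
    objectives = {}
    for t in sset.targets:
        objectives[t.name] = StructureObjective(weight=1.0, dose_gy=rx.dose_gy, kind="uniform")
    for o in sset.oars:
        objectives[o.name] = StructureObjective(
            weight=0.5, dose_gy=0.2 * rx.dose_gy, kind="max"
        )
    return PlanParameters(objectives)


def standard_phantom_spec(n_oars: int = 2, seed: int = 0) -> PhantomSpec:
    """The canonical study phantom: a central 12-mm PTV inside a circular body
    with up to three OARs beyond the primary field edge, 16 coplanar beams.

    ``n_oars`` between 1 and 3 controls how much of the plan trade-off space
    is occupied; tighter custom geometries can be built directly through
    :class:`PhantomSpec`.
    """
    if not 1 <= n_oars <= 3:
        raise ValueError("standard phantom supports 1-3 OARs")
    oars = [
        OARSpec("OAR1", (40.0, 0.0), 9.0),
        OARSpec("OAR2", (-32.0, 26.0), 8.0),
        OARSpec("OAR3", (-20.0, -36.0), 7.0),
    ]
    return PhantomSpec(oar_specs=oars[:n_oars], seed=seed)


# ---------------------------------------------------------------------------
# reference library
# ---------------------------------------------------------------------------

def _jittered_spec(spec: PhantomSpec, jitter_mm: float, rng: np.random.Generator) -> PhantomSpec:
    """Perturb each non-external structure's boundary by at most ``jitter_mm``:
    the centre shift magnitude and the size change each use half the budget."""

    def center_delta():
        ang = rng.uniform(0.0, 2 * np.pi)
        mag = rng.uniform(0.0, jitter_mm / 2.0)
        return mag * np.array([np.cos(ang), np.sin(ang)])

    dr = rng.uniform(-jitter_mm / 2.0, jitter_mm / 2.0)
    dc = center_delta()
    new_spec = replace(
        spec,
        ptv_radius_mm=max(spec.ptv_radius_mm + dr, spec.voxel_size_mm),
        ptv_center_offset_mm=tuple(np.asarray(spec.ptv_center_offset_mm) + dc),
        oar_specs=[],
    )
    oars = []
    for oar in spec.oar_specs:
        dro = rng.uniform(-jitter_mm / 2.0, jitter_mm / 2.0)
        dco = center_delta()
        a, b = oar.semi_axes()
        size = (
            max(a + dro, spec.voxel_size_mm)
            if oar.shape == "circle"
            else (max(a + dro, spec.voxel_size_mm), max(b + dro, spec.voxel_size_mm))
        )
        oars.append(
            replace(
                oar,
                center_offset_mm=tuple(np.asarray(oar.center_offset_mm) + dco),
                size_mm=size,
            )
        )
    return replace(new_spec, oar_specs=oars)


def generate_reference_library(
    base_spec: PhantomSpec,
    n_cases: int,
    jitter_mm: float,
    seed: int,
    site: str = "phantom",
    base_params: PlanParameters | None = None,
    beam: PencilBeamConfig | None = None,
    opt_config: OptimizerConfig | None = None,
    dvh_resolution_gy: float = DEFAULT_RESOLUTION_GY,
) -> list[ReferenceCase]:
    """Emulate a library of previously treated patients.

    Each case perturbs the base geometry by at most ``jitter_mm`` and runs the
    inner optimizer to convergence on its own geometry, so each stored DVH is
    achievable where it was planned.
    """
    if n_cases < 1:
        raise ValueError("need at least one library case")
    if jitter_mm < 0:
        raise ValueError("jitter must be nonnegative")
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        spec_i = _jittered_spec(base_spec, jitter_mm, rng)
        sset, influence, rx = generate_phantom(spec_i, beam)
        params = (base_params or default_plan_parameters(sset, rx)).copy()
        fluence, trace = dose_engine.optimize(
            params, influence, sset, config=opt_config
        )
        dose = compute_dose(fluence, influence)
        dvhs = {
            s.name: compute_dvh(dose, s.mask, dvh_resolution_gy, name=s.name)
            for s in sset.structures
            if s.role != "external"
        }
        case = ReferenceCase(
            case_id=f"ref{i:03d}",
            site=site,
            structures=sset,
            prescription=rx,
            params=params,
            dvhs=dvhs,
            fluence=fluence,
            spec=spec_i,
        )
        case.validate()
        cases.append(case)
    return cases


# ---------------------------------------------------------------------------
# plain-text serialization: specs, cases and libraries
# ---------------------------------------------------------------------------

def write_phantom_spec(spec: PhantomSpec, path: str | Path) -> None:
    data = {
        "grid_shape": [int(v) for v in spec.grid_shape],
        "voxel_size_mm": float(spec.voxel_size_mm),
        "ptv_radius_mm": float(spec.ptv_radius_mm),
        "ptv_center_offset_mm": [float(v) for v in spec.ptv_center_offset_mm],
        "oar_specs": [
            {
                "name": o.name,
                "center_offset_mm": [float(v) for v in o.center_offset_mm],
                "size_mm": [float(v) for v in o.size_mm]
                if isinstance(o.size_mm, tuple)
                else float(o.size_mm),
                "shape": o.shape,
            }
            for o in spec.oar_specs
        ],
        "beam_angles_deg": [float(v) for v in spec.beam_angles_deg],
        "beamlets_per_beam": int(spec.beamlets_per_beam),
        "external_radius_mm": None
        if spec.external_radius_mm is None
        else float(spec.external_radius_mm),
        "prescription_dose_gy": float(spec.prescription_dose_gy),
        "fractions": int(spec.fractions),
        "seed": int(spec.seed),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_phantom_spec(path: str | Path) -> PhantomSpec:
    d = yaml.safe_load(Path(path).read_text())
    oars = [
        OARSpec(
            name=o["name"],
            center_offset_mm=tuple(o["center_offset_mm"]),
            size_mm=tuple(o["size_mm"]) if isinstance(o["size_mm"], list) else o["size_mm"],
            shape=o.get("shape", "circle"),
        )
        for o in d.get("oar_specs", [])
    ]
    return PhantomSpec(
        grid_shape=tuple(d["grid_shape"]),
        voxel_size_mm=d["voxel_size_mm"],
        ptv_radius_mm=d["ptv_radius_mm"],
        ptv_center_offset_mm=tuple(d.get("ptv_center_offset_mm", (0.0, 0.0))),
        oar_specs=oars,
        beam_angles_deg=list(d["beam_angles_deg"]),
        beamlets_per_beam=d["beamlets_per_beam"],
        external_radius_mm=d.get("external_radius_mm"),
        prescription_dose_gy=d.get("prescription_dose_gy", 50.0),
        fractions=d.get("fractions", 25),
        seed=d.get("seed", 0),
    )


def save_case(case: PlanningCase, directory: str | Path) -> None:
    """Case directory: contours + prescription + meta + the generating spec."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_contours(case.structures, d / "contours.txt")
    (d / "meta.yaml").write_text(
        yaml.safe_dump({"case_id": case.case_id, "site": case.site}, sort_keys=True)
    )
    (d / "prescription.yaml").write_text(
        yaml.safe_dump(
            {"dose_gy": case.prescription.dose_gy, "fractions": case.prescription.fractions},
            sort_keys=True,
        )
    )
    if case.spec is not None:
        write_phantom_spec(case.spec, d / "phantom_spec.yaml")


def load_case(directory: str | Path, beam: PencilBeamConfig | None = None) -> PlanningCase:
    """Rebuild a planning case (including its influence matrix) from a case directory."""
    d = Path(directory)
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    spec = read_phantom_spec(d / "phantom_spec.yaml")
    case = make_case(spec, case_id=meta["case_id"], site=meta["site"], beam=beam)
    return case


def save_reference_case(case: ReferenceCase, directory: str | Path) -> None:
    """One subdirectory per case: contours, prescription, parameters, DVH file, fluence."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_contours(case.structures, d / "contours.txt")
    (d / "meta.yaml").write_text(
        yaml.safe_dump({"case_id": case.case_id, "site": case.site}, sort_keys=True)
    )
    (d / "prescription.yaml").write_text(
        yaml.safe_dump(
            {"dose_gy": case.prescription.dose_gy, "fractions": case.prescription.fractions},
            sort_keys=True,
        )
    )
    write_parameters(case.params, d / "parameters.yaml")
    write_dvh_file(
        [case.dvhs[k] for k in sorted(case.dvhs)], d / "dvh.txt"
    )
    if case.fluence is not None:
        np.savetxt(d / "fluence.txt", case.fluence)
    if case.spec is not None:
        write_phantom_spec(case.spec, d / "phantom_spec.yaml")


def load_reference_case(directory: str | Path) -> ReferenceCase:
    d = Path(directory)
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    rx_d = yaml.safe_load((d / "prescription.yaml").read_text())
    sset = read_contours(d / "contours.txt")
    params = read_parameters(d / "parameters.yaml")
    curves = read_dvh_file(d / "dvh.txt")
    fluence = None
    if (d / "fluence.txt").exists():
        fluence = np.loadtxt(d / "fluence.txt")
    spec = None
    if (d / "phantom_spec.yaml").exists():
        spec = read_phantom_spec(d / "phantom_spec.yaml")
    case = ReferenceCase(
        case_id=meta["case_id"],
        site=meta["site"],
        structures=sset,
        prescription=Prescription(rx_d["dose_gy"], rx_d["fractions"]),
        params=params,
        dvhs={c.structure: c for c in curves},
        fluence=fluence,
        spec=spec,
    )
    case.validate()
    return case


def save_library(cases: list[ReferenceCase], directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for case in cases:
        save_reference_case(case, d / case.case_id)


def load_library(directory: str | Path) -> list[ReferenceCase]:
    d = Path(directory)
    subdirs = sorted(p for p in d.iterdir() if p.is_dir())
    if not subdirs:
        raise ValueError(f"no reference cases found under {d}")
    return [load_reference_case(p) for p in subdirs]
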