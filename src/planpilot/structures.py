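"""Structure-set geometry for inverse treatment planning.

A planning case is described by named structures (one target, any number of
organs at risk, exactly one external/body contour) living on a shared regular
voxel grid.  Each structure carries two coupled representations:

* a boolean voxel mask (row-major, ``(ny, nx)``), and
* a closed polygon contour in physical millimetres.

Conventions: voxel indices are 0-based; the physical coordinate of voxel
``(row, col)`` is its centre, ``x = (col + 0.5) * voxel_size_mm`` and
``y = (row + 0.5) * voxel_size_mm``.  Contours are ``(k, 2)`` arrays of
``(x, y)`` vertices in mm with the first vertex repeated at the end.

Also implemented here are the planning-room structure operations: Boolean
combinations of masks (``and``, ``or``, ``xor``, ``sub``, ``not``) and the
conversion of an isodose level into a structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import shapely
from shapely.geometry import Polygon
from skimage import measure

__all__ = [
    "GeometryError",
    "DegenerateGeometryError",
    "Structure",
    "StructureSet",
    "boolean_structure",
    "isodose_to_structure",
    "center_of_mass",
    "mask_to_contour",
    "contour_to_mask",
    "structure_volume_cc",
    "write_contours",
    "read_contours",
    "write_mask",
    "read_mask",
]

ROLES = ("target", "oar", "external")
BOOLEAN_OPS = ("and", "or", "xor", "sub", "not")


class GeometryError(ValueError):
    """Invalid or inconsistent structure geometry."""


class DegenerateGeometryError(GeometryError):
    """Geometry that makes the planning problem ill-posed (e.g. target/OAR overlap)."""


# ---------------------------------------------------------------------------
# mask <-> contour conversion
# ---------------------------------------------------------------------------

def mask_to_contour(mask: np.ndarray, voxel_size_mm: float) -> np.ndarray:
    """Extract the closed boundary polygon (mm) of a connected boolean mask.

    The contour is traced at the half-level between voxel centres, so
    rasterising it again with :func:`contour_to_mask` reproduces the mask
    exactly on the generating grid.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise GeometryError("cannot contour an empty mask")
    padded = np.pad(mask, 1).astype(float)
    loops = measure.find_contours(padded, 0.5)
    if not loops:  # pragma: no cover - unreachable for nonempty masks
        raise GeometryError("no boundary found")
    # keep the outermost loop (largest enclosed area)
    best, best_area = None, -1.0
    for loop in loops:
        rc = loop - 1.0  # undo padding
        xy = np.column_stack([(rc[:, 1] + 0.5), (rc[:, 0] + 0.5)]) * voxel_size_mm
        area = abs(Polygon(xy).area) if len(xy) >= 3 else 0.0
        if area > best_area:
            best, best_area = xy, area
    if best_area <= 0:
        raise GeometryError("degenerate (zero-area) boundary")
    return best


def contour_to_mask(
    contour: np.ndarray, grid_shape: tuple[int, int], voxel_size_mm: float
) -> np.ndarray:
    """Rasterise a closed polygon (mm) onto the grid: voxel centres inside."""
    poly = Polygon(np.asarray(contour, dtype=float))
    if not poly.is_valid or poly.area == 0:
        raise GeometryError("degenerate (zero-area or self-intersecting) contour")
    ny, nx = grid_shape
    xs = (np.arange(nx) + 0.5) * voxel_size_mm
    ys = (np.arange(ny) + 0.5) * voxel_size_mm
    X, Y = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, X.ravel(), Y.ravel())
    return inside.reshape(ny, nx)


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """A named anatomical structure: role, voxel mask and polygon contour."""

    name: str
    role: str
    mask: np.ndarray
    contour: np.ndarray

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        self.mask = np.asarray(self.mask, dtype=bool)
        self.contour = np.asarray(self.contour, dtype=float)

    @classmethod
    def from_mask(cls, name: str, role: str, mask: np.ndarray, voxel_size_mm: float) -> "Structure":
        return cls(name, role, mask, mask_to_contour(mask, voxel_size_mm))


@dataclass
class StructureSet:
    """All structures of one case on a shared grid."""

    voxel_size_mm: float
    structures: list[Structure] = field(default_factory=list)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return tuple(self.structures[0].mask.shape)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.structures]

    def __getitem__(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(f"no structure named {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.structures)

    @property
    def external(self) -> Structure:
        ext = [s for s in self.structures if s.role == "external"]
        if len(ext) != 1:
            raise GeometryError(f"expected exactly one external structure, found {len(ext)}")
        return ext[0]

    @property
    def targets(self) -> list[Structure]:
        return [s for s in self.structures if s.role == "target"]

    @property
    def oars(self) -> list[Structure]:
        return [s for s in self.structures if s.role == "oar"]

    def validate(self) -> None:
        """Enforce the structure-set invariants."""
        if len(set(self.names)) != len(self.names):
            raise GeometryError("structure names must be unique")
        ext = self.external  # checks exactly-one
        shapes = {s.mask.shape for s in self.structures}
        if len(shapes) != 1:
            raise GeometryError(f"masks on inconsistent grids: {shapes}")
        if not self.targets or not any(t.mask.any() for t in self.targets):
            raise GeometryError("target mask must be nonempty")
        for s in self.structures:
            if s is ext:
                continue
            if np.any(s.mask & ~ext.mask):
                raise GeometryError(f"structure {s.name!r} extends outside the external contour")


# ---------------------------------------------------------------------------
# planning-room operations
# ---------------------------------------------------------------------------

def boolean_structure(
    a: np.ndarray,
    b: np.ndarray | None,
    op: str,
    external: np.ndarray | None = None,
) -> np.ndarray:
    """Combine two masks with set algebra.

    ``op`` is one of ``and``, ``or``, ``xor``, ``sub``, ``not``.  ``not``
    ignores ``b`` and complements within the external contour (structures are
    anatomy-bounded, so the complement of a structure is "everything else in
    the patient", not the whole grid).  The result is always clipped to the
    external mask when one is given.
    """
    a = np.asarray(a, dtype=bool)
    if op not in BOOLEAN_OPS:
        raise ValueError(f"unknown Boolean op {op!r}; expected one of {BOOLEAN_OPS}")
    ext = None if external is None else np.asarray(external, dtype=bool)
    if ext is not None and ext.shape != a.shape:
        raise ValueError(f"external grid {ext.shape} does not match mask grid {a.shape}")
    if op == "not":
        if ext is None:
            raise ValueError("'not' requires an external mask to complement within")
        result = ~a
    else:
        if b is None:
            raise ValueError(f"op {op!r} requires a second mask")
        b = np.asarray(b, dtype=bool)
        if b.shape != a.shape:
            raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
        if op == "and":
            result = a & b
        elif op == "or":
            result = a | b
        elif op == "xor":
            result = a ^ b
        else:  # sub
            result = a & ~b
    if ext is not None:
        result = result & ext
    return result


def isodose_to_structure(dose: np.ndarray, level_gy: float) -> np.ndarray:
    """Convert an isodose level into a structure mask (dose >= level, inclusive)."""
    if level_gy <= 0:
        raise ValueError(f"isodose level must be positive, got {level_gy}")
    return np.asarray(dose, dtype=float) >= level_gy


def center_of_mass(mask: np.ndarray, voxel_size_mm: float) -> np.ndarray:
    """Unweighted centroid of the voxel centres of a mask, in physical mm."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("center of mass of an empty mask is undefined")
    x = (cols.mean() + 0.5) * voxel_size_mm
    y = (rows.mean() + 0.5) * voxel_size_mm
    return np.array([x, y])


def structure_volume_cc(
    mask: np.ndarray, voxel_size_mm: float, slice_thickness_mm: float | None = None
) -> float:
    """Physical volume of a 2D-slice mask in cc (slice thickness defaults to the voxel size)."""
    t = voxel_size_mm if slice_thickness_mm is None else slice_thickness_mm
    return float(np.count_nonzero(mask)) * voxel_size_mm**2 * t / 1000.0


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------

def write_contours(sset: StructureSet, path: str | Path) -> None:
    """Write a structure set as a plain-text contour file.

    Format: a two-line grid header, then one block per structure —
    ``structure: <name>`` / ``role: <role>`` followed by one ``x,y`` (mm)
    vertex per line; blocks separated by blank lines.
    """
    ny, nx = sset.grid_shape
    lines = [f"grid_shape: {ny} {nx}", f"voxel_size_mm: {float(sset.voxel_size_mm)!r}"]
    for s in sset.structures:
        lines.append("")
        lines.append(f"structure: {s.name}")
        lines.append(f"role: {s.role}")
        lines.extend(f"{float(x)!r},{float(y)!r}" for x, y in s.contour)
    Path(path).write_text("\n".join(lines) + "\n")


def read_contours(path: str | Path) -> StructureSet:
    """Read a contour file and rebuild the structure set (masks rasterised from contours)."""
    text = Path(path).read_text().splitlines()
    grid_shape = None
    voxel_size = None
    blocks: list[tuple[str, str, list[list[float]]]] = []
    current: tuple[str, str, list[list[float]]] | None = None
    for i, raw in enumerate(text, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("grid_shape:"):
            ny, nx = line.split(":", 1)[1].split()
            grid_shape = (int(ny), int(nx))
        elif line.startswith("voxel_size_mm:"):
            voxel_size = float(line.split(":", 1)[1])
        elif line.startswith("structure:"):
            current = (line.split(":", 1)[1].strip(), "", [])
            blocks.append(current)
        elif line.startswith("role:"):
            if current is None:
                raise GeometryError(f"line {i}: role before any structure")
            blocks[-1] = (current[0], line.split(":", 1)[1].strip(), current[2])
            current = blocks[-1]
        else:
            if current is None:
                raise GeometryError(f"line {i}: vertex before any structure header")
            try:
                x, y = (float(v) for v in line.split(","))
            except ValueError as exc:
                raise GeometryError(f"line {i}: malformed vertex {line!r}") from exc
            current[2].append([x, y])
    if grid_shape is None or voxel_size is None:
        raise GeometryError("contour file is missing the grid header")
    structures = []
    for name, role, verts in blocks:
        contour = np.asarray(verts, dtype=float)
        mask = contour_to_mask(contour, grid_shape, voxel_size)
        structures.append(Structure(name, role, mask, contour))
    return StructureSet(voxel_size_mm=voxel_size, structures=structures)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Serialise a boolean mask to a portable dense text file (0/1 grid)."""
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d")


def read_mask(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=int).astype(bool)
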