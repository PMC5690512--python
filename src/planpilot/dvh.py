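"""Cumulative dose-volume histograms, DVH statistics and the tabular export dialect.

The cumulative DVH of a structure gives, for every dose level ``d``, the
percentage of the structure's volume receiving at least ``d`` Gy (the ">="
convention, universal in clinical practice).  The curve is discretised on a
regular dose grid with a configurable bin width, capped by default at
0.001 Gy; the summary statistics Dmin/Dmax/Dmean in the curve header are
always computed from the raw voxel doses, not from the binned table.

For outer-loop plan comparison the inverse curve is sampled at ``J`` fixed
volume-fraction control points ("segments"): segment ``j`` is the dose
``D_x`` at volume fraction ``x_j``, i.e. the minimum dose received by the
hottest ``x_j`` percent of the structure.  Two plans are compared segment by
segment.

File dialect (plain comma-separated text), one block per structure,
blocks separated by a blank line::

    Structure: <name>
    Dmin: <Gy>
    Dmax: <Gy>
    Dmean: <Gy>
    Dose[Gy],Volume[%]
    0.000000,100.000000
    ...

Round-tripping a curve through a file is lossless at the stored resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DVHCurve",
    "SegmentVector",
    "DVHParseError",
    "DEFAULT_RESOLUTION_GY",
    "DEFAULT_SEGMENT_FRACTIONS",
    "compute_dvh",
    "dvh_statistic",
    "sample_segments",
    "write_dvh_file",
    "read_dvh_file",
]

#: finest (and default) dose bin width of the discretised DVH table
DEFAULT_RESOLUTION_GY = 0.001

#: default volume-fraction control points for segment sampling (percent)
DEFAULT_SEGMENT_FRACTIONS = tuple(np.linspace(2.5, 97.5, 20))


class DVHParseError(ValueError):
    """Malformed DVH file."""


@dataclass
class DVHCurve:
    """Cumulative DVH of one structure plus raw-dose header statistics."""

    structure: str
    dose_gy: np.ndarray      # increasing bin edges starting at 0
    volume_pct: np.ndarray   # nonincreasing, volume_pct[0] == 100
    dmin_gy: float
    dmax_gy: float
    dmean_gy: float

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        self.volume_pct = np.asarray(self.volume_pct, dtype=float)
        if self.dose_gy.shape != self.volume_pct.shape:
            raise ValueError("dose and volume arrays differ in length")

    @property
    def resolution_gy(self) -> float:
        return float(self.dose_gy[1] - self.dose_gy[0])


@dataclass
class SegmentVector:
    """Doses at fixed volume-fraction control points of one structure's DVH."""

    structure: str
    volume_fractions: np.ndarray  # strictly increasing, percent, in (0, 100)
    doses_gy: np.ndarray          # nonincreasing with increasing fraction

    def __post_init__(self) -> None:
        self.volume_fractions = np.asarray(self.volume_fractions, dtype=float)
        self.doses_gy = np.asarray(self.doses_gy, dtype=float)


def compute_dvh(
    dose: np.ndarray,
    mask: np.ndarray,
    resolution_gy: float = DEFAULT_RESOLUTION_GY,
    name: str = "",
) -> DVHCurve:
    """Cumulative DVH of the voxels of ``mask`` in the dose grid.

    ``volume_pct(d) = 100 * |{v in mask : dose_v >= d}| / |mask|``.  Bins run
    from 0 past the maximum dose so the curve always reaches 0.
    """
    if resolution_gy <= 0:
        raise ValueError("resolution must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot compute a DVH over an empty mask")
    voxel_doses = np.asarray(dose, dtype=float)[mask]
    n = voxel_doses.size
    dmax = float(voxel_doses.max())
    n_bins = int(np.floor(dmax / resolution_gy)) + 2
    bins = np.arange(n_bins) * resolution_gy
    sorted_doses = np.sort(voxel_doses)
    volume = 100.0 * (n - np.searchsorted(sorted_doses, bins, side="left")) / n
    return DVHCurve(
        structure=name,
        dose_gy=bins,
        volume_pct=volume,
        dmin_gy=float(voxel_doses.min()),
        dmax_gy=dmax,
        dmean_gy=float(voxel_doses.mean()),
    )


def dvh_statistic(curve: DVHCurve, kind: str, value: float) -> float:
    """Evaluate a V_x or D_x statistic on a DVH curve.

    * ``kind="V"``: volume percent receiving at least ``value`` Gy (linear
      interpolation between bins).
    * ``kind="D"``: minimum dose received by the hottest ``value`` percent of
      the volume — the inverse curve, interpolated.
    """
    if kind == "V":
        if value < 0 or value > curve.dose_gy[-1]:
            raise ValueError(
                f"V_x query {value} Gy outside the curve's dose range "
                f"[0, {curve.dose_gy[-1]:.3f}]"
            )
        return float(np.interp(value, curve.dose_gy, curve.volume_pct))
    if kind == "D":
        if value < 0 or value > 100:
            raise ValueError(f"D_x query {value}% outside [0, 100]")
        vol = curve.volume_pct
        idx = int(np.nonzero(vol >= value)[0][-1])  # vol[0] == 100 guarantees a hit
        if idx == len(vol) - 1:
            return float(curve.dose_gy[-1])
        v1, v2 = vol[idx], vol[idx + 1]
        d1, d2 = curve.dose_gy[idx], curve.dose_gy[idx + 1]
        return float(d1 + (d2 - d1) * (v1 - value) / (v1 - v2))
    raise ValueError(f"unknown DVH statistic kind {kind!r}; expected 'V' or 'D'")


def sample_segments(curve: DVHCurve, volume_fractions=DEFAULT_SEGMENT_FRACTIONS) -> SegmentVector:
    """Sample the inverse DVH at fixed volume fractions (percent, strictly increasing)."""
    fracs = np.asarray(volume_fractions, dtype=float)
    if fracs.size == 0:
        raise ValueError("volume_fractions must be nonempty")
    if np.any(fracs <= 0) or np.any(fracs >= 100):
        raise ValueError("volume fractions must lie strictly inside (0, 100)")
    if fracs.size > 1 and np.any(np.diff(fracs) <= 0):
        raise ValueError("volume fractions must be strictly increasing")
    doses = np.array([dvh_statistic(curve, "D", f) for f in fracs])
    return SegmentVector(curve.structure, fracs, doses)


# ---------------------------------------------------------------------------
# file dialect
# ---------------------------------------------------------------------------

_HEADERS = ("Dmin", "Dmax", "Dmean")
_COLUMN_LINE = "Dose[Gy],Volume[%]"


def write_dvh_file(curves, path: str | Path) -> None:
    """Write curves in the per-structure block dialect described in the module docstring."""
    blocks = []
    seen = set()
    for c in curves:
        if c.structure in seen:
            raise ValueError(f"duplicate structure name {c.structure!r}")
        seen.add(c.structure)
        lines = [
            f"Structure: {c.structure}",
            f"Dmin: {c.dmin_gy:.6f}",
            f"Dmax: {c.dmax_gy:.6f}",
            f"Dmean: {c.dmean_gy:.6f}",
            _COLUMN_LINE,
        ]
        lines.extend(
            f"{d:.6f},{v:.6f}" for d, v in zip(c.dose_gy, c.volume_pct)
        )
        blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n")


def read_dvh_file(path: str | Path) -> list[DVHCurve]:
    """Parse a DVH file; raises :class:`DVHParseError` naming the offending line."""
    lines = Path(path).read_text().splitlines()
    curves: list[DVHCurve] = []
    names: set[str] = set()
    i, n = 0, len(lines)
    while i < n:
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("Structure:"):
            raise DVHParseError(f"line {i + 1}: expected 'Structure:' header, got {lines[i]!r}")
        name = lines[i].split(":", 1)[1].strip()
        if name in names:
            raise DVHParseError(f"line {i + 1}: duplicate structure name {name!r}")
        names.add(name)
        i += 1
        stats = {}
        for key in _HEADERS:
            if i >= n or not lines[i].startswith(f"{key}:"):
                raise DVHParseError(f"line {i + 1}: expected '{key}:' header")
            try:
                stats[key] = float(lines[i].split(":", 1)[1])
            except ValueError as exc:
                raise DVHParseError(f"line {i + 1}: malformed {key} value") from exc
            i += 1
        if i >= n or lines[i].strip() != _COLUMN_LINE:
            raise DVHParseError(f"line {i + 1}: expected column header {_COLUMN_LINE!r}")
        i += 1
        doses, vols = [], []
        while i < n and lines[i].strip():
            try:
                d, v = (float(x) for x in lines[i].split(","))
            except ValueError as exc:
                raise DVHParseError(f"line {i + 1}: malformed table row {lines[i]!r}") from exc
            doses.append(d)
            vols.append(v)
            i += 1
        if not doses:
            raise DVHParseError(f"line {i + 1}: structure {name!r} has an empty table")
        curves.append(
            DVHCurve(
                structure=name,
                dose_gy=np.array(doses),
                volume_pct=np.array(vols),
                dmin_gy=stats["Dmin"],
                dmax_gy=stats["Dmax"],
                dmean_gy=stats["Dmean"],
            )
        )
    return curves
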