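"""Ureter, stent and obstruction geometry, and obstruction-severity metrics.

The ureter lumen is described by inner diameters ``D_i`` measured at 16
equally spaced stations (``i = 0`` at the ureteropelvic junction, ``i = 15``
at the vesicoureteric junction).  A double-J stent of outer diameter ``D_s``
occupies part of the lumen; a drilled sphere lodged in the upper ureter
models a controlled occlusion.

Severity metrics
----------------
The occlusion severity is quantified from cross-sectional areas:

    OB%  = 100 * (1 - A_gap / A_sphere),     A_gap = A_PShole - A_s

where ``A_s`` is the stent cross-section, ``A_PShole`` the area of the hole
drilled through the sphere and ``A_sphere`` the sphere cross-section.
``OB% = 100`` means the stent fills the hole completely (no extra-luminal
flow past the obstruction).  The *distributed* obstruction caused by the
stent alone at station ``i`` follows by letting the "hole" be the local
lumen itself (``A_PShole = A_sphere = A_i``):

    OB_i% = 100 * A_s / A_i
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TextIO

import numpy as np

__all__ = [
    "UreterProfile",
    "StentSpec",
    "ObstructionSpec",
    "GeometryError",
    "circle_area",
    "circle_diameter",
    "obstruction_severity",
    "distributed_obstruction",
    "hole_area_for_severity",
    "read_profile",
    "write_profile",
]


class GeometryError(ValueError):
    """Invalid geometric configuration (non-physical dimensions)."""


def circle_area(diameter_mm: float) -> float:
    """Area pi*d^2/4 of a circle, mm^2 from mm (or any consistent units)."""
    if not diameter_mm > 0:
        raise GeometryError(f"diameter must be positive, got {diameter_mm}")
    return math.pi * diameter_mm**2 / 4.0


def circle_diameter(area_mm2: float) -> float:
    """Inverse of :func:`circle_area`."""
    if not area_mm2 > 0:
        raise GeometryError(f"area must be positive, got {area_mm2}")
    return math.sqrt(4.0 * area_mm2 / math.pi)


@dataclass(frozen=True)
class UreterProfile:
    """Inner-diameter profile of the ureter lumen.

    Parameters
    ----------
    diameters_mm
        Inner diameter at each station, proximal (UPJ) to distal (VUJ).
    length_mm
        Total conduit length.
    section_positions_mm
        Axial coordinate of each station, measured from the UPJ.  Defaults
        to equal spacing over ``[0, length_mm]``.
    """

    diameters_mm: tuple[float, ...]
    length_mm: float
    section_positions_mm: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        diams = tuple(float(d) for d in self.diameters_mm)
        object.__setattr__(self, "diameters_mm", diams)
        if len(diams) < 2:
            raise GeometryError("profile needs at least 2 stations")
        if any(d <= 0 for d in diams):
            raise GeometryError("all diameters must be positive")
        if not self.length_mm > 0:
            raise GeometryError("length must be positive")
        if not self.section_positions_mm:
            pos = tuple(np.linspace(0.0, self.length_mm, len(diams)))
        else:
            pos = tuple(float(x) for x in self.section_positions_mm)
        if len(pos) != len(diams):
            raise GeometryError("positions and diameters differ in length")
        if pos[0] != 0.0 or abs(pos[-1] - self.length_mm) > 1e-9:
            raise GeometryError("positions must span [0, length_mm]")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise GeometryError("positions must be strictly increasing")
        object.__setattr__(self, "section_positions_mm", pos)

    @property
    def n_sections(self) -> int:
        return len(self.diameters_mm)

    @property
    def areas_mm2(self) -> tuple[float, ...]:
        return tuple(circle_area(d) for d in self.diameters_mm)

    @property
    def min_diameter_mm(self) -> float:
        return min(self.diameters_mm)

    def diameter_at(self, x_mm: float) -> float:
        """Piecewise-linear interpolation of the diameter at axial x."""
        if not 0.0 <= x_mm <= self.length_mm + 1e-9:
            raise GeometryError(f"x={x_mm} outside [0, {self.length_mm}] mm")
        return float(
            np.interp(x_mm, self.section_positions_mm, self.diameters_mm)
        )


@dataclass(frozen=True)
class StentSpec:
    """Double-J stent geometry.

    ``first_hole_offset_mm`` is the axial coordinate (from the UPJ, i.e. the
    pelvis end of the conduit) of the first side hole; side holes repeat
    every ``hole_spacing_mm``.  Negative offsets place the leading holes in
    the renal-pelvis curl of the stent.
    """

    inner_diameter_mm: float = 1.28
    outer_diameter_mm: float = 2.08
    length_mm: float = 410.0
    hole_diameter_mm: float = 0.8
    hole_spacing_mm: float = 10.0
    first_hole_offset_mm: float = -35.0

    def __post_init__(self) -> None:
        if not 0 < self.inner_diameter_mm < self.outer_diameter_mm:
            raise GeometryError("need 0 < inner diameter < outer diameter")
        if self.hole_diameter_mm > self.inner_diameter_mm:
            raise GeometryError("hole diameter exceeds stent inner diameter")
        if self.length_mm <= 0 or self.hole_spacing_mm <= 0:
            raise GeometryError("length and hole spacing must be positive")

    @property
    def cross_section_mm2(self) -> float:
        """Outer cross-sectional area A_s (the lumen area it occupies)."""
        return circle_area(self.outer_diameter_mm)

    @property
    def lumen_area_mm2(self) -> float:
        return circle_area(self.inner_diameter_mm)

    @property
    def wall_thickness_mm(self) -> float:
        return (self.outer_diameter_mm - self.inner_diameter_mm) / 2.0

    def hole_positions_mm(self, up_to_mm: float) -> list[float]:
        """Axial hole coordinates from the first hole up to ``up_to_mm``."""
        pos: list[float] = []
        x = self.first_hole_offset_mm
        while x < up_to_mm - 1e-9:
            pos.append(x)
            x += self.hole_spacing_mm
        return pos


@dataclass(frozen=True)
class ObstructionSpec:
    """A drilled sphere lodged in the ureter, threaded on the stent.

    ``hole_area_mm2`` (A_PShole) is the area of the drilled passage; the
    annular gap left around the stent is ``A_gap = A_PShole - A_s``.
    """

    sphere_diameter_mm: float = 6.07
    hole_area_mm2: float = circle_area(2.08)
    axial_position_index: int = 0

    def __post_init__(self) -> None:
        if self.sphere_diameter_mm <= 0:
            raise GeometryError("sphere diameter must be positive")
        if self.hole_area_mm2 <= 0:
            raise GeometryError("hole area must be positive")

    @property
    def sphere_area_mm2(self) -> float:
        return circle_area(self.sphere_diameter_mm)

    def gap_area_mm2(self, stent: StentSpec) -> float:
        gap = self.hole_area_mm2 - stent.cross_section_mm2
        if gap < -1e-12:
            raise GeometryError(
                "sphere hole is smaller than the stent cross-section "
                f"({self.hole_area_mm2:.4g} < {stent.cross_section_mm2:.4g} mm^2)"
            )
        return max(gap, 0.0)


def obstruction_severity(
    hole_area_mm2: float, sphere_area_mm2: float, stent_area_mm2: float
) -> float:
    """Severity OB% of a sphere-with-hole occlusion, in [0, 100].

    ``OB% = 100 * (1 - (A_PShole - A_s) / A_sphere)``.  Equals 100 when the
    stent exactly fills the hole (zero annular gap) and ``100*A_s/A_sphere``
    when the hole is as large as the sphere itself.
    """
    if hole_area_mm2 < stent_area_mm2 - 1e-12:
        raise GeometryError(
            f"hole area {hole_area_mm2:.4g} mm^2 smaller than stent area "
            f"{stent_area_mm2:.4g} mm^2: stent cannot pass through"
        )
    if hole_area_mm2 > sphere_area_mm2 + 1e-12:
        raise GeometryError(
            f"hole area {hole_area_mm2:.4g} mm^2 exceeds sphere area "
            f"{sphere_area_mm2:.4g} mm^2"
        )
    gap = max(hole_area_mm2 - stent_area_mm2, 0.0)
    return 100.0 * (1.0 - gap / sphere_area_mm2)


def hole_area_for_severity(
    ob_percent: float, sphere_area_mm2: float, stent_area_mm2: float
) -> float:
    """Hole area realising a requested OB% (inverse of the severity formula)."""
    ob_min = 100.0 * stent_area_mm2 / sphere_area_mm2
    if not ob_min - 1e-9 <= ob_percent <= 100.0 + 1e-9:
        raise GeometryError(
            f"OB%={ob_percent} unattainable; attainable interval is "
            f"[{ob_min:.4g}, 100] for this sphere/stent pairing"
        )
    return stent_area_mm2 + sphere_area_mm2 * (1.0 - ob_percent / 100.0)


def distributed_obstruction(
    profile: UreterProfile, stent_area_mm2: float
) -> list[float]:
    """Stent-only obstruction severity OB_i% = 100*A_s/A_i per station.

    Maximal at the narrowest station; raises if the stent does not fit.
    """
    out: list[float] = []
    for i, area in enumerate(profile.areas_mm2):
        if area < stent_area_mm2 - 1e-12:
            raise GeometryError(
                f"stent (A_s={stent_area_mm2:.4g} mm^2) does not fit lumen "
                f"section i={i} (A_i={area:.4g} mm^2)"
            )
        out.append(100.0 * stent_area_mm2 / area)
    return out


# -- profile serialisation ---------------------------------------------------

_LENGTH_RE = re.compile(r"#\s*length_mm\s*=\s*([0-9.eE+-]+)")


def read_profile(source: str | Path | TextIO) -> UreterProfile:
    """Read a ureter profile from CSV with columns ``index,diameter_mm``.

    An optional comment line ``# length_mm=<value>`` carries the conduit
    length; without it the length defaults to 289 mm.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    length_mm = 289.0
    rows: dict[int, float] = {}
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _LENGTH_RE.match(line)
            if m:
                length_mm = float(m.group(1))
            continue
        if not header_seen:
            cols = [c.strip().lower() for c in line.split(",")]
            if cols[:2] != ["index", "diameter_mm"]:
                raise GeometryError(
                    f"row {lineno}: expected header 'index,diameter_mm'"
                )
            header_seen = True
            continue
        parts = line.split(",")
        try:
            idx = int(parts[0])
            diam = float(parts[1])
        except (ValueError, IndexError) as exc:
            raise GeometryError(f"row {lineno}: cannot parse {line!r}") from exc
        if idx in rows:
            raise GeometryError(f"row {lineno}: duplicate index {idx}")
        rows[idx] = diam
    if not rows:
        raise GeometryError("no data rows found")
    indices = sorted(rows)
    if indices != list(range(len(indices))):
        missing = sorted(set(range(max(indices) + 1)) - set(indices))
        raise GeometryError(f"missing indices {missing}")
    return UreterProfile(
        diameters_mm=tuple(rows[i] for i in indices), length_mm=length_mm
    )


def write_profile(profile: UreterProfile, dest: str | Path | TextIO) -> None:
    """Write a profile in the format accepted by :func:`read_profile`."""
    buf = io.StringIO()
    buf.write(f"# length_mm={profile.length_mm!r}\n")
    buf.write("index,diameter_mm\n")
    for i, d in enumerate(profile.diameters_mm):
        buf.write(f"{i},{d!r}\n")
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(buf.getvalue())
    else:
        dest.write(buf.getvalue())
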