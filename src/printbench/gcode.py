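"""Volumetrically calibrated G-code serialization.

With the "diameter trick" — declaring a theoretical filament diameter of
2/sqrt(pi) = 1.12838 mm so the implied cross-section is exactly 1 mm^2 —
every millimetre of commanded E travel corresponds to exactly 1 mm^3 of
material.  A positive-displacement pump whose rotation distance is set to
10 mm^3 per revolution then executes a 10 mm E command as one full motor
turn, so extrusion volumes can be prescribed directly in the toolpath with
no slicer-side conversion factors.

Dialect: absolute XY (G90), absolute E (M82), millimetre units (G21),
feedrate in mm/min, 4-decimal coordinate and E formatting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .patterns import Toolpath

__all__ = ["VolumetricCalibration", "effective_unit_diameter", "to_gcode", "parse_gcode"]


def effective_unit_diameter() -> float:
    """Filament diameter whose cross-sectional area is exactly 1 mm^2.

    pi * (d/2)^2 = 1  =>  d = 2/sqrt(pi) = 1.12838 mm (5-decimal rounding).
    """
    return 2.0 / math.sqrt(math.pi)


@dataclass(frozen=True)
class VolumetricCalibration:
    """Unit-volume E-value calibration of a positive-displacement extruder.

    ``filament_diameter`` is the theoretical diameter declared to the motion
    stack (mm); ``rotation_distance`` the extruded volume per motor
    revolution (mm^3/rev); ``extrusion_factor`` the commanded fraction of the
    theoretical volumetric flow (1.0 = nominal dosing, < 1 deliberate
    under-extrusion to compensate die swell).
    """

    filament_diameter: float = 2.0 / math.sqrt(math.pi)
    rotation_distance: float = 10.0
    extrusion_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.filament_diameter <= 0:
            raise ValueError("filament_diameter must be positive")
        if self.rotation_distance <= 0:
            raise ValueError("rotation_distance must be positive")
        if not (0.0 < self.extrusion_factor <= 1.0):
            raise ValueError("extrusion_factor must be in (0, 1]")

    @property
    def cross_section_area(self) -> float:
        """Implied filament cross-section in mm^2 (1.0 for the unit diameter)."""
        return math.pi * (self.filament_diameter / 2.0) ** 2

    def revolutions_for(self, e_mm3: float) -> float:
        return e_mm3 / self.rotation_distance


def to_gcode(t: Toolpath, cal: VolumetricCalibration, speed: float = 20.0,
             layer_height: float | None = None, travel_speed: float = 60.0) -> str:
    """Serialize a toolpath as volumetrically calibrated G-code text.

    For each extrude segment the E increment is
    ``length * commanded_width * layer_height * extrusion_factor`` in mm^3;
    because 1 E-unit = 1 mm^3 under the unit-area calibration, E directly
    accumulates deposited volume.  Travel segments emit no E.  ``speed`` and
    ``travel_speed`` are mm/s, emitted as mm/min feedrates.
    """
    if layer_height is None:
        layer_height = t.metadata.get("layer_height")
    if layer_height is None or layer_height <= 0:
        raise ValueError("a positive layer_height is required (argument or toolpath metadata)")
    if np.any(t.widths[t.extrude] <= 0):
        raise ValueError("extrude segments must carry a positive commanded width")

    lengths = t.segment_lengths()
    lines = [
        "; printbench benchmark toolpath",
        f"; pattern: {t.metadata.get('pattern', 'unknown')}",
        f"; calibration: filament_diameter={cal.filament_diameter:.5f} mm "
        f"(cross-section {cal.cross_section_area:.6f} mm^2), "
        f"rotation_distance={cal.rotation_distance:.4f} mm^3/rev, "
        f"extrusion_factor={cal.extrusion_factor:.4f}",
        f"; layer_height: {layer_height:.4f} mm",
        "G21 ; millimetre units",
        "G90 ; absolute XY",
        "M82 ; absolute E",
        "G92 E0",
    ]
    x0, y0 = t.vertices[0]
    lines.append(f"G0 X{x0:.4f} Y{y0:.4f} Z{layer_height:.4f} F{travel_speed * 60:.0f}")
    e = 0.0
    current_layer = 0
    for i in range(len(t.extrude)):
        x, y = t.vertices[i + 1]
        layer = int(t.layers[i])
        if layer != current_layer:
            lines.append(f"G1 Z{(layer + 1) * layer_height:.4f} F{travel_speed * 60:.0f}")
            current_layer = layer
        if t.extrude[i]:
            e += lengths[i] * t.widths[i] * layer_height * cal.extrusion_factor
            lines.append(f"G1 X{x:.4f} Y{y:.4f} E{e:.4f} F{speed * 60:.0f}")
        else:
            lines.append(f"G0 X{x:.4f} Y{y:.4f} F{travel_speed * 60:.0f}")
    lines.append(f"; total extruded volume: {e:.4f} mm^3 "
                 f"({cal.revolutions_for(e):.4f} pump revolutions)")
    return "\n".join(lines) + "\n"


def parse_gcode(text: str) -> dict:
    """Minimal G-code reader for round-trip checks.

    Returns vertices (list of (x, y)), the absolute E value after each move,
    and per-move extrude flags.  Only G0/G1 X/Y/E words are interpreted.
    """
    xs: list[tuple[float, float]] = []
    e_values: list[float] = []
    extrude_flags: list[bool] = []
    x = y = e = 0.0
    for raw in text.splitlines():
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        words = line.split()
        if words[0] not in ("G0", "G1"):
            if words[0] == "G92":
                for w in words[1:]:
                    if w.startswith("E"):
                        e = float(w[1:])
            continue
        new_e = e
        moved = False
        for w in words[1:]:
            if w.startswith("X"):
                x = float(w[1:])
                moved = True
            elif w.startswith("Y"):
                y = float(w[1:])
                moved = True
            elif w.startswith("E"):
                new_e = float(w[1:])
        if not moved:
            continue
        xs.append((x, y))
        extrude_flags.append(new_e > e)
        e = new_e
        e_values.append(e)
    return {"vertices": xs, "e_values": e_values, "extrude": extrude_flags}
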