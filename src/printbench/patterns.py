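"""Benchmark toolpath generation for extrusion-bioprinting print-quality tests.

The four canonical test geometries are procedurally generated as planar
polylines with per-segment extrusion metadata:

* a frequency-modulated ("chirped") square-wave serpentine for the filament
  fusion test, where the spacing between successive vertical legs shrinks
  with |x| so a single print sweeps a whole range of line spacings;
* a square lattice grid whose pores probe the printability index and
  porosity;
* a single straight line crossing a pillar fixture with increasing gap
  spans, for the filament collapse test;
* a plain straight line for width/uniformity measurements.

All lengths are millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ChirpParams",
    "GridParams",
    "CollapseFixture",
    "Toolpath",
    "chirped_square_wave",
    "square_wave_roots",
    "serpentine_toolpath",
    "grid_toolpath",
    "collapse_toolpath",
    "line_toolpath",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class ChirpParams:
    """Parameters of the chirped square wave  f(x) = A * sgn(sin(F * |x|^n)).

    ``amplitude`` is the rail offset A (mm), ``base_freq`` the base angular
    frequency F (rad / mm^n), ``chirp_rate`` the exponent n that compresses
    the period with |x|, ``x_range`` the closed interval swept, and
    ``sample_step`` the coarse sampling used to sanity-check that no sign
    change of the inner sinusoid can be skipped between samples.
    """

    amplitude: float = 10.0
    base_freq: float = 0.05
    chirp_rate: float = 2.1
    x_range: tuple[float, float] = (0.0, 50.0)
    sample_step: float = 0.05

    def __post_init__(self) -> None:
        if not (self.amplitude > 0 and self.base_freq > 0 and self.chirp_rate > 0):
            raise ValueError("amplitude, base_freq and chirp_rate must be positive")
        if self.sample_step <= 0:
            raise ValueError("sample_step must be positive")
        x0, x1 = self.x_range
        if not (math.isfinite(x0) and math.isfinite(x1)) or x1 <= x0:
            raise ValueError("x_range must be a finite, increasing interval")
        if x0 < 0:
            raise ValueError("x_range must lie in x >= 0 (the pattern is mirrored in |x|)")


@dataclass(frozen=True)
class GridParams:
    """Square-lattice scaffold layer: ``outer_size`` per side, strands every
    ``pore_pitch`` in both directions, stacked ``n_layers`` times."""

    outer_size: float = 30.0
    pore_pitch: float = 5.0
    n_layers: int = 2
    layer_height: float = 0.51
    commanded_line_width: float = 0.41

    def __post_init__(self) -> None:
        if self.pore_pitch <= 0 or self.outer_size <= 0:
            raise ValueError("outer_size and pore_pitch must be positive")
        if self.pore_pitch > self.outer_size:
            raise ValueError("pore_pitch exceeds outer_size")
        ratio = self.outer_size / self.pore_pitch
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("outer_size must be an integer multiple of pore_pitch")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.layer_height <= 0:
            raise ValueError("layer_height must be positive")
        if self.commanded_line_width <= 0:
            raise ValueError("commanded_line_width must be positive")

    @property
    def lines_per_direction(self) -> int:
        return int(round(self.outer_size / self.pore_pitch)) + 1

    @property
    def n_pores(self) -> int:
        return (self.lines_per_direction - 1) ** 2


@dataclass(frozen=True)
class CollapseFixture:
    """Pillar fixture for the filament collapse test: a row of pillars of
    ``pillar_width`` separated by the (strictly increasing) ``gap_list``."""

    gap_list: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)
    pillar_width: float = 2.0
    pillar_height: float = 10.0

    def __post_init__(self) -> None:
        gaps = tuple(float(g) for g in self.gap_list)
        object.__setattr__(self, "gap_list", gaps)
        if len(gaps) == 0:
            raise ValueError("gap_list must not be empty")
        if any(g < 0 for g in gaps):
            raise ValueError("gaps must be non-negative")
        if any(b <= a for a, b in zip(gaps, gaps[1:])):
            raise ValueError("gaps must be strictly increasing")
        if self.pillar_width <= 0 or self.pillar_height <= 0:
            raise ValueError("pillar dimensions must be positive")

    @property
    def degenerate_gaps(self) -> tuple[int, ...]:
        """Indices of zero-width gaps (a fully supported line)."""
        return tuple(i for i, g in enumerate(self.gap_list) if g == 0.0)


# ---------------------------------------------------------------------------
# toolpath container


@dataclass
class Toolpath:
    """Ordered planar polyline with per-segment extrusion metadata.

    ``vertices`` is an (N, 2) float array of XY positions in mm; segment i
    joins vertex i to i+1.  ``extrude`` flags deposition segments,
    ``widths`` carries the commanded line width per segment (0 for travel),
    and ``layers`` the zero-based layer index per segment.
    """

    vertices: np.ndarray
    extrude: np.ndarray
    widths: np.ndarray
    layers: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.extrude = np.asarray(self.extrude, dtype=bool)
        self.widths = np.asarray(self.widths, dtype=float)
        self.layers = np.asarray(self.layers, dtype=int)
        n = len(self.vertices)
        if n < 2:
            raise ValueError("a toolpath needs at least two vertices")
        if self.vertices.shape != (n, 2):
            raise ValueError("vertices must be an (N, 2) array")
        for arr, name in ((self.extrude, "extrude"), (self.widths, "widths"), (self.layers, "layers")):
            if arr.shape != (n - 1,):
                raise ValueError(f"{name} must have one entry per segment")
        lengths = self.segment_lengths()
        if np.any(lengths <= 0):
            raise ValueError("segments must have nonzero length")
        if np.any(self.widths[self.extrude] <= 0):
            raise ValueError("extrude segments must carry a positive commanded width")

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)

    @property
    def total_extruded_length(self) -> float:
        return float(self.segment_lengths()[self.extrude].sum())

    @property
    def n_layers(self) -> int:
        return int(self.layers.max()) + 1

    def strands(self) -> list[dict]:
        """Runs of consecutive extrude segments, as dicts with ``vertices``
        (M, 2), ``width`` (mm) and ``length`` (mm).  A strand is what the
        renderer draws as one continuous filament."""
        out: list[dict] = []
        i = 0
        n_seg = len(self.extrude)
        while i < n_seg:
            if not self.extrude[i]:
                i += 1
                continue
            j = i
            while j + 1 < n_seg and self.extrude[j + 1] and self.widths[j + 1] == self.widths[i] \
                    and self.layers[j + 1] == self.layers[i]:
                j += 1
            verts = self.vertices[i : j + 2]
            seg_len = np.linalg.norm(np.diff(verts, axis=0), axis=1)
            out.append(
                {
                    "vertices": verts,
                    "width": float(self.widths[i]),
                    "length": float(seg_len.sum()),
                    "layer": int(self.layers[i]),
                }
            )
            i = j + 1
        return out

    def to_csv(self, path) -> None:
        """Vertex table export: x, y, extrude flag and width of the incoming segment."""
        import pandas as pd

        n = len(self.vertices)
        df = pd.DataFrame(
            {
                "x_mm": self.vertices[:, 0],
                "y_mm": self.vertices[:, 1],
                "extrude_in": np.concatenate(([False], self.extrude)),
                "width_mm": np.concatenate(([0.0], self.widths)),
                "layer": np.concatenate(([0], self.layers)),
            }
        )
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# the chirped square wave


def chirped_square_wave(x, p: ChirpParams):
    """Evaluate A * sgn(sin(F * |x|^n)) with the convention sgn(0) := +1.

    Accepts a scalar or array; rejects non-finite input.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("x must be finite")
    inner = np.sin(p.base_freq * np.abs(arr) ** p.chirp_rate)
    val = np.where(inner >= 0.0, p.amplitude, -p.amplitude)
    if np.isscalar(x) or arr.ndim == 0:
        return float(val)
    return val


def square_wave_roots(p: ChirpParams) -> np.ndarray:
    """Sign-change positions of sin(F x^n) in the open interval x_range.

    These satisfy F x^n = k*pi; since F x^n is strictly increasing on x >= 0
    the roots are x_k = (k*pi/F)^(1/n), enumerated for successive k.
    """
    x0, x1 = p.x_range
    phi0 = p.base_freq * x0 ** p.chirp_rate
    k = max(1, int(math.ceil(phi0 / math.pi)))
    if abs(k * math.pi - phi0) < 1e-12:
        k += 1
    roots = []
    while True:
        r = (k * math.pi / p.base_freq) ** (1.0 / p.chirp_rate)
        if r >= x1:
            break
        if r > x0:
            roots.append(r)
        k += 1
    return np.asarray(roots)


def serpentine_toolpath(p: ChirpParams, commanded_width: float = 0.41,
                        layer_height: float = 0.41) -> Toolpath:
    """Serpentine polyline tracing the chirped square wave.

    Horizontal runs at y = ±A are joined by vertical legs at each sign change
    of the inner sinusoid; with chirp_rate > 1 the leg spacing shrinks with
    |x|, sweeping line spacings from coarse to fine in one continuous print.
    The leg positions and spacings are attached as metadata for the fusion
    analysis.
    """
    if commanded_width <= 0:
        raise ValueError("commanded_width must be positive")
    roots = square_wave_roots(p)
    if len(roots) < 2:
        raise ValueError("degenerate pattern: x_range contains fewer than 2 sign changes")
    if np.min(np.diff(roots)) <= p.sample_step:
        raise ValueError(
            "sample_step too coarse: consecutive samples could skip a sign change"
        )
    x0, x1 = p.x_range
    a = p.amplitude
    rail = 1.0 if math.sin(p.base_freq * (x0 + 1e-12) ** p.chirp_rate) >= 0 else -1.0
    pts = [(x0, rail * a)]
    for r in roots:
        pts.append((r, rail * a))
        rail = -rail
        pts.append((r, rail * a))
    pts.append((x1, rail * a))
    verts = np.asarray(pts)
    n_seg = len(verts) - 1
    return Toolpath(
        vertices=verts,
        extrude=np.ones(n_seg, dtype=bool),
        widths=np.full(n_seg, float(commanded_width)),
        layers=np.zeros(n_seg, dtype=int),
        metadata={
            "pattern": "serpentine",
            "params": p,
            "leg_positions": roots,
            "leg_spacings": np.diff(roots),
            "amplitude": a,
            "commanded_width": float(commanded_width),
            "layer_height": float(layer_height),
        },
    )


def grid_toolpath(p: GridParams) -> Toolpath:
    """Square lattice: per layer, ``lines_per_direction`` longitudinal plus
    the same number of transverse extrude lines spanning ``outer_size``
    (boundary lines included), drawn boustrophedon with travel hops between
    lines.  Layers repeat the pattern at increasing layer_height offsets
    recorded in the segment layer indices."""
    n = p.lines_per_direction
    s = p.outer_size
    pitch = p.pore_pitch
    verts: list[tuple[float, float]] = []
    extrude: list[bool] = []
    layers: list[int] = []

    def emit_line(p0, p1, layer):
        if not verts:
            verts.append(p0)
        elif verts[-1] != p0:
            verts.append(p0)
            extrude.append(False)
            layers.append(layer)
        verts.append(p1)
        extrude.append(True)
        layers.append(layer)

    for layer in range(p.n_layers):
        for i in range(n):  # horizontal lines
            y = i * pitch
            x_from, x_to = (0.0, s) if i % 2 == 0 else (s, 0.0)
            emit_line((x_from, y), (x_to, y), layer)
        for i in range(n):  # vertical lines
            x = i * pitch
            y_from, y_to = (s, 0.0) if i % 2 == 0 else (0.0, s)
            emit_line((x, y_from), (x, y_to), layer)

    n_seg = len(extrude)
    extr = np.asarray(extrude, dtype=bool)
    widths = np.where(extr, p.commanded_line_width, 0.0)
    return Toolpath(
        vertices=np.asarray(verts, dtype=float),
        extrude=extr,
        widths=widths,
        layers=np.asarray(layers, dtype=int),
        metadata={
            "pattern": "grid",
            "params": p,
            "layer_height": p.layer_height,
            "lines_per_direction": n,
            "n_pores": p.n_pores,
            "layer_indices": list(range(p.n_layers)),
        },
    )


def collapse_toolpath(f: CollapseFixture, commanded_width: float = 0.41,
                      layer_height: float = 0.41) -> Toolpath:
    """Single straight extrude line crossing every pillar and gap of the
    collapse fixture, with the gap intervals recorded in metadata for the
    downstream deflection-angle measurement."""
    x = 0.0
    gap_intervals: list[tuple[float, float]] = []
    for g in f.gap_list:
        x += f.pillar_width
        gap_intervals.append((x, x + g))
        x += g
    x += f.pillar_width  # trailing pillar
    total = x
    return Toolpath(
        vertices=np.asarray([[0.0, 0.0], [total, 0.0]]),
        extrude=np.asarray([True]),
        widths=np.asarray([float(commanded_width)]),
        layers=np.zeros(1, dtype=int),
        metadata={
            "pattern": "collapse",
            "fixture": f,
            "gap_intervals": gap_intervals,
            "degenerate_gaps": f.degenerate_gaps,
            "total_length": total,
            "commanded_width": float(commanded_width),
            "layer_height": float(layer_height),
        },
    )


def line_toolpath(length: float = 30.0, commanded_width: float = 0.41,
                  layer_height: float = 0.41) -> Toolpath:
    """A single straight extruded filament along +x, for line tests."""
    if length <= 0:
        raise ValueError("length must be positive")
    return Toolpath(
        vertices=np.asarray([[0.0, 0.0], [float(length), 0.0]]),
        extrude=np.asarray([True]),
        widths=np.asarray([float(commanded_width)]),
        layers=np.zeros(1, dtype=int),
        metadata={
            "pattern": "line",
            "length": float(length),
            "commanded_width": float(commanded_width),
            "layer_height": float(layer_height),
        },
    )
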