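"""Seeded synthetic imaging of deposited filaments.

The study's camera photographs are emulated by a geometric deposition model:
strands are drawn at the commanded width times a spreading ratio (die
swell), their outlines perturbed along the boundary normal by seeded
band-limited noise (edge roughness), concave corners and near-touching
strands merged by a morphological closing (gel coalescence at crossings and
in narrow serpentine gaps), and side views rendered with a parabolic sag
between pillar supports.  An illumination ramp and additive Gaussian noise
stand in for imperfect lighting and sensor noise.

Ink is rendered dark on a light background (the study dyes the ink for
contrast); images are 8-bit grayscale with a known pixels-per-mm scale and
a top-left, y-down origin.  Rendering is anti-aliased: edge pixels carry
fractional ink coverage, so sub-pixel boundary positions survive into the
image.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

from .patterns import Toolpath

__all__ = [
    "DepositionModel",
    "SagModel",
    "RasterImage",
    "render_topview",
    "render_sideview",
    "apply_camera_noise",
]

_INK = 25.0
_BACKGROUND = 230.0


@dataclass(frozen=True)
class DepositionModel:
    """How a commanded toolpath turns into deposited material.

    ``spread_ratio`` multiplies the commanded width (1.0 = perfect fidelity,
    ~1.8 = strong die swell); ``roughness_amplitude`` is the RMS
    boundary-normal displacement (mm) of band-limited edge noise with
    correlation length ``roughness_wavelength`` (mm);
    ``corner_round_radius`` (mm) rounds/fills concave corners at crossings;
    strands whose edge-to-edge distance is at most ``fusion_gap`` (mm)
    merge into one region.
    """

    spread_ratio: float = 1.0
    roughness_amplitude: float = 0.0
    roughness_wavelength: float = 2.0
    corner_round_radius: float = 0.0
    fusion_gap: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spread_ratio <= 0:
            raise ValueError("spread_ratio must be positive")
        if self.roughness_amplitude < 0 or self.roughness_wavelength <= 0:
            raise ValueError("roughness must be non-negative with positive wavelength")
        if self.corner_round_radius < 0 or self.fusion_gap < 0:
            raise ValueError("corner_round_radius and fusion_gap must be non-negative")


@dataclass(frozen=True)
class SagModel:
    """Parabolic sag of a filament suspended over a gap.

    ``span`` is the free span between the supports (mm), ``max_sag`` the
    midspan deflection (mm), ``filament_thickness`` the strand diameter in
    side view (mm).  For a parabola the slope at the supports is
    4 * max_sag / span, which is what the collapse-angle metric measures.
    """

    span: float
    max_sag: float
    filament_thickness: float = 0.8
    shape: str = "parabolic"

    def __post_init__(self) -> None:
        if self.span <= 0 or self.filament_thickness <= 0:
            raise ValueError("span and filament_thickness must be positive")
        if self.max_sag < 0:
            raise ValueError("max_sag must be non-negative")
        if self.shape != "parabolic":
            raise ValueError("only the parabolic sag shape is supported")

    @property
    def support_slope(self) -> float:
        return 4.0 * self.max_sag / self.span

    @property
    def support_angle_deg(self) -> float:
        return math.degrees(math.atan(self.support_slope))


@dataclass
class RasterImage:
    """8-bit grayscale raster with a physical scale.

    ``scale`` is pixels per mm; the origin convention is top-left with y
    increasing downward.  ``metadata['origin_mm']`` gives the world-mm
    coordinate of the top-left image corner, so pixel (row, col) has its
    center at origin + ((col + 0.5)/scale, (row + 0.5)/scale).
    """

    pixels: np.ndarray
    scale: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(np.round(self.pixels), 0, 255).astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def ink_coverage(self) -> np.ndarray:
        """Fractional ink coverage per pixel, inverting the dark-on-light
        rendering: 0 = pure background, 1 = fully inked."""
        lo, hi = _INK, _BACKGROUND
        return np.clip((hi - self.pixels.astype(float)) / (hi - lo), 0.0, 1.0)

    def save(self, path) -> None:
        """Write PNG/TIFF plus a JSON sidecar with scale and metadata."""
        path = Path(path)
        iio.imwrite(path, self.pixels)
        sidecar = {"scale_px_per_mm": self.scale, "metadata": _jsonable(self.metadata)}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "RasterImage":
        path = Path(path)
        pixels = iio.imread(path)
        if pixels.ndim == 3:
            from .imageops import to_grayscale

            pixels = to_grayscale(pixels)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        scale = 1.0
        metadata: dict = {}
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            scale = float(sidecar["scale_px_per_mm"])
            metadata = sidecar.get("metadata", {})
        return cls(pixels=pixels, scale=scale, metadata=metadata)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return repr(obj)


def _smooth_profile(rng: np.random.Generator, length: float, wavelength: float,
                    amplitude: float, ds: float | None = None):
    """Band-limited boundary-displacement profile along arclength.

    White noise on control points half a wavelength apart is smoothed and
    spline-interpolated onto a dense grid, then normalized so its RMS over
    the strand equals ``amplitude``.  Returns (s_grid, values) in mm.
    """
    if ds is None:
        ds = max(min(wavelength / 8.0, 0.05), 1e-3)
    s_grid = np.arange(0.0, length + ds, ds)
    if amplitude == 0.0:
        return s_grid, np.zeros_like(s_grid)
    spacing = wavelength / 2.0
    n_ctrl = int(math.ceil(length / spacing)) + 5
    ctrl_s = (np.arange(n_ctrl) - 2) * spacing
    ctrl = gaussian_filter1d(rng.standard_normal(n_ctrl), sigma=1.0, mode="wrap")
    vals = CubicSpline(ctrl_s, ctrl)(s_grid)
    rms = float(np.sqrt(np.mean(vals**2)))
    if rms < 1e-12:
        return s_grid, np.zeros_like(s_grid)
    return s_grid, vals * (amplitude / rms)


def _profile_arclength(s_grid: np.ndarray, vals: np.ndarray) -> float:
    return float(np.sum(np.hypot(np.diff(s_grid), np.diff(vals))))


def render_topview(t: Toolpath, m: DepositionModel, scale: float = 20.0,
                   margin_mm: float = 2.0) -> RasterImage:
    """Render the top view of a deposited toolpath.

    Strands are drawn at commanded width x spread_ratio with round caps and
    joints, per-side boundary noise, and a closing of radius
    max(fusion_gap/2, corner_round_radius) that merges near-touching
    strands and fills concave crossing corners.  The sidecar metadata keeps
    the ground-truth deposition parameters (and for straight strands the
    realized mean width and boundary-arc-length uniformity ratio) for
    recovery tests.
    """
    if scale < 10:
        raise ValueError("scale must be at least 10 px/mm to resolve strands")
    strands = t.strands()
    if not strands:
        raise ValueError("toolpath has no extrude segments")
    min_w = min(s["width"] for s in strands) * m.spread_ratio
    if min_w * scale < 2:
        raise ValueError(
            f"rendered strand width {min_w:.3f} mm is under-resolved at {scale} px/mm"
        )
    half_w_max = max(s["width"] for s in strands) * m.spread_ratio / 2.0
    if m.roughness_amplitude >= min_w / 2.0:
        raise ValueError("roughness_amplitude must stay below the strand half-width")

    verts_all = t.vertices
    pad = margin_mm + half_w_max + 4.0 * m.roughness_amplitude
    x_min = float(verts_all[:, 0].min() - pad)
    y_min = float(verts_all[:, 1].min() - pad)
    x_max = float(verts_all[:, 0].max() + pad)
    y_max = float(verts_all[:, 1].max() + pad)
    width_px = int(math.ceil((x_max - x_min) * scale))
    height_px = int(math.ceil((y_max - y_min) * scale))
    coverage = np.zeros((height_px, width_px), dtype=np.float64)

    rng = np.random.default_rng(m.seed)
    strand_truth = []
    for strand in strands:
        half_w = strand["width"] * m.spread_ratio / 2.0
        s_grid, n_left = _smooth_profile(rng, strand["length"], m.roughness_wavelength,
                                         m.roughness_amplitude)
        _, n_right = _smooth_profile(rng, strand["length"], m.roughness_wavelength,
                                     m.roughness_amplitude)
        verts = strand["vertices"]
        seg_vec = np.diff(verts, axis=0)
        seg_len = np.linalg.norm(seg_vec, axis=1)
        seg_start_arc = np.concatenate(([0.0], np.cumsum(seg_len[:-1])))
        reach = half_w + 4.0 * m.roughness_amplitude + 2.0 / scale
        for k in range(len(seg_len)):
            p0 = verts[k]
            d = seg_vec[k] / seg_len[k]
            lo_x = min(p0[0], verts[k + 1][0]) - reach
            hi_x = max(p0[0], verts[k + 1][0]) + reach
            lo_y = min(p0[1], verts[k + 1][1]) - reach
            hi_y = max(p0[1], verts[k + 1][1]) + reach
            c0 = max(0, int((lo_x - x_min) * scale))
            c1 = min(width_px, int(math.ceil((hi_x - x_min) * scale)) + 1)
            r0 = max(0, int((lo_y - y_min) * scale))
            r1 = min(height_px, int(math.ceil((hi_y - y_min) * scale)) + 1)
            if c0 >= c1 or r0 >= r1:
                continue
            xs = x_min + (np.arange(c0, c1) + 0.5) / scale
            ys = y_min + (np.arange(r0, r1) + 0.5) / scale
            gx, gy = np.meshgrid(xs, ys)
            rel_x = gx - p0[0]
            rel_y = gy - p0[1]
            proj = rel_x * d[0] + rel_y * d[1]
            proj_c = np.clip(proj, 0.0, seg_len[k])
            dist = np.hypot(rel_x - proj_c * d[0], rel_y - proj_c * d[1])
            if m.roughness_amplitude > 0:
                arc = seg_start_arc[k] + proj_c
                cross = rel_x * d[1] - rel_y * d[0]
                noise = np.where(
                    cross >= 0,
                    np.interp(arc, s_grid, n_left),
                    np.interp(arc, s_grid, n_right),
                )
                hw_eff = half_w + noise
            else:
                hw_eff = half_w
            cov = np.clip(0.5 + (hw_eff - dist) * scale, 0.0, 1.0)
            np.maximum(coverage[r0:r1, c0:c1], cov, out=coverage[r0:r1, c0:c1])
        truth = {"width_mm": 2.0 * half_w, "layer": strand["layer"]}
        if len(seg_len) == 1 and m.roughness_amplitude >= 0:
            # straight strand: the realized boundary arc lengths give the
            # ground-truth uniformity ratio for recovery tests
            arc_l = _profile_arclength(s_grid, n_left)
            arc_r = _profile_arclength(s_grid, n_right)
            w_mean = 2.0 * half_w + float(np.mean(n_left) + np.mean(n_right))
            p_th = 2.0 * strand["length"] + 2.0 * w_mean
            truth["width_mean_mm"] = w_mean
            truth["uf"] = (arc_l + arc_r + 2.0 * w_mean) / p_th
        strand_truth.append(truth)

    close_r = max(m.fusion_gap / 2.0, m.corner_round_radius)
    if close_r > 0:
        from skimage.morphology import closing, disk

        coverage = closing(coverage, disk(max(1, int(round(close_r * scale)))))

    pixels = _BACKGROUND - (_BACKGROUND - _INK) * coverage
    meta = {
        "view": "top",
        "origin_mm": (x_min, y_min),
        "seed": m.seed,
        "deposition": {
            "spread_ratio": m.spread_ratio,
            "roughness_amplitude": m.roughness_amplitude,
            "roughness_wavelength": m.roughness_wavelength,
            "corner_round_radius": m.corner_round_radius,
            "fusion_gap": m.fusion_gap,
        },
        "pattern": t.metadata.get("pattern"),
        "strand_truth": strand_truth,
    }
    for key in ("leg_positions", "leg_spacings", "amplitude", "gap_intervals"):
        if key in t.metadata:
            meta[key] = np.asarray(t.metadata[key]).tolist()
    return RasterImage(pixels=pixels, scale=scale, metadata=meta)


def render_sideview(s: SagModel, scale: float = 20.0, pillar_width: float = 2.0,
                    pillar_height: float = 10.0, margin_mm: float = 2.0) -> RasterImage:
    """Render a side view of a filament suspended between two pillars.

    The filament underside rests on the pillar tops at the supports and
    follows a parabola of the stated midspan sag between them; the pillars
    extend outward from the supports.  Metadata records the support
    positions and the pillar-top line in image-frame mm for the collapse
    analysis.
    """
    if s.filament_thickness * scale < 3:
        raise ValueError("scale too coarse: filament thickness must span >= 3 px")
    if s.max_sag > pillar_height:
        raise ValueError("max_sag exceeds pillar height")

    t = s.filament_thickness
    x_min = -pillar_width - margin_mm
    x_max = s.span + pillar_width + margin_mm
    y_min = -(t + margin_mm)
    y_max = pillar_height + margin_mm
    width_px = int(math.ceil((x_max - x_min) * scale))
    height_px = int(math.ceil((y_max - y_min) * scale))

    xs = x_min + (np.arange(width_px) + 0.5) / scale
    ys = y_min + (np.arange(height_px) + 0.5) / scale
    gx, gy = np.meshgrid(xs, ys)

    # underside depth below the pillar-top line (0 over the pillars)
    x_on_span = np.clip(gx, 0.0, s.span)
    depth = 4.0 * s.max_sag * x_on_span * (s.span - x_on_span) / s.span**2
    depth = np.where((gx >= -pillar_width) & (gx <= s.span + pillar_width), depth, np.inf)
    centerline = depth - t / 2.0
    cov = np.clip(0.5 + (t / 2.0 - np.abs(gy - centerline)) * scale, 0.0, 1.0)

    pillars = ((gy >= 0.0) & (gy <= pillar_height)
               & (((gx >= -pillar_width) & (gx <= 0.0))
                  | ((gx >= s.span) & (gx <= s.span + pillar_width))))
    cov = np.maximum(cov, pillars.astype(float))

    pixels = _BACKGROUND - (_BACKGROUND - _INK) * cov
    meta = {
        "view": "side",
        "origin_mm": (x_min, y_min),
        "support_x_mm": (-x_min, s.span - x_min),
        "pillar_top_mm": -y_min,
        "span_mm": s.span,
        "max_sag_mm": s.max_sag,
        "filament_thickness_mm": t,
        "truth_angle_deg": s.support_angle_deg,
    }
    return RasterImage(pixels=pixels, scale=scale, metadata=meta)


def apply_camera_noise(img: RasterImage, illum_gradient: float = 0.0,
                       noise_sd: float = 0.0, seed: int = 0) -> RasterImage:
    """Imperfect acquisition: a linear illumination ramp (left edge brighter
    by the factor 1 + illum_gradient relative to the right edge) and seeded
    additive Gaussian intensity noise, clipped to 0-255."""
    if not (0.0 <= illum_gradient < 1.0):
        raise ValueError("illum_gradient must be in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    px = img.pixels.astype(float)
    h, w = px.shape
    ramp = 1.0 + illum_gradient * (1.0 - np.arange(w) / max(w - 1, 1))
    px = px * ramp[None, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        px = px + rng.normal(0.0, noise_sd, size=px.shape)
    meta = dict(img.metadata)
    meta["camera_noise"] = {"illum_gradient": illum_gradient, "noise_sd": noise_sd,
                            "seed": seed}
    return RasterImage(pixels=np.clip(px, 0, 255), scale=img.scale, metadata=meta)
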