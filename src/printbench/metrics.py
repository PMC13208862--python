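"""Print-quality metrics for extrusion bioprinting.

Implements the standard quantitative printability descriptors computed from
segmented images plus the commanded geometry:

* Spreading Ratio  SR = w_ext / d_nozzle           (1.0 = ideal fidelity)
* Uniformity Ratio UF = p_ext / p_th               (1.0 = smooth filament)
* Printability Index Pr = L^2 / (16 A)             (1.0 = square pore)
* Collapse angle theta and collapse rate Cf = 100 (Act - Aca)/Act
* Apparent yield stress sigma0 = rho g L / sin(theta)  (inverse of the
  filament-collapse force balance theta = asin(rho g L / sigma0), with L
  half the gap span; "apparent" because the model ignores filament volume)
* Filament-fusion descriptors: line thickness lt, commanded spacing ls and
  the minimum open line spacing lmin
* Pore descriptors: hydraulic radius A/P, area, perimeter.

Angles are reported in degrees, stresses in Pa, lengths in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure as skmeasure

from .imageops import BinaryMask, ParticleRecord
from .render import RasterImage

__all__ = [
    "NozzleSpec",
    "MaterialParams",
    "LineWidthResult",
    "LineMetrics",
    "GapRecord",
    "FusionResult",
    "CollapseAngleResult",
    "CollapseMeasurement",
    "measure_line_width",
    "spreading_ratio",
    "uniformity_ratio",
    "printability_index",
    "collapse_angle",
    "collapse_rate",
    "apparent_yield_stress",
    "deflection_angle_for_stress",
    "fusion_analysis",
    "strand_width_from_ink_area",
]


@dataclass(frozen=True)
class NozzleSpec:
    """Dispensing nozzle; the study uses a 22 G tip of 410 um bore."""

    gauge: str = "22G"
    inner_diameter: float = 0.41  # mm

    def __post_init__(self) -> None:
        if self.inner_diameter <= 0:
            raise ValueError("inner_diameter must be positive")


@dataclass(frozen=True)
class MaterialParams:
    """Physical constants for the collapse-test force balance.

    Density in kg/m^3 (hydrogel inks are essentially water-dense), gravity
    in m/s^2, and the rheometer-measured reference yield stress in Pa for
    comparison with the apparent value inferred from deflection.
    """

    density: float = 1000.0
    gravity: float = 9.81
    reference_yield_stress: float = 350.0

    def __post_init__(self) -> None:
        if min(self.density, self.gravity, self.reference_yield_stress) <= 0:
            raise ValueError("all material parameters must be positive")


@dataclass(frozen=True)
class LineWidthResult:
    mean_mm: float
    sd_mm: float
    n_sections: int
    n_broken: int


@dataclass(frozen=True)
class LineMetrics:
    """Bundle of straight-line test metrics (widths in mm)."""

    mean_width: float
    width_sd: float
    measured_perimeter: float
    theoretical_perimeter: float
    uniformity: float
    spreading_ratio: float | None = None


@dataclass(frozen=True)
class GapRecord:
    spacing: float  # commanded ls, mm
    open: bool


@dataclass(frozen=True)
class FusionResult:
    gaps: tuple[GapRecord, ...]
    lmin: float  # mm; nan if every gap has fused
    line_thickness: float  # mean lt over legs, mm
    missing_legs: tuple[int, ...] = ()


@dataclass(frozen=True)
class CollapseAngleResult:
    theta_deg: float
    left_deg: float
    right_deg: float
    ruptured: bool = False


@dataclass(frozen=True)
class CollapseMeasurement:
    deflection_angle: float  # degrees
    theoretical_area: float  # Act, mm^2
    actual_area: float  # Aca, mm^2
    collapse_rate: float  # Cf, percent
    half_gap: float  # L, mm


# ---------------------------------------------------------------------------
# helpers


def _coverage_and_scale(img) -> tuple[np.ndarray, float]:
    """Fractional ink coverage from a RasterImage (sub-pixel, preferred) or a
    BinaryMask (whole-pixel)."""
    if isinstance(img, RasterImage):
        return img.ink_coverage(), img.scale
    if isinstance(img, BinaryMask):
        return img.mask.astype(float), img.scale
    raise TypeError("expected a RasterImage or BinaryMask")


def _origin(img) -> tuple[float, float]:
    if isinstance(img, RasterImage):
        return tuple(img.metadata.get("origin_mm", (0.0, 0.0)))
    return tuple(img.origin_mm)


# ---------------------------------------------------------------------------
# line tests


def measure_line_width(img, axis: str = "auto",
                       end_margin: float = 0.05) -> LineWidthResult:
    """Mean and SD of the filament width across the line.

    The width at each cross-section is the integrated ink fraction of the
    column (densitometric width), which stays sub-pixel accurate where a
    binary run-length count is quantized to whole pixels.  The filament is
    first rotated to horizontal if needed; the outermost ``end_margin``
    fraction of sections at each end is excluded, and zero-width sections
    (a broken filament) are excluded and counted.
    """
    cov, scale = _coverage_and_scale(img)
    fg = cov > 0.5
    if not fg.any():
        raise ValueError("no filament found")

    if axis == "auto":
        rows, cols = np.nonzero(fg)
        coords = np.column_stack([cols - cols.mean(), rows - rows.mean()])
        cxx, cxy = coords[:, 0] @ coords[:, 0], coords[:, 0] @ coords[:, 1]
        cyy = coords[:, 1] @ coords[:, 1]
        angle = 0.5 * math.atan2(2 * cxy, cxx - cyy)  # major axis vs +x, y down
        if abs(angle) > math.radians(2.0):
            cov = ndi.rotate(cov, math.degrees(angle), reshape=True, order=1)
    elif axis == "vertical":
        cov = cov.T
    elif axis != "horizontal":
        raise ValueError("axis must be 'auto', 'horizontal' or 'vertical'")

    widths_px = cov.sum(axis=0)
    occupied = np.nonzero(widths_px > 0.5)[0]
    if occupied.size < 4:
        raise ValueError("filament too short to measure")
    # every section within the occupied extent counts, so interior gaps
    # (a broken filament) are detected rather than silently skipped
    extent = np.arange(occupied[0], occupied[-1] + 1)
    margin = int(round(end_margin * extent.size))
    sel = extent[margin : extent.size - margin] if margin else extent
    w = widths_px[sel] / scale
    broken = w < 1.0 / scale
    good = w[~broken]
    if good.size == 0:
        raise ValueError("filament is broken throughout the measurement window")
    return LineWidthResult(mean_mm=float(good.mean()), sd_mm=float(good.std(ddof=0)),
                           n_sections=int(good.size), n_broken=int(broken.sum()))


def spreading_ratio(w_ext: float, nozzle: NozzleSpec) -> float:
    """SR = printed filament width over nozzle inner diameter."""
    if w_ext <= 0:
        raise ValueError("w_ext must be positive")
    return w_ext / nozzle.inner_diameter


def uniformity_ratio(img, segment_length: float | None = None,
                     nozzle: NozzleSpec | None = None) -> LineMetrics:
    """UF = measured boundary perimeter over the theoretical smooth perimeter.

    The filament is clipped to a central measurement window of
    ``segment_length`` mm (default: the occupied extent minus 5% margins);
    p_ext is the sub-pixel contour length of the clipped region (including
    the two cut ends) and p_th = 2*segment_length + 2*mean width, using the
    measured mean width so that UF isolates boundary roughness from
    spreading.
    """
    cov, scale = _coverage_and_scale(img)
    widths_px = cov.sum(axis=0)
    occupied = np.nonzero(widths_px > 0.5)[0]
    if occupied.size < 4:
        raise ValueError("no filament found")
    if segment_length is None:
        margin = max(1, int(round(0.05 * occupied.size)))
        c0, c1 = occupied[margin], occupied[-margin]
    else:
        n = int(round(segment_length * scale))
        mid = (occupied[0] + occupied[-1]) // 2
        c0, c1 = mid - n // 2, mid - n // 2 + n
        if c0 < occupied[0] or c1 > occupied[-1] + 1:
            raise ValueError("segment_length exceeds the filament extent")
    window = cov[:, c0:c1]

    n_regions = skmeasure.label(window > 0.5, connectivity=2).max()
    if n_regions > 1:
        # tolerate sub-pixel specks but reject genuinely split filaments
        lab = skmeasure.label(window > 0.5, connectivity=2)
        sizes = np.bincount(lab.ravel())[1:]
        if (sizes > 0.01 * sizes.max()).sum() > 1:
            raise ValueError("multiple filament regions in the measurement window")

    length = (c1 - c0) / scale
    w_cols = window.sum(axis=0) / scale
    w_mean = float(w_cols.mean())
    w_sd = float(w_cols.std(ddof=0))

    # An anti-aliased coverage field already locates the boundary sub-pixel;
    # a hard binary mask needs light smoothing (plus the half-pixel offset
    # correction) to suppress the marching-squares staircase bias on
    # oblique boundary stretches.
    binary_input = isinstance(img, BinaryMask)
    padded = np.pad(window, 4)
    if binary_input:
        from scipy.ndimage import gaussian_filter

        padded = gaussian_filter(padded, 1.0)
    contour_lens = [float(np.hypot(*np.diff(c, axis=0).T).sum())
                    for c in skmeasure.find_contours(padded, 0.5)]
    p_ext = sum(contour_lens)
    if binary_input and contour_lens:
        p_ext += math.pi
    p_ext /= scale
    p_th = 2.0 * length + 2.0 * w_mean
    return LineMetrics(
        mean_width=w_mean,
        width_sd=w_sd,
        measured_perimeter=p_ext,
        theoretical_perimeter=p_th,
        uniformity=p_ext / p_th,
        spreading_ratio=(w_mean / nozzle.inner_diameter) if nozzle else None,
    )


# ---------------------------------------------------------------------------
# pore metrics


def printability_index(p) -> float:
    """Pr = perimeter^2 / (16 * area): 1 for a square pore, pi/4 for a disk,
    > 1 for ragged or elongated pores.  Accepts a ParticleRecord or an
    (perimeter, area) pair."""
    if isinstance(p, ParticleRecord):
        per, area = p.perimeter, p.area
    else:
        per, area = p
    if per <= 0 or area <= 0:
        raise ValueError("perimeter and area must be positive")
    return per**2 / (16.0 * area)


# ---------------------------------------------------------------------------
# collapse test


def _column_centerline(cov: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Coverage-weighted mean row per column (sub-pixel centerline); NaN for
    empty columns.  Sub-threshold coverage (sensor noise on the background)
    is ignored so faint speckle far from the filament cannot bias the mean."""
    out = np.full(cols.size, np.nan)
    rows = np.arange(cov.shape[0], dtype=float)
    for i, c in enumerate(cols):
        w = np.where(cov[:, c] >= 0.25, cov[:, c], 0.0)
        tot = w.sum()
        if tot > 0.5:
            out[i] = float((rows * w).sum() / tot)
    return out


def collapse_angle(img, support_x: tuple[float, float] | None = None,
                   fit_window: float = 2.0) -> CollapseAngleResult:
    """Deflection angle theta at the supports of a suspended filament.

    The per-column centerline (coverage-weighted mean row) is extracted over
    a ``fit_window`` mm region inward from each support and fitted with a
    parabola whose tangent slope at the support gives the local angle;
    theta is the mean of the two absolute angles.  A straight filament
    yields 0 degrees.  Columns with no foreground between the supports set
    the rupture flag.
    """
    cov, scale = _coverage_and_scale(img)
    if support_x is None:
        meta = img.metadata if isinstance(img, RasterImage) else {}
        if "support_x_mm" not in meta:
            raise ValueError("support_x required (not present in image metadata)")
        support_x = tuple(meta["support_x_mm"])
    x0, x1 = support_x
    if not (0 <= x0 < x1):
        raise ValueError("supports must lie inside the image, left < right")

    c_left, c_right = int(round(x0 * scale)), int(round(x1 * scale))
    c_left = max(c_left, 0)
    c_right = min(c_right, cov.shape[1])
    span_cols = np.arange(c_left + 1, c_right - 1)
    center_all = _column_centerline(cov, span_cols)
    ruptured = bool(np.isnan(center_all).any())

    n_fit = max(4, int(round(fit_window * scale)))
    angles = []
    for support_col, inward in ((c_left, +1), (c_right - 1, -1)):
        cols = support_col + inward * np.arange(1, n_fit + 1)
        cols = cols[(cols >= 0) & (cols < cov.shape[1])]
        center = _column_centerline(cov, cols)
        ok = ~np.isnan(center)
        if ok.sum() < 4:
            angles.append(np.nan)
            continue
        x_mm = (cols[ok] - support_col) * inward / scale  # distance inward, mm
        y_mm = center[ok] / scale
        coeffs = np.polyfit(x_mm, y_mm, 2)
        slope = coeffs[1]  # dy/dx at the support (x = 0)
        angles.append(math.degrees(math.atan(abs(slope))))
    theta = float(np.nanmean(angles)) if not all(np.isnan(a) for a in angles) else np.nan
    return CollapseAngleResult(theta_deg=theta, left_deg=angles[0],
                               right_deg=angles[1], ruptured=ruptured)


def _lower_boundary_px(cov: np.ndarray, col: int) -> float:
    """Sub-pixel row of the lower ink boundary in a column (NaN if empty).

    Under linear anti-aliasing a pixel with fractional coverage a on the
    lower edge puts the boundary at row + a - 0.5.
    """
    w = cov[:, col]
    fg = np.nonzero(w >= 0.5)[0]
    if fg.size == 0:
        return np.nan
    r = fg[-1]
    if r + 1 < w.size and 0.0 < w[r + 1] < 0.5:
        return (r + 1) + w[r + 1] - 0.5
    return r + w[r] - 0.5 if w[r] < 1.0 else r + 0.5


def collapse_rate(img, reference_depth: float,
                  support_x: tuple[float, float] | None = None,
                  pillar_top: float | None = None,
                  fit_window: float = 2.0) -> CollapseMeasurement:
    """Collapse rate Cf from the sagging filament's lower boundary.

    Act is the theoretical rectangular area ``span * reference_depth``
    under a straight filament resting on the pillar tops; Aca is Act minus
    the area enclosed between the pillar-top chord and the filament's lower
    boundary, so Cf = 100 (Act - Aca)/Act is the fraction of that reference
    area lost to sagging.  A straight filament gives Cf = 0.
    """
    cov, scale = _coverage_and_scale(img)
    meta = img.metadata if isinstance(img, RasterImage) else {}
    if support_x is None:
        support_x = tuple(meta["support_x_mm"])
    if pillar_top is None:
        pillar_top = float(meta["pillar_top_mm"])
    x0, x1 = support_x
    span = x1 - x0
    if reference_depth <= 0:
        raise ValueError("reference_depth must be positive")

    c_left, c_right = int(round(x0 * scale)), int(round(x1 * scale))
    cols = np.arange(c_left + 1, c_right - 1)
    boundary = np.array([_lower_boundary_px(cov, c) for c in cols])
    depth = (boundary + 0.5) / scale - pillar_top  # +0.5: row index -> pixel center
    depth = depth[~np.isnan(depth)]
    depth = np.clip(depth, 0.0, None)
    if depth.size and depth.max() > reference_depth + 1e-9:
        raise ValueError("filament sags below the reference floor")
    enclosed = float(depth.sum()) / scale  # mm^2
    act = span * reference_depth
    aca = act - enclosed
    theta = collapse_angle(img, support_x=support_x, fit_window=fit_window).theta_deg
    return CollapseMeasurement(
        deflection_angle=theta,
        theoretical_area=act,
        actual_area=aca,
        collapse_rate=100.0 * enclosed / act,
        half_gap=span / 2.0,
    )


def apparent_yield_stress(theta_deg: float, m: MaterialParams, half_gap: float) -> float:
    """Invert the collapse force balance: sigma0 = rho g L / sin(theta).

    ``half_gap`` L is in mm (converted to metres).  A vanishing deflection
    makes the estimate unbounded (yield stress above the measurable range).
    """
    if half_gap <= 0:
        raise ValueError("half_gap must be positive")
    if not (0.0 < theta_deg <= 90.0):
        raise ValueError(
            "deflection angle must lie in (0, 90] degrees; theta -> 0 means the "
            "apparent yield stress is above the measurable range"
        )
    return m.density * m.gravity * (half_gap / 1000.0) / math.sin(math.radians(theta_deg))


def deflection_angle_for_stress(sigma0: float, m: MaterialParams, half_gap: float) -> float:
    """Forward model theta = asin(rho g L / sigma0) in degrees (roundtrip of
    :func:`apparent_yield_stress`)."""
    arg = m.density * m.gravity * (half_gap / 1000.0) / sigma0
    if not (0.0 < arg <= 1.0):
        raise ValueError("stress too low: the filament cannot support the span")
    return math.degrees(math.asin(arg))


# ---------------------------------------------------------------------------
# filament fusion


def fusion_analysis(img, serpentine_meta: dict, open_fraction: float = 0.9,
                    end_margin: float = 0.05) -> FusionResult:
    """Fusion metrics of a rendered serpentine.

    A gap between adjacent vertical legs counts as open when a background
    corridor spans at least ``open_fraction`` of the leg length between
    them; lmin is the smallest commanded spacing among open gaps.  lt is
    the mean measured leg width (excluding ``end_margin`` fractions near
    the rails and legs flagged as missing/discontinuous).
    """
    cov, scale = _coverage_and_scale(img)
    fg = cov > 0.5
    ox, oy = _origin(img)
    legs_mm = np.asarray(serpentine_meta["leg_positions"], dtype=float)
    amp = float(serpentine_meta["amplitude"])
    if legs_mm.size < 2:
        raise ValueError("serpentine metadata must contain at least two legs")
    spacings = np.diff(legs_mm)

    leg_cols = np.round((legs_mm - ox) * scale).astype(int)
    # rows spanned by the legs, keeping clear of the horizontal rails
    rail_clear = max(2.0 / scale, 0.08 * 2 * amp)
    r0 = int(round((-amp + rail_clear - oy) * scale))
    r1 = int(round((amp - rail_clear - oy) * scale))
    r0, r1 = max(r0, 0), min(r1, fg.shape[0])
    if r1 - r0 < 4:
        raise ValueError("serpentine legs too short to analyse")
    rows = np.arange(r0, r1)
    m_rows = int(round(end_margin * rows.size))
    rows = rows[m_rows : rows.size - m_rows] if m_rows else rows

    # per-leg width (horizontal run length around the commanded position)
    half_windows = np.empty((legs_mm.size, 2), dtype=int)
    for k in range(legs_mm.size):
        left = (leg_cols[k - 1] + leg_cols[k]) // 2 if k > 0 else 0
        right = (leg_cols[k] + leg_cols[k + 1]) // 2 if k + 1 < legs_mm.size else fg.shape[1]
        half_windows[k] = (left, right)

    leg_widths: list[float] = []
    missing: list[int] = []
    for k in range(legs_mm.size):
        left, right = half_windows[k]
        widths = []
        n_missing = 0
        for r in rows:
            seg = fg[r, left:right]
            if not seg.any():
                n_missing += 1
                continue
            # contiguous run nearest the commanded column
            cols_fg = np.nonzero(seg)[0] + left
            target = leg_cols[k]
            nearest = cols_fg[np.argmin(np.abs(cols_fg - target))]
            lo = hi = nearest
            while lo - 1 >= left and fg[r, lo - 1]:
                lo -= 1
            while hi + 1 < right and fg[r, hi + 1]:
                hi += 1
            if lo == left or hi == right - 1:
                continue  # fused into the neighbour: width ill-defined here
            widths.append((hi - lo + 1) / scale)
        if n_missing > 0.1 * rows.size:
            missing.append(k)  # genuine discontinuity: no ink where a leg belongs
        elif widths:
            # fused legs (no measurable free-standing width) are simply
            # excluded from the lt average
            leg_widths.append(float(np.mean(widths)))

    gap_records: list[GapRecord] = []
    for k in range(spacings.size):
        band = fg[rows[0] : rows[-1] + 1, leg_cols[k] + 1 : leg_cols[k + 1]]
        if band.shape[1] == 0:
            gap_records.append(GapRecord(spacing=float(spacings[k]), open=False))
            continue
        open_rows = (~band).any(axis=1)
        gap_records.append(
            GapRecord(spacing=float(spacings[k]),
                      open=bool(open_rows.mean() >= open_fraction))
        )

    open_spacings = [g.spacing for g in gap_records if g.open]
    lmin = float(min(open_spacings)) if open_spacings else float("nan")
    lt = float(np.mean(leg_widths)) if leg_widths else float("nan")
    return FusionResult(gaps=tuple(gap_records), lmin=lmin, line_thickness=lt,
                        missing_legs=tuple(missing))


# ---------------------------------------------------------------------------
# grid helpers


def strand_width_from_ink_area(ink_area: float, outer_size: float, n_cells: int) -> float:
    """Strand width implied by the ink area of a square grid clipped to its
    outer square: inverts the strip-union area 2*n*L*w - n^2*w^2 (n =
    pores per side, L = outer size; the two boundary strips count half)."""
    L, n = float(outer_size), int(n_cells)
    disc = L**2 - ink_area * 1.0
    if disc < 0:
        raise ValueError("ink area exceeds what any strand width can produce")
    return (L - math.sqrt(disc)) / n
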