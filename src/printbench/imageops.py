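"""Fiji-style segmentation workflow: grayscale, threshold, label, measure.

Mirrors the classic ImageJ/Fiji porosity pipeline for printed scaffolds —
8-bit grayscale conversion, a global threshold so pores appear as bright
foreground, connected-component particle analysis with area/perimeter/
circularity, and size/circularity/border filtering.

Measurement conventions: 8-connected foreground with 4-connected background
(the standard topology pairing); areas from pixel counts; perimeters from
the sub-pixel marching-squares contour at the 0.5 iso-level (pixel-edge
counting overestimates oblique boundaries by up to ~27%, which would
corrupt Pr, UF and the hydraulic radius); all physical quantities in mm
via the mask's pixels-per-mm scale; top-left origin, y down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure as skmeasure
from skimage.filters import threshold_otsu

from .render import RasterImage

__all__ = [
    "BinaryMask",
    "ParticleRecord",
    "ParticleFilter",
    "FIJI_PORE_FILTER",
    "DEFAULT_PORE_FILTER",
    "to_grayscale",
    "binarize",
    "label_particles",
    "filter_particles",
    "contour_perimeter_px",
    "porosity",
]


@dataclass
class BinaryMask:
    """Boolean foreground mask with physical scale and threshold provenance."""

    mask: np.ndarray
    scale: float
    provenance: dict = field(default_factory=dict)
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or self.mask.size == 0:
            raise ValueError("mask must be a non-empty 2-D boolean array")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def save(self, path) -> None:
        import json
        from pathlib import Path

        import imageio.v3 as iio

        path = Path(path)
        iio.imwrite(path, (self.mask * np.uint8(255)))
        sidecar = {"scale_px_per_mm": self.scale, "provenance": self.provenance,
                   "origin_mm": list(self.origin_mm)}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


@dataclass(frozen=True)
class ParticleRecord:
    """One segmented particle (pore or ink region).

    ``circularity`` is 4*pi*A/P^2 (1 for a disk), capped at 1.05 to absorb
    perimeter-estimator overshoot on tiny particles; ``hydraulic_radius``
    is A/P by definition.
    """

    label: int
    area: float  # mm^2
    perimeter: float  # mm
    circularity: float
    hydraulic_radius: float
    centroid: tuple[float, float]  # (x, y) mm in the image frame
    touches_border: bool
    area_px: int

    @classmethod
    def from_measurements(cls, label: int, area: float, perimeter: float,
                          centroid: tuple[float, float], touches_border: bool,
                          area_px: int) -> "ParticleRecord":
        if area <= 0 or perimeter <= 0:
            raise ValueError("area and perimeter must be positive")
        circ = min(4.0 * np.pi * area / perimeter**2, 1.05)
        return cls(label=label, area=area, perimeter=perimeter, circularity=circ,
                   hydraulic_radius=area / perimeter, centroid=centroid,
                   touches_border=touches_border, area_px=area_px)


@dataclass(frozen=True)
class ParticleFilter:
    """Size/shape/border particle filter.

    ``min_area`` is in mm^2 unless ``min_area_px`` is given instead (the
    classic Fiji setting is pixel-based).  The circularity window is a
    closed interval within [0, 1.05].
    """

    min_area: float = 0.0
    min_area_px: float | None = None
    circularity_range: tuple[float, float] = (0.0, 1.05)
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if self.min_area < 0 or (self.min_area_px is not None and self.min_area_px < 0):
            raise ValueError("min_area must be non-negative")
        lo, hi = self.circularity_range
        if lo > hi:
            raise ValueError("inverted circularity range")
        if not (0.0 <= lo <= 1.05 and 0.0 <= hi <= 1.05):
            raise ValueError("circularity bounds must lie in [0, 1.05]")


#: The study's literal Fiji preset: 2.5 px^2 minimum size, circularity 0.00-0.10.
FIJI_PORE_FILTER = ParticleFilter(min_area_px=2.5, circularity_range=(0.0, 0.10),
                                  exclude_border=True)
#: Default pipeline preset: size + border filtering, permissive circularity
#: (an ideal square pore has circularity ~0.785 and would be rejected by the
#: 0.00-0.10 window).
DEFAULT_PORE_FILTER = ParticleFilter(min_area_px=2.5, circularity_range=(0.0, 1.05),
                                     exclude_border=True)


def to_grayscale(img):
    """Convert 1- or 3-channel input to 8-bit luminance-weighted grayscale.

    Accepts a RasterImage (returned unchanged) or a HxW / HxWx3 array.
    """
    if isinstance(img, RasterImage):
        return img
    arr = np.asarray(img)
    if arr.ndim == 2:
        return np.clip(np.round(arr.astype(float)), 0, 255).astype(np.uint8)
    if arr.ndim == 3 and arr.shape[2] == 3:
        lum = arr[..., 0] * 0.2125 + arr[..., 1] * 0.7154 + arr[..., 2] * 0.0721
        return np.clip(np.round(lum), 0, 255).astype(np.uint8)
    raise ValueError(f"unsupported channel count: shape {arr.shape}")


def binarize(img: RasterImage, method: str = "otsu", threshold: float | None = None,
             polarity: str = "bright") -> BinaryMask:
    """Global threshold of an 8-bit grayscale image.

    ``polarity='bright'`` keeps pixels strictly above the threshold as
    foreground (pores appear bright between dark ink strands);
    ``polarity='dark'`` keeps pixels below it (the ink itself).  ``method``
    is ``'otsu'`` (256-bin histogram) or ``'fixed'`` with an explicit
    threshold.  The applied threshold is recorded in the mask provenance.
    """
    if polarity not in ("bright", "dark"):
        raise ValueError("polarity must be 'bright' or 'dark'")
    px = img.pixels
    if method == "otsu":
        if px.min() == px.max():
            raise ValueError("constant image: Otsu cannot separate foreground")
        thr = float(threshold_otsu(px, nbins=256))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold value")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = px > thr if polarity == "bright" else px < thr
    return BinaryMask(
        mask=mask,
        scale=img.scale,
        provenance={"method": method, "threshold": thr, "polarity": polarity},
        origin_mm=tuple(img.metadata.get("origin_mm", (0.0, 0.0))),
    )


def contour_perimeter_px(region_mask: np.ndarray, smooth_sigma: float | None = None) -> float:
    """Sub-pixel perimeter of a binary region in pixel units.

    Polygonal arc length of the marching-squares contour(s) at the 0.5
    iso-level of the (zero-padded) region.  Two corrections keep the bias
    below ~2% across shapes: a light Gaussian smoothing of the binary field
    suppresses the staircase bias on oblique boundaries (raw marching
    squares overestimates a digitized disk by ~6%), and a half-pixel
    Minkowski offset (+pi px on the outer contour, -pi on holes) maps the
    pixel-center iso-contour onto the pixel-area boundary, which the
    smoothing corners would otherwise undercut on rectangles.

    ``smooth_sigma`` defaults to an adaptive value (0.8-1.6 px, growing with
    the region's minor dimension) so large smooth particles get enough
    smoothing while small rectangles keep their corners.
    """
    if smooth_sigma is None:
        min_dim = min(region_mask.shape)
        smooth_sigma = float(np.clip(min_dim / 16.0, 0.8, 1.6))
    padded = np.pad(region_mask.astype(float), max(4, int(3 * smooth_sigma) + 1))
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        padded = gaussian_filter(padded, smooth_sigma)
    contours = skmeasure.find_contours(padded, 0.5)
    lengths = [float(np.hypot(*np.diff(c, axis=0).T).sum()) for c in contours]
    if not lengths or sum(lengths) == 0.0:
        if smooth_sigma > 0:
            # tiny specks can be smoothed below the iso-level; fall back to raw
            return contour_perimeter_px(region_mask, smooth_sigma=0.0)
        return 0.0
    outer = int(np.argmax(lengths))
    return sum(L + (np.pi if i == outer else -np.pi) for i, L in enumerate(lengths))


def label_particles(mask: BinaryMask, connectivity: int = 8) -> list[ParticleRecord]:
    """Connected-component particle analysis.

    One record per foreground component under the stated connectivity
    (8 by default; background is implicitly 4-connected).  Areas are pixel
    counts over scale^2; perimeters use the sub-pixel contour estimator;
    ``touches_border`` flags components with any pixel on the image edge.
    An empty mask yields an empty list.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab = skmeasure.label(mask.mask, connectivity=1 if connectivity == 4 else 2)
    records: list[ParticleRecord] = []
    h, w = mask.mask.shape
    scale = mask.scale
    for region in skmeasure.regionprops(lab):
        r0, c0, r1, c1 = region.bbox
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        per_px = contour_perimeter_px(region.image)
        cy, cx = region.centroid
        records.append(
            ParticleRecord.from_measurements(
                label=int(region.label),
                area=region.area / scale**2,
                perimeter=per_px / scale,
                centroid=((cx + 0.5) / scale, (cy + 0.5) / scale),
                touches_border=bool(touches),
                area_px=int(region.area),
            )
        )
    records.sort(key=lambda r: r.label)
    return records


def filter_particles(records, f: ParticleFilter) -> list[ParticleRecord]:
    """Apply size, circularity and border criteria; deterministic label order."""
    lo, hi = f.circularity_range
    out = []
    for r in sorted(records, key=lambda r: r.label):
        if f.min_area_px is not None:
            if r.area_px < f.min_area_px:
                continue
        elif r.area < f.min_area:
            continue
        if not (lo <= r.circularity <= hi):
            continue
        if f.exclude_border and r.touches_border:
            continue
        out.append(r)
    return out


def particles_to_csv(records, path) -> None:
    """Write a particle table (one row per record) as CSV."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "label": r.label,
                "area_mm2": r.area,
                "perimeter_mm": r.perimeter,
                "circularity": r.circularity,
                "hydraulic_radius_mm": r.hydraulic_radius,
                "centroid_x_mm": r.centroid[0],
                "centroid_y_mm": r.centroid[1],
                "touches_border": r.touches_border,
                "area_px": r.area_px,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def porosity(mask: BinaryMask, roi: tuple[float, float, float, float] | None = None) -> float:
    """Foreground (pore) area as a percentage of a rectangular ROI.

    ``roi`` is (x0, y0, x1, y1) in world mm (the mask's origin_mm frame);
    None analyses the full image.
    """
    m = mask.mask
    if roi is not None:
        x0, y0, x1, y1 = roi
        ox, oy = mask.origin_mm
        c0 = int(round((x0 - ox) * mask.scale))
        c1 = int(round((x1 - ox) * mask.scale))
        r0 = int(round((y0 - oy) * mask.scale))
        r1 = int(round((y1 - oy) * mask.scale))
        c0, r0 = max(c0, 0), max(r0, 0)
        c1, r1 = min(c1, m.shape[1]), min(r1, m.shape[0])
        if c1 <= c0 or r1 <= r0:
            raise ValueError("empty ROI")
        m = m[r0:r1, c0:c1]
    if m.size == 0:
        raise ValueError("empty ROI")
    return 100.0 * float(m.sum()) / m.size
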