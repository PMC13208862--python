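"""Deposition-model presets emulating the two extrusion systems.

The pneumatic preset reproduces the qualitative signature of pressure-driven
extrusion at the minimum extrusion pressure: strong die swell (SR ~ 1.8),
noticeably rougher boundaries (UF ~ 1.04), pronounced gel accumulation at
crossings and early coalescence in narrow gaps.

The screw (positive-displacement) presets are parameterized by the
volumetric extrusion factor: the deposited strand width interpolates
linearly from 0.45 mm at 50% to 0.76 mm at 100% flow (relative to a
0.41 mm nozzle this spans SR 1.10 ... 1.85), with smoother boundaries
(UF ~ 1.02) and much later fusion.
"""

from __future__ import annotations

from .metrics import NozzleSpec
from .render import DepositionModel

__all__ = ["pneumatic_deposition", "screw_deposition", "screw_strand_width",
           "DEFAULT_NOZZLE"]

DEFAULT_NOZZLE = NozzleSpec(gauge="22G", inner_diameter=0.41)

#: strand widths at the ends of the screw extrusion-factor sweep (mm)
_SCREW_W50 = 0.45
_SCREW_W100 = 0.76


def screw_strand_width(extrusion_factor_pct: float) -> float:
    """Deposited strand width (mm) at a given volumetric extrusion factor,
    interpolating the linear flow-to-width response between 50% and 100%."""
    if not (0 < extrusion_factor_pct <= 100):
        raise ValueError("extrusion factor must be in (0, 100] percent")
    return _SCREW_W50 + (_SCREW_W100 - _SCREW_W50) * (extrusion_factor_pct - 50.0) / 50.0


def pneumatic_deposition(seed: int = 0, nozzle: NozzleSpec = DEFAULT_NOZZLE) -> DepositionModel:
    """Pneumatic system at minimum extrusion pressure."""
    return DepositionModel(
        spread_ratio=1.82,
        roughness_amplitude=0.08,
        roughness_wavelength=0.4,
        corner_round_radius=0.35,
        fusion_gap=0.8,
        seed=seed,
    )


def screw_deposition(extrusion_factor_pct: float, seed: int = 0,
                     nozzle: NozzleSpec = DEFAULT_NOZZLE) -> DepositionModel:
    """Screw-driven system at the given volumetric extrusion factor (%)."""
    width = screw_strand_width(extrusion_factor_pct)
    return DepositionModel(
        spread_ratio=width / nozzle.inner_diameter,
        roughness_amplitude=0.055,
        roughness_wavelength=0.4,
        corner_round_radius=0.1,
        fusion_gap=0.1,
        seed=seed,
    )
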