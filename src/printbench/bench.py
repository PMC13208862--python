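"""End-to-end benchmark orchestration: generate -> render -> segment ->
measure -> report.

A :class:`BenchmarkConfig` names a set of samples, each referencing a
benchmark pattern (grid, line, serpentine, collapse) and a deposition
preset; :func:`run_benchmark` executes every stage per sample
deterministically (all randomness flows from one master seed, expanded per
sample from a hash of the sample name so adding samples never perturbs
existing ones), writes the per-sample artifacts (G-code, images, masks,
particle tables) and rolls the metrics up into a :class:`BenchmarkReport`.

The default configuration mirrors the study's sample matrix: a pneumatic
grid/line/serpentine plus a screw-driven extrusion-factor sweep from 50% to
100%, three replicates each (replicates vary only the noise seed), and
collapse side views at the three flow rates.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gcode import VolumetricCalibration, to_gcode
from .imageops import (DEFAULT_PORE_FILTER, FIJI_PORE_FILTER, ParticleFilter,
                       binarize, filter_particles, label_particles,
                       particles_to_csv, porosity)
from .metrics import (MaterialParams, NozzleSpec, apparent_yield_stress,
                      collapse_rate, fusion_analysis, printability_index,
                      strand_width_from_ink_area, uniformity_ratio)
from .patterns import (ChirpParams, CollapseFixture, GridParams,
                       collapse_toolpath, grid_toolpath, line_toolpath,
                       serpentine_toolpath)
from .presets import (DEFAULT_NOZZLE, pneumatic_deposition, screw_deposition)
from .render import (DepositionModel, SagModel, apply_camera_noise,
                     render_sideview, render_topview)

__all__ = ["SampleSpec", "BenchmarkConfig", "BenchmarkReport", "run_benchmark",
           "compare_systems", "default_config", "load_config"]

log = logging.getLogger("printbench")

_FILTER_PRESETS = {"default": DEFAULT_PORE_FILTER, "fiji": FIJI_PORE_FILTER}


@dataclass(frozen=True)
class SampleSpec:
    """One benchmark sample: a pattern printed with a deposition preset."""

    name: str
    pattern: str
    deposition: str
    system: str = "screw"
    extrusion_factor: float = 100.0  # percent
    n_replicates: int = 3
    max_sag: float | None = None  # collapse side views only, mm


@dataclass
class BenchmarkConfig:
    samples: list[SampleSpec]
    patterns: dict[str, dict]
    depositions: dict[str, dict]
    scale: float = 20.0
    filter_preset: str = "default"
    seed: int = 0
    nozzle: NozzleSpec = field(default_factory=lambda: DEFAULT_NOZZLE)
    material: MaterialParams = field(default_factory=MaterialParams)
    illum_gradient: float = 0.05
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("sample names must be unique")
        for s in self.samples:
            if s.pattern not in self.patterns:
                raise ValueError(f"sample {s.name!r} references unknown pattern {s.pattern!r}")
            if s.deposition not in self.depositions:
                raise ValueError(
                    f"sample {s.name!r} references unknown deposition preset {s.deposition!r}")
        if self.filter_preset not in _FILTER_PRESETS:
            raise ValueError(f"unknown filter preset {self.filter_preset!r}")

    def canonical_hash(self) -> str:
        blob = json.dumps(_as_plain(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class BenchmarkReport:
    rows: pd.DataFrame
    provenance: dict

    def write(self, out_dir: Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out_dir / "report.csv", index=False)
        payload = {
            "provenance": self.provenance,
            "rows": json.loads(self.rows.to_json(orient="records")),
        }
        (out_dir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def _as_plain(obj):
    if isinstance(obj, (SampleSpec, NozzleSpec, MaterialParams)):
        return _as_plain(asdict(obj))
    if isinstance(obj, BenchmarkConfig):
        return {
            "samples": [_as_plain(s) for s in obj.samples],
            "patterns": _as_plain(obj.patterns),
            "depositions": _as_plain(obj.depositions),
            "scale": obj.scale,
            "filter_preset": obj.filter_preset,
            "seed": obj.seed,
            "nozzle": _as_plain(obj.nozzle),
            "material": _as_plain(obj.material),
            "illum_gradient": obj.illum_gradient,
            "noise_sd": obj.noise_sd,
        }
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj


def sample_seed(master_seed: int, name: str) -> int:
    """Stable per-sample seed: a hash of the sample name mixed with the
    master seed, so the sample set can change without perturbing others."""
    digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# configuration


def default_config(seed: int = 0) -> BenchmarkConfig:
    """The study's sample matrix: pneumatic baseline plus a screw
    extrusion-factor sweep (50-100%), grids, lines, serpentines and
    collapse side views at the three characterized flow rates."""
    patterns = {
        "grid30": {"type": "grid", "outer_size": 30.0, "pore_pitch": 5.0,
                   "n_layers": 2, "layer_height": 0.51, "commanded_line_width": 0.41},
        "line30": {"type": "line", "length": 30.0, "commanded_width": 0.41},
        "serpentine": {"type": "serpentine", "amplitude": 10.0, "base_freq": 0.05,
                       "chirp_rate": 2.1, "x_range": [0.0, 50.0],
                       "commanded_width": 0.41},
        # midspan sag per sample reproduces the deflection angles measured
        # at the three flow rates over the 32 mm span
        "collapse32": {"type": "collapse", "span": 32.0, "filament_thickness": 0.8,
                       "pillar_width": 2.0, "pillar_height": 10.0},
    }
    depositions = {"pneumatic": {"system": "pneumatic"}}
    samples = [SampleSpec("GridP", "grid30", "pneumatic", system="pneumatic"),
               SampleSpec("LineP", "line30", "pneumatic", system="pneumatic"),
               SampleSpec("SerpentineP", "serpentine", "pneumatic", system="pneumatic")]
    for f in (50, 60, 70, 80, 90, 100):
        depositions[f"screw{f}"] = {"system": "screw", "extrusion_factor": float(f)}
        samples.append(SampleSpec(f"Grid{f}S", "grid30", f"screw{f}",
                                  extrusion_factor=float(f)))
        samples.append(SampleSpec(f"Line{f}S", "line30", f"screw{f}",
                                  extrusion_factor=float(f)))
    samples.append(SampleSpec("SerpentineS", "serpentine", "screw100",
                              extrusion_factor=100.0))
    for f, sag in ((50, 1.273), (75, 2.025), (100, 3.151)):
        key = f"screw{f}"
        if key not in depositions:
            depositions[key] = {"system": "screw", "extrusion_factor": float(f)}
        samples.append(SampleSpec(f"Collapse{f}S", "collapse32", key,
                                  extrusion_factor=float(f), max_sag=sag,
                                  n_replicates=1))
    return BenchmarkConfig(samples=samples, patterns=patterns,
                           depositions=depositions, seed=seed)


def load_config(path) -> BenchmarkConfig:
    """Read a benchmark configuration from YAML."""
    data = yaml.safe_load(Path(path).read_text())
    samples = [SampleSpec(**s) for s in data["samples"]]
    kwargs = {}
    if "nozzle" in data:
        kwargs["nozzle"] = NozzleSpec(**data["nozzle"])
    if "material" in data:
        kwargs["material"] = MaterialParams(**data["material"])
    for key in ("scale", "filter_preset", "seed", "illum_gradient", "noise_sd"):
        if key in data:
            kwargs[key] = data[key]
    return BenchmarkConfig(samples=samples, patterns=data["patterns"],
                           depositions=data["depositions"], **kwargs)


def build_toolpath(pattern: dict):
    """Instantiate a toolpath from a pattern definition dict."""
    kind = pattern["type"]
    if kind == "grid":
        keys = ("outer_size", "pore_pitch", "n_layers", "layer_height",
                "commanded_line_width")
        return grid_toolpath(GridParams(**{k: pattern[k] for k in keys if k in pattern}))
    if kind == "line":
        return line_toolpath(pattern.get("length", 30.0),
                             pattern.get("commanded_width", 0.41))
    if kind == "serpentine":
        p = ChirpParams(amplitude=pattern.get("amplitude", 10.0),
                        base_freq=pattern.get("base_freq", 0.05),
                        chirp_rate=pattern.get("chirp_rate", 2.1),
                        x_range=tuple(pattern.get("x_range", (0.0, 50.0))))
        return serpentine_toolpath(p, pattern.get("commanded_width", 0.41))
    if kind == "collapse":
        fixture = CollapseFixture(gap_list=tuple(pattern.get("gap_list", (1, 2, 4, 8, 16))),
                                  pillar_width=pattern.get("pillar_width", 2.0),
                                  pillar_height=pattern.get("pillar_height", 10.0))
        return collapse_toolpath(fixture, pattern.get("commanded_width", 0.41))
    raise ValueError(f"unknown pattern type {kind!r}")


def build_deposition(preset: dict, seed: int, nozzle: NozzleSpec) -> DepositionModel:
    if "spread_ratio" in preset:  # fully explicit model
        return DepositionModel(seed=seed, **{k: v for k, v in preset.items()
                                             if k != "system"})
    system = preset.get("system", "screw")
    if system == "pneumatic":
        return pneumatic_deposition(seed=seed, nozzle=nozzle)
    if system == "screw":
        return screw_deposition(preset.get("extrusion_factor", 100.0), seed=seed,
                                nozzle=nozzle)
    raise ValueError(f"unknown deposition system {system!r}")


# ---------------------------------------------------------------------------
# per-sample analysis


def _analyse_grid(img, pattern: dict, pfilter: ParticleFilter, nozzle: NozzleSpec) -> dict:
    outer = pattern["outer_size"]
    n_cells = int(round(outer / pattern["pore_pitch"]))
    mask = binarize(img, "otsu", polarity="bright")
    particles = label_particles(mask)
    pores = filter_particles(particles, pfilter)
    roi = (0.0, 0.0, outer, outer)
    por = porosity(mask, roi=roi)
    ink_area = (100.0 - por) / 100.0 * outer**2
    width = strand_width_from_ink_area(ink_area, outer, n_cells)
    row = {
        "porosity_pct": por,
        "n_pores": len(pores),
        "strand_width_mm": width,
        "spreading_ratio": width / nozzle.inner_diameter,
    }
    if pores:
        prs = [printability_index(r) for r in pores]
        row.update(
            pr_mean=float(np.mean(prs)),
            pr_sd=float(np.std(prs)),
            hydraulic_radius_mm=float(np.mean([r.hydraulic_radius for r in pores])),
            pore_area_mm2=float(np.mean([r.area for r in pores])),
            pore_perimeter_mm=float(np.mean([r.perimeter for r in pores])),
        )
    return row, mask, particles


def _analyse_line(img, pattern: dict, nozzle: NozzleSpec) -> dict:
    lm = uniformity_ratio(img, nozzle=nozzle)
    return {
        "width_mm": lm.mean_width,
        "width_sd_mm": lm.width_sd,
        "spreading_ratio": lm.spreading_ratio,
        "uniformity": lm.uniformity,
    }


def _analyse_serpentine(img, toolpath) -> dict:
    fr = fusion_analysis(img, toolpath.metadata)
    return {
        "lt_mm": fr.line_thickness,
        "lmin_mm": fr.lmin,
        "n_open_gaps": sum(g.open for g in fr.gaps),
        "n_gaps": len(fr.gaps),
        "n_missing_legs": len(fr.missing_legs),
    }


def _analyse_collapse(img, pattern: dict, material: MaterialParams) -> dict:
    depth = pattern.get("pillar_height", 10.0)
    cm = collapse_rate(img, reference_depth=depth)
    row = {
        "theta_deg": cm.deflection_angle,
        "cf_pct": cm.collapse_rate,
        "half_gap_mm": cm.half_gap,
    }
    try:
        row["sigma0_pa"] = apparent_yield_stress(cm.deflection_angle, material,
                                                 cm.half_gap)
    except ValueError:
        row["sigma0_pa"] = float("inf")  # no measurable deflection
    return row


# ---------------------------------------------------------------------------
# the run


def run_benchmark(cfg: BenchmarkConfig, out_dir) -> BenchmarkReport:
    """Execute every stage for every sample and write all artifacts.

    Per-sample failures are recorded in the report (``error`` column) and
    the run continues; an invalid configuration raises before any output.
    Two runs with identical config produce byte-identical report tables.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pfilter = _FILTER_PRESETS[cfg.filter_preset]
    rows = []
    artifacts: dict[str, list[str]] = {}
    for spec in cfg.samples:
        t0 = time.perf_counter()
        base_seed = sample_seed(cfg.seed, spec.name)
        sdir = out_dir / spec.name
        sdir.mkdir(parents=True, exist_ok=True)
        files: list[str] = []
        try:
            pattern = cfg.patterns[spec.pattern]
            rep_rows = []
            for rep in range(spec.n_replicates):
                seed = (base_seed + rep) % (2**31)
                row = {"sample": spec.name, "replicate": rep, "system": spec.system,
                       "pattern": pattern["type"],
                       "extrusion_factor_pct": spec.extrusion_factor, "error": ""}
                if pattern["type"] == "collapse":
                    sag = spec.max_sag if spec.max_sag is not None else 0.0
                    model = SagModel(span=pattern.get("span", 32.0), max_sag=sag,
                                     filament_thickness=pattern.get("filament_thickness", 0.8))
                    img = render_sideview(model, scale=cfg.scale,
                                          pillar_width=pattern.get("pillar_width", 2.0),
                                          pillar_height=pattern.get("pillar_height", 10.0))
                    img = apply_camera_noise(img, cfg.illum_gradient, cfg.noise_sd,
                                             seed=seed)
                    img_path = sdir / f"side_{rep}.png"
                    img.save(img_path)
                    files += [img_path.name, img_path.name + ".json"]
                    row.update(_analyse_collapse(img, pattern, cfg.material))
                else:
                    toolpath = build_toolpath(pattern)
                    model = build_deposition(cfg.depositions[spec.deposition],
                                             seed=seed, nozzle=cfg.nozzle)
                    if rep == 0:
                        cal = VolumetricCalibration(
                            extrusion_factor=spec.extrusion_factor / 100.0)
                        gcode_path = sdir / f"{spec.name}.gcode"
                        gcode_path.write_text(to_gcode(toolpath, cal))
                        toolpath.to_csv(sdir / f"{spec.name}_toolpath.csv")
                        files += [gcode_path.name, f"{spec.name}_toolpath.csv"]
                    img = render_topview(toolpath, model, scale=cfg.scale)
                    img = apply_camera_noise(img, cfg.illum_gradient, cfg.noise_sd,
                                             seed=seed)
                    img_path = sdir / f"top_{rep}.png"
                    img.save(img_path)
                    files += [img_path.name, img_path.name + ".json"]
                    if pattern["type"] == "grid":
                        grid_row, mask, particles = _analyse_grid(img, pattern,
                                                                  pfilter, cfg.nozzle)
                        row.update(grid_row)
                        if rep == 0:
                            mask.save(sdir / "mask_0.png")
                            particles_to_csv(particles, sdir / "particles_0.csv")
                            files += ["mask_0.png", "mask_0.png.json", "particles_0.csv"]
                    elif pattern["type"] == "line":
                        row.update(_analyse_line(img, pattern, cfg.nozzle))
                    elif pattern["type"] == "serpentine":
                        row.update(_analyse_serpentine(img, toolpath))
                rep_rows.append(row)
            rows.extend(rep_rows)
        except Exception as exc:  # per-sample failure: record and continue
            log.warning("sample %s failed: %s", spec.name, exc)
            rows.append({"sample": spec.name, "replicate": 0, "system": spec.system,
                         "pattern": cfg.patterns[spec.pattern]["type"],
                         "extrusion_factor_pct": spec.extrusion_factor,
                         "error": str(exc)})
        artifacts[spec.name] = files
        log.info("sample %s: %.2f s", spec.name, time.perf_counter() - t0)

    df = pd.DataFrame(rows)
    report = BenchmarkReport(
        rows=df,
        provenance={
            "config_hash": cfg.canonical_hash(),
            "seed": cfg.seed,
            "version": __version__,
            "artifacts": artifacts,
        },
    )
    report.write(out_dir)
    return report


def aggregate(report: BenchmarkReport) -> pd.DataFrame:
    """Mean +/- SD of every numeric metric per sample across replicates."""
    num = report.rows.drop(columns=["error"], errors="ignore")
    grouped = num.groupby("sample", sort=False)
    means = grouped.mean(numeric_only=True).drop(columns=["replicate"], errors="ignore")
    sds = grouped.std(numeric_only=True).drop(columns=["replicate"], errors="ignore")
    sds.columns = [f"{c}_repsd" for c in sds.columns]
    return means.join(sds)


def compare_systems(report: BenchmarkReport, metric: str,
                    baseline: str | None = None) -> pd.DataFrame:
    """Per-sample table of one metric, sorted, with deltas vs a baseline."""
    agg = aggregate(report)
    if metric not in agg.columns:
        raise KeyError(f"unknown metric {metric!r}; available: {sorted(agg.columns)}")
    table = agg[[metric]].dropna()
    if len(table) < 2:
        raise ValueError("need at least two samples with this metric to compare")
    table = table.sort_values(metric)
    if baseline is not None:
        if baseline not in table.index:
            raise KeyError(f"baseline sample {baseline!r} has no value for {metric!r}")
        table = table.assign(**{f"delta_vs_{baseline}":
                                table[metric] - table.loc[baseline, metric]})
    return table
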