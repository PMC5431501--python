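"""Run configuration: one YAML document describing geometry, fluid,
experiment design, generator and analysis settings.

Every block is optional; omitted keys fall back to the bench study's
setup (size 30/0.04 taper canals 23 mm long, a 30-gauge side-venting
needle, three 0.5 mm cross-channels over the middle third, water-like
irrigant, the 2 x 2 x 4 design with 12 replicates of 5 mL deliveries).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import (
    AnastomosisChannel,
    CanalGeometry,
    Needle,
    RootCanalSystem,
    _default_channels,
)
from .hydraulics import Fluid
from .synthetic_data import (
    CONTROL_NOISE_BOUND,
    ExperimentDesign,
    GroupGeneratorSpec,
    BENCH_GROUP_STATS,
    default_group_specs,
)

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """A configuration key failed validation."""


_KNOWN_BLOCKS = {
    "canal", "needle", "channels", "fluid", "design", "generator",
    "analysis", "seed",
}


def _take(block: dict, allowed: set[str], where: str) -> dict:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in block {where!r}")
    return block


@dataclass
class RunConfig:
    """Fully resolved run configuration."""

    canal: CanalGeometry = field(default_factory=CanalGeometry)
    needle: Needle = field(default_factory=Needle)
    channels: tuple[AnastomosisChannel, ...] = field(
        default_factory=lambda: _default_channels()
    )
    fluid: Fluid = field(default_factory=Fluid)
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    group_specs: dict = field(default_factory=default_group_specs)
    p_threshold: float = 4.0
    grid: float = 0.5
    alpha: float = 0.05
    k_imp: float = 1.0
    reference_pressure_kPa: float = 8.63
    reference_depth_mm: float = 1.0
    reference_flow_mL_min: float = 9.5
    raw: dict = field(default_factory=dict)

    def system(self, model: str) -> RootCanalSystem:
        if model == "separate":
            return RootCanalSystem(
                canal_a=self.canal, canal_b=self.canal, channels=()
            )
        if model == "anastomosis":
            return RootCanalSystem(
                canal_a=self.canal, canal_b=self.canal, channels=self.channels
            )
        raise ConfigError(f"unknown model {model!r}")

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Load a YAML config; ``None`` gives the all-defaults configuration.

    ``seed`` overrides the config's master seed when given.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        raw = loaded
    unknown = set(raw) - _KNOWN_BLOCKS
    if unknown:
        raise ConfigError(f"unknown top-level block(s) {sorted(unknown)}")

    canal_kw = _take(dict(raw.get("canal", {})),
                     {"apical_diameter", "taper", "length"}, "canal")
    canal = CanalGeometry(**canal_kw)

    needle_kw = _take(
        dict(raw.get("needle", {})),
        {"gauge", "outer_diameter", "inner_diameter", "tip_style", "vent_offset"},
        "needle",
    )
    needle = Needle(**needle_kw)

    ch = _take(
        dict(raw.get("channels", {})),
        {"count", "width", "depth", "length", "positions", "profile"},
        "channels",
    )
    count = int(ch.get("count", 3))
    positions = ch.get("positions")
    base = {
        "width": float(ch.get("width", 0.5)),
        "depth": float(ch.get("depth", 0.5)),
        "length": float(ch.get("length", 1.0)),
        "profile": ch.get("profile", "square"),
    }
    if positions is not None:
        channels = tuple(
            AnastomosisChannel(axial_position=float(p), **base) for p in positions
        )
    else:
        template = _default_channels(count, canal.length, base["length"])
        channels = tuple(
            AnastomosisChannel(axial_position=c.axial_position, **base)
            for c in template
        )

    fluid_kw = _take(dict(raw.get("fluid", {})),
                     {"density", "dynamic_viscosity"}, "fluid")
    fluid = Fluid(**fluid_kw)

    d = _take(
        dict(raw.get("design", {})),
        {"models", "depths", "flow_rates", "replicates", "volume"},
        "design",
    )
    design = ExperimentDesign(
        models=tuple(d.get("models", ("separate", "anastomosis"))),
        depths=tuple(float(x) for x in d.get("depths", (1.0, 3.0))),
        flow_rates=tuple(float(x) for x in d.get("flow_rates", (1.5, 2.5, 9.5, 15.6))),
        replicates=int(d.get("replicates", 12)),
        volume=float(d.get("volume", 5.0)),
        seed=int(seed if seed is not None else raw.get("seed", 0)),
    )

    g = _take(
        dict(raw.get("generator", {})),
        {"noise_sd", "rise_time", "control_noise_bound", "overrides"},
        "generator",
    )
    noise_sd = float(g.get("noise_sd", CONTROL_NOISE_BOUND))
    specs = {}
    for key in design.groups:
        if key in BENCH_GROUP_STATS:
            med, iqr = BENCH_GROUP_STATS[key]
        else:
            raise ConfigError(
                f"group {key} has no default median; provide a generator "
                "override with target_median/iqr"
            )
        specs[key] = GroupGeneratorSpec(
            target_median=med,
            dispersion=iqr / 2.0,
            rise_time=float(g.get("rise_time", 3.0)),
            noise_sd=noise_sd,
            control_noise_bound=float(g.get("control_noise_bound", CONTROL_NOISE_BOUND)),
        )
    for label, over in (g.get("overrides") or {}).items():
        model, depth_s, flow_s = str(label).split("/")
        key = (model, float(depth_s.rstrip("m")), float(flow_s))
        if key not in specs:
            raise ConfigError(f"override {label!r} names a group outside the design")
        prev = specs[key]
        specs[key] = GroupGeneratorSpec(
            target_median=float(over.get("target_median", prev.target_median)),
            dispersion=float(over.get("iqr", 2.0 * prev.dispersion)) / 2.0,
            rise_time=float(over.get("rise_time", prev.rise_time)),
            noise_sd=float(over.get("noise_sd", prev.noise_sd)),
            control_noise_bound=prev.control_noise_bound,
        )

    a = _take(
        dict(raw.get("analysis", {})),
        {
            "p_threshold", "grid", "alpha", "k_imp",
            "reference_pressure_kPa", "reference_depth_mm", "reference_flow_mL_min",
        },
        "analysis",
    )
    resolved = dict(raw)
    resolved["seed"] = design.seed
    return RunConfig(
        canal=canal,
        needle=needle,
        channels=channels,
        fluid=fluid,
        design=design,
        group_specs=specs,
        p_threshold=float(a.get("p_threshold", 4.0)),
        grid=float(a.get("grid", 0.5)),
        alpha=float(a.get("alpha", 0.05)),
        k_imp=float(a.get("k_imp", 1.0)),
        reference_pressure_kPa=float(a.get("reference_pressure_kPa", 8.63)),
        reference_depth_mm=float(a.get("reference_depth_mm", 1.0)),
        reference_flow_mL_min=float(a.get("reference_flow_mL_min", 9.5)),
        raw=resolved,
    )
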