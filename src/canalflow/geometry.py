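"""Geometry of a simulated two-canal root with optional anastomoses.

The simulated root is machined in a rigid block: two parallel tapered
canals whose apical ends are closed (each connected to a pressure sensor
through a primed, liquid-filled line), optionally joined by small milled
cross-channels ("anastomoses").  An irrigation needle inserted into the
test canal partially occludes it; every pressure in the system is driven
by the *net* cross-sectional area left for fluid flow between the canal
wall and the needle shaft.

Axial convention: station 0 mm is the faux apical terminus; stations grow
coronally.  The needle tip sits at ``station == insertion_depth`` and the
shaft occupies all stations coronal to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Needle",
    "CanalGeometry",
    "AnastomosisChannel",
    "RootCanalSystem",
    "AnnulusSection",
    "NeedleBindsError",
    "canal_diameter_at",
    "net_flow_area",
    "net_area_profile",
]


class NeedleBindsError(ValueError):
    """Needle outer diameter meets or exceeds the canal diameter somewhere
    along the occupied length: insertion would not be non-binding."""


@dataclass(frozen=True)
class Needle:
    """An irrigation needle, described by its hypodermic gauge and diameters.

    Defaults are the ISO 9626 nominal normal-wall dimensions of a 30-gauge
    needle (outer 0.31 mm, inner 0.159 mm), the size used with closed-end
    side-venting tips in apical irrigation.

    Parameters
    ----------
    gauge : int
        Hypodermic gauge label.
    outer_diameter, inner_diameter : float
        Shaft diameters in mm; ``outer > inner > 0``.
    tip_style : {"side_vent", "open_end"}
        Closed-end side-venting tips expel fluid through a lateral outlet.
    vent_offset : float
        Distance (mm) from the physical tip to the centre of the side-vent
        outlet; 0 for an open-ended needle.
    """

    gauge: int = 30
    outer_diameter: float = 0.31
    inner_diameter: float = 0.159
    tip_style: str = "side_vent"
    vent_offset: float = 0.5

    def __post_init__(self) -> None:
        if not self.outer_diameter > self.inner_diameter > 0:
            raise ValueError("need outer_diameter > inner_diameter > 0")
        if self.vent_offset < 0:
            raise ValueError("vent_offset must be >= 0")
        if self.tip_style not in ("side_vent", "open_end"):
            raise ValueError(f"unknown tip_style {self.tip_style!r}")


@dataclass(frozen=True)
class CanalGeometry:
    """A tapered instrumented canal.

    The canal is the shape left by an instrument of tip size
    ``apical_diameter`` (mm) and constant ``taper`` (mm of diameter per mm
    of length), run to a working length of ``length`` mm.  Diameter at
    station ``d`` is ``apical_diameter + taper * d``.
    """

    apical_diameter: float = 0.30
    taper: float = 0.04
    length: float = 23.0

    def __post_init__(self) -> None:
        if self.apical_diameter <= 0:
            raise ValueError("apical_diameter must be > 0")
        if self.taper < 0:
            raise ValueError("taper must be >= 0")
        if self.length <= 0:
            raise ValueError("length must be > 0")

    def diameter_at(self, d: float) -> float:
        return canal_diameter_at(self, d)


@dataclass(frozen=True)
class AnastomosisChannel:
    """A milled cross-channel joining the two canals.

    ``width``/``depth`` are the slot cross-section (mm); ``length`` is the
    inter-canal span (mm) and ``axial_position`` the station (mm coronal to
    the apical terminus) at which the channel meets both canals.
    ``profile`` is "square" (slot milled full-depth) or "rounded"
    (semicircular-bottom slot left by a ball-nosed cutter).
    """

    width: float = 0.5
    depth: float = 0.5
    length: float = 1.0
    axial_position: float = 11.5
    profile: str = "square"

    def __post_init__(self) -> None:
        for name in ("width", "depth", "length", "axial_position"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.profile not in ("square", "rounded"):
            raise ValueError(f"unknown profile {self.profile!r}")

    @property
    def area(self) -> float:
        """Cross-sectional area in mm^2."""
        if self.profile == "square":
            return self.width * self.depth
        # rectangle over a semicircular bottom of radius width/2
        r = self.width / 2.0
        return self.width * (self.depth - r) + math.pi * r * r / 2.0

    @property
    def perimeter(self) -> float:
        """Wetted perimeter in mm."""
        if self.profile == "square":
            return 2.0 * (self.width + self.depth)
        r = self.width / 2.0
        return 2.0 * (self.depth - r) + self.width + math.pi * r

    @property
    def hydraulic_diameter(self) -> float:
        return 4.0 * self.area / self.perimeter


def _default_channels(
    n: int = 3, canal_length: float = 23.0, separation: float = 1.0
) -> tuple[AnastomosisChannel, ...]:
    """Evenly spaced channels over the middle third of the canal length."""
    positions = np.linspace(canal_length / 3.0, 2.0 * canal_length / 3.0, n + 2)[1:-1]
    return tuple(
        AnastomosisChannel(axial_position=float(p), length=separation)
        for p in positions
    )


@dataclass(frozen=True)
class RootCanalSystem:
    """Two parallel canals, optionally joined by anastomosis channels.

    An empty ``channels`` tuple is the *separate* model; any channels make
    it the *anastomosis* model.
    """

    canal_a: CanalGeometry = field(default_factory=CanalGeometry)
    canal_b: CanalGeometry = field(default_factory=CanalGeometry)
    channels: tuple[AnastomosisChannel, ...] = ()
    canal_separation: float = 1.0

    def __post_init__(self) -> None:
        if self.canal_separation <= 0:
            raise ValueError("canal_separation must be > 0")
        max_len = min(self.canal_a.length, self.canal_b.length)
        for ch in self.channels:
            if ch.axial_position >= max_len:
                raise ValueError(
                    f"channel at {ch.axial_position} mm lies beyond the "
                    f"{max_len} mm canal length"
                )

    @property
    def is_anastomosed(self) -> bool:
        return len(self.channels) > 0

    @classmethod
    def separate_model(cls, **kwargs) -> "RootCanalSystem":
        """The bench 'separate canal model': two unconnected canals."""
        return cls(channels=(), **kwargs)

    @classmethod
    def anastomosis_model(cls, n_channels: int = 3, **kwargs) -> "RootCanalSystem":
        """The bench 'canal anastomosis model': three milled cross-channels
        spread over the middle third of the root (positions configurable by
        passing ``channels`` explicitly)."""
        canal = kwargs.get("canal_a", CanalGeometry())
        sep = kwargs.get("canal_separation", 1.0)
        if "channels" not in kwargs:
            kwargs["channels"] = _default_channels(n_channels, canal.length, sep)
        return cls(**kwargs)


@dataclass(frozen=True)
class AnnulusSection:
    """The flow cross-section of a canal at one axial station.

    Where the needle shaft is present the section is the annulus between
    canal wall and shaft; elsewhere it is the full circle.  ``net_area`` is
    the area available for fluid flow (mm^2); ``hydraulic_diameter`` is the
    canal diameter minus the needle outer diameter when the needle is
    present, else the canal diameter (mm).
    """

    canal_diameter: float
    needle_outer_diameter: float  # 0.0 where the needle is absent
    net_area: float
    hydraulic_diameter: float

    @property
    def net_area_m2(self) -> float:
        return self.net_area * 1e-6

    @property
    def hydraulic_diameter_m(self) -> float:
        return self.hydraulic_diameter * 1e-3


def canal_diameter_at(geometry: CanalGeometry, d: float) -> float:
    """Canal diameter (mm) at station ``d`` mm coronal to the apical terminus.

    Linear taper law: ``apical_diameter + taper * d``.  ``d`` must lie in
    ``[0, length]``.
    """
    if not 0.0 <= d <= geometry.length:
        raise ValueError(
            f"station {d} mm outside canal [0, {geometry.length}] mm"
        )
    return geometry.apical_diameter + geometry.taper * d


def _check_binding(
    canal: CanalGeometry, needle: Needle, insertion_depth: float
) -> None:
    # taper >= 0 so the narrowest occupied station is the needle tip
    tip_diameter = canal_diameter_at(canal, insertion_depth)
    if tip_diameter <= needle.outer_diameter:
        raise NeedleBindsError(
            f"canal diameter {tip_diameter:.3f} mm at the needle tip "
            f"(depth {insertion_depth} mm) does not clear the needle outer "
            f"diameter {needle.outer_diameter} mm; insertion would bind"
        )


def net_flow_area(
    system: RootCanalSystem,
    needle: Needle,
    insertion_depth: float,
    station: float,
    canal: str = "a",
) -> AnnulusSection:
    """Net cross-sectional area available for fluid flow at one station.

    The needle occupies all stations coronal to its tip
    (``station >= insertion_depth``); there the net area is the annulus
    ``pi/4 (D_canal^2 - D_needle^2)``, elsewhere the full circle
    ``pi/4 D_canal^2``.

    Raises
    ------
    NeedleBindsError
        If the canal does not clear the needle anywhere it is occupied.
    """
    if insertion_depth <= 0:
        # at depth 0 a default needle (OD 0.31 mm) cannot clear the 0.30 mm
        # terminus; treat non-positive depth as a binding insertion outright
        raise NeedleBindsError(
            f"insertion depth must be > 0 (got {insertion_depth} mm): the "
            "needle binds at the apical terminus"
        )
    geom = system.canal_a if canal == "a" else system.canal_b
    _check_binding(geom, needle, insertion_depth)
    d_canal = canal_diameter_at(geom, station)
    if station >= insertion_depth:
        net = math.pi / 4.0 * (d_canal**2 - needle.outer_diameter**2)
        if net <= 0:
            raise NeedleBindsError(
                f"needle binds at station {station} mm"
            )
        return AnnulusSection(
            canal_diameter=d_canal,
            needle_outer_diameter=needle.outer_diameter,
            net_area=net,
            hydraulic_diameter=d_canal - needle.outer_diameter,
        )
    return AnnulusSection(
        canal_diameter=d_canal,
        needle_outer_diameter=0.0,
        net_area=math.pi / 4.0 * d_canal**2,
        hydraulic_diameter=d_canal,
    )


def net_area_profile(
    system: RootCanalSystem,
    needle: Needle,
    depths: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Net flow area at the needle tip for a sweep of insertion depths.

    For each depth the reported station is the tip station itself — the
    narrowest, pressure-controlling section.  Default sweep: 1–10 mm in
    0.5 mm steps (19 rows), the depth range probed in the bench pilot.

    Returns a DataFrame with columns ``station_mm`` and ``net_area_mm2``;
    strictly increasing in depth for a positively tapered canal.
    """
    if depths is None:
        depths = np.arange(1.0, 10.0 + 0.25, 0.5)
    rows = []
    for d in depths:
        sec = net_flow_area(system, needle, insertion_depth=float(d), station=float(d))
        rows.append({"station_mm": float(d), "net_area_mm2": sec.net_area})
    return pd.DataFrame(rows)
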