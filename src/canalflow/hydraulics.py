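"""Periapical pressure from flow rate, geometry and fluid properties.

Three estimation routes, in increasing fidelity:

1. *Dynamic-pressure deduction*: the closed apical sensor predominantly
   reads the kinetic head of the incoming fluid column, ``q = 1/2 rho v^2``
   with ``v = Q / A`` the effective velocity through the net annular area
   between canal wall and needle shaft.

2. *Force calibration*: since pressure is force over area, one measured
   reference pressure at a known net area fixes an equivalent force
   ``F = p_ref A_ref``; the pressure at any other insertion depth is then
   ``F / A(depth)``.  Frictional head loss is deliberately excluded from
   this route.

3. *Lumped resistive network*: canals and cross-channels become edges of a
   hydraulic network (laminar Hagen-Poiseuille conductances, optional
   Darcy-Weisbach/Blasius turbulent correction); node pressures solve
   Kirchhoff mass conservation.  Closed apical dead-ends carry no flow and
   sit at the adjacent junction's static pressure plus an impingement share
   ``k_imp`` of the dynamic pressure, transmitted through the primed
   incompressible column (Pascal's law).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import quad

from .geometry import (
    AnastomosisChannel,
    AnnulusSection,
    Needle,
    NeedleBindsError,
    RootCanalSystem,
    canal_diameter_at,
    net_flow_area,
)

__all__ = [
    "Fluid",
    "FlowSpec",
    "ForceCalibration",
    "HydraulicNetwork",
    "NetworkSolution",
    "effective_velocity",
    "dynamic_pressure",
    "reynolds_number",
    "calibrate_force",
    "theoretical_pressure_at_depth",
    "annulus_laminar_conductance",
    "pipe_laminar_conductance",
    "duct_laminar_conductance",
    "solve_network",
    "pressure_reduction_factor",
]

#: laminar/turbulent transition for the Reynolds regime flag
RE_TRANSITION = 2300.0


@dataclass(frozen=True)
class Fluid:
    """Irrigant properties. Defaults: water-like 2% NaOCl at 25 C."""

    density: float = 1000.0  # kg/m^3
    dynamic_viscosity: float = 1.0e-3  # Pa s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and dynamic_viscosity must be > 0")


@dataclass(frozen=True)
class FlowSpec:
    """Irrigant delivery: flow rate (mL/min canonical) and total volume (mL)."""

    flow_rate: float  # mL/min
    delivered_volume: float = 5.0  # mL

    def __post_init__(self) -> None:
        if self.flow_rate < 0:
            raise ValueError("flow_rate must be >= 0")
        if self.delivered_volume <= 0:
            raise ValueError("delivered_volume must be > 0")

    @property
    def ml_per_s(self) -> float:
        return self.flow_rate / 60.0

    @property
    def m3_per_s(self) -> float:
        return self.flow_rate * 1e-6 / 60.0


@dataclass(frozen=True)
class ForceCalibration:
    """Equivalent apical force fixed by one reference measurement.

    ``force = reference_pressure * reference_area`` in SI; dividing by the
    net area at any other depth predicts the pressure there.
    """

    reference_pressure: float  # kPa
    reference_area: float  # mm^2
    force: float  # N

    @classmethod
    def from_reference(cls, p_ref_kpa: float, area_mm2: float) -> "ForceCalibration":
        if p_ref_kpa <= 0:
            raise ValueError("reference pressure must be > 0")
        if area_mm2 <= 0:
            raise ValueError("reference area must be > 0")
        force = (p_ref_kpa * 1e3) * (area_mm2 * 1e-6)
        return cls(reference_pressure=p_ref_kpa, reference_area=area_mm2, force=force)


def effective_velocity(flow: FlowSpec | float, section: AnnulusSection) -> float:
    """Effective fluid velocity ``v = Q / A`` in m/s.

    ``flow`` may be a FlowSpec or a plain rate in mL/min.
    """
    q = flow.m3_per_s if isinstance(flow, FlowSpec) else flow * 1e-6 / 60.0
    if section.net_area_m2 <= 0:
        raise ValueError("net area must be > 0")
    return q / section.net_area_m2


def dynamic_pressure(fluid: Fluid, v: float) -> float:
    """Dynamic pressure ``1/2 rho v^2`` in kPa for velocity ``v`` (m/s).

    The kinetic energy per unit *volume* of the moving fluid — the head a
    closed-end sensor reads when the incoming jet stagnates against the
    confined column.
    """
    if v < 0:
        raise ValueError("velocity must be >= 0")
    return 0.5 * fluid.density * v * v / 1e3


def reynolds_number(
    fluid: Fluid, v: float, section: AnnulusSection
) -> tuple[float, str]:
    """Reynolds number ``rho v D_h / mu`` and its regime flag.

    Returns ``(Re, regime)`` with regime ``"laminar"`` for Re < 2300 else
    ``"turbulent"``.
    """
    if section.hydraulic_diameter_m <= 0:
        raise ValueError("hydraulic diameter must be > 0")
    re = fluid.density * abs(v) * section.hydraulic_diameter_m / fluid.dynamic_viscosity
    return re, ("laminar" if re < RE_TRANSITION else "turbulent")


def calibrate_force(p_ref_kpa: float, section_ref: AnnulusSection) -> ForceCalibration:
    """Fix the equivalent apical force from one reference measurement."""
    return ForceCalibration.from_reference(p_ref_kpa, section_ref.net_area)


def theoretical_pressure_at_depth(
    cal: ForceCalibration, section: AnnulusSection
) -> float:
    """Predicted pressure ``F / A`` (kPa) at the net area of another depth.

    Strictly decreasing in insertion depth for a positively tapered canal;
    returns the reference pressure exactly at the reference area.
    """
    if section.net_area_m2 <= 0:
        raise ValueError("net area must be > 0")
    return cal.force / section.net_area_m2 / 1e3


# ---------------------------------------------------------------------------
# laminar conductances (SI: m^3/s per Pa)
# ---------------------------------------------------------------------------


def annulus_laminar_conductance(
    r_outer: float, r_inner: float, length: float, fluid: Fluid
) -> float:
    """Hagen-Poiseuille conductance of a concentric annulus.

    ``Q / dP = (pi / 8 mu L) [r_o^4 - r_i^4 - (r_o^2 - r_i^2)^2 / ln(r_o/r_i)]``
    with radii and length in metres.  Reduces to the circular-pipe law as
    ``r_i -> 0``.
    """
    if not r_outer > r_inner >= 0:
        raise ValueError("need r_outer > r_inner >= 0")
    if length <= 0:
        raise ValueError("length must be > 0")
    mu = fluid.dynamic_viscosity
    if r_inner == 0.0:
        return math.pi * r_outer**4 / (8.0 * mu * length)
    ro2, ri2 = r_outer**2, r_inner**2
    bracket = r_outer**4 - r_inner**4 - (ro2 - ri2) ** 2 / math.log(r_outer / r_inner)
    return math.pi * bracket / (8.0 * mu * length)


def pipe_laminar_conductance(radius: float, length: float, fluid: Fluid) -> float:
    """Circular-pipe Hagen-Poiseuille conductance ``pi r^4 / (8 mu L)``."""
    return annulus_laminar_conductance(radius, 0.0, length, fluid)


# leading terms of the rectangular-duct series sum_{n odd} tanh(n pi w / 2h)/n^5
_RECT_ODD_N = np.arange(1, 12, 2, dtype=float)


def duct_laminar_conductance(channel: AnastomosisChannel, fluid: Fluid) -> float:
    """Laminar conductance of a milled cross-channel.

    Square profile uses the exact rectangular-duct series
    ``Q/dP = (h^3 w / 12 mu L)[1 - (192 h / pi^5 w) sum tanh(n pi w/2h)/n^5]``.
    The rounded (semicircular-bottom) profile reuses the series with an
    effective depth ``area / width``, preserving the true cross-sectional
    area.
    """
    w = channel.width * 1e-3
    h = (channel.depth if channel.profile == "square" else channel.area / channel.width) * 1e-3
    length = channel.length * 1e-3
    mu = fluid.dynamic_viscosity
    # series is symmetric under (w, h) swap only through its closed form;
    # take h <= w for rapid convergence
    a, b = (h, w) if h <= w else (w, h)
    series = float(np.sum(np.tanh(_RECT_ODD_N * math.pi * b / (2.0 * a)) / _RECT_ODD_N**5))
    factor = 1.0 - (192.0 * a / (math.pi**5 * b)) * series
    return a**3 * b * factor / (12.0 * mu * length)


# ---------------------------------------------------------------------------
# lumped hydraulic network
# ---------------------------------------------------------------------------


@dataclass
class _Edge:
    node_a: str
    node_b: str
    conductance: float  # laminar, m^3/s per Pa
    # geometry for the turbulent correction (None -> always laminar)
    area_m2: float | None = None
    hydraulic_diameter_m: float | None = None
    length_m: float | None = None
    label: str = ""
    flow: float = 0.0  # signed a->b, m^3/s, set by solve


@dataclass
class NetworkSolution:
    """Solved state: node pressures (kPa, gauge) and edge flows (mL/min)."""

    node_pressures: dict[str, float]
    edge_flows: list[tuple[str, str, str, float]]  # (label, node_a, node_b, mL/min)
    apical_pressures: dict[str, float] = field(default_factory=dict)
    iterations: int = 1
    regime: str = "laminar"


class HydraulicNetwork:
    """A lumped resistive hydraulic network.

    Nodes are string ids; one or more *reference* nodes sit at atmospheric
    (0 gauge) pressure; flow is injected at named nodes.  Edges carry
    laminar conductances, optionally with the cross-section geometry needed
    for a Darcy-Weisbach/Blasius turbulent correction.  Dead-end nodes
    (degree 1, no injection) are ordinary nodes: zero flow through their
    edge pins them to the neighbouring pressure.
    """

    def __init__(self, fluid: Fluid | None = None):
        self.fluid = fluid or Fluid()
        self._nodes: dict[str, dict] = {}
        self._edges: list[_Edge] = []

    # -- construction ------------------------------------------------------
    def add_node(self, name: str, kind: str = "junction") -> None:
        if kind not in ("junction", "atmosphere", "dead_end", "vent"):
            raise ValueError(f"unknown node kind {kind!r}")
        self._nodes[name] = {"kind": kind}

    def add_edge(
        self,
        node_a: str,
        node_b: str,
        conductance: float,
        *,
        area_m2: float | None = None,
        hydraulic_diameter_m: float | None = None,
        length_m: float | None = None,
        label: str = "",
    ) -> None:
        for n in (node_a, node_b):
            if n not in self._nodes:
                raise KeyError(f"unknown node {n!r}")
        if conductance < 0:
            raise ValueError("conductance must be >= 0")
        if conductance > 0:
            self._edges.append(
                _Edge(node_a, node_b, conductance, area_m2,
                      hydraulic_diameter_m, length_m, label)
            )

    @property
    def nodes(self) -> dict[str, dict]:
        return self._nodes

    @property
    def edges(self) -> list[_Edge]:
        return self._edges

    # -- solution ----------------------------------------------------------
    def _components(self) -> list[set[str]]:
        parent = {n: n for n in self._nodes}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for e in self._edges:
            ra, rb = find(e.node_a), find(e.node_b)
            if ra != rb:
                parent[ra] = rb
        comps: dict[str, set[str]] = {}
        for n in self._nodes:
            comps.setdefault(find(n), set()).add(n)
        return list(comps.values())

    def _solve_linear(
        self,
        conductances: np.ndarray,
        injections: Mapping[str, float],
    ) -> dict[str, float]:
        """Kirchhoff solve with given per-edge conductances; pressures in Pa."""
        refs = {n for n, a in self._nodes.items() if a["kind"] == "atmosphere"}
        pressures: dict[str, float] = {n: 0.0 for n in refs}
        for comp in self._components():
            comp_refs = comp & refs
            unknown = sorted(comp - refs)
            inj = {n: injections.get(n, 0.0) for n in comp}
            if not comp_refs:
                if any(abs(q) > 0 for q in inj.values()):
                    raise ValueError(
                        "flow injected into a component with no atmospheric "
                        "outlet: steady state is undefined"
                    )
                for n in comp:
                    pressures[n] = 0.0
                continue
            if not unknown:
                continue
            index = {n: i for i, n in enumerate(unknown)}
            m = len(unknown)
            lap = np.zeros((m, m))
            q = np.array([inj[n] for n in unknown])
            for e, g in zip(self._edges, conductances):
                if e.node_a not in comp or g <= 0:
                    continue
                ia = index.get(e.node_a)
                ib = index.get(e.node_b)
                if ia is not None:
                    lap[ia, ia] += g
                if ib is not None:
                    lap[ib, ib] += g
                if ia is not None and ib is not None:
                    lap[ia, ib] -= g
                    lap[ib, ia] -= g
            p = np.linalg.solve(lap, q)
            # iterative refinement: drive the Kirchhoff residual to rounding
            for _ in range(2):
                r = q - lap @ p
                p += np.linalg.solve(lap, r)
            for n, i in index.items():
                pressures[n] = float(p[i])
        return pressures

    def solve(
        self,
        injections: Mapping[str, float],
        *,
        turbulent_correction: bool = False,
        rtol: float = 1e-10,
        max_iter: int = 200,
    ) -> NetworkSolution:
        """Solve for node pressures given injections (m^3/s per node).

        With ``turbulent_correction`` the per-edge conductance is replaced,
        for edges whose Reynolds number exceeds 2300 and which carry
        cross-section metadata, by the Darcy-Weisbach value with Blasius
        friction ``f = 0.316 Re^-0.25``, iterated to fixed point at relative
        tolerance ``rtol``.
        """
        for n in injections:
            if n not in self._nodes:
                raise KeyError(f"unknown injection node {n!r}")
        g0 = np.array([e.conductance for e in self._edges])
        pressures = self._solve_linear(g0, injections)
        regime = "laminar"
        iterations = 1
        if turbulent_correction and self._edges:
            rho, mu = self.fluid.density, self.fluid.dynamic_viscosity
            g = g0.copy()
            for iterations in range(2, max_iter + 2):
                g_new = g0.copy()
                any_turbulent = False
                for i, e in enumerate(self._edges):
                    if e.area_m2 is None or e.hydraulic_diameter_m is None or e.length_m is None:
                        continue
                    dp = pressures[e.node_a] - pressures[e.node_b]
                    q = g[i] * dp
                    v = abs(q) / e.area_m2
                    re = rho * v * e.hydraulic_diameter_m / mu
                    if re <= RE_TRANSITION:
                        continue
                    any_turbulent = True
                    f = 0.316 * re**-0.25
                    dp_turb = f * (e.length_m / e.hydraulic_diameter_m) * 0.5 * rho * v * v
                    if dp_turb > 0:
                        g_new[i] = abs(q) / dp_turb
                if not any_turbulent:
                    break
                regime = "turbulent-corrected"
                new_pressures = self._solve_linear(g_new, injections)
                scale = max(abs(p) for p in new_pressures.values()) or 1.0
                delta = max(
                    abs(new_pressures[n] - pressures[n]) for n in pressures
                )
                # damped fixed point for robustness near the transition
                pressures = {
                    n: 0.5 * (pressures[n] + new_pressures[n]) for n in pressures
                }
                g = 0.5 * (g + g_new)
                if delta <= rtol * scale:
                    pressures = new_pressures
                    break
            else:
                raise RuntimeError(
                    f"turbulent fixed-point iteration did not converge in "
                    f"{max_iter} iterations"
                )
            g_final = g
        else:
            g_final = g0
        flows = []
        for e, gi in zip(self._edges, g_final):
            e.flow = gi * (pressures[e.node_a] - pressures[e.node_b])
            flows.append((e.label, e.node_a, e.node_b, e.flow * 6e7))
        return NetworkSolution(
            node_pressures={n: p / 1e3 for n, p in pressures.items()},
            edge_flows=flows,
            iterations=iterations,
            regime=regime,
        )

    def residuals(self, injections: Mapping[str, float]) -> dict[str, float]:
        """Net signed flow (m^3/s) at every non-atmosphere node after solve."""
        net = {n: -injections.get(n, 0.0) for n in self._nodes}
        for e in self._edges:
            net[e.node_a] += e.flow
            net[e.node_b] -= e.flow
        return {
            n: v for n, v in net.items() if self._nodes[n]["kind"] != "atmosphere"
        }


# ---------------------------------------------------------------------------
# network construction from the root-canal geometry
# ---------------------------------------------------------------------------

def _canal_segment_conductance(
    canal, needle: Needle | None, s0: float, s1: float, fluid: Fluid
) -> tuple[float, float, float]:
    """Series conductance of a canal run [s0, s1] mm; returns
    (conductance, min_area_m2, min_dh_m). ``needle`` present over the whole
    run or absent (None)."""
    # adaptive integration of the local resistance per unit length along the
    # linear taper; additive over any split of the run to quad tolerance
    r_in = (needle.outer_diameter / 2.0) * 1e-3 if needle is not None else 0.0

    def resistance_per_m(s_mm: float) -> float:
        r_out = (canal_diameter_at(canal, float(s_mm)) / 2.0) * 1e-3
        return 1.0 / annulus_laminar_conductance(r_out, r_in, 1.0, fluid)

    val, _ = quad(
        resistance_per_m, s0, s1, epsrel=1e-12, epsabs=0.0, limit=200
    )
    resistance = val * 1e-3  # integrand sampled per mm of station
    # taper >= 0: the narrowest section of the run sits at its apical end
    r_tip = (canal_diameter_at(canal, s0) / 2.0) * 1e-3
    min_area = math.pi * (r_tip**2 - r_in**2)
    min_dh = 2.0 * (r_tip - r_in)
    return 1.0 / resistance, min_area, min_dh


def build_network(
    system: RootCanalSystem,
    needle: Needle,
    insertion_depth: float,
    fluid: Fluid | None = None,
    *,
    channel_conductance_scale: float = 1.0,
) -> tuple[HydraulicNetwork, str]:
    """Assemble the lumped network for a needle in canal A.

    Returns ``(network, vent_node)``.  Node naming: ``a:<station>`` /
    ``b:<station>`` junctions, ``a:top`` / ``b:top`` atmospheric outlets,
    ``a:apex`` / ``b:apex`` closed dead-ends.
    """
    fluid = fluid or Fluid()
    # binding check at the narrowest occupied station
    net_flow_area(system, needle, insertion_depth, insertion_depth, canal="a")

    net = HydraulicNetwork(fluid)
    ch_stations = sorted({ch.axial_position for ch in system.channels})

    # canal A: vent node at the needle tip, junctions at channels, top outlet
    a_stations = [insertion_depth] + [s for s in ch_stations if s > insertion_depth]
    vent = f"a:{insertion_depth:g}"
    net.add_node(vent, kind="vent")
    for s in a_stations[1:]:
        net.add_node(f"a:{s:g}", kind="junction")
    net.add_node("a:top", kind="atmosphere")
    net.add_node("a:apex", kind="dead_end")
    runs = list(zip(a_stations, a_stations[1:] + [system.canal_a.length]))
    for (s0, s1), name1 in zip(
        runs, [f"a:{s:g}" for s in a_stations[1:]] + ["a:top"]
    ):
        g, area, dh = _canal_segment_conductance(
            system.canal_a, needle, s0, s1, fluid
        )
        net.add_edge(
            f"a:{s0:g}", name1, g,
            area_m2=area, hydraulic_diameter_m=dh, length_m=(s1 - s0) * 1e-3,
            label=f"a[{s0:g}-{s1:g}]",
        )

    # canal B: junctions at channels, top outlet; apical run below the
    # lowest channel is stagnant (dead end)
    net.add_node("b:apex", kind="dead_end")
    if ch_stations:
        for s in ch_stations:
            net.add_node(f"b:{s:g}", kind="junction")
        net.add_node("b:top", kind="atmosphere")
        b_runs = list(zip(ch_stations, ch_stations[1:] + [system.canal_b.length]))
        for (s0, s1), name1 in zip(
            b_runs, [f"b:{s:g}" for s in ch_stations[1:]] + ["b:top"]
        ):
            g, area, dh = _canal_segment_conductance(
                system.canal_b, None, s0, s1, fluid
            )
            net.add_edge(
                f"b:{s0:g}", name1, g,
                area_m2=area, hydraulic_diameter_m=dh, length_m=(s1 - s0) * 1e-3,
                label=f"b[{s0:g}-{s1:g}]",
            )

    # cross-channels
    for ch in system.channels:
        s = ch.axial_position
        a_node = f"a:{s:g}" if s > insertion_depth else vent
        g = duct_laminar_conductance(ch, fluid) * channel_conductance_scale
        net.add_edge(
            a_node, f"b:{s:g}", g,
            area_m2=ch.area * 1e-6,
            hydraulic_diameter_m=ch.hydraulic_diameter * 1e-3,
            length_m=ch.length * 1e-3,
            label=f"ch@{s:g}",
        )
    return net, vent


def solve_network(
    system: RootCanalSystem,
    needle: Needle,
    insertion_depth: float,
    flow: FlowSpec,
    fluid: Fluid | None = None,
    *,
    k_imp: float = 1.0,
    turbulent_correction: bool = True,
    channel_conductance_scale: float = 1.0,
) -> NetworkSolution:
    """Solve the two-canal system with the needle venting into canal A.

    Flow is injected at the vent node (taken at the needle-tip station) and
    leaves through the coronal access openings at atmospheric pressure.
    The closed apical dead-ends carry zero net flow; each sits at its
    adjacent junction's static pressure plus ``k_imp`` times the dynamic
    pressure of the narrowest occupied annulus, transmitted through the
    primed column if (and only if) the dead-end communicates with the
    injected flow.

    Returns a :class:`NetworkSolution` whose ``apical_pressures`` maps
    ``"a"``/``"b"`` to the two sensor readings in kPa.
    """
    if not 0.0 <= k_imp <= 1.0:
        raise ValueError("k_imp must lie in [0, 1]")
    fluid = fluid or Fluid()
    net, vent = build_network(
        system, needle, insertion_depth, fluid,
        channel_conductance_scale=channel_conductance_scale,
    )
    sol = net.solve(
        {vent: flow.m3_per_s}, turbulent_correction=turbulent_correction
    )
    tip_section = net_flow_area(system, needle, insertion_depth, insertion_depth)
    v_tip = effective_velocity(flow, tip_section)
    q_dyn = dynamic_pressure(fluid, v_tip)

    sol.apical_pressures["a"] = sol.node_pressures[vent] + k_imp * q_dyn
    ch_stations = sorted({ch.axial_position for ch in system.channels})
    # canal B communicates with the injected flow only through a channel of
    # positive conductance; otherwise its sensor reads null (control canal)
    has_channel_flow = any(e.label.startswith("ch@") for e in net.edges)
    if ch_stations and has_channel_flow:
        lowest_b = f"b:{ch_stations[0]:g}"
        sol.apical_pressures["b"] = sol.node_pressures[lowest_b] + k_imp * q_dyn
    else:
        sol.apical_pressures["b"] = 0.0
    sol.node_pressures["a:apex"] = sol.apical_pressures["a"]
    sol.node_pressures["b:apex"] = sol.apical_pressures["b"]
    return sol


def pressure_reduction_factor(separate_p: float, anastomosis_p: float) -> float:
    """Percent reduction of the anastomosis-model pressure relative to the
    separate-model pressure: ``100 (1 - p_anastomosis / p_separate)``."""
    if separate_p <= 0:
        raise ValueError("separate-model pressure must be > 0")
    return 100.0 * (1.0 - anastomosis_p / separate_p)
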