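"""Synthetic bench experiment: seeded two-channel pressure recordings.

Emulates the bench protocol: 16 groups (2 canal models x 2 needle
insertion depths x 4 flow rates), 12 recordings per group, two 1 Hz
pressure channels per recording (the needle-bearing *test* canal and the
parallel *adjacent* canal).  Each trace rises logistically to a plateau
held for the delivery duration of a 5 mL volume, then decays to zero.

Statistical structure generated:

* test-channel plateau maxima are log-normal about a configurable group
  median (pressures are positive and the bench data were non-normal and
  heteroscedastic), with the spread set from the group's interquartile
  range;
* in the separate model the adjacent channel reads bounded noise about
  null (a fluid-tight seal leaks nothing across);
* in the anastomosis model the adjacent channel tracks the test channel
  within the same +/-0.0067 kPa sensor bound (the connected canals
  equalize by Pascal's law).

Default group medians/IQRs are the bench study's published values, so a
default run reproduces the study conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hydraulics import FlowSpec
from .signal_processing import PressureRecording, delivery_duration

__all__ = [
    "ExperimentDesign",
    "GroupGeneratorSpec",
    "BENCH_GROUP_STATS",
    "default_group_specs",
    "group_key",
    "generate_trace",
    "generate_experiment",
    "generate_anatomy_counts",
]

#: published bench medians and interquartile ranges of the maximum apical
#: pressure (kPa) per (model, depth mm, flow mL/min) group
BENCH_GROUP_STATS: dict[tuple[str, float, float], tuple[float, float]] = {
    ("separate", 1.0, 1.5): (2.59, 0.16),
    ("separate", 1.0, 2.5): (4.58, 0.28),
    ("separate", 1.0, 9.5): (8.63, 0.01),
    ("separate", 1.0, 15.6): (79.49, 0.16),
    ("separate", 3.0, 1.5): (1.00, 0.07),
    ("separate", 3.0, 2.5): (1.72, 0.02),
    ("separate", 3.0, 9.5): (4.81, 0.08),
    ("separate", 3.0, 15.6): (31.68, 0.92),
    ("anastomosis", 1.0, 1.5): (1.21, 0.14),
    ("anastomosis", 1.0, 2.5): (1.55, 0.13),
    ("anastomosis", 1.0, 9.5): (4.23, 0.09),
    ("anastomosis", 1.0, 15.6): (7.85, 0.26),
    ("anastomosis", 3.0, 1.5): (0.43, 0.07),
    ("anastomosis", 3.0, 2.5): (0.45, 0.13),
    ("anastomosis", 3.0, 9.5): (0.90, 0.08),
    ("anastomosis", 3.0, 15.6): (2.55, 0.03),
}

#: sensor bound observed on the needle-free control channel (kPa)
CONTROL_NOISE_BOUND = 0.0067


@dataclass(frozen=True)
class ExperimentDesign:
    """The 2 x 2 x 4 factorial with replicate count and master seed."""

    models: tuple[str, ...] = ("separate", "anastomosis")
    depths: tuple[float, ...] = (1.0, 3.0)
    flow_rates: tuple[float, ...] = (1.5, 2.5, 9.5, 15.6)
    replicates: int = 12
    volume: float = 5.0  # mL delivered per recording
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        if not (self.models and self.depths and self.flow_rates):
            raise ValueError("all design factors must be non-empty")

    @property
    def groups(self) -> list[tuple[str, float, float]]:
        return [
            (m, d, q)
            for m in self.models
            for d in self.depths
            for q in self.flow_rates
        ]


@dataclass(frozen=True)
class GroupGeneratorSpec:
    """Per-group trace parameters.

    ``dispersion`` is the half-IQR of the plateau distribution (kPa);
    ``noise_sd`` bounds the additive sample noise on the test channel and
    ``control_noise_bound`` the adjacent-channel sensor bound.
    """

    target_median: float  # kPa
    dispersion: float = 0.0  # kPa, half the interquartile range
    rise_time: float = 3.0  # s
    noise_sd: float = CONTROL_NOISE_BOUND  # kPa
    control_noise_bound: float = CONTROL_NOISE_BOUND  # kPa

    def __post_init__(self) -> None:
        if self.target_median <= 0:
            raise ValueError("target_median must be > 0")
        if self.dispersion < 0 or self.noise_sd < 0 or self.control_noise_bound < 0:
            raise ValueError("spread parameters must be >= 0")
        if self.rise_time <= 0:
            raise ValueError("rise_time must be > 0")

    @property
    def lognormal_sigma(self) -> float:
        """Log-scale sigma giving a log-normal with this median and IQR.

        For ``X = m exp(sigma Z)`` the IQR is
        ``m (exp(z75 sigma) - exp(-z75 sigma))`` with ``z75 = 0.67449``;
        solving the quadratic in ``exp(z75 sigma)`` gives sigma in closed
        form.
        """
        if self.dispersion == 0:
            return 0.0
        z75 = 0.6744897501960817
        ratio = 2.0 * self.dispersion / self.target_median
        u = (ratio + math.sqrt(ratio * ratio + 4.0)) / 2.0
        return math.log(u) / z75


def group_key(model: str, depth: float, flow: float) -> str:
    """Canonical group label, e.g. ``separate/1mm/15.6``."""
    return f"{model}/{depth:g}mm/{flow:g}"


def default_group_specs(
    noise_sd: float = CONTROL_NOISE_BOUND,
) -> dict[tuple[str, float, float], GroupGeneratorSpec]:
    """One spec per group, centred on the published bench medians/IQRs."""
    return {
        key: GroupGeneratorSpec(
            target_median=med, dispersion=iqr / 2.0, noise_sd=noise_sd
        )
        for key, (med, iqr) in BENCH_GROUP_STATS.items()
    }


def _rng_for(seed: int, *counters: int) -> np.random.Generator:
    """Per-recording generator: master seed plus a counter spawn key."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=tuple(counters))
    )


def _trace_shape(n_rise: int, n_plateau: int, n_decay: int = 8) -> np.ndarray:
    """Unit trace: logistic rise, flat plateau at exactly 1, decay to 0."""
    t_rise = np.arange(1, n_rise + 1, dtype=float)
    # logistic centred mid-rise; capped strictly below 1 so the maximum of a
    # noiseless trace sits on the plateau
    rise = 1.0 / (1.0 + np.exp(-6.0 * (t_rise / n_rise - 0.5)))
    rise = np.minimum(rise, 0.98)
    plateau = np.ones(n_plateau)
    decay = np.exp(-0.5 * np.arange(1, n_decay + 1, dtype=float))
    return np.concatenate([[0.0], rise, plateau, decay])


def generate_trace(
    spec: GroupGeneratorSpec,
    flow: FlowSpec,
    seed: int | np.random.Generator,
    *,
    channel_id: str = "test",
    group_id: str = "group",
    replicate: int = 0,
) -> PressureRecording:
    """One 1 Hz test-channel recording.

    The plateau level is drawn log-normal about ``spec.target_median``, the
    plateau lasts the delivery duration of ``flow``, and bounded uniform
    noise (``+/- noise_sd``) rides on every sample, so the recording
    maximum is the drawn plateau plus bounded noise.  Identical seeds give
    identical traces.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = delivery_duration(flow)
    n_plateau = int(round(duration))
    if n_plateau < 2:
        raise ValueError(
            f"delivery lasts {duration:.2f} s: fewer than 2 plateau samples "
            "at 1 Hz; increase volume or decrease flow rate"
        )
    plateau_level = spec.target_median * math.exp(
        spec.lognormal_sigma * rng.standard_normal()
    )
    n_rise = max(1, int(round(spec.rise_time)))
    shape = _trace_shape(n_rise, n_plateau)
    pressures = plateau_level * shape
    if spec.noise_sd > 0:
        pressures = pressures + rng.uniform(-spec.noise_sd, spec.noise_sd, shape.size)
    times = np.arange(shape.size, dtype=float)
    return PressureRecording(
        channel_id=channel_id,
        group_id=group_id,
        times=times,
        pressures=pressures,
        unit="kPa",
        replicate=replicate,
    )


def generate_experiment(
    design: ExperimentDesign,
    specs: dict[tuple[str, float, float], GroupGeneratorSpec] | None = None,
) -> tuple[list[PressureRecording], pd.DataFrame]:
    """The full recording set plus its ground-truth table.

    For every group and replicate, a test-channel trace and its paired
    adjacent-channel trace are generated: separate model -> the adjacent
    channel is bounded sensor noise about null; anastomosis model -> the
    adjacent channel equals the test channel within the sensor bound.

    Returns ``(recordings, ground_truth)`` with ground truth columns
    ``group, model, depth_mm, flow_mL_min, true_median_kPa, true_iqr_kPa``.
    """
    if specs is None:
        specs = default_group_specs()
    recordings: list[PressureRecording] = []
    truth_rows = []
    for g_idx, (model, depth, flow_rate) in enumerate(design.groups):
        key = (model, depth, flow_rate)
        if key not in specs:
            raise KeyError(f"no generator spec for group {key}")
        spec = specs[key]
        gid = group_key(model, depth, flow_rate)
        flow = FlowSpec(flow_rate=flow_rate, delivered_volume=design.volume)
        for rep in range(design.replicates):
            rng = _rng_for(design.seed, g_idx, rep)
            test = generate_trace(
                spec, flow, rng, channel_id="test", group_id=gid, replicate=rep
            )
            bound = spec.control_noise_bound
            if model == "anastomosis":
                adj_p = test.pressures + (
                    rng.uniform(-bound, bound, test.pressures.size)
                    if bound > 0
                    else 0.0
                )
            else:
                adj_p = (
                    rng.uniform(-bound, bound, test.pressures.size)
                    if bound > 0
                    else np.zeros(test.pressures.size)
                )
            recordings.append(test)
            recordings.append(
                PressureRecording(
                    channel_id="adjacent",
                    group_id=gid,
                    times=test.times,
                    pressures=adj_p,
                    unit="kPa",
                    replicate=rep,
                )
            )
        truth_rows.append(
            {
                "group": gid,
                "model": model,
                "depth_mm": depth,
                "flow_mL_min": flow_rate,
                "true_median_kPa": spec.target_median,
                "true_iqr_kPa": 2.0 * spec.dispersion,
            }
        )
    return recordings, pd.DataFrame(truth_rows)


def generate_anatomy_counts(
    seed: int,
    n_teeth: int = 200,
    *,
    p_single_rooted: float = 153 / 200,
    p_double_canal: float = 84 / 153,
    p_first_premolar: float = 34 / 84,
    p_anastomosis_first: float = 17 / 34,
    p_anastomosis_second: float = 17 / 50,
) -> pd.DataFrame:
    """Synthetic micro-CT survey counts (hierarchical binomial draws).

    Mimics a 200-tooth premolar survey: single-rooted teeth, double-canal
    teeth among them, split into first/second premolars, each with its own
    anastomosis prevalence.  Default probabilities are the bench survey's
    observed proportions.  Returns a count table with columns
    ``stratum, numerator, denominator``.
    """
    for name, p in [
        ("p_single_rooted", p_single_rooted),
        ("p_double_canal", p_double_canal),
        ("p_first_premolar", p_first_premolar),
        ("p_anastomosis_first", p_anastomosis_first),
        ("p_anastomosis_second", p_anastomosis_second),
    ]:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = _rng_for(seed, 9999)
    n_single = int(rng.binomial(n_teeth, p_single_rooted))
    n_double = int(rng.binomial(n_single, p_double_canal))
    n_first = int(rng.binomial(n_double, p_first_premolar))
    n_second = n_double - n_first
    n_anast_first = int(rng.binomial(n_first, p_anastomosis_first))
    n_anast_second = int(rng.binomial(n_second, p_anastomosis_second))
    return pd.DataFrame(
        [
            {"stratum": "single_rooted", "numerator": n_single, "denominator": n_teeth},
            {"stratum": "double_canal", "numerator": n_double, "denominator": n_single},
            {
                "stratum": "anastomosis_first_premolar",
                "numerator": n_anast_first,
                "denominator": n_first,
            },
            {
                "stratum": "anastomosis_second_premolar",
                "numerator": n_anast_second,
                "denominator": n_second,
            },
            {
                "stratum": "anastomosis_double_canal",
                "numerator": n_anast_first + n_anast_second,
                "denominator": n_double,
            },
        ]
    )
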