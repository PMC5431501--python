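"""Group summaries, calibration-curve thresholds and nonparametric tests.

The analysis mirrors a bench irrigation study: maximum pressures per
recording are summarised as medians and interquartile ranges per group;
flow-rate -> pressure calibration is a least-squares quadratic whose
crossing of the 4 kPa intraosseous threshold defines the safe flow rate;
between-model contrasts use the Mann-Whitney rank-sum test and
within-model contrasts a Friedman-type blocked rank analysis with Dunn
pairwise comparisons (Bonferroni family-wise adjustment) summarised as a
compact letter display.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hydraulics import pressure_reduction_factor
from .signal_processing import PressureRecording, extract_max

__all__ = [
    "GroupSummary",
    "PolynomialFit",
    "MannWhitneyResult",
    "RankAnalysisResult",
    "INTRAOSSEOUS_KPA",
    "maxima_table",
    "summarize_groups",
    "model_reduction_table",
    "fit_flow_pressure_curve",
    "threshold_flow_rate",
    "compare_models",
    "within_model_ranks",
    "prevalence_stats",
]

#: average intraosseous blood pressure of cancellous-bone sinusoids
INTRAOSSEOUS_KPA = 4.0

GROUP_COLS = ["model", "depth_mm", "flow_mL_min"]


@dataclass(frozen=True)
class GroupSummary:
    model: str
    depth_mm: float
    flow_mL_min: float
    n: int
    median_kPa: float
    iqr_kPa: float


@dataclass(frozen=True)
class PolynomialFit:
    """Quadratic calibration ``P = a + b Q + c Q^2`` (kPa vs mL/min)."""

    a: float
    b: float
    c: float
    r_squared: float
    residual_scale: float
    q_min: float
    q_max: float

    def predict(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        return self.a + self.b * q + self.c * q * q


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int
    degenerate: bool = False


@dataclass(frozen=True)
class RankAnalysisResult:
    """Friedman omnibus plus Dunn pairwise comparisons and letter groups."""

    statistic: float
    p_value: float
    mean_ranks: pd.Series  # condition -> mean within-block rank
    pairwise: pd.DataFrame  # condition_a, condition_b, z, p_adjusted, significant
    letters: dict[str, str]  # condition -> letter group(s), ordered by rank


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def maxima_table(
    recordings: list[PressureRecording], channel: str = "test"
) -> pd.DataFrame:
    """Maximum pressure per recording of one channel, with parsed group
    factors (columns ``model, depth_mm, flow_mL_min, replicate, max_kPa``)."""
    rows = []
    for rec in recordings:
        if rec.channel_id != channel:
            continue
        mx = extract_max(rec.to_unit("kPa"))
        model, depth_s, flow_s = rec.group_id.split("/")
        rows.append(
            {
                "model": model,
                "depth_mm": float(depth_s.rstrip("m")),
                "flow_mL_min": float(flow_s),
                "replicate": rec.replicate,
                "max_kPa": mx.value,
            }
        )
    if not rows:
        raise ValueError(f"no recordings for channel {channel!r}")
    return pd.DataFrame(rows)


def summarize_groups(
    maxima: pd.DataFrame,
    value_col: str = "max_kPa",
    by: list[str] | None = None,
    interpolation: str = "linear",
) -> pd.DataFrame:
    """Median and IQR of maximum pressures per group.

    Quartiles use linear interpolation (numpy/pandas type-7) by default;
    pass another numpy quantile ``method`` to change the convention.
    """
    by = by or GROUP_COLS
    if maxima.empty:
        raise ValueError("empty maxima table")

    def _summary(values: pd.Series) -> pd.Series:
        x = values.to_numpy(dtype=float)
        if x.size == 0:
            raise ValueError("empty group")
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], method=interpolation)
        return pd.Series({"n": x.size, "median_kPa": med, "iqr_kPa": q3 - q1})

    out = (
        maxima.groupby(by, sort=True)[value_col]
        .apply(_summary)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def model_reduction_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Inter-model median pressure reduction per matched (depth, flow).

    Requires a summary holding both models; returns columns ``depth_mm,
    flow_mL_min, separate_kPa, anastomosis_kPa, reduction_pct``.
    """
    wide = summary.pivot_table(
        index=["depth_mm", "flow_mL_min"], columns="model", values="median_kPa"
    )
    for model in ("separate", "anastomosis"):
        if model not in wide.columns:
            raise ValueError(f"summary lacks the {model!r} model")
    rows = []
    for (depth, flow), r in wide.iterrows():
        rows.append(
            {
                "depth_mm": depth,
                "flow_mL_min": flow,
                "separate_kPa": r["separate"],
                "anastomosis_kPa": r["anastomosis"],
                "reduction_pct": pressure_reduction_factor(
                    r["separate"], r["anastomosis"]
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# calibration curve and safe-flow threshold
# ---------------------------------------------------------------------------


def fit_flow_pressure_curve(points) -> PolynomialFit:
    """Least-squares quadratic through ``(Q, P)`` points.

    Requires at least three distinct flow rates; three distinct noiseless
    points are interpolated exactly.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an iterable of (Q, P) pairs")
    q, p = pts[:, 0], pts[:, 1]
    if np.unique(q).size < 3:
        raise ValueError("need at least 3 distinct flow rates for a quadratic")
    design = np.column_stack([np.ones_like(q), q, q * q])
    coef, _, rank, _ = np.linalg.lstsq(design, p, rcond=None)
    if rank < 3:
        raise ValueError("rank-deficient quadratic design")
    fitted = design @ coef
    resid = p - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(1, q.size - 3)
    return PolynomialFit(
        a=float(coef[0]),
        b=float(coef[1]),
        c=float(coef[2]),
        r_squared=r2,
        residual_scale=math.sqrt(ss_res / dof),
        q_min=float(q.min()),
        q_max=float(q.max()),
    )


def threshold_flow_rate(
    fit: PolynomialFit,
    p_threshold: float = INTRAOSSEOUS_KPA,
    grid: float | None = None,
) -> float | None:
    """Smallest positive flow rate at which the fitted curve reaches
    ``p_threshold``.

    Returns the smallest positive real root of ``a + bQ + cQ^2 =
    p_threshold`` not exceeding the fitted range; ``None`` when the curve
    never reaches the threshold there ("no-threshold").  With ``grid`` the
    root is snapped *up* to the pilot grid resolution (e.g. 0.5 mL/min),
    reporting the first probed flow at which the threshold is exceeded.
    """
    a, b, c = fit.a - p_threshold, fit.b, fit.c
    roots: list[float] = []
    if abs(c) < 1e-300:
        if b != 0:
            roots = [-a / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc >= 0:
            s = math.sqrt(disc)
            roots = [(-b - s) / (2.0 * c), (-b + s) / (2.0 * c)]
    eps = 1e-9
    candidates = sorted(r for r in roots if eps < r <= fit.q_max + eps)
    if not candidates:
        return None
    root = candidates[0]
    if grid is not None:
        return math.ceil(root / grid - 1e-9) * grid
    return root


# ---------------------------------------------------------------------------
# nonparametric comparisons
# ---------------------------------------------------------------------------


def compare_models(group_a, group_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney rank-sum comparison of two groups.

    Exact null distribution for samples of at most 12 without ties; full
    permutation enumeration for tied samples of at most 12 observations in
    total; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return MannWhitneyResult(
            u_statistic=a.size * b.size / 2.0,
            p_value=1.0,
            method="degenerate",
            n_a=a.size,
            n_b=b.size,
            degenerate=True,
        )
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and max(a.size, b.size) <= 12:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    elif has_ties and pooled.size <= 12:
        method = "permutation"
        res = stats.mannwhitneyu(
            a,
            b,
            alternative="two-sided",
            method=stats.PermutationMethod(n_resamples=np.inf),
        )
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return MannWhitneyResult(
        u_statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        method=method,
        n_a=a.size,
        n_b=b.size,
    )


def _compact_letters(order: list[str], nonsig: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display for conditions sorted by descending mean rank.

    Mean-rank ordering makes the not-significant relation interval-shaped:
    the interval [i, j] is homogeneous iff its extreme pair is
    not-significant.  Maximal homogeneous intervals each receive a letter.
    """
    k = len(order)
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and (order[i], order[j + 1]) in nonsig:
            j += 1
        intervals.append((i, j))
    # drop intervals nested inside another
    maximal = [
        (i, j)
        for (i, j) in intervals
        if not any((p <= i and j <= q) and (p, q) != (i, j) for (p, q) in intervals)
    ]
    maximal = sorted(set(maximal))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    letters: dict[str, list[str]] = {name: [] for name in order}
    for letter, (i, j) in zip(alphabet, maximal):
        for idx in range(i, j + 1):
            letters[order[idx]].append(letter)
    return {name: "".join(v) for name, v in letters.items()}


def within_model_ranks(
    maxima: pd.DataFrame,
    value_col: str = "max_kPa",
    condition_cols: list[str] | None = None,
    block_col: str = "replicate",
    alpha: float = 0.05,
) -> RankAnalysisResult:
    """Friedman-type blocked rank analysis across conditions of one model.

    Replicates are the blocks of the repeated design: within every block
    the conditions are ranked (average ranks on ties), the Friedman
    statistic tests the omnibus hypothesis, and Dunn pairwise z-statistics
    ``z = |Rbar_i - Rbar_j| / sqrt(k(k+1)/(6n))`` with Bonferroni
    adjustment over all ``k(k-1)/2`` pairs give the significance partition
    reported as a compact letter display.
    """
    condition_cols = condition_cols or ["depth_mm", "flow_mL_min"]
    df = maxima.copy()
    df["_condition"] = df[condition_cols].astype(str).agg("/".join, axis=1)
    wide = df.pivot_table(index=block_col, columns="_condition", values=value_col)
    if wide.isna().any().any():
        raise ValueError("unbalanced blocks: every condition must appear in "
                         "every replicate block")
    k = wide.shape[1]
    n = wide.shape[0]
    if k < 3:
        raise ValueError("need at least 3 conditions for the Friedman test")
    values = wide.to_numpy()
    if np.all(values == values[:, :1]):
        statistic, p_value = 0.0, 1.0
    else:
        statistic, p_value = stats.friedmanchisquare(
            *[values[:, i] for i in range(k)]
        )
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    mean_ranks = pd.Series(ranks.mean(axis=0), index=wide.columns)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    m = k * (k - 1) // 2
    rows = []
    nonsig: set[tuple[str, str]] = set()
    for ca, cb in itertools.combinations(wide.columns, 2):
        z = abs(mean_ranks[ca] - mean_ranks[cb]) / se
        p_adj = min(1.0, 2.0 * stats.norm.sf(z) * m)
        significant = p_adj < alpha
        rows.append(
            {
                "condition_a": ca,
                "condition_b": cb,
                "z": z,
                "p_adjusted": p_adj,
                "significant": significant,
            }
        )
        if not significant:
            nonsig.add((ca, cb))
            nonsig.add((cb, ca))
    order = list(mean_ranks.sort_values(ascending=False).index)
    letters = _compact_letters(order, nonsig)
    return RankAnalysisResult(
        statistic=float(statistic),
        p_value=float(p_value),
        mean_ranks=mean_ranks,
        pairwise=pd.DataFrame(rows),
        letters=letters,
    )


# ---------------------------------------------------------------------------
# anatomy prevalence
# ---------------------------------------------------------------------------


def prevalence_stats(counts: pd.DataFrame) -> pd.DataFrame:
    """Percent prevalence per stratum from a numerator/denominator table.

    Percentages are reported to two decimals, as anatomical surveys print
    them.
    """
    required = {"stratum", "numerator", "denominator"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns {sorted(missing)}")
    out = counts.copy()
    if (out["denominator"] <= 0).any():
        raise ValueError("zero or negative denominator")
    if ((out["numerator"] < 0) | (out["numerator"] > out["denominator"])).any():
        raise ValueError("numerator must lie in [0, denominator]")
    out["percent"] = (100.0 * out["numerator"] / out["denominator"]).round(2)
    return out
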