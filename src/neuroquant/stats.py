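"""Hierarchical weighted aggregation and group statistics.

Neurite lengths are collected in a nested design: several measurements per
picture, several pictures per replicate, replicates per experiment,
independent experiments.  Aggregation follows the design upward:

1. picture mean of its measurements;
2. within a replicate, picture means are pooled weighted by the number of
   measurements each picture contributed;
3. within an experiment, replicate summaries are pooled weighted by the
   inverse of their variances;
4. across experiments, the overall mean is again the inverse-variance
   weighted mean.

Inverse-variance weighting minimizes the pooled variance when the inputs
are independent and unbiased.  Degenerate members (zero variance, e.g. a
single picture in a replicate) are handled by substituting the smallest
positive member variance, falling back to count weighting when no positive
variance exists at the level.

Group comparisons use one-way ANOVA at the 95% confidence level followed by
a Tukey post-hoc test (Tukey-Kramer for unequal group sizes); agreement
between paired assays is summarized by the determination coefficient R**2
of a least-squares line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

Hierarchy = Mapping[str, Mapping[str, Mapping[str, Sequence[float]]]]


@dataclass(frozen=True)
class LevelSummary:
    """(mean, variance, n) at one aggregation level."""

    mean: float
    variance: float
    n: int
    label: str = ""
    degenerate: bool = False  # variance 0 because n == 1 or identical values

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")


@dataclass(frozen=True)
class PooledEstimate:
    """Weighted pooled mean across one level's summaries."""

    mean: float
    variance_of_mean: float
    n_levels: int
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.variance_of_mean < 0:
            raise ValueError("variance_of_mean must be >= 0")
        w = np.asarray(self.weights)
        if (w < -1e-12).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")

    @property
    def sem(self) -> float:
        """Standard error of the pooled mean: sqrt(variance_of_mean)."""
        return float(np.sqrt(self.variance_of_mean))


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float

    def __post_init__(self) -> None:
        if self.df_between < 1 or self.df_within < 1:
            raise ValueError("degrees of freedom must be >= 1")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class TukeyComparison:
    group_a: str
    group_b: str
    mean_difference: float
    q_statistic: float
    significant_at_alpha: bool
    alpha: float = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    r_squared: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_pairs < 3:
            raise ValueError("need at least 3 pairs")


# --------------------------------------------------------------------------
# Level summaries and pooling
# --------------------------------------------------------------------------


def summarize(values: Sequence[float], label: str = "") -> LevelSummary:
    """Sample mean and unbiased sample variance of one level's raw values.

    With a single value the variance is 0 and the summary is flagged
    degenerate so that downstream pooling can apply its fallback.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"level {label!r}: empty value list")
    mean = float(arr.mean())
    if arr.size == 1:
        return LevelSummary(mean=mean, variance=0.0, n=1, label=label, degenerate=True)
    var = float(arr.var(ddof=1))
    return LevelSummary(mean=mean, variance=var, n=int(arr.size), label=label,
                        degenerate=(var == 0.0))


def weighted_mean_by_count(summaries: Sequence[LevelSummary], label: str = "") -> LevelSummary:
    """Pool summaries weighting each mean by its measurement count.

    ``mean = sum(n_i * m_i) / sum(n_i)``.  The variance carried upward (the
    next level weighs by its inverse) is the count-weighted unbiased sample
    variance of the member means about the pooled mean,
    ``sum(n_i * (m_i - m)**2) / (N - 1)``; with a single member it is 0 and
    the summary is flagged degenerate.
    """
    if not summaries:
        raise ValueError("no summaries to pool")
    n = np.array([s.n for s in summaries], dtype=float)
    m = np.array([s.mean for s in summaries], dtype=float)
    total = float(n.sum())
    mean = float((n * m).sum() / total)
    if len(summaries) == 1 or total <= 1:
        return LevelSummary(mean=mean, variance=0.0, n=int(total), label=label, degenerate=True)
    var = float((n * (m - mean) ** 2).sum() / (total - 1))
    return LevelSummary(mean=mean, variance=var, n=int(total), label=label,
                        degenerate=(var == 0.0))


def inverse_variance_pool(summaries: Sequence[LevelSummary]) -> PooledEstimate:
    """Pool summaries with weights proportional to the inverse of their variances.

    ``w_i = (1/v_i) / sum(1/v_j)``; ``mean = sum(w_i m_i)``;
    ``variance_of_mean = 1 / sum(1/v_i)``.

    Degenerate members (variance 0) take the smallest positive member
    variance; if no member has positive variance the pool falls back to
    count weighting with zero reported variance of the mean.
    """
    if not summaries:
        raise ValueError("no summaries to pool")
    m = np.array([s.mean for s in summaries], dtype=float)
    v = np.array([s.variance for s in summaries], dtype=float)
    if (v < 0).any():
        raise ValueError("negative variance")
    if len(summaries) == 1:
        return PooledEstimate(mean=float(m[0]), variance_of_mean=float(v[0]),
                              n_levels=1, weights=(1.0,))
    if (v <= 0).any():
        positive = v[v > 0]
        if positive.size:
            floor = float(positive.min())
            logger.warning(
                "inverse-variance pool: %d degenerate member(s); substituting "
                "smallest positive variance %.3g", int((v <= 0).sum()), floor)
            v = np.where(v > 0, v, floor)
        else:
            logger.warning("inverse-variance pool: all variances degenerate; "
                           "falling back to count weighting")
            n = np.array([s.n for s in summaries], dtype=float)
            w = n / n.sum()
            return PooledEstimate(mean=float((w * m).sum()), variance_of_mean=0.0,
                                  n_levels=len(summaries), weights=tuple(w))
    inv = 1.0 / v
    w = inv / inv.sum()
    return PooledEstimate(
        mean=float((w * m).sum()),
        variance_of_mean=float(1.0 / inv.sum()),
        n_levels=len(summaries),
        weights=tuple(float(x) for x in w),
    )


def hierarchical_neurite_mean(hierarchy: Hierarchy) -> PooledEstimate:
    """Full aggregation chain over experiment -> replicate -> picture -> values.

    Pictures are summarized, count-weight pooled within each replicate,
    replicates are inverse-variance pooled within each experiment, and the
    experiment estimates are inverse-variance pooled into the overall mean.
    A pooled estimate is converted back to a level summary (its variance of
    the mean becomes the member variance at the next level).
    """
    if not hierarchy:
        raise ValueError("empty hierarchy")
    exp_summaries: list[LevelSummary] = []
    for e_key in hierarchy:
        rep_summaries: list[LevelSummary] = []
        for r_key in hierarchy[e_key]:
            pics = [summarize(vals, label=f"{e_key}/{r_key}/{p_key}")
                    for p_key, vals in hierarchy[e_key][r_key].items()]
            rep_summaries.append(weighted_mean_by_count(pics, label=f"{e_key}/{r_key}"))
        pooled = inverse_variance_pool(rep_summaries)
        exp_summaries.append(LevelSummary(
            mean=pooled.mean, variance=pooled.variance_of_mean,
            n=int(sum(s.n for s in rep_summaries)), label=e_key,
            degenerate=(pooled.variance_of_mean == 0.0)))
    return inverse_variance_pool(exp_summaries)


# --------------------------------------------------------------------------
# Group comparisons
# --------------------------------------------------------------------------


def _check_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrs.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    return arrs


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA: between/within decomposition, F upper tail."""
    arrs = _check_groups(groups)
    all_vals = np.concatenate(list(arrs.values()))
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    df_b = len(arrs) - 1
    df_w = all_vals.size - len(arrs)
    if ss_within <= 0:
        raise ValueError("zero within-group variance: F undefined")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(f_statistic=float(f), df_between=df_b, df_within=df_w, p_value=p)


def tukey_q_critical(k: int, df_within: int, alpha: float = 0.05) -> float:
    """Upper-alpha critical value of the studentized range for k groups."""
    return float(sps.studentized_range.ppf(1 - alpha, k, df_within))


def tukey_hsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> list[TukeyComparison]:
    """All pairwise comparisons after ANOVA via the studentized range.

    ``q = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))`` (the Tukey-Kramer
    form, exact for equal n); a pair is significant when q exceeds the
    studentized-range critical value at (k, df_within, alpha).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    arrs = _check_groups(groups)
    k = len(arrs)
    df_w = sum(a.size for a in arrs.values()) - k
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    if ss_within <= 0:
        raise ValueError("zero within-group variance: Tukey q undefined")
    msw = ss_within / df_w
    q_crit = tukey_q_critical(k, df_w, alpha)
    labels = list(arrs)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrs[labels[i]], arrs[labels[j]]
            diff = float(a.mean() - b.mean())
            se = np.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size))
            q = abs(diff) / se
            out.append(TukeyComparison(
                group_a=labels[i], group_b=labels[j], mean_difference=diff,
                q_statistic=float(q), significant_at_alpha=bool(q > q_crit), alpha=alpha))
    return out


def determination_coefficient(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """R**2 of the least-squares line of y on x: 1 - SS_res/SS_tot."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(ya) == 0:
        raise ValueError("constant y: determination coefficient undefined")
    if np.ptp(xa) == 0:
        raise ValueError("constant x: slope undefined")
    res = sps.linregress(xa, ya)
    r2 = float(res.rvalue**2)
    return CorrelationResult(r_squared=min(r2, 1.0), n_pairs=int(xa.size))


# --------------------------------------------------------------------------
# Assay normalization
# --------------------------------------------------------------------------


def normalize_assay(raw: float, protein_content: float | None, control_value: float) -> float:
    """Protein-content normalization followed by control normalization.

    ``(raw / protein_content if supplied else raw) / control_value``.
    """
    if control_value <= 0:
        raise ValueError("control_value must be > 0")
    if protein_content is not None:
        if protein_content <= 0:
            raise ValueError("protein_content must be > 0 when supplied")
        raw = raw / protein_content
    return raw / control_value


def normalize_assay_table(df, control: str):
    """Apply the normalization chain to an assay table.

    Expects columns ``condition, raw_value, protein_content``; returns a
    copy with a ``normalized`` column where each row is protein-normalized
    then divided by the mean protein-normalized control value.
    """
    if control not in set(df["condition"]):
        raise ValueError(f"control condition {control!r} missing from table")
    per_protein = df["raw_value"] / df["protein_content"]
    control_value = float(per_protein[df["condition"] == control].mean())
    if control_value <= 0:
        raise ValueError("non-positive control value")
    out = df.copy()
    out["normalized"] = per_protein / control_value
    return out
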