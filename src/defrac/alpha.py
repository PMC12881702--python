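"""Richness, repeat rarefaction, fraction comparisons and temporal trends.

Richness is the number of distinct ASVs observed in a sample. Because library
sizes differ strongly between size fractions, richness is also computed on
repeat-rarefied data: each sample is subsampled without replacement to a
common depth many times and the per-iteration richness values are averaged.
Samples whose library is shallower than the rarefaction depth are excluded
and reported rather than imputed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AsvTable, SampleRecord, ValidationError

__all__ = ["RichnessSeries", "TrendResult", "richness", "repeat_rarefy_richness",
           "richness_series", "compare_richness", "richness_trend",
           "expected_rarefied_richness"]


@dataclass(frozen=True)
class RichnessSeries:
    """Per-sample richness values joined to their sampling context.

    ``table`` columns: sample_id, week, depth, fraction, phase, richness.
    ``excluded`` lists samples dropped because their library size was below
    the rarefaction depth (empty for raw richness).
    """

    table: pd.DataFrame
    rarefaction_depth: int | None = None
    n_iterations: int | None = None
    excluded: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class TrendResult:
    """OLS fit of richness on week for one (depth, fraction) series."""

    slope: float
    intercept: float
    r_squared: float
    classification: str  # increasing / decreasing / constant
    n_points: int


def richness(row: pd.Series | np.ndarray, mode: str = "counts") -> int:
    """Number of ASVs with a positive count in one sample.

    Defined for counts only: a presence threshold on relative abundances
    would be arbitrary.
    """
    if mode != "counts":
        raise ValidationError("richness is defined on counts-mode data only")
    values = np.asarray(row, dtype=float)
    return int((values > 0).sum())


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # Stable per-sample stream: independent of iteration order and of which
    # other samples are processed in the same run.
    digest = hashlib.blake2b(f"{sample_id}".encode(), digest_size=8).digest()
    return np.random.default_rng([seed, int.from_bytes(digest, "big") % (2**63)])


def repeat_rarefy_richness(
    row: pd.Series | np.ndarray,
    depth: int,
    iterations: int = 100,
    seed: int = 0,
    sample_id: str = "",
) -> float | None:
    """Mean richness over repeated without-replacement subsamples of ``depth`` reads.

    Subsampling is multivariate hypergeometric (draw ``depth`` reads from the
    library without replacement). Returns ``None`` when the library is
    shallower than ``depth`` — the caller decides whether to drop or report
    the sample. When the depth equals the library size the subsample is the
    whole library and the result is the raw richness, exactly.
    """
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    counts = np.asarray(row, dtype=float)
    if np.any(counts % 1 != 0):
        raise ValidationError("repeat rarefaction requires integer counts")
    counts = counts.astype(np.int64)
    library = int(counts.sum())
    if library < depth:
        return None
    if library == depth:
        return float((counts > 0).sum())
    rng = _sample_rng(seed, sample_id)
    draws = rng.multivariate_hypergeometric(counts, depth, size=iterations)
    return float((draws > 0).sum(axis=1).mean())


def expected_rarefied_richness(counts: Sequence[float], depth: int) -> float:
    """Closed-form expectation of rarefied richness (hypergeometric).

    E[S_d] = sum_i [1 - C(T - n_i, d) / C(T, d)] where T is the library size.
    Used as an independent oracle for the Monte-Carlo estimator.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if depth > total:
        raise ValidationError("depth exceeds library size")
    # log-space ratio C(T-n, d)/C(T, d) for numerical safety
    from scipy.special import gammaln

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    probs_absent = np.where(
        total - counts >= depth,
        np.exp(log_comb(total - counts, depth) - log_comb(total, depth)),
        0.0,
    )
    return float(np.sum(1.0 - probs_absent))


def richness_series(
    table: AsvTable,
    metadata: Mapping[str, SampleRecord],
    depth: int | None = None,
    iterations: int = 100,
    seed: int = 0,
) -> RichnessSeries:
    """Raw (``depth=None``) or repeat-rarefied richness for every sample."""
    rows, excluded = [], []
    for sid in table.sample_ids:
        rec = metadata[sid]
        counts = table.row(sid)
        if depth is None:
            value: float | None = float(richness(counts))
        else:
            value = repeat_rarefy_richness(counts, depth, iterations, seed, sample_id=sid)
        if value is None:
            excluded.append(sid)
            continue
        rows.append({
            "sample_id": sid, "week": rec.week, "depth": rec.depth,
            "fraction": rec.fraction, "phase": rec.phase, "richness": value,
        })
    return RichnessSeries(
        table=pd.DataFrame(rows, columns=["sample_id", "week", "depth",
                                          "fraction", "phase", "richness"]),
        rarefaction_depth=depth,
        n_iterations=None if depth is None else iterations,
        excluded=excluded,
    )


def compare_richness(series: RichnessSeries) -> dict:
    """One-way ANOVA across fractions plus Holm-corrected pairwise t-tests.

    Fractions with fewer than 2 observations are excluded with a warning
    entry. Pairs with zero pooled variance are reported on a degenerate path
    (mean difference and an ``exact_separation`` flag) instead of a t
    statistic.
    """
    groups = {
        frac: sub["richness"].to_numpy(dtype=float)
        for frac, sub in series.table.groupby("fraction")
    }
    excluded = [f for f, v in groups.items() if len(v) < 2]
    groups = {f: v for f, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValidationError("compare_richness needs >= 2 fractions with >= 2 samples")

    order = sorted(groups)
    arrays = [groups[f] for f in order]
    concat = np.concatenate(arrays)
    if np.ptp(concat) == 0:
        f_stat, anova_p = np.nan, 1.0  # every observation identical
    elif all(np.var(a) == 0 for a in arrays):
        f_stat, anova_p = np.inf, 0.0  # zero within-group variance, groups differ
    else:
        f_stat, anova_p = stats.f_oneway(*arrays)

    pair_rows = []
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            a, b = arrays[i], arrays[j]
            diff = float(a.mean() - b.mean())
            pooled_var = np.var(a, ddof=1) + np.var(b, ddof=1)
            if pooled_var == 0:
                pair_rows.append({
                    "fraction_a": order[i], "fraction_b": order[j],
                    "mean_difference": diff, "t_stat": np.nan,
                    "p_raw": 1.0 if diff == 0 else 0.0,
                    "exact_separation": diff != 0,
                })
            else:
                t_stat, p = stats.ttest_ind(a, b)
                pair_rows.append({
                    "fraction_a": order[i], "fraction_b": order[j],
                    "mean_difference": diff, "t_stat": float(t_stat),
                    "p_raw": float(p), "exact_separation": False,
                })
    pairwise = pd.DataFrame(pair_rows)
    if len(pairwise):
        pairwise["p_holm"] = multipletests(pairwise["p_raw"], method="holm")[1]
    return {
        "anova_f": float(f_stat) if np.isfinite(f_stat) else np.nan,
        "anova_p": float(anova_p),
        "means": {f: float(groups[f].mean()) for f in order},
        "pairwise": pairwise,
        "excluded_fractions": excluded,
    }


def richness_trend(
    weeks: Sequence[float],
    values: Sequence[float],
    epsilon: float = 0.0,
) -> TrendResult:
    """Classify the temporal richness trend by the OLS slope on week.

    ``epsilon`` sets the half-width of the "constant" band; the default 0
    classifies any nonzero slope by its sign.
    """
    weeks = np.asarray(weeks, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(weeks) < 3:
        raise ValidationError("richness_trend needs >= 3 time points")
    if len(weeks) != len(values):
        raise ValidationError("weeks and values must align")
    fit = stats.linregress(weeks, values)
    slope = float(fit.slope)
    if abs(slope) <= epsilon:
        classification = "constant"
    else:
        classification = "increasing" if slope > 0 else "decreasing"
    return TrendResult(
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        classification=classification,
        n_points=len(weeks),
    )
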