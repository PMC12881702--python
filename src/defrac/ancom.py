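"""ANCOM-style differential abundance across sample groups.

Analysis of Composition of Microbiomes sidesteps the compositionality of
count tables by testing additive log-ratios: for each ASV i, the log-ratio
log((x_i + pc)/(x_j + pc)) against every other ASV j is compared across
groups with a rank test, and W_i counts how many of those m - 1 tests reject.
A taxon whose abundance genuinely shifts between groups moves against most
references, so a large W (by convention >= cutoff * (m - 1)) flags it as
differentially abundant. Rejection counting is ANCOM's own error control;
no multiplicity correction is applied inside the reference loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import AsvTable, ValidationError

__all__ = ["AncomResult", "ancom", "pairwise_ancom"]


@dataclass(frozen=True)
class AncomResult:
    """Per-ASV W statistics at a given rejection cutoff.

    ``table`` columns: w_stat (int in 0..m-1), significant (bool at
    ``cutoff * (m - 1)``).
    """

    table: pd.DataFrame
    cutoff: float
    alpha: float
    test_name: str
    n_asvs: int

    @property
    def significant_asvs(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _group_arrays(sample_ids: list[str], groups: Mapping[str, str]) -> dict[str, np.ndarray]:
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise ValidationError(f"group labels missing for samples: {missing[:5]}")
    out: dict[str, list[int]] = {}
    for i, s in enumerate(sample_ids):
        out.setdefault(groups[s], []).append(i)
    return {g: np.asarray(idx) for g, idx in out.items()}


def ancom(
    table: AsvTable,
    groups: Mapping[str, str],
    alpha: float = 0.05,
    cutoff: float = 0.7,
    pseudocount: float = 1.0,
) -> AncomResult:
    """ANCOM W statistics for every ASV across >= 2 sample groups.

    Two groups are compared with the two-sided Mann-Whitney U test (normal
    approximation with tie correction — fully deterministic); more than two
    with Kruskal-Wallis. The per-sample scale cancels inside each log-ratio,
    so W is invariant to per-sample count scaling.
    """
    if table.mode != "counts":
        raise ValidationError("ancom expects a counts-mode table")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if not 0 < cutoff <= 1:
        raise ValidationError("cutoff must be in (0, 1]")
    m = len(table.asv_ids)
    if m < 2:
        raise ValidationError("ancom needs >= 2 ASVs")
    idx_by_group = _group_arrays(table.sample_ids, groups)
    if len(idx_by_group) < 2:
        raise ValidationError("ancom needs >= 2 groups")
    small = [g for g, idx in idx_by_group.items() if len(idx) < 2]
    if small:
        raise ValidationError(f"groups with < 2 samples: {small}")

    logx = np.log(table.data.to_numpy(dtype=float) + pseudocount)  # n x m
    group_list = sorted(idx_by_group)

    if len(group_list) == 2:
        test_name = "mann-whitney"
        reject = _pairwise_rejections_two_groups(
            logx, idx_by_group[group_list[0]], idx_by_group[group_list[1]], alpha
        )
    else:
        test_name = "kruskal-wallis"
        reject = _pairwise_rejections_k_groups(
            logx, [idx_by_group[g] for g in group_list], alpha
        )

    w = reject.sum(axis=1)
    threshold = cutoff * (m - 1)
    out = pd.DataFrame(
        {"w_stat": w.astype(int), "significant": w >= threshold},
        index=pd.Index(table.asv_ids, name="asv_id"),
    )
    return AncomResult(table=out, cutoff=cutoff, alpha=alpha,
                       test_name=test_name, n_asvs=m)


def _pairwise_rejections_two_groups(
    logx: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, alpha: float
) -> np.ndarray:
    """Boolean (m x m) matrix: test of log-ratio i/j rejects between 2 groups.

    All m(m-1)/2 Mann-Whitney tests run in one vectorized call on the
    (m, m, n) log-ratio stack; identical-sample degenerate ratios yield
    p = 1 via the tie-corrected normal approximation.
    """
    m = logx.shape[1]
    # lr[i, j, k] = log-ratio of ASV i over ASV j in sample k
    lr_a = logx[idx_a].T[:, None, :] - logx[idx_a].T[None, :, :]
    lr_b = logx[idx_b].T[:, None, :] - logx[idx_b].T[None, :, :]
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(lr_a, lr_b, axis=-1, method="asymptotic",
                                 alternative="two-sided")
    pvals = np.asarray(res.pvalue)
    pvals = np.nan_to_num(pvals, nan=1.0)  # all-tied ratios: never reject
    reject = pvals < alpha
    np.fill_diagonal(reject, False)
    return reject


def _pairwise_rejections_k_groups(
    logx: np.ndarray, group_idx: list[np.ndarray], alpha: float
) -> np.ndarray:
    m = logx.shape[1]
    reject = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            samples = [logx[idx, i] - logx[idx, j] for idx in group_idx]
            flat = np.concatenate(samples)
            if np.ptp(flat) == 0:
                continue
            _, p = stats.kruskal(*samples)
            if p < alpha:
                reject[i, j] = reject[j, i] = True
    return reject


def pairwise_ancom(
    table: AsvTable,
    groups: Mapping[str, str],
    pairs_to_test: list[tuple[str, str]],
    alpha: float = 0.05,
    cutoff: float = 0.7,
    pseudocount: float = 1.0,
) -> tuple[dict[tuple[str, str], AncomResult], pd.DataFrame]:
    """Run ANCOM restricted to each requested pair of group labels.

    Returns the per-pair results plus a summary frame with the number of
    significant ASVs per pair — the headline comparison between fraction
    pairs such as (SL, W).
    """
    available = {groups[s] for s in table.sample_ids if s in groups}
    results: dict[tuple[str, str], AncomResult] = {}
    rows = []
    for a, b in pairs_to_test:
        unknown = [g for g in (a, b) if g not in available]
        if unknown:
            raise ValidationError(f"unknown group labels: {unknown}")
        ids = [s for s in table.sample_ids if groups[s] in (a, b)]
        sub = table.subset(sample_ids=ids).drop_empty_asvs()
        res = ancom(sub, groups, alpha=alpha, cutoff=cutoff, pseudocount=pseudocount)
        results[(a, b)] = res
        rows.append({
            "group_a": a, "group_b": b,
            "n_significant": int(res.table["significant"].sum()),
            "n_asvs": res.n_asvs,
        })
    return results, pd.DataFrame(rows)
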