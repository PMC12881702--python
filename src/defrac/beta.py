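"""Compositional transforms, distance matrices, ordination and PERMANOVA.

Sequencing data are compositional: only relative information is meaningful.
The centred log-ratio (CLR) transform maps each sample x to
log(x_i / g(x)) with g the geometric mean, after a pseudocount has replaced
zeros; Euclidean distance between CLR rows is the Aitchison distance.
Bray-Curtis dissimilarity (1 - sum min(x_i, y_i) on normalized profiles)
complements it as an abundance-overlap measure. Group structure on a
distance matrix is tested with one-way PERMANOVA (permutation pseudo-F).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io import AsvTable, SampleRecord, ValidationError

__all__ = ["DistanceMatrix", "PermanovaResult", "PcoaResult", "PhaseContrast",
           "clr_transform", "aitchison_distance", "bray_curtis", "pcoa",
           "permanova", "pairwise_permanova", "paired_distances",
           "phase_contrast", "select_extreme_pairs"]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with a metric label."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str  # aitchison | bray_curtis

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be 0")
        if np.any(v < 0):
            raise ValidationError("distances must be >= 0")

    def get(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    n_samples: int


@dataclass(frozen=True)
class PcoaResult:
    """Classical MDS embedding: coordinates scaled by sqrt(eigenvalue)."""

    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray    # all eigenvalues, descending
    negative_eigenvalues: np.ndarray


@dataclass(frozen=True)
class PhaseContrast:
    """Per-depth mean SL-W dissimilarity in each bloom phase.

    ``table`` columns: depth, mean_prebloom, mean_bloom, ci95_prebloom,
    ci95_bloom, delta (= mean_bloom - mean_prebloom), n_prebloom, n_bloom.
    """

    table: pd.DataFrame
    omitted_depths: list[float]


def clr_transform(table: AsvTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio transform of a counts table.

    ``pseudocount`` is added to every count before closure so zeros have a
    finite image; each output row sums to 0 (to 1e-9).
    """
    if table.mode != "counts":
        raise ValidationError("clr_transform expects a counts-mode table")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    x = table.data.to_numpy(dtype=float) + pseudocount
    props = x / x.sum(axis=1, keepdims=True)
    logs = np.log(props)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.data.index, columns=table.data.columns)


def aitchison_distance(table: AsvTable, pseudocount: float = 1.0) -> DistanceMatrix:
    """Euclidean distance between CLR-transformed samples."""
    if len(table.sample_ids) < 2:
        raise ValidationError("need >= 2 samples for a distance matrix")
    clr = clr_transform(table, pseudocount).to_numpy()
    dm = squareform(pdist(clr, metric="euclidean"))
    return DistanceMatrix(table.sample_ids, dm, "aitchison")


def bray_curtis(table: AsvTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between relative-abundance profiles.

    Counts-mode input is auto-normalized with a warning; for normalized rows
    the scipy Bray-Curtis formula equals 1 - sum min(x_i, y_i).
    """
    data = table.data.to_numpy(dtype=float)
    if table.mode == "counts":
        warnings.warn("bray_curtis: counts-mode input auto-normalized to relative",
                      stacklevel=2)
        sums = data.sum(axis=1)
        if np.any(sums == 0):
            raise ValidationError("cannot normalize an all-zero sample")
        data = data / sums[:, None]
    dm = squareform(pdist(data, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, dm, "bray_curtis")


def pcoa(dm: DistanceMatrix, k: int = 2) -> PcoaResult:
    """Principal coordinates analysis (classical MDS).

    Double-centres -D^2/2, eigendecomposes, and returns the first ``k`` axes
    with positive eigenvalues; negative eigenvalues (non-Euclidean input) are
    reported and their axes dropped, truncating ``k`` with a warning.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    d2 = dm.values**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals[0]) if n else 0)
    positive = eigvals > tol
    n_pos = int(positive.sum())
    if k > n_pos:
        warnings.warn(f"pcoa: only {n_pos} positive eigenvalues; truncating k={k}",
                      stacklevel=2)
        k = n_pos
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    return PcoaResult(
        coordinates=pd.DataFrame(
            coords, index=dm.sample_ids, columns=[f"PC{i+1}" for i in range(k)]
        ),
        eigenvalues=eigvals,
        negative_eigenvalues=eigvals[eigvals < -tol],
    )


def _permanova_stats(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and integer group labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    n_groups = labels.max() + 1
    for g in range(n_groups):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among, df_within = n_groups - 1, n - n_groups
    f = (ss_among / df_among) / (ss_within / df_within) if ss_within > 0 else np.inf
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    p = (#{F_perm >= F_obs} + 1) / (n_permutations + 1) over seeded label
    permutations; R^2 = SS_among / SS_total. Every group needs >= 2 samples.
    """
    labels_str = np.array([groups[s] for s in dm.sample_ids])
    uniq, labels = np.unique(labels_str, return_inverse=True)
    if len(uniq) < 2:
        raise ValidationError("permanova needs >= 2 groups")
    counts = np.bincount(labels)
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise ValidationError(f"groups with < 2 samples: {small}")
    d2 = dm.values**2
    f_obs, r2 = _permanova_stats(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        f_perm, _ = _permanova_stats(d2, perm)
        if f_perm >= f_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs), r_squared=float(r2), p_value=float(p),
        n_permutations=n_permutations, n_samples=len(labels),
    )


def pairwise_permanova(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """PERMANOVA for every unordered pair of group labels."""
    labels = sorted({groups[s] for s in dm.sample_ids})
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            ids = [s for s in dm.sample_ids if groups[s] in (a, b)]
            res = permanova(dm.subset(ids), groups, n_permutations, seed)
            rows.append({
                "group_a": a, "group_b": b, "pseudo_f": res.pseudo_f,
                "r_squared": res.r_squared, "p_value": res.p_value,
                "n_samples": res.n_samples,
            })
    return pd.DataFrame(rows)


def paired_distances(
    dm: DistanceMatrix,
    metadata: Mapping[str, SampleRecord],
    fraction_a: str = "SL",
    fraction_b: str = "W",
) -> pd.DataFrame:
    """Distance between the two fractions' samples at each matched (week, depth).

    Returns a frame with columns week, depth, phase, sample_a, sample_b,
    distance — the per-context dissimilarity series used for phase contrasts
    and extreme-pair selection. Contexts lacking either fraction are skipped.
    """
    by_context: dict[tuple[int, float], dict[str, str]] = {}
    for sid in dm.sample_ids:
        rec = metadata[sid]
        if rec.fraction in (fraction_a, fraction_b):
            by_context.setdefault(rec.context, {})[rec.fraction] = sid
    rows = []
    for (week, depth) in sorted(by_context):
        slot = by_context[(week, depth)]
        if fraction_a in slot and fraction_b in slot:
            sa, sb = slot[fraction_a], slot[fraction_b]
            rows.append({
                "week": week, "depth": depth, "phase": metadata[sa].phase,
                "sample_a": sa, "sample_b": sb, "distance": dm.get(sa, sb),
            })
    return pd.DataFrame(rows, columns=["week", "depth", "phase",
                                       "sample_a", "sample_b", "distance"])


def _t_ci_halfwidth(values: np.ndarray, level: float = 0.95) -> float:
    n = len(values)
    if n < 2 or np.ptp(values) == 0:
        return 0.0
    sem = stats.sem(values)
    return float(sem * stats.t.ppf(0.5 + level / 2, n - 1))


def phase_contrast(pairs: pd.DataFrame) -> PhaseContrast:
    """Per-depth mean paired dissimilarity in the pre-bloom vs bloom phases.

    ``pairs`` is the output of :func:`paired_distances`. Depths with no pairs
    in one phase are omitted with a warning. 95% CIs are t-intervals on the
    per-pair distances.
    """
    rows, omitted = [], []
    for depth, sub in pairs.groupby("depth"):
        pre = sub.loc[sub["phase"] == "pre_bloom", "distance"].to_numpy()
        blo = sub.loc[sub["phase"] == "bloom", "distance"].to_numpy()
        if len(pre) == 0 or len(blo) == 0:
            omitted.append(float(depth))
            warnings.warn(f"phase_contrast: depth {depth} lacks a phase; omitted",
                          stacklevel=2)
            continue
        rows.append({
            "depth": float(depth),
            "mean_prebloom": float(pre.mean()),
            "mean_bloom": float(blo.mean()),
            "ci95_prebloom": _t_ci_halfwidth(pre),
            "ci95_bloom": _t_ci_halfwidth(blo),
            "delta": float(blo.mean() - pre.mean()),
            "n_prebloom": len(pre),
            "n_bloom": len(blo),
        })
    return PhaseContrast(table=pd.DataFrame(rows), omitted_depths=omitted)


def select_extreme_pairs(
    pairs: pd.DataFrame, k_low: int, k_high: int
) -> pd.DataFrame:
    """The k_low most similar and k_high most dissimilar matched pairs.

    Ranks by distance; ties at a cut are broken by (week, depth) lexicographic
    order. The returned frame adds a ``tail`` column ("low" / "high").
    """
    if k_low < 0 or k_high < 0:
        raise ValidationError("k_low and k_high must be >= 0")
    if k_low + k_high > len(pairs):
        raise ValidationError("k_low + k_high exceeds the number of pairs")
    ranked = pairs.sort_values(["distance", "week", "depth"],
                               kind="mergesort").reset_index(drop=True)
    low = ranked.head(k_low).assign(tail="low")
    high = ranked.tail(k_high).assign(tail="high").iloc[::-1].reset_index(drop=True)
    return pd.concat([low, high], ignore_index=True)
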