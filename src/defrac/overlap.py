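"""Venn partitioning of ASV sets across size fractions and weighted set contributions.

The unweighted view counts how many ASVs are unique to, or shared between,
size fractions. The weighted view scores each Venn region s by

    W_s = n_s * (sum of read counts of the ASVs in s) / (total read count)

so that regions holding many abundant ASVs outweigh regions holding many rare
ones. As printed the statistic is not bounded by 1 (the n_s multiplier), so
both the raw value and its normalization W_s / sum(W_s) are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import pandas as pd

from .io import AsvTable, SampleRecord, ValidationError

__all__ = ["WeightedSetPartition", "venn_partition", "weighted_contribution",
           "shared_fraction", "fraction_asv_sets"]


@dataclass(frozen=True)
class WeightedSetPartition:
    """Disjoint Venn regions of ASV ids with per-region weights.

    ``table`` has one row per region with columns ``n_s`` (ASV count),
    ``reads`` (summed read count), ``weight_raw`` (W_s) and
    ``weight_normalized`` (W_s / sum W_s).
    """

    regions: dict[str, frozenset[str]]
    table: pd.DataFrame

    @property
    def n_total(self) -> int:
        return int(self.table["n_s"].sum())

    @property
    def total_reads(self) -> float:
        return float(self.table["reads"].sum())


def venn_partition(sets: Mapping[str, set[str] | frozenset[str]]) -> dict[str, frozenset[str]]:
    """Exhaustive disjoint Venn partition of 2 or 3 labelled ASV sets.

    Region labels are ``"<label>_only"`` for single-set regions and
    intersection labels joined with the "∩" sign (members of exactly those
    sets and no other). Empty regions are included with empty sets.
    """
    labels = list(sets)
    if len(labels) not in (2, 3):
        raise ValidationError(
            f"venn_partition supports 2 or 3 sets, got {len(labels)}"
        )
    regions: dict[str, frozenset[str]] = {}
    for k in range(1, len(labels) + 1):
        for inside in combinations(labels, k):
            name = f"{inside[0]}_only" if k == 1 else "∩".join(inside)
            members = frozenset.intersection(*(frozenset(sets[l]) for l in inside))
            for other in labels:
                if other not in inside:
                    members -= frozenset(sets[other])
            regions[name] = members
    return regions


def weighted_contribution(
    partition: Mapping[str, frozenset[str] | set[str]],
    reads: Mapping[str, float] | pd.Series,
) -> WeightedSetPartition:
    """Score every Venn region with the weighted contribution statistic W_s.

    ``reads`` maps each ASV id to its summed read count (>= 0) across the
    samples under study; the denominator is the total over all ASVs in the
    partition. Raw weights are reported verbatim alongside their
    normalization, which sums to 1 over non-empty partitions.
    """
    all_asvs = frozenset().union(*partition.values()) if partition else frozenset()
    missing = [a for a in all_asvs if a not in reads]
    if missing:
        raise ValidationError(f"read counts missing for ASVs: {sorted(missing)[:5]}")
    bad = [a for a in all_asvs if reads[a] < 0]
    if bad:
        raise ValidationError(f"negative read counts for ASVs: {sorted(bad)[:5]}")
    total_reads = float(sum(reads[a] for a in all_asvs))
    if total_reads == 0:
        raise ValidationError("total read count over the partition is zero")

    rows = []
    for name, members in partition.items():
        n_s = len(members)
        region_reads = float(sum(reads[a] for a in members))
        rows.append({
            "region": name,
            "n_s": n_s,
            "reads": region_reads,
            "weight_raw": n_s * region_reads / total_reads,
        })
    table = pd.DataFrame(rows).set_index("region")
    w_sum = table["weight_raw"].sum()
    table["weight_normalized"] = table["weight_raw"] / w_sum if w_sum > 0 else 0.0
    return WeightedSetPartition(
        regions={k: frozenset(v) for k, v in partition.items()},
        table=table,
    )


def shared_fraction(
    partition: WeightedSetPartition, shared_regions: list[str]
) -> tuple[float, float]:
    """Proportion of ASVs (and of reads) falling in the given regions.

    Returns ``(count_proportion, read_weighted_proportion)``; used e.g. to
    summarise how much of the community the fraction-shared regions carry.
    """
    unknown = [r for r in shared_regions if r not in partition.table.index]
    if unknown:
        raise ValidationError(f"unknown region labels: {unknown}")
    sub = partition.table.loc[shared_regions]
    n_total = partition.n_total
    total_reads = partition.total_reads
    count_prop = float(sub["n_s"].sum() / n_total) if n_total else 0.0
    read_prop = float(sub["reads"].sum() / total_reads) if total_reads else 0.0
    return count_prop, read_prop


def fraction_asv_sets(
    table: AsvTable,
    metadata: Mapping[str, SampleRecord],
    fractions: list[str],
    by_context: bool = False,
) -> dict:
    """ASV presence sets per size fraction.

    An ASV belongs to a fraction's set when its count is positive in any
    sample of that fraction (whole-series aggregation, the convention used
    for multi-depth Venn summaries). With ``by_context=True`` a mapping
    ``(week, depth) -> {fraction -> set}`` is returned instead.
    """
    uncovered = [s for s in table.sample_ids if s not in metadata]
    if uncovered:
        raise ValidationError(f"metadata does not cover samples: {uncovered}")
    if not by_context:
        out: dict[str, set[str]] = {f: set() for f in fractions}
        for sid in table.sample_ids:
            frac = metadata[sid].fraction
            if frac in out:
                row = table.row(sid)
                out[frac].update(row.index[row.to_numpy() > 0])
        return out
    grouped: dict[tuple[int, float], dict[str, set[str]]] = {}
    for sid in table.sample_ids:
        rec = metadata[sid]
        if rec.fraction not in fractions:
            continue
        slot = grouped.setdefault(rec.context, {f: set() for f in fractions})
        row = table.row(sid)
        slot[rec.fraction].update(row.index[row.to_numpy() > 0])
    return grouped
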