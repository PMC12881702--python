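"""Dominant-genus identification and cross-fraction agreement scoring.

Each sample's most-abundant genus is its "dominant" genus. Two fractions
agree at a (week, depth) context when their samples share the same dominant
genus; the agreement score is the proportion of matched contexts with equal
dominants, reported overall and per bloom phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import AsvTable, SampleRecord, TaxonomyMap, ValidationError

__all__ = ["DominanceReport", "aggregate_to_genus", "dominant_genus",
           "dominance_by_context", "agreement", "top_genera"]


@dataclass(frozen=True)
class DominanceReport:
    """Dominant genus per sample with sampling context attached.

    ``table`` columns: sample_id, week, depth, fraction, phase,
    dominant_genus, tied (True when the argmax was not unique).
    """

    table: pd.DataFrame


def aggregate_to_genus(table: AsvTable, taxonomy: TaxonomyMap) -> AsvTable:
    """Sum ASV columns within genus labels (row sums are preserved).

    Unclassified/uncultured genera are pooled under rank-qualified labels
    such as ``uncultured_<family>`` so that distinct unknown lineages do not
    collapse into one bucket.
    """
    missing = taxonomy.covers(table.asv_ids)
    if missing:
        raise ValidationError(f"taxonomy missing for ASVs: {missing[:10]}")
    labels = [taxonomy.genus_label(a) for a in table.asv_ids]
    grouped = table.data.T.groupby(pd.Index(labels, name="genus")).sum().T
    return AsvTable(grouped, mode=table.mode)


def dominant_genus(genus_row: pd.Series) -> tuple[str, bool]:
    """Most-abundant genus of one sample; ties broken lexicographically.

    Returns ``(genus, tied)``; a zero row has no dominant genus and raises.
    """
    values = genus_row.to_numpy(dtype=float)
    if values.sum() <= 0:
        raise ValidationError("cannot determine dominance of a zero row")
    best = values.max()
    winners = sorted(genus_row.index[values == best])
    return winners[0], len(winners) > 1


def dominance_by_context(
    table: AsvTable,
    metadata: Mapping[str, SampleRecord],
    taxonomy: TaxonomyMap,
) -> DominanceReport:
    """Dominant genus of every sample after genus aggregation."""
    genus_table = aggregate_to_genus(table, taxonomy)
    rows = []
    for sid in genus_table.sample_ids:
        rec = metadata[sid]
        genus, tied = dominant_genus(genus_table.row(sid))
        rows.append({
            "sample_id": sid, "week": rec.week, "depth": rec.depth,
            "fraction": rec.fraction, "phase": rec.phase,
            "dominant_genus": genus, "tied": tied,
        })
    return DominanceReport(table=pd.DataFrame(rows))


def agreement(
    report: DominanceReport,
    fraction_a: str,
    fraction_b: str,
    per_depth: bool = False,
) -> dict:
    """Share of matched (week, depth) contexts where two fractions agree.

    Returns overall, per-phase, and (optionally) per-depth proportions;
    contexts lacking either fraction are excluded and reported. An empty
    matched-context list is an error.
    """
    df = report.table
    a = df[df["fraction"] == fraction_a].set_index(["week", "depth"])
    b = df[df["fraction"] == fraction_b].set_index(["week", "depth"])
    common = a.index.intersection(b.index)
    skipped = sorted(set(a.index.symmetric_difference(b.index)))
    if len(common) == 0:
        raise ValidationError(
            f"no matched (week, depth) contexts between {fraction_a} and {fraction_b}"
        )
    merged = pd.DataFrame({
        "genus_a": a.loc[common, "dominant_genus"],
        "genus_b": b.loc[common, "dominant_genus"],
        "phase": a.loc[common, "phase"],
    })
    merged["match"] = merged["genus_a"] == merged["genus_b"]
    out = {
        "overall": float(merged["match"].mean()),
        "n_contexts": int(len(merged)),
        "per_phase": {ph: float(sub["match"].mean())
                      for ph, sub in merged.groupby("phase")},
        "skipped_contexts": skipped,
    }
    if per_depth:
        out["per_depth"] = {
            float(d): float(sub["match"].mean())
            for d, sub in merged.groupby(level="depth")
        }
    return out


def top_genera(genus_table: AsvTable, k: int = 20) -> pd.Series:
    """The k most abundant genera by mean relative abundance across samples."""
    data = genus_table.data.to_numpy(dtype=float)
    if genus_table.mode == "counts":
        sums = data.sum(axis=1, keepdims=True)
        if np.any(sums == 0):
            raise ValidationError("cannot rank genera with an all-zero sample")
        data = data / sums
    means = pd.Series(data.mean(axis=0), index=genus_table.data.columns)
    return means.sort_values(ascending=False).head(k)
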