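"""Reconstitution of de-fractionated (SL) community profiles.

Size fractionation splits one water sample into a small free-living fraction
(S, 0.2-3 um) and a large particle-associated fraction (L, > 3 um) that are
sequenced separately. De-fractionation merges the two observed compositions
back into a single whole-community estimate by weighting each fraction with
its DNA yield, which proxies the biomass captured on each filter:

    C_i = (O_i^S * DNA_S + O_i^L * DNA_L) / (DNA_S + DNA_L)

where O_i^X is the observed relative abundance of ASV i in fraction X. The
merge is a convex combination, so the result is itself a composition over the
union of the S and L ASV sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AsvTable, FractionPair, SampleRecord, ValidationError

__all__ = ["DefractionationResult", "defractionate", "defractionate_all",
           "to_count_scale"]

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class DefractionationResult:
    """One merged SL profile with per-ASV provenance.

    ``provenance`` flags each ASV of the union support as coming from the S
    fraction only, the L fraction only, or both (``shared``); ASVs absent from
    both parents keep an explicit zero and the flag ``absent``.
    """

    sl_row: pd.Series          # relative abundances over the ASV union
    sl_record: SampleRecord    # fraction "SL", dna_concentration = DNA_T
    provenance: pd.Series      # per-ASV flag in {from_S_only, from_L_only, shared, absent}


def _check_relative(row: pd.Series, label: str) -> None:
    vals = row.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValidationError(f"{label}: negative abundance")
    if abs(vals.sum() - 1.0) > 1e-6:
        raise ValidationError(
            f"{label}: row is not a normalized composition (sum={vals.sum()!r}); "
            "convert counts with to_relative first"
        )


def defractionate(pair: FractionPair) -> DefractionationResult:
    """Merge one matched S/L pair into its de-fractionated SL profile.

    Both parent rows must be relative compositions. The output support is
    exactly the union of the parent supports and the output row is
    re-normalized by its sum to absorb floating-point rounding, keeping the
    row-sum invariant at 1 to 1e-9.
    """
    s_rec, l_rec = pair.s_record, pair.l_record
    context = f"pair (week={s_rec.week}, depth={s_rec.depth})"
    _check_relative(pair.s_row, f"{context} S row")
    _check_relative(pair.l_row, f"{context} L row")

    union = pair.s_row.index.union(pair.l_row.index, sort=False)
    s = pair.s_row.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    l = pair.l_row.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    dna_s, dna_l = s_rec.dna_concentration, l_rec.dna_concentration
    dna_t = dna_s + dna_l
    if dna_t <= 0:
        raise ValidationError(f"{context}: DNA_T must be > 0")

    merged = (s * dna_s + l * dna_l) / dna_t
    total = merged.sum()
    if total > 0:
        merged = merged / total

    in_s, in_l = s > 0, l > 0
    flags = np.where(
        in_s & in_l, "shared",
        np.where(in_s, "from_S_only", np.where(in_l, "from_L_only", "absent")),
    )
    sl_record = SampleRecord(
        sample_id=f"{s_rec.sample_id}+{l_rec.sample_id}",
        week=s_rec.week,
        depth=s_rec.depth,
        fraction="SL",
        dna_concentration=dna_t,
        phase_split_week=s_rec.phase_split_week,
    )
    return DefractionationResult(
        sl_row=pd.Series(merged, index=union),
        sl_record=sl_record,
        provenance=pd.Series(flags, index=union),
    )


def defractionate_all(
    pairs: Iterable[FractionPair],
) -> tuple[AsvTable, dict[str, SampleRecord], dict[str, pd.Series]]:
    """De-fractionate every pair and stack the SL rows over the global ASV union.

    Returns ``(sl_table, sl_metadata, provenance)``. Sample order is
    deterministic (week, then depth) regardless of input order; ASVs absent
    from a pair's parents are explicit zeros. Per-pair failures are re-raised
    with the pair's (week, depth) identity attached by :func:`defractionate`.
    """
    pairs = sorted(pairs, key=lambda p: p.context)
    if not pairs:
        raise ValidationError("defractionate_all requires at least one pair")
    results = [defractionate(p) for p in pairs]

    union: pd.Index = results[0].sl_row.index
    for res in results[1:]:
        union = union.union(res.sl_row.index, sort=False)
    union = union.sort_values()

    rows = np.vstack([r.sl_row.reindex(union, fill_value=0.0).to_numpy() for r in results])
    sample_ids = [r.sl_record.sample_id for r in results]
    table = AsvTable(
        pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"), columns=union),
        mode="relative",
    )
    metadata = {r.sl_record.sample_id: r.sl_record for r in results}
    provenance = {r.sl_record.sample_id: r.provenance for r in results}
    return table, metadata, provenance


def to_count_scale(table: AsvTable, library_sizes: Sequence[float] | pd.Series) -> AsvTable:
    """Approximate a counts-mode table from a relative one.

    Each relative row is scaled by its target library size (for SL profiles
    the convention is the sum of the parent S and L read depths) and rounded
    half-to-even for determinism. This is an approximation of a real count
    table: rounded rows need not sum exactly to the requested depth.
    """
    if table.mode != "relative":
        raise ValidationError("to_count_scale expects a relative-mode table")
    sizes = np.asarray(library_sizes, dtype=float)
    if sizes.shape != (len(table.sample_ids),):
        raise ValidationError("one library size per sample is required")
    counts = np.rint(table.data.to_numpy() * sizes[:, None])
    return AsvTable(
        pd.DataFrame(counts, index=table.data.index, columns=table.data.columns),
        mode="counts",
    )
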