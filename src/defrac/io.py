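"""Domain types, validation and readers/writers for ASV tables, metadata and taxonomy.

The universal currency of the package is the :class:`AsvTable`, a rectangular
samples x ASVs abundance matrix carried either on the count scale (``mode="counts"``)
or as per-sample relative abundances that close to 1 (``mode="relative"``).
Sample identity in a fractionation study is fully indexed by
``(week, depth, fraction)``; sample-id strings are free-form join keys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "FRACTION_CODES",
    "AsvTable",
    "SampleRecord",
    "TaxonomyMap",
    "FractionPair",
    "read_asv_table",
    "write_asv_table",
    "to_relative",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "pair_fractions",
    "phase_of_week",
]

#: Recognised size-fraction codes: small free-living (S, 0.2-3 um), large
#: particle-associated (L, > 3 um), unfractionated whole water (W, > 0.2 um),
#: de-fractionated in silico merge (SL), and physically pooled extracts (P).
FRACTION_CODES = ("S", "L", "W", "SL", "P")

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

DEFAULT_PHASE_SPLIT_WEEK = 8


class ValidationError(ValueError):
    """An input violates a domain invariant (negative count, duplicate id, ...)."""


class ParseError(ValueError):
    """A file could not be parsed as the expected format."""


def phase_of_week(week: int, phase_split_week: int = DEFAULT_PHASE_SPLIT_WEEK) -> str:
    """Classify a sampling week into the pre-bloom or bloom phase.

    Weeks up to and including ``phase_split_week`` are ``"pre_bloom"``; later
    weeks are ``"bloom"`` (the spring-bloom default splits weeks 1-8 from 9-16).
    """
    return "pre_bloom" if week <= phase_split_week else "bloom"


@dataclass(frozen=True)
class AsvTable:
    """Samples x ASVs abundance matrix.

    Parameters
    ----------
    data :
        DataFrame with unique sample ids as the index and unique ASV ids as
        columns; all values finite and >= 0, absence encoded as explicit 0.
    mode :
        ``"counts"`` for read counts, ``"relative"`` for compositions whose
        rows each sum to 1 (to 1e-9).
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        df = self.data
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate ASV ids: {dupes}")
        values = df.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValidationError("table contains NaN or infinite values")
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value at sample {df.index[i]!r}, ASV {df.columns[j]!r}"
            )
        if self.mode == "relative" and len(df):
            sums = values.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
            if bad.size:
                raise ValidationError(
                    f"relative-mode rows must sum to 1: sample {df.index[bad[0]]!r} "
                    f"sums to {sums[bad[0]]!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row(self, sample_id: str) -> pd.Series:
        if sample_id not in self.data.index:
            raise KeyError(f"unknown sample {sample_id!r}")
        return self.data.loc[sample_id]

    def subset(self, sample_ids: Iterable[str] | None = None,
               asv_ids: Iterable[str] | None = None) -> "AsvTable":
        """Restrict to the given samples and/or ASVs (order preserved)."""
        df = self.data
        if sample_ids is not None:
            df = df.loc[list(sample_ids)]
        if asv_ids is not None:
            df = df[list(asv_ids)]
        return AsvTable(df, mode=self.mode)

    def drop_empty_asvs(self) -> "AsvTable":
        """Drop ASV columns that are zero in every retained sample."""
        keep = self.data.columns[(self.data.to_numpy() > 0).any(axis=0)]
        return AsvTable(self.data[keep], mode=self.mode)


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata binding a sample to its sampling context.

    ``dna_concentration`` enters the de-fractionation weighting only through
    ratios, so any mass-per-volume unit works as long as it is the same within
    a paired S/L set. ``phase`` is derived from ``week`` at construction.
    """

    sample_id: str
    week: int
    depth: float
    fraction: str
    dna_concentration: float = 0.0
    phase_split_week: int = DEFAULT_PHASE_SPLIT_WEEK
    phase: str = field(init=False)

    def __post_init__(self) -> None:
        if self.fraction not in FRACTION_CODES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown fraction {self.fraction!r}"
            )
        if self.week < 1:
            raise ValidationError(f"sample {self.sample_id!r}: week must be >= 1")
        if self.depth <= 0:
            raise ValidationError(f"sample {self.sample_id!r}: depth must be positive")
        if self.dna_concentration < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: dna_concentration must be >= 0"
            )
        object.__setattr__(self, "phase", phase_of_week(self.week, self.phase_split_week))

    @property
    def context(self) -> tuple[int, float]:
        """The (week, depth) sampling context this sample belongs to."""
        return (self.week, self.depth)


@dataclass(frozen=True)
class TaxonomyMap:
    """Ranked lineage (domain..genus) and community label per ASV.

    Unknown ASVs can be back-filled with an all-"Unclassified" lineage via
    :meth:`with_defaults_for`; community is one of prokaryote / chloroplast /
    eukaryote and is used only as a sample-set filter, never re-derived.
    """

    lineages: pd.DataFrame  # index asv_id, columns TAXONOMY_RANKS + community

    def __post_init__(self) -> None:
        missing = [c for c in (*TAXONOMY_RANKS, "community") if c not in self.lineages.columns]
        if missing:
            raise ValidationError(f"taxonomy missing columns: {missing}")
        if self.lineages.index.duplicated().any():
            raise ValidationError("duplicate ASV ids in taxonomy")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.lineages.index)

    def covers(self, asv_ids: Iterable[str]) -> list[str]:
        """Return the ASV ids NOT covered by this map."""
        return [a for a in asv_ids if a not in self.lineages.index]

    def with_defaults_for(self, asv_ids: Iterable[str],
                          community: str = "prokaryote") -> "TaxonomyMap":
        missing = self.covers(asv_ids)
        if not missing:
            return self
        filler = pd.DataFrame(
            {r: "Unclassified" for r in TAXONOMY_RANKS} | {"community": community},
            index=pd.Index(missing, name=self.lineages.index.name),
        )
        return TaxonomyMap(pd.concat([self.lineages, filler]))

    def genus_label(self, asv_id: str) -> str:
        """Deepest informative rank at or above genus, with an
        ``uncultured_<rank>`` / ``unclassified_<rank>`` qualification when the
        genus itself is uninformative (mirrors common bar-plot relabelling)."""
        row = self.lineages.loc[asv_id]
        genus = str(row["genus"])
        low = genus.lower()
        if genus and low not in ("unclassified", "uncultured", "nan", ""):
            return genus
        qualifier = "uncultured" if low == "uncultured" else "unclassified"
        for rank in reversed(TAXONOMY_RANKS[:-1]):  # family up to domain
            name = str(row[rank])
            if name and name.lower() not in ("unclassified", "uncultured", "nan", ""):
                return f"{qualifier}_{name}"
        return qualifier

    def community_of(self, asv_id: str) -> str:
        return str(self.lineages.loc[asv_id, "community"])


@dataclass(frozen=True)
class FractionPair:
    """Matched small- and large-fraction samples from one (week, depth)."""

    s_record: SampleRecord
    l_record: SampleRecord
    s_row: pd.Series
    l_row: pd.Series

    def __post_init__(self) -> None:
        if self.s_record.fraction != "S" or self.l_record.fraction != "L":
            raise ValidationError("FractionPair requires an S record and an L record")
        if self.s_record.context != self.l_record.context:
            raise ValidationError(
                f"paired samples disagree on (week, depth): "
                f"{self.s_record.context} vs {self.l_record.context}"
            )
        if self.dna_total <= 0:
            raise ValidationError(
                f"pair at (week={self.s_record.week}, depth={self.s_record.depth}): "
                "DNA_S + DNA_L must be > 0"
            )

    @property
    def dna_total(self) -> float:
        """Summed DNA concentration of the two parent fractions (DNA_T)."""
        return self.s_record.dna_concentration + self.l_record.dna_concentration

    @property
    def context(self) -> tuple[int, float]:
        return self.s_record.context


# ---------------------------------------------------------------------------
# Readers / writers


def read_asv_table(path: str | Path, format: str = "tsv") -> AsvTable:
    """Read an ASV count table.

    TSV dialect: first column sample_id, header row of ASV identifiers,
    tab-separated UTF-8. BIOM support is the dense JSON (v1) flavour.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_asv_tsv(path)
    if format == "biom":
        return _read_asv_biom(path)
    raise ValueError(f"unknown format {format!r}")


def _read_asv_tsv(path: Path) -> AsvTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: could not parse TSV ({exc})") from exc
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ParseError(f"{path}: missing value in row {row!r}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric value ({exc})") from exc
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values.index.name = "sample_id"
    return AsvTable(values, mode="counts")


def write_asv_table(table: AsvTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        df = table.data.copy()
        if table.mode == "counts" and np.allclose(df.to_numpy() % 1, 0):
            df = df.astype(int)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
    elif format == "biom":
        _write_asv_biom(table, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_asv_biom(path: Path) -> AsvTable:
    # BIOM v1 is a plain JSON document; only the dense matrix_type is supported.
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON (line {exc.lineno})") from exc
    if doc.get("matrix_type") != "dense":
        raise ParseError(f"{path}: only dense BIOM tables are supported")
    asv_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    data = np.asarray(doc["data"], dtype=float)  # BIOM rows are observations
    df = pd.DataFrame(data.T, index=pd.Index(sample_ids, name="sample_id"),
                      columns=asv_ids)
    return AsvTable(df, mode="counts")


def _write_asv_biom(table: AsvTable, path: Path) -> None:
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "defrac",
        "matrix_type": "dense",
        "matrix_element_type": "float",
        "shape": [len(table.asv_ids), len(table.sample_ids)],
        "rows": [{"id": a, "metadata": None} for a in table.asv_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": table.data.to_numpy(dtype=float).T.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def to_relative(table: AsvTable) -> AsvTable:
    """Convert a counts table to per-sample relative abundances.

    Every row must have a positive sum; all-zero rows are invalid because a
    composition cannot be formed from them.
    """
    if table.mode != "counts":
        raise ValidationError("to_relative expects a counts-mode table")
    values = table.data.to_numpy(dtype=float)
    sums = values.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValidationError(
            f"sample {table.data.index[zero[0]]!r} has zero total count"
        )
    rel = pd.DataFrame(values / sums[:, None], index=table.data.index,
                       columns=table.data.columns)
    return AsvTable(rel, mode="relative")


METADATA_COLUMNS = ("sample_id", "week", "depth_m", "fraction", "dna_concentration")


def read_metadata(path: str | Path,
                  phase_split_week: int = DEFAULT_PHASE_SPLIT_WEEK) -> dict[str, SampleRecord]:
    """Read per-sample metadata TSV into a sample_id -> SampleRecord mapping."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: metadata missing columns {missing}")
    records: dict[str, SampleRecord] = {}
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid in records:
            raise ValidationError(f"duplicate sample_id {sid!r} in metadata")
        records[sid] = SampleRecord(
            sample_id=sid,
            week=int(row["week"]),
            depth=float(row["depth_m"]),
            fraction=str(row["fraction"]),
            dna_concentration=float(row["dna_concentration"]),
            phase_split_week=phase_split_week,
        )
    return records


def write_metadata(records: Mapping[str, SampleRecord] | Iterable[SampleRecord],
                   path: str | Path) -> None:
    if isinstance(records, Mapping):
        records = records.values()
    rows = [
        {
            "sample_id": r.sample_id,
            "week": r.week,
            "depth_m": r.depth,
            "fraction": r.fraction,
            "dna_concentration": r.dna_concentration,
            "phase": r.phase,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = "asv_id"
    return TaxonomyMap(df)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    df = taxonomy.lineages.copy()
    df.index.name = "asv_id"
    df.to_csv(path, sep="\t")


def pair_fractions(
    table: AsvTable,
    metadata: Mapping[str, SampleRecord],
) -> tuple[list[FractionPair], list[SampleRecord]]:
    """Match S and L samples by (week, depth) into :class:`FractionPair` objects.

    Returns ``(pairs, orphans)`` where *orphans* are S or L samples whose
    partner is absent; unmatched samples are reported, never silently dropped.
    Table rows must be in relative mode (the de-fractionation weighting is
    defined on compositions); pass ``to_relative(counts)`` first.
    """
    uncovered = [s for s in table.sample_ids if s not in metadata]
    if uncovered:
        raise ValidationError(f"metadata does not cover samples: {uncovered}")
    by_context: dict[tuple[int, float], dict[str, SampleRecord]] = {}
    for sid in table.sample_ids:
        rec = metadata[sid]
        if rec.fraction not in ("S", "L"):
            continue
        slot = by_context.setdefault(rec.context, {})
        if rec.fraction in slot:
            raise ValidationError(
                f"duplicate (week={rec.week}, depth={rec.depth}, "
                f"fraction={rec.fraction}) samples: "
                f"{slot[rec.fraction].sample_id!r} and {rec.sample_id!r}"
            )
        slot[rec.fraction] = rec
    pairs: list[FractionPair] = []
    orphans: list[SampleRecord] = []
    for context in sorted(by_context):
        slot = by_context[context]
        if "S" in slot and "L" in slot:
            s_rec, l_rec = slot["S"], slot["L"]
            pairs.append(FractionPair(
                s_record=s_rec, l_record=l_rec,
                s_row=table.row(s_rec.sample_id), l_row=table.row(l_rec.sample_id),
            ))
        else:
            orphans.extend(slot.values())
    return pairs, orphans
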