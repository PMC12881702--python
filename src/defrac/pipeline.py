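"""End-to-end orchestration of the fraction-comparison study.

``run`` executes the fixed stage order — load or simulate, community filter,
de-fractionate, alpha diversity, beta diversity, overlap, differential
abundance, dominance — writing one TSV per stage plus a machine-readable
``summary.json`` index. Every stage is seeded from the single run seed, so
two runs with the same config produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alpha as alpha_mod
from .ancom import pairwise_ancom
from . import beta as beta_mod
from . import dominance as dom_mod
from . import overlap as overlap_mod
from .defractionation import defractionate_all, to_count_scale
from .io import (AsvTable, SampleRecord, TaxonomyMap, ValidationError,
                 pair_fractions, read_asv_table, read_metadata, read_taxonomy,
                 to_relative, write_asv_table, write_metadata)
from .simulate import SyntheticCommunityConfig, generate

__all__ = ["RunConfig", "run"]

logger = logging.getLogger("defrac")

DEFAULT_RAREFACTION_DEPTHS = {"prokaryote": 7500, "chloroplast": 715, "eukaryote": 50}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run.

    Either ``simulation`` is set (synthetic study) or all three input paths
    are; ``community`` filters ASVs through the taxonomy's community label
    before any analysis, and selects the matching rarefaction depth.
    """

    out_dir: str | Path = "defrac_out"
    simulation: SyntheticCommunityConfig | None = None
    table_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    community: str = "all"  # prokaryote | chloroplast | eukaryote | all
    rarefaction_depths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_RAREFACTION_DEPTHS))
    rarefaction_iterations: int = 100
    phase_split_week: int = 8
    pseudocount: float = 1.0
    permutations: int = 999
    alpha: float = 0.05
    cutoff: float = 0.7
    k_low: int = 9
    k_high: int = 9
    seed: int = 0

    def validate(self) -> None:
        if self.simulation is None:
            for name in ("table_path", "metadata_path", "taxonomy_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValidationError(f"{name} is required without simulation")
                if not Path(p).exists():
                    raise ValidationError(f"{name} does not exist: {p}")
        if self.community not in ("prokaryote", "chloroplast", "eukaryote", "all"):
            raise ValidationError(f"unknown community filter {self.community!r}")
        if not 0 < self.alpha < 1 or not 0 < self.cutoff <= 1:
            raise ValidationError("alpha in (0,1) and cutoff in (0,1] required")
        if self.permutations < 1 or self.rarefaction_iterations < 1:
            raise ValidationError("permutations and iterations must be >= 1")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SyntheticCommunityConfig(**sim)
        return cls(simulation=sim, **raw)

    @property
    def rarefaction_depth(self) -> int:
        if self.community in self.rarefaction_depths:
            return int(self.rarefaction_depths[self.community])
        return int(self.rarefaction_depths["prokaryote"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        logger.info("stage simulate: seed=%d", config.simulation.seed)
        ds = generate(config.simulation)
        return ds.table, ds.metadata, ds.taxonomy
    table = read_asv_table(config.table_path)
    metadata = read_metadata(config.metadata_path,
                             phase_split_week=config.phase_split_week)
    taxonomy = read_taxonomy(config.taxonomy_path)
    return table, metadata, taxonomy


def _filter_community(table: AsvTable, taxonomy: TaxonomyMap,
                      community: str) -> AsvTable:
    if community == "all":
        return table
    keep = [a for a in table.asv_ids
            if a in taxonomy.lineages.index and taxonomy.community_of(a) == community]
    if not keep:
        raise ValidationError(
            f"community filter {community!r} leaves no ASVs in the table")
    return table.subset(asv_ids=keep)


def run(config: RunConfig) -> dict:
    """Execute the full study; returns the summary dict written to disk."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": _config_dict(config), "stages": {}}
    artifacts: dict[str, Path] = {}

    def record(stage: str, name: str, path: Path) -> None:
        artifacts[name] = path
        summary["stages"].setdefault(stage, []).append(name)

    # --- load / simulate -------------------------------------------------
    table, metadata, taxonomy = _load_inputs(config)
    taxonomy = taxonomy.with_defaults_for(table.asv_ids)
    table = _filter_community(table, taxonomy, config.community)
    table = table.drop_empty_asvs()
    nonzero = [s for s in table.sample_ids if table.row(s).sum() > 0]
    dropped = sorted(set(table.sample_ids) - set(nonzero))
    if dropped:
        logger.warning("dropping %d empty samples: %s", len(dropped), dropped[:5])
        table = table.subset(sample_ids=nonzero)
    counts_path = out_dir / "counts.tsv"
    write_asv_table(table, counts_path)
    write_metadata({s: metadata[s] for s in table.sample_ids},
                   out_dir / "metadata.tsv")
    record("input", "counts", counts_path)
    record("input", "metadata", out_dir / "metadata.tsv")

    # --- de-fractionation -------------------------------------------------
    logger.info("stage defractionate")
    rel = to_relative(table)
    pairs, orphans = pair_fractions(rel, metadata)
    if not pairs:
        raise ValidationError("no matched S/L pairs; cannot de-fractionate")
    sl_rel, sl_meta, _ = defractionate_all(pairs)
    parent_depth = {
        sid: float(table.row(rec_pair.s_record.sample_id).sum()
                   + table.row(rec_pair.l_record.sample_id).sum())
        for sid, rec_pair in zip(sl_rel.sample_ids, sorted(pairs, key=lambda p: p.context))
    }
    sl_counts = to_count_scale(sl_rel, [parent_depth[s] for s in sl_rel.sample_ids])
    write_asv_table(sl_rel, out_dir / "sl_relative.tsv")
    write_metadata(sl_meta, out_dir / "sl_metadata.tsv")
    record("defractionate", "sl_relative", out_dir / "sl_relative.tsv")
    record("defractionate", "sl_metadata", out_dir / "sl_metadata.tsv")
    summary["defractionation"] = {
        "n_pairs": len(pairs),
        "n_orphans": len(orphans),
        "orphan_samples": sorted(o.sample_id for o in orphans),
    }

    # combined counts table over S, L, W, SL for count-based analyses
    all_asvs = table.data.columns.union(sl_counts.data.columns).sort_values()
    combined = AsvTable(
        pd.concat([
            table.data.reindex(columns=all_asvs, fill_value=0.0),
            sl_counts.data.reindex(columns=all_asvs, fill_value=0.0),
        ]),
        mode="counts",
    )
    all_meta: dict[str, SampleRecord] = {**metadata, **sl_meta}
    fractions_present = sorted({all_meta[s].fraction for s in combined.sample_ids})

    # --- alpha diversity --------------------------------------------------
    logger.info("stage alpha: depth=%d iters=%d seed=%d",
                config.rarefaction_depth, config.rarefaction_iterations, config.seed)
    raw_series = alpha_mod.richness_series(combined, all_meta)
    rare_series = alpha_mod.richness_series(
        combined, all_meta, depth=config.rarefaction_depth,
        iterations=config.rarefaction_iterations, seed=config.seed)
    raw_series.table.to_csv(out_dir / "richness_raw.tsv", sep="\t", index=False)
    rare_series.table.to_csv(out_dir / "richness_rarefied.tsv", sep="\t", index=False)
    record("alpha", "richness_raw", out_dir / "richness_raw.tsv")
    record("alpha", "richness_rarefied", out_dir / "richness_rarefied.tsv")

    comparison = alpha_mod.compare_richness(raw_series)
    comparison["pairwise"].to_csv(out_dir / "richness_tests.tsv", sep="\t", index=False)
    record("alpha", "richness_tests", out_dir / "richness_tests.tsv")
    trends = []
    for (depth, fraction), sub in raw_series.table.groupby(["depth", "fraction"]):
        if len(sub) < 3:
            continue
        t = alpha_mod.richness_trend(sub["week"], sub["richness"])
        trends.append({"depth": depth, "fraction": fraction, "slope": t.slope,
                       "r_squared": t.r_squared, "classification": t.classification})
    trends_df = pd.DataFrame(trends)
    trends_df.to_csv(out_dir / "richness_trends.tsv", sep="\t", index=False)
    record("alpha", "richness_trends", out_dir / "richness_trends.tsv")
    summary["alpha"] = {
        "richness_means": comparison["means"],
        "anova_f": _jsonable(comparison["anova_f"]),
        "anova_p": comparison["anova_p"],
        "rarefaction_depth": config.rarefaction_depth,
        "excluded_by_depth": rare_series.excluded,
        "trend_slopes": {f"{r['fraction']}@{r['depth']:g}m": r["slope"]
                         for r in trends},
    }

    # --- beta diversity ---------------------------------------------------
    logger.info("stage beta: permutations=%d seed=%d", config.permutations, config.seed)
    adm = beta_mod.aitchison_distance(combined, pseudocount=config.pseudocount)
    adm.to_frame().to_csv(out_dir / "aitchison.tsv", sep="\t")
    record("beta", "aitchison", out_dir / "aitchison.tsv")
    groups = {s: all_meta[s].fraction for s in combined.sample_ids}
    perm_table = beta_mod.pairwise_permanova(
        adm, groups, n_permutations=config.permutations, seed=config.seed)
    perm_table.to_csv(out_dir / "permanova.tsv", sep="\t", index=False)
    record("beta", "permanova", out_dir / "permanova.tsv")

    rel_all = AsvTable(
        pd.concat([rel.data.reindex(columns=all_asvs, fill_value=0.0),
                   sl_rel.data.reindex(columns=all_asvs, fill_value=0.0)]),
        mode="relative")
    bdm = beta_mod.bray_curtis(rel_all)
    sl_w = beta_mod.paired_distances(bdm, all_meta, "SL", "W")
    contrast = beta_mod.phase_contrast(sl_w)
    contrast.table.to_csv(out_dir / "phase_contrast.tsv", sep="\t", index=False)
    record("beta", "phase_contrast", out_dir / "phase_contrast.tsv")

    sl_w_ait = beta_mod.paired_distances(adm, all_meta, "SL", "W")
    k_low = min(config.k_low, len(sl_w_ait))
    k_high = min(config.k_high, max(0, len(sl_w_ait) - k_low))
    extremes = beta_mod.select_extreme_pairs(sl_w_ait, k_low, k_high)
    extremes.to_csv(out_dir / "extreme_pairs.tsv", sep="\t", index=False)
    record("beta", "extreme_pairs", out_dir / "extreme_pairs.tsv")
    summary["beta"] = {
        "permanova": perm_table.to_dict(orient="records"),
        "phase_contrast": contrast.table.to_dict(orient="records"),
        "n_extreme_pairs": int(len(extremes)),
    }

    # --- overlap ----------------------------------------------------------
    logger.info("stage overlap")
    venn_fracs = [f for f in ("S", "L", "W") if f in fractions_present]
    sets = overlap_mod.fraction_asv_sets(combined, all_meta, venn_fracs)
    partition = overlap_mod.venn_partition(sets)
    reads = combined.data.sum(axis=0)
    weighted = overlap_mod.weighted_contribution(partition, reads)
    weighted.table.to_csv(out_dir / "overlap.tsv", sep="\t")
    record("overlap", "overlap", out_dir / "overlap.tsv")
    shared_labels = [r for r in weighted.table.index
                     if "∩" in r]  # any region shared by >= 2 fractions
    count_prop, read_prop = overlap_mod.shared_fraction(weighted, shared_labels)
    summary["overlap"] = {
        "n_asvs": weighted.n_total,
        "shared_count_proportion": count_prop,
        "shared_read_proportion": read_prop,
        "regions": {r: int(n) for r, n in weighted.table["n_s"].items()},
    }

    # --- differential abundance -------------------------------------------
    logger.info("stage ancom: alpha=%g cutoff=%g", config.alpha, config.cutoff)
    test_pairs = [(a, b) for i, a in enumerate(fractions_present)
                  for b in fractions_present[i + 1:]]
    _, ancom_summary = pairwise_ancom(
        combined, groups, test_pairs, alpha=config.alpha,
        cutoff=config.cutoff, pseudocount=config.pseudocount)
    ancom_summary.to_csv(out_dir / "ancom.tsv", sep="\t", index=False)
    record("ancom", "ancom", out_dir / "ancom.tsv")
    summary["ancom"] = ancom_summary.to_dict(orient="records")

    # --- dominance ---------------------------------------------------------
    logger.info("stage dominance")
    report = dom_mod.dominance_by_context(combined, all_meta, taxonomy)
    report.table.to_csv(out_dir / "dominance.tsv", sep="\t", index=False)
    record("dominance", "dominance", out_dir / "dominance.tsv")
    agreements = {}
    for a, b in test_pairs:
        try:
            agreements[f"{a}-{b}"] = dom_mod.agreement(report, a, b)["overall"]
        except ValidationError:
            continue
    summary["dominance"] = {
        "n_distinct_dominants": int(report.table["dominant_genus"].nunique()),
        "agreement": agreements,
    }

    # --- index -------------------------------------------------------------
    summary["artifacts"] = {name: {"path": str(p.name), "sha256": _sha256(p)}
                            for name, p in artifacts.items()}
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True,
                                       default=_jsonable) + "\n")
    logger.info("summary written to %s", summary_path)
    return summary


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["out_dir"] = str(d["out_dir"])
    return d


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return None
    if isinstance(x, np.bool_):
        return bool(x)
    if isinstance(x, Path):
        return str(x)
    if isinstance(x, float):
        return x
    raise TypeError(f"not JSON-serializable: {type(x)}")
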