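# defrac

**De-fractionation and comparison of size-fractionated amplicon microbial
communities.**

Marine microbiome surveys often size-fractionate seawater by filtering it
sequentially through a large-pore (3 μm) and a small-pore (0.2 μm) filter,
splitting the community into a particle-associated fraction (*L*, > 3 μm) and
a free-living fraction (*S*, 0.2–3 μm) that are extracted and sequenced
separately. Other surveys use a single 0.2 μm filter and obtain one
unfractionated whole-community sample (*W*). `defrac` makes the two designs
comparable: it computationally *de-fractionates* matched S/L sample pairs
into a merged profile (*SL*) and provides the full analysis battery needed to
judge how well SL, S and L recover W — richness and its temporal trends,
ASV-set overlap, compositional beta-diversity, dominant-taxon agreement and
differential abundance — plus a synthetic ground-truth generator so that
every stage can be validated end to end without any sequencing data.

## The core statistic

Given the observed relative abundance `O_ij^X` of ASV *i* in sample *j* of
fraction *X*, and the DNA concentration `DNA_j^X` of each fraction extract
(a proxy for the biomass captured on each filter), the de-fractionated
relative abundance is the DNA-weighted convex combination

```
C_ij^SL = (O_ij^S · DNA_j^S  +  O_ij^L · DNA_j^L) / (DNA_j^S + DNA_j^L)
```

Weighting by DNA concentration matters: pooling the fractions equally would
over-represent the low-biomass > 3 μm fraction. Because the merge is convex,
`C^SL` is itself a composition over the union of the S and L ASV sets, and
when DNA yield is proportional to captured biomass, the expected SL
composition equals the expected whole-community composition.

The comparison battery around it:

- **Overlap** — Venn partition of fraction ASV sets, each region *s* scored
  with the weighted contribution `W_s = n_s · Σ_{i∈s} RA_i / Σ_i RA_i`
  (reported raw and normalized), separating rare-unique from abundant-shared
  ASVs.
- **Alpha diversity** — richness, repeat rarefaction (multivariate
  hypergeometric subsampling, mean over iterations), one-way ANOVA with
  Holm-corrected pairwise *t*-tests, and OLS richness-trend classification.
- **Beta diversity** — CLR transform, Aitchison and Bray–Curtis distances,
  PCoA, one-way and pairwise PERMANOVA, pre-bloom/bloom phase contrasts, and
  selection of the most/least similar SL–W pairs.
- **Differential abundance** — ANCOM: per-ASV W statistics from pairwise
  log-ratio rank tests across fraction groups.
- **Dominance** — genus-level aggregation and cross-fraction agreement of
  each sample's dominant genus.

## Worked example

Simulate a compact fractionated time series, de-fractionate it, and check
how close each set gets to the unfractionated samples:

```python
import defrac

cfg = defrac.SyntheticCommunityConfig(
    n_asvs=60, n_weeks=6, depths=(1.0, 10.0), seed=3)
ds = defrac.generate(cfg)           # S, L and W counts + DNA concentrations
print(ds.table.shape)               # (36, 60): 6 weeks x 2 depths x 3 fractions

report = defrac.recovery_report(ds) # de-fractionates and scores every context
print(report[["bc_sl_w", "bc_s_w", "bc_l_w"]].mean())
```

which prints

```
(36, 60)
bc_sl_w    0.018014
bc_s_w     0.158516
bc_l_w     0.578314
```

i.e., the mean Bray–Curtis dissimilarity to the unfractionated sample is
0.018 for the de-fractionated SL profile, 0.159 for the free-living fraction
alone and 0.578 for the particle-associated fraction alone: DNA-weighted
merging recovers the whole community an order of magnitude better than
either fraction by itself.

The same study runs from the shell:

```bash
defrac simulate --out-dir sim/ --seed 3
defrac merge --table sim/counts.tsv --metadata sim/metadata.tsv --out sim/sl.tsv
defrac run --config run.yaml        # full pipeline with summary.json
```

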