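# Methods

This note records the models, conventions and numerical choices behind
`defrac`, and what the synthetic validation does and does not establish.

## De-fractionation model

A size-fractionated sampling design splits each water sample into a
large/particle-associated fraction (L, > 3 μm) and a small/free-living
fraction (S, 0.2–3 μm). The de-fractionated profile is the DNA-weighted
convex combination of the two observed compositions,

    C_i = (O_i^S · DNA_S + O_i^L · DNA_L) / (DNA_S + DNA_L),

applied per matched (week, depth) pair. Assumptions:

- DNA concentration of each extract is proportional to the biomass captured
  on its filter, with the same proportionality for both fractions of a pair.
  Only the ratio DNA_S : DNA_L enters, so units are free as long as they are
  identical within a pair.
- The observed compositions are unbiased for the fraction compositions
  (amplification and extraction biases are assumed shared across fractions).
- ASVs absent from a fraction contribute an exact zero, not a pseudocount:
  the merge is arithmetic on the printed formula.

The merged row is re-normalized by its sum after the weighted average to
absorb floating-point rounding; the row-sum invariant is enforced at 1e-9.
Because rarefaction-style analyses need counts, a count-scale SL table can
be produced by scaling the relative profile by the *sum of the parent S and
L library sizes* and rounding half-to-even. This is a documented
approximation (rounded rows need not hit the requested depth exactly); the
sum-of-parents convention reflects that SL aggregates two sequencing runs.

## Overlap weighting

Fraction ASV sets are "presence anywhere in the fraction's samples" across
the whole series; per-(week, depth) sets are available through a grouping
flag. The Venn partition is exhaustive and disjoint for 2 or 3 sets. Each
region s is scored with

    W_s = n_s · (Σ_{i∈s} RA_i) / (Σ_i RA_i),

where RA_i is the summed read count of ASV i and n_s the region's ASV count.
As printed this statistic is not bounded by 1 (the n_s multiplier), so the
package reports both the raw value and the normalization W_s / Σ W_s, and
uses the normalized form for proportion-style outputs. `shared_fraction`
additionally reports the plain count proportion and read-weighted proportion
of any set of regions, which is the natural scale for statements like
"unique ASVs carry under 3% of reads". RA defaults to read counts; a flag
switches to relative-abundance weighting.

## Alpha diversity

Richness is the number of ASVs with positive count; it is deliberately
undefined for relative-mode rows (any presence threshold would be
arbitrary). Repeat rarefaction subsamples each library without replacement
(multivariate hypergeometric) at a fixed depth, averaging richness over
iterations (default 100). Samples shallower than the depth are excluded and
reported, never imputed — matching the practical concern that low-coverage
large-fraction samples would otherwise silently vanish. Default depths per
community are 7500 (prokaryotes), 715 (chloroplasts) and 50 (eukaryotes),
chosen as values that retain most samples while equalizing effort; raw
richness is always reported alongside.

Reproducibility: each sample draws from its own generator seeded by
(master seed, blake2b(sample_id)), so results are independent of iteration
and sample order. The Monte-Carlo mean is tested against the closed-form
hypergeometric expectation E[S_d] = Σ_i [1 − C(T−n_i, d)/C(T, d)].

Fraction comparison is a one-way ANOVA plus all pairwise two-sided t-tests
with Holm correction. Pairs with zero pooled variance take an explicit
degenerate path (mean difference + exact-separation flag) instead of a
t statistic. Temporal trends are OLS of richness on week per
(depth, fraction); the "constant" classification band epsilon defaults to 0
(any nonzero slope classifies by sign) and is configurable for noisy data.

## Beta diversity

The CLR transform adds a pseudocount (default 1) to every count before
closure — simple, deterministic zero handling; the pseudocount is the one
tunable and is shared with ANCOM. Aitchison distance is Euclidean distance
on CLR rows; Bray–Curtis operates on relative abundances (so the natively
relative SL profiles are first-class) and counts-mode input is
auto-normalized with a warning. PCoA is classical MDS via eigendecomposition
of the double-centred −D²/2; negative eigenvalues are reported and their
axes dropped.

PERMANOVA is one-way, with pseudo-F computed from among/within sums of
squared distances and p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1) over seeded
label permutations (default 999, seed required). It is implemented in the
package so that many-simulation calibration runs stay cheap and seeding is
explicit; `skbio.stats.distance.permanova` serves as an independent
cross-check in the test suite. Phase contrasts use t-interval 95% CIs on the
per-pair SL–W distances per depth. Extreme-pair selection sorts by distance
with (week, depth) lexicographic tie-breaking; the default 9 lowest + 9
highest pairs is configurable.

## Differential abundance (ANCOM)

For each ASV pair (i, j), the additive log-ratio log((x_i+pc)/(x_j+pc)) is
compared across groups with a two-sided Mann-Whitney U test (two groups;
normal approximation with tie correction, hence fully deterministic) or
Kruskal-Wallis (more). W_i counts rejections at alpha (default 0.05, no
within-loop multiplicity correction — rejection counting is ANCOM's own
control); an ASV is flagged when W_i ≥ cutoff·(m−1) with cutoff 0.7. All
m(m−1)/2 two-group tests run in one vectorized call, keeping m = 200,
n = 40 in the seconds range. W is invariant to per-sample count scaling
because the per-sample scale cancels in every log-ratio. The scikit-bio
ANCOM (different internals: f_oneway, within-loop Holm, tau/theta cutoff
heuristic) is used as a qualitative cross-check on planted signals only.

## Dominance

Tables are aggregated to genus by summing ASV columns; unclassified or
uncultured genera become rank-qualified labels (e.g. `uncultured_<family>`)
so unknown lineages do not collapse into one bucket. The dominant genus is
the per-sample argmax, ties broken lexicographically and flagged. Agreement
between two fractions is the share of matched (week, depth) contexts with
the same dominant genus, reported overall, per phase, and optionally per
depth (the pooled-vs-per-depth choice is left to the caller since both views
are informative).

## Synthetic community generator

The generator emulates a weekly, multi-depth spring-bloom series in which
every context is sampled fractionated (S, L) and unfractionated (W):

- **Community structure.** Each of `n_asvs` (default 300) ASVs is
  free-living, particle-associated or generalist (default proportions
  0.5 / 0.3 / 0.2) with 3 μm-filter retention probabilities 0.05 / 0.9 / 0.5.
  Base abundances are lognormal(0, 1.5); a fixed per-(depth, ASV) lognormal
  shift (σ = 0.5) differentiates depth communities and weekly
  lognormal noise (σ = 0.3) adds temporal variability.
- **Bloom.** From week 9 of 16, 8 bloom taxa are multiplied by a fold
  increase of 30 that compounds by 1.25 per week, concentrating reads in few
  taxa and depressing observed richness — the diversity collapse blooms
  cause in real series.
- **Fractionation.** Biomass splits deterministically as B_L = p·B,
  B_S = (1−p)·B by class retention p (an optional stochastic mode routes
  each taxon's biomass whole-cell style); the total is re-derived as
  B_S + B_L so conservation holds bit-exactly. DNA concentration of a
  fraction is proportional to its captured biomass, optionally with
  lognormal noise (default σ = 0: the noise is the lever for studying when
  DNA-weighted merging degrades).
- **Sequencing.** Reads are multinomial draws from each fraction's biomass
  closure. Mean library sizes default to 34 000 (S), 8 000 (L) and
  20 000 (W) reads — the per-sample scale of the three fraction types in
  comparable field studies — with lognormal spread σ = 0.2.
- **Taxonomy.** Genus labels follow a Dirichlet over ~n_asvs/5 genera so
  several ASVs share genera; all ASVs are labelled prokaryote by default.

All randomness flows from one seed through named blake2b-derived substreams
(classes, abundance, depth_effect, temporal, bloom, split, dna_noise,
library, reads), so outputs are byte-identical across runs and stable under
partial reconfiguration.

Because DNA tracks biomass exactly by default, the expected SL composition
equals the expected W composition, making the central recovery property
testable: mean Bray–Curtis(SL, W) is small, below both BC(S, W) and
BC(L, W), and shrinks monotonically as the common library size grows through
10³–10⁵ reads.

**What the generator does not emulate.** Extraction/amplification bias,
PCR chimeras, 18S under-amplification, physically pooled (P) libraries, and
fraction-specific capture biases that change over time. The last point means
the generator does not reproduce a bloom-time *increase* in SL–W
dissimilarity: with DNA exactly proportional to biomass, SL–W differences
are pure sampling noise, and read concentration during the bloom actually
lowers them slightly. A real bloom-phase divergence would have to come from
capture or yield biases, which can be explored via `dna_noise_sigma` but are
off by default. Passing tests therefore establish the correctness and
calibration of the machinery and the in-silico recovery claim — not that
any field community satisfies the proportional-yield assumption.

## Pipeline

`defrac run` executes load/simulate → community filter → de-fractionation →
alpha → beta → overlap → ANCOM → dominance in fixed order, writing one TSV
per stage plus `summary.json`, which embeds the config, per-stage artifact
list and sha256 hashes of every output. The hashes let external tooling
detect stale artifacts; the pipeline itself always recomputes end to end —
with every stage seeded, two runs with the same config are byte-identical,
which the suite asserts. Community partitioning is purely a filter on the
taxonomy's community label; the package never re-classifies.

Problem sizes used in the validation suite: the calibration checks run 500
PERMANOVA null simulations at 199 permutations (n = 12, two groups) and 200
ANCOM null simulations (m = 30, n = 10 per group); rarefaction is verified
at 10 000 iterations on 20 random libraries; recovery and determinism run
the default 16 × 5 design and a 6-week × 2-depth pipeline respectively —
sizes chosen to make Monte-Carlo bounds tight while keeping the whole suite
in the one-minute range.

## Known limitations

- Eq-style DNA weighting assumes a single pooled DNA measurement per
  fraction; replicate or blank-corrected measurements must be reduced to one
  value upstream.
- Dense-JSON BIOM only; sparse HDF5 BIOM is out of scope.
- PERMANOVA is one-way only (fraction or phase), matching the comparisons
  the package is built for; no dbRDA/CCA, no UniFrac (no tree in scope).
- The count-scale SL table is an approximation for rarefaction-style
  analyses, as described above.
- Richness is the only alpha-diversity index; Shannon or phylogenetic
  diversity would need the (absent) tree and are deliberately out of scope.
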