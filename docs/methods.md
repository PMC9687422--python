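# Methods

## The analysis

Genus-level nematode counts from a warming-gradient soil survey are turned
into community indicators in four stages: (1) each genus is classified by
trophic guild (Ba, Fu, Pp, Op) and colonizer–persister (c-p) score through
a reference table; (2) counts are standardized to individuals per 100 g dry
soil; (3) nine ecological indices are computed per sample and summarized
per treatment; (4) treatments and depth layers are compared with ANOVA and
LSD letter displays. Because raw field counts for the motivating study
system are not publicly deposited, a seeded synthetic generator reproduces
the design so that every stage is exercised end to end.

## Taxonomy reference

The bundled table covers the 35 genera recorded in the alpine-meadow
system. Guild assignments follow the genera's conventional feeding types;
carnivores are folded into the omnivore/predator guild, so exactly four
guilds exist. c-p scores are not published per genus for this system, so
the defaults follow the canonical family-level colonizer–persister
assignments (Rhabditidae/Panagrolaimidae 1, Cephalobidae/Aphelenchidae/
Tylenchidae 2, Hoplolaimidae/Criconematidae/Heteroderidae 3, most
Dorylaimida 4, Discolaimidae 5). These are an editorial default, not a
reconstruction of any particular study's choices; users supply their own
CSV (`genus,guild,cp_value`) to override. Genus lookup is
case-insensitive because abbreviation conventions vary.

Genera missing from the reference are *carried*, not dropped: they count
toward N in the diversity indices (they are real individuals) but are
excluded from every guild-based index, and the unresolved set is reported.

## Density standardization

`density = count × 100 / dry_mass`. The default water-content convention
is wet-mass basis, `dry = fresh × (1 − w)`; a dry-mass basis
(`dry = fresh / (1 + w)`) is selectable, since oven-drying protocols are
compatible with either bookkeeping. The fresh mass is assumed to be the
extracted aliquot, not the whole mixed bag.

## Indices and the two formula dialects

Diversity indices use raw counts; the rest use the guild × c-p tally.
The faunal-profile components admit two published spellings:

- **canonical** (default): `b = 0.8(Ba₂+Fu₂)`, `e = 3.2·Ba₁ + 0.8·Fu₂` —
  basal and enrichment fauna are microbial feeders, consistent with MI
  being restricted to non-plant-parasitic taxa and the structure component
  to Ba/Fu/Op.
- **paper_literal**: `b = 0.8(Pp₂+Fu₂)`, `e = 3.2·Pp₁ + 0.8·Fu₂`, as some
  method sections print the formulas with plant-parasite classes.

Both share `s = Σₖ₌₃..₅ Wₖ(Baₖ+Fuₖ+Opₖ)` with W₃ = 1.8, W₄ = 3.2,
W₅ = 5.0. PPI likewise has a canonical within-guild denominator (keeping
it on the interpretable 1–5 scale) and a literal whole-community
denominator. Which dialect a given publication actually computed is often
undecidable from its text — both are first-class and tested here.

Undefined values (WI or PPI with no plant parasites, J′ with one taxon,
EI/SI with zero components, NCR with no microbial feeders) raise typed
errors at the function level; the table builder converts them to explicit
`NA` markers with the reason recorded in a companion column, and they are
excluded from treatment means with the contributing count (`n_defined`)
reported.

### Aggregation

Treatment summaries are mean-of-replicates: each replicate's index is
computed first, then averaged (mean ± SE, SE = SD/√n). For ratio indices
this differs from the pooled ratio-of-means — e.g. with the published
D-treatment guild shares (Ba 47.14, Fu 14.91, Pp 14.10) the pooled ratio
gives WI = 4.40, while the published per-treatment WI is 5.11, which only a
mean of per-replicate ratios can produce. Mean-of-replicates is therefore
the default and the only aggregation offered.

### Numerical choices

Indices are kept at full precision internally and rounded only for
display. EI and SI are clamped to [0, 100] to absorb one-ulp floating
overshoot. Identical replicates report SE exactly 0. Faunal-profile
quadrant boundaries (EI or SI exactly 50) fall to the lower quadrant and
are flagged.

## Statistics

One-way ANOVA is the standard between/within decomposition; Fisher's LSD
declares a pair different when `|Δmean| > t₁₋α/₂,df_w √(MSW(1/nᵢ+1/nⱼ))`,
α = 0.05 by default. Letters come from an insert-and-absorb construction
that is exact: two groups share a letter **iff** their pair is not
significant; letters are ordered by descending group mean. With zero
within-group variance the LSD is degenerate, and groups are separated by
strict mean inequality instead.

The two-factor warming × soil-layer ANOVA is implemented only for the
balanced complete layout (the study design is balanced 5 × 5 × 3, giving
df 4, 4, 16, 50 and corrected total 74): in unbalanced data the
Type-I/II/III sums-of-squares choice changes the answer and nothing in a
balanced design motivates one, so unbalanced input is rejected with a
pointer to the one-way path. Fitting goes through an OLS two-factor model
(statsmodels); tests cross-check the sums of squares against a direct
cell-mean computation.

## Synthetic communities

The generator emulates the study conditions, not any particular dataset:

- **Design**: 5 treatments × 3 replicates × 5 depth layers (0–5 … 30–40 cm),
  one sample per cell; fresh mass uniform on 50–70 g, the protocol's
  weighing range.
- **Depth profile**: expected density declines from the surface with
  default relative weights 1 / 0.55 / 0.30 / 0.20 / 0.12 and a surface
  expectation of 420 ind·100 g⁻¹ dry soil, reproducing the strong surface
  aggregation of field profiles while keeping deep-layer samples non-empty
  at the study's n. These two numbers are illustrative: within-treatment
  variance components are unknowable from published summaries.
- **Trophic composition**: per-treatment guild proportions use the
  published relative abundances where printed (all five Ba values; Fu and
  Pp for CK, B, D); Fu for A and C are interpolated and Op is the residual.
- **Moisture**: per-sample water content is drawn (SD 0.03, clipped) around
  treatment means declining linearly from the published endpoints 61.27 %
  (control) to 29.13 % (strongest warming).
- **Counts**: the total per sample is a negative-binomial draw (size 10,
  mildly overdispersed — field nematode counts are overdispersed relative
  to Poisson) around density × dry mass/100; genus counts are a single
  multinomial over guild-probability × within-guild frequency, so the
  trophic proportions the indices consume are directly controllable.
  Dominant field genera get 4× within-guild weight.
- **Determinism**: all randomness flows from one `numpy` generator seeded
  by the config (or an override), so identical seeds give bit-identical
  matrices across processes.

What passing tests on synthetic data do **not** show: agreement with real
field values of the indices (the generator has no spatial structure, no
genus–depth interaction, no year effects, and its variance components are
assumptions), and no test asserts that simulated index values match the
published per-treatment table. What they do show: the formulas are
implemented exactly (brute-force oracle equivalence at 1e-12), the design
bookkeeping is correct (df structure, conservation laws), and the pipeline
handles degenerate communities without crashing or silently imputing.

## Known limitations

- Indices not used in this analysis (channel index, basal index, metabolic
  footprints) are out of scope, as are ordination and path models.
- The LSD procedure is unadjusted for multiplicity, matching common field
  practice; with many treatments its letter displays are liberal.
- The compact-letter construction guarantees exactness, not minimal letter
  count.
- Parameter recovery of the simulator's trophic fractions uses multinomial
  standard errors from pooled counts, which is exact for this generator
  but would understate uncertainty for field data with plot-level
  heterogeneity.

## Problem sizes

The default analysis runs on the 75-sample design (≈4,500 individuals);
property suites use 1,000 random tallies and 50–200 replicate simulations,
sizes at which the law-of-large-numbers checks have comfortable margins.
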