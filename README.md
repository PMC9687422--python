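# nemafauna

Faunal analysis of soil nematode communities for warming-gradient field
studies, built around a 5-treatment (CK, A–D) × 3-replicate × 5-depth-layer
alpine-meadow design.

Soil nematodes are standard bioindicators: their trophic guilds
(bacterivores **Ba**, fungivores **Fu**, plant parasites **Pp**,
omnivores/predators **Op**) and their position on the 1–5
colonizer–persister (c-p) life-history scale summarize the state of the
soil food web. This package provides, for genus-level count tables:

- **Taxonomy reference** — genus → guild and genus → c-p mapping, with a
  bundled 35-genus default table for the alpine-meadow system (user-overridable).
- **Density standardization** — individuals per 100 g dry soil from fresh
  mass and gravimetric water content.
- **Ecological indices** — Shannon–Wiener `H′ = −Σ pᵢ ln pᵢ`, Pielou
  `J′ = H′/ln S`, Simpson dominance `λ = Σ pᵢ²`, nematode channel ratio
  `NCR = Ba/(Ba+Fu)`, Wasilewska index `WI = (Ba+Fu)/Pp`, maturity index
  `MI = Σ cᵢ pᵢ` over free-living taxa, plant parasite index
  `PPI = Σ vᵢ fᵢ`, and the faunal profile: basal `b`, enrichment `e`,
  structure `s` components with `EI = 100·e/(e+b)` and `SI = 100·s/(s+b)`
  (structure weights W₃ = 1.8, W₄ = 3.2, W₅ = 5.0). Two formula dialects
  (`canonical` and `paper_literal`) are first-class; see `docs/methods.md`.
- **Statistics** — one-way ANOVA with Fisher's LSD and exact compact-letter
  displays; balanced two-factor warming × soil-layer ANOVA with interaction.
- **Synthetic communities** — a seeded generator shaped like the field
  design, for end-to-end testing when raw field counts are unavailable.

## Worked example

```python
from nemafauna import GuildCpTally, ncr, generate_dataset, index_table

# channel ratio straight from per-guild relative abundances (percent)
ck = GuildCpTally({("Ba", 2): 40.31, ("Fu", 2): 13.42})
print(round(ncr(ck), 2))   # 0.75  -> bacterial-dominated decomposition

# full synthetic pipeline: 75 samples through all nine indices
matrix = generate_dataset(seed=42)
table = index_table(matrix)
print(table.per_treatment.query("index == 'NCR'")[
    ["treatment", "mean", "se", "letter"]])
```

The first value, 0.75, is the channel ratio for the control community:
above 0.5 means organic-matter decomposition runs mainly through the
bacterial channel. The second block prints per-treatment NCR means with
standard errors and LSD significance letters (treatments sharing a letter
do not differ at α = 0.05); with the default simulation it ranges roughly
0.67–0.84 across treatments, all bacterial-dominated.

The same pipeline is available from the shell:

```sh
nemafauna simulate --seed 42 --out results/data
nemafauna indices  --counts results/data/counts.csv --meta results/data/metadata.csv --out results
nemafauna compare  --per-sample results/indices_per_sample.csv --out results
```

The numbered scripts under `analysis/` run the same steps as a narrated
sequence (simulate → indices → treatment/depth ANOVA → faunal-profile
quadrants) and write their tables under `results/`.

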