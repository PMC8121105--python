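# trijunction

Null-model analysis of T-cell diapedesis routes across brain endothelial
monolayers.

T cells crossing an endothelial monolayer (e.g. the blood–brain barrier)
take one of three routes: **transcellular** (through a cell body),
**paracellular across a bicellular junction** (the border curve shared by
two cells), or **paracellular across a tricellular junction** (the point
where three or more cells meet). Observing that many crossings happen at
tricellular junctions is only meaningful against a baseline: junctions
cover some fraction of the monolayer, so even randomly placed crossings
would hit them sometimes. This package quantifies that baseline and tests
observed event compositions against it.

## The model

Bicellular junctions are curves and tricellular junctions are points —
both have zero area — so each is dilated by a radius *r* and every
monolayer pixel is assigned one category with priority TRI > BI > BODY
(a pixel within *r* of a tricellular pixel is TRI; otherwise within *r*
of a bicellular pixel, BI; otherwise BODY). Under the **random-location
null model**, an event lands on any monolayer pixel with equal
probability, so the observed counts (n_TRI, n_BI, n_BODY) are multinomial
with probabilities (p_TRI(r), p_BI(r), p_BODY(r)) equal to the categories'
pixel frequencies. The package tests this with:

- a **Monte-Carlo exact multinomial goodness-of-fit test** ordered by
  outcome likelihood, p = (1 + #{sim at most as likely}) / (n_mc + 1) —
  appropriate at the tens-of-events scale where chi-square asymptotics
  fail; and
- **per-category exact binomial tests** with Benjamini–Hochberg
  adjustment, Wilson 95% intervals, and enrichment ratios
  (observed fraction / null probability).

The geometry comes from a junction-labeled fluorescence image: mean
z-projection → rolling-ball background subtraction (radius 20 px) →
boundary watershed into a cell label map → boundary mask → skeleton →
skeleton graph, whose branch-point clusters are the tricellular junctions
and traced paths the bicellular pixels. An independent label-adjacency
route (≥3 distinct labels around a pixel corner) cross-checks the
skeleton route. A synthetic-monolayer generator (relaxed Voronoi
tessellations, fluorescence-like renders, uniform or junction-tropic
event placement) provides exact ground truth for every stage.

## Worked example

```yaml
# config.yaml
pixel_size: 0.5
seed: 11
n_mc: 999
radii: [1.0, 3.0, 6.0]
simulate:
  n_cells: 40
  domain_width: 150
  domain_height: 150
  noise_sd: 0.15
  z_planes: 3
  n_events: 80
  event_kind: il1b_lo_all_events   # 60% tricellular events
```

```bash
trijunction run-all --config config.yaml --out out/
```

prints (events generated 60% tricellular, tested against the null):

```
radius 1 µm: n=80 (TRI 20, BI 41, BODY 19), global p=0.001 -> tricellular enriched 30.41x (adj p=6.6e-24); bicellular enriched 3.66x (adj p=3.49e-15)
radius 3 µm: n=80 (TRI 50, BI 22, BODY 8), global p=0.001 -> tricellular enriched 9.10x (adj p=2.25e-37)
radius 6 µm: n=80 (TRI 57, BI 16, BODY 7), global p=0.001 -> tricellular enriched 2.91x (adj p=5.74e-18)
```

At radius 1 µm tricellular zones cover well under 1% of the monolayer, so
even the events that fall just outside the 1-µm zone leave a 30-fold
enrichment; by radius 6 µm the zones have grown (null p_TRI ≈ 0.2) and
the enrichment settles near 3×. The global Monte-Carlo p of 0.001 is the
resolution floor at n_mc = 999. `out/` also contains the radius-sweep
table and plot, the per-radius results JSON/CSV, stacked
observed-vs-expected bars, and a manifest with config, seeds and input
checksums. Each stage is also available separately
(`simulate | segment | junctions | sweep | test | report`), and
externally produced label TIFFs can replace the built-in segmentation.

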