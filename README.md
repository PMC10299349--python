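# markercover

Minimal-weight marker gene panel selection by partial set-multi-cover
integer programming on binarized single-cell expression.

For each cell class `k`, `markercover` selects a set of genes `M_k`
minimizing the total gene weight subject to a covering constraint: at least
a fraction `1 - alpha` of the class's cells must express (raw count above a
threshold `theta`, default 0) at least `depth` of the selected genes. Gene
weights compare off-class to in-class detection probability, so cheap genes
are class-specific; requiring `depth` simultaneously detected markers makes
the panels robust to dropout. The package also provides:

- **nested expansion** — regrow a panel at a larger depth as a superset of a
  previously fitted panel;
- **transfer** — per-cell covering depth, expressed-proportion, per-class
  covering rates, and bulk-sample panel scores on a new dataset;
- **mapping** — cross-dataset cell-type mapping via 0–1-normalized covering
  rates;
- **evaluation** — panel redundancy, global panel intersection, balanced
  accuracy, and a frequency-difference reference ranking for size-matched
  baselines;
- **simulation** — zero-inflated labeled count matrices with planted
  class-specific markers (and an optional "sibling classes" redundancy trap)
  so everything is testable without downloads.

Three interchangeable covering back-ends solve the same instance: an exact
MILP (HiGHS via `scipy.optimize.milp`), an exhaustive brute-force oracle for
small instances, and a greedy heuristic whose objective upper-bounds the
optimum.

## CLI

One entry point with six subcommands; every output file gets a companion
`*.provenance.json` with the resolved configuration and input digests.

```sh
# synthetic data: counts (.mtx) + genes.tsv + cells.tsv + truth.json
markercover simulate --config sim.json --out-prefix sim

# fit one covering panel per class
markercover fit --counts sim.mtx --genes sim.genes.tsv --cells sim.cells.tsv \
    --label-col label --depth 3 --alpha 0.05 --out panels.json

# nested expansion to a larger depth (needs the training matrix again)
markercover expand --panels panels.json --counts sim.mtx --genes sim.genes.tsv \
    --cells sim.cells.tsv --label-col label --depth 5 --out expanded.json

# transfer panels to a target dataset
markercover transfer --panels panels.json --counts target.mtx \
    --genes target.genes.tsv --cells target.cells.tsv --label-col label \
    --mode rate --depth 3 --out transfer.tsv

# cross-dataset cell-type mapping (normalized covering rates)
markercover map --panels panels.json --counts target.mtx \
    --genes target.genes.tsv --cells target.cells.tsv --label-col label \
    --depth 5 --threshold 0.8 --out mapping.tsv

# panel-quality metrics
markercover eval --panels panels.json --reference other_panels.json \
    --pred pred.tsv --truth truth.tsv --out metrics.json
```

Matrix inputs are Matrix Market coordinate files plus `genes.tsv` /
`cells.tsv` metadata (tab-separated, header row mandatory), or a dense CSV
with genes as rows. Matrices are stored genes × cells; pass
`--orientation cells_by_genes` explicitly to transpose on read — orientation
is never guessed. Gene matching across datasets is exact-string; map
orthologs or aliases before transfer.

## Python API

```python
from markercover import CoverConfig, fit_all_classes
from markercover.synthdata import SimConfig, simulate

em, truth = simulate(SimConfig(seed=0))
panels, report = fit_all_classes(em, CoverConfig(depth=3, alpha=0.05))
for p in panels:
    print(p.class_name, p.genes, p.achieved_rate, p.solver_status)
```

Key defaults: weight scheme `mean_ratio` (average off-class detection
probability over the in-class probability), candidate filter weight ≤ 1 and
in-class detection probability ≥ 0.1, binarization threshold `theta = 0`
(count ≥ 1), mapping depth 5 with normalized-rate threshold 0.8. Achieved
covering rates in panels are always recomputed from the returned gene set,
never taken from solver bookkeeping.

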