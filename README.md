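# alphamorph

2D alpha-shape descriptors of retinal microvascular morphology.

The package thins a binary vessel segmentation to a 1-pixel skeleton,
treats its pixels as a planar point set, and summarises the vasculature
with four descriptors derived from the Delaunay-filtration alpha-shape:

| descriptor | meaning |
|---|---|
| `op_alpha_min` | minimum alpha at which the shape is a single region covering all skeleton points (complexity: smaller = more complex) |
| `op_area` | area of that optimum shape, in squared pixels (spread) |
| `vs` | vessel shape, `op_area / op_alpha_min` |
| `grad_alpha` | slope of a Tukey-bisquare robust line fitted to VS against the percentage of pixels remaining across 20 spur-erosion iterations (lower = many small terminal vessels) |

A fractal-dimension comparator (box counting and a generalised sandbox
D_q spectrum), a seeded synthetic vessel-tree generator (with neovascular
tuft and lesion-blob corruptions and an exactly pixel-matched
tufted-vs-control pairing protocol), and the statistical evaluation stages
(Kruskal-Wallis / Benjamini-Hochberg / Dunn-Bonferroni group comparison,
bootstrapped lasso/ridge/elastic-net logistic-regression feature importance
with lambda_min / lambda_1SE selection, and Dice / relative-error /
Pearson / rank-sum agreement analysis) round out the pipeline.

## CLI

```sh
alphamorph synth --seed 7 --out-dir out/              # synthetic skeleton + JSON ground truth
alphamorph descriptors out/tree_seed7.png --out d.csv # per-image descriptor rows
alphamorph erosion-series out/tree_seed7.png --out s.csv
alphamorph fd out/tree_seed7.png --out fd.csv --method box_counting
alphamorph stats group d.csv --out omnibus.csv        # + .posthoc.csv
alphamorph stats bootstrap d.csv --positive-label PDR --out importance.csv
alphamorph stats agreement manual.csv automatic.csv --out agreement.csv
```

Inputs are PNG/TIFF rasters (any nonzero pixel in any channel is vessel
foreground); tables are UTF-8 CSV with full float precision.  Every
stochastic stage takes an explicit `--seed` and reruns byte-identically.

## Library entry points

```python
from alphamorph import (
    triangulate, build_alpha_shape, find_optimal_alpha,
    skeletonize, spur_erode, erosion_series,
    compute_descriptors, robust_line_fit,
)
from alphamorph.fractal import box_counting_fd, sandbox_fd
from alphamorph.synthetic import TreeParams, generate_vessel_tree, matched_tuft_pair
from alphamorph.stats import group_comparison, bootstrap_feature_importance
```

Coordinates are (row, col) pixel centres, 0-based, row axis increasing
downward; alpha values are in pixels and areas in squared pixels.
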