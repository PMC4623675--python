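# rhizograph

Fully automated trait analysis of flatbed root scans.

Root system architecture is a core phenotype in crop research: the
number, length, diameter, surface area and volume of primary roots, and
the number and length of the lateral roots each primary bears, all
respond to genotype and to nutrient or water stress. The standard
measurement route for soil-grown plants — wash the roots, spread them in
a tray, scan at 600–800 dpi — produces images that are simple in
principle (dark roots on a light background) but hard in practice:
backgrounds carry illumination gradients, remnant soil particles cling
to root hairs, and spread roots overlap. Tools that threshold globally
or skeletonise naively miscount roots badly under these conditions.

`rhizograph` analyses such scans without any manual threshold or seed
point:

1. **Segmentation** — edge detection plus RANSAC fitting of a low-order
   polynomial background surface separates roots from a non-uniform
   background; the foreground margin is derived from the residual spread
   of the background inliers.
2. **Thickness estimation** — the Euclidean distance transform gives the
   local root diameter at every medial-axis point; the pooled diameter
   histogram is fitted with a two-component Gaussian mixture
   `P(χ) = Σ_k W_k N(χ | μ_k, σ_k)` (K = 2: laterals and primaries) by
   least squares against `H(χ)/N_m`, yielding the mean thickness of each
   class and the threshold `θ_t = 2σ_1`.
3. **Noise-robust thinning** — topology-preserving skeletonisation
   followed by a distance-transform-guided spur filter, so soil specks
   on root boundaries do not become false root tips.
4. **Graph construction and scoring** — the skeleton becomes an
   undirected multigraph `G = (V, E)`; each edge carries its pixel path,
   chain-code length `l_i`, thickness profile and *specific score*
   `α_i = (T̄_i − θ_t)·l_i`, positive for thick primary-like segments and
   negative for thin ones.
5. **Graph reduction** — loop removal and five pruning rules (negative
   terminal edges; parallel-edge reduction; weakest-at-junction terminal
   edges; degree-2 contraction with score recomputation; smallest-score
   pruning at overlap junctions) shrink the graph to a handful of
   vertices while provenance maps every reduced edge back to the
   original skeleton.
6. **Primary-root identification** — primary roots are the simple paths
   between terminal vertices that maximise the accumulated specific
   score `Σ α_i`, found exactly (exhaustive enumeration on small graphs,
   best-first branch-and-bound with an admissible bound otherwise) and
   extracted greedily, edge-disjointly.
7. **Traits** — per primary root: length, mean/min/max diameter, surface
   area and volume under a local-cylinder model
   (`δA = π w(s) δl`, `δV = π w(s)² δl / 4`), plus the attached lateral
   count, total lateral length and linear lateral density; laterals are
   grouped by the primary they emerge from.

A seeded synthetic-scene generator (`rhizograph.synthetic_roots`)
renders ground-truthed scans — curved primaries, attached laterals,
background gradients, boundary soil specks, forced overlaps — so every
stage is testable end to end without external data.

## Worked example

```bash
# render a ground-truthed synthetic scan (5 primaries, soil noise)
rhizograph synth --seed 1 -o scene
# analyse it and write the trait table
rhizograph analyze scene1.png -o traits.csv --overlay overlay.png
```

which prints:

```
scene 1: scene1.png (5 primaries, 45 laterals)
scene1.png: 5 primary root(s), 45 lateral tip(s); traits -> traits.csv
```

Here the pipeline recovered all 5 primary roots and all 45 lateral root
tips of the generated scene. `traits.csv` holds one row per primary root
(lengths in mm, areas in mm², volumes in mm³, lateral counts and
laterals per cm of primary root) plus a `TOTAL` plant-summary row, and
`overlay.png` shows each identified primary in its own colour with the
laterals in yellow.

The same analysis is available as a library:

```python
from rhizograph import load_scan, analyze_image

scan = load_scan("my_scan.tif")          # dpi read from the file
result = analyze_image(scan)
print(result.primary_count, result.lateral_count)
result.report.per_primary                 # pandas DataFrame of traits
```

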