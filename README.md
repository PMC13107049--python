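# fpbarcode

Analysis toolkit for **trichromatic split-fluorescent-protein intensity
barcoding** of cell populations.

Split FPs are β-barrel fluorescent proteins dissected into the 11th
β-strand (FP₁₁) and the complementary first ten strands (FP₁₋₁₀); neither
fluoresces alone, and reassembly restores fluorescence. Fusing a tandem
array of FP₁₁ peptides to a carrier protein makes complemented brightness
a function of the repeat count, so a triple of copy numbers
(c_C, c_G, c_R) over cyan (CFP2), green (mNG3Asp) and red (sfCherry3Csp)
channels is a deterministic intensity *barcode* for one cell population.
This package implements the downstream analysis for such experiments,
from per-cell intensity tables (microscopy segmentation or flow-cytometry
exports) to population calls and spatial statistics:

- **`fpbarcode.tags`** — combinatorics of the copy-number library
  (levels {0,1,2,4,8}, total repeats ≤ 12 → 96 barcodes) and label-capacity
  calculators.
- **`fpbarcode.features`** — background subtraction, pooled-median
  normalization, and the spherical-coordinate features
  `r = (x²+y²+z²)^½`, `Angle_CvsG = tan⁻¹(y/x)`, `Angle_RvsCG = cos⁻¹(z/r)`
  (degrees, x/y/z = cyan/green/red), which are invariant to per-cell
  expression level.
- **`fpbarcode.classify`** — a class-conditional Gaussian mixture: one
  Gaussian per labeled population fitted by moment matching (no EM), with
  membership probabilities `P(k|x) = N(x|μ_k, Σ_k) / Σⱼ N(x|μⱼ, Σⱼ)` whose
  maximum is a per-cell reliability score; plus confusion/accuracy/
  sensitivity metrics and a k-means alternative with majority-vote cluster
  merging.
- **`fpbarcode.panel`** — pairwise discriminability of populations by
  unsupervised two-component mixtures, and max–min panel selection
  (random-sampling search with an exhaustive oracle).
- **`fpbarcode.spatial`** — Clark–Evans dispersion index and heterotypic
  nearest-neighbor adjacency ratios against a label-permutation null.
- **`fpbarcode.simulate`** — a synthetic generator for intensity tables
  (sub-linear ~1.7-fold-per-doubling amplification, log-normal expression
  and channel noise, additive background) and for labeled point patterns
  (random / clustered / attracted), so the whole pipeline is testable
  without imaging data.
- **`fpbarcode.io` / CLI** — CSV cell tables, YAML configs, model JSON,
  and a thin `fpbarcode` command with subcommands
  `simulate | enumerate-tags | train | classify | pairwise | select-panel |
  spatial | kmeans`.

## Worked example

`examples/02_classify_populations.py` simulates a 20-population panel at
the default noise calibration and runs the full identification pipeline:

```
held-out accuracy over 20 populations: 0.936
fraction of cells with membership probability > 0.95: 0.800
```

The first number is pooled per-cell correctness on a 20% held-out split
after fitting one Gaussian per population in angle space; the second is
the fraction of cells whose top membership probability exceeds 0.95 — the
reliability readout used to flag trustworthy calls. A randomly drawn
panel is shown here; `examples/03_panel_selection.py` shows how the
max–min search picks panels whose *worst* pair is still separable, and
`examples/04_spatial_interactions.py` detects a planted cell–cell
attraction through the adjacency ratio (ratio 1.50, empirical p = 0.01,
for the attracted pair; ≈ 1 for indifferent populations).

Each example script is self-contained and prints what its numbers mean.

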