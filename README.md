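# punctapol

Quantification of planar-cell-polarity (PCP) junction organization from
microscopy data, with synthetic ground-truth generators for every input.

## The problem

Core PCP proteins — the atypical cadherin Celsr1 together with Frizzled6 and
Vangl2 — localize asymmetrically at epithelial cell junctions, where Celsr1
organizes into dense, evenly spaced puncta. Point mutations that disrupt
lateral (cis) clustering leave trans-adhesion intact but scatter the puncta,
destabilize the junctional pool, and scramble the cross-junctional
Frizzled6/Vangl2 asymmetry. Testing that chain of phenotypes requires a
battery of quantitative image analyses:

- **dSTORM puncta metrics** — segment clusters in molecule-count renderings
  (binarize, close with a 17-px disk, label with 8-connectivity, restrict
  labels to original pixels), keep clusters with ≥ 10 molecules as *puncta*,
  and report per-punctum molecule count, convex-hull area, and density
  = count / hull area, plus a manual exclusion list for mis-merged puncta.
- **Ripley's L clustering** — for each punctum's point pattern (one point
  per occupied pixel) in a window equal to its bounding box plus a 200 nm
  buffer, estimate L(r) = √(K(r)/π) with Ripley's isotropic edge correction;
  under complete spatial randomness E[L(r)] = r. Groups of patterns (e.g.
  wild-type vs mutant) are compared with a studentized permutation test
  integrating the studentized squared difference of group-mean L over
  r ∈ [0, 200] nm (patterns with < 3 points dropped).
- **FRAP mobile fractions** — normalized recovery
  (F_t − F_bleach)/(F_pre − F_bleach) and mobile fraction
  M = (F_end − F_bleach)/(F_pre − F_bleach) with F_end the mean of the final
  three timepoints; group summaries, fold changes, Welch t-tests.
- **Nematic polarity** — per cell, the intensity-weighted nematic vector
  Q = Σ I·(cos 2θ, sin 2θ)/Σ I over junction pixels with tangent angle θ;
  tissue magnitude of average polarity Mp = |mean Q|.
- **Border metrics** — border-enrichment ratios (border/cell-pair and
  two-ROI definitions), Pearson colocalization of two channels over a band
  ROI, along-border profiles classifying cross-junctional co-occurrence vs
  lateral anti-phase separation, and the bait-normalized co-IP band ratio.

Every stage consumes standard files (TIFF rasters, CSV tables/traces, JSON
ROIs) and every input can be generated synthetically with known ground truth
(`punctapol.simulate`), so the full pipeline is testable end to end with no
external data.

## Worked example

```python
import numpy as np
import punctapol as pp

# simulate a wild-type-like border at 3 nm/px and run the puncta pipeline
mmap, truth = pp.make_puncta_map(pp.PunctaSimParams(seed=11), "wt")
mask = pp.binarize_molecule_map(mmap)
labels = pp.segment_clusters(mask, closing_radius_px=17, connectivity=8)
table = pp.measure_puncta(labels, mmap, min_molecules=10)
print(pp.puncta_summary(table).round(3))

# Ripley's L for the first punctum, then a two-group permutation test
pats = [pp.PointPattern(p.pixel_coords[:, ::-1] * mmap.pixel_size_nm,
                        pp.build_window(p.pixel_coords[:, ::-1] * 3.0,
                                        buffer=200.0))
        for p in table.retained]
lf = pp.ripley_l(pats[0], r_max=200.0)
```

which prints

```
                     mean        sd        se    n
molecule_count    141.250    98.392    49.196  4.0
hull_area_px2    3111.875  3057.020  1528.510  4.0
density_per_px2     0.078     0.045     0.022  4.0
```

i.e. four qualifying puncta averaging 141 molecules over ~3100 px² hulls at
0.078 molecules/px². The excess statistic `L(50 nm) − 50 = 69.5 nm` is far
above the CSR expectation of 0, confirming clustering; testing these four
patterns against four patterns derived from uniformly scattered molecules
gives `Tbar = 11144.5, p = 0.0180`. A noise-free FRAP trace simulated at
mobile fraction 0.507 is recovered as `0.529` from a trace with 1% noise.

The same operations are available from a shell:

```sh
punctapol simulate --what puncta --profile wt --seed 11 --out-dir demo/
punctapol puncta --in demo/map_wt.tif --radius 17 --min-molecules 10 \
    --out demo/table.csv --overlay demo/hulls.tif
punctapol report --seed 3 --out-dir demo/   # end-to-end WT-vs-mutant demo
```

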