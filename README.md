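# polarfish

Quantify front–back mRNA polarization at the invasive front of leader cells
in 3D cancer spheroids, from multi-channel single-molecule FISH z-stacks.

## The problem

Collectively invading cancer cells (e.g. MDA-MB-231 spheroids in Matrigel)
polarize along a front–back axis, and specific mRNAs accumulate at the
invasive front of the leader cell. After branched-DNA smFISH, each mRNA
appears as one diffraction-limited spot in a confocal z-stack with four
channels: a nuclear stain, a whole-cell stain, and two RNA species (RNA1,
RNA2). `polarfish` turns such stacks into a per-cell polarity index and a
statistical comparison of the two RNA species:

1. **Detect** RNA spots in each RNA channel of the masked stack
   (Gaussian smoothing, an isodata + robust-noise intensity floor,
   3×3×3 local maxima, minimum-separation pruning, centroid refinement).
2. **Partition** the user-drawn cell-front outline into four boundary
   segments — *nuclear*, *side1*, *invasive*, *side2* — from four clicks
   made clockwise starting at the nuclear side (clicks snap to the nearest
   outline vertex).
3. **Measure**, for every spot inside the outline, the nearest Euclidean
   distance to each segment. Per image, with Nd_i and Id_i the nuclear and
   invasive distances of spot *i*,

   ```
   L = (1/n) Σ (Nd_i + Id_i)          n = all spots, both RNA types
   M = (1/n_t) Σ Id_i / L             per RNA type t
   ```

   M lies in [0, 1]: 0 means the RNA sits at the invasive edge, 1 at the
   nuclear edge.
4. **Compare** the two RNA types across cells using one (M_RNA1, M_RNA2)
   pair per image — so heavily expressing cells do not dominate — with a
   Wilcoxon matched-pairs signed-rank test (exact null for ≤ 25 pairs),
   plus kernel-density plots of the per-image M values and per-spot
   normalized-distance histograms.

A fully ground-truthed synthetic generator (capsule-shaped cells,
PSF-blurred spots over Poisson + read noise, a tunable invasive placement
bias) makes every stage testable without any microscope data.

## Worked example

```python
from polarfish import synthetic_data as sd
from polarfish.model import PolarityModel

# 8 synthetic images; RNA1 planted invasive-biased (target M ≈ 0.25),
# RNA2 uniform (target M ≈ 0.5)
pooled = sd.simulate_study_distances(8, effect=0.25, seed=11,
                                     n_spots=(40, 40))
print(PolarityModel(pooled).fit().summary())
```

```
Front-back RNA polarity comparison
==================================================
 image_id  n1  n2        L  M_rna1  M_rna2
        1  40  40  94.2528  0.2021  0.4994
        2  40  40 122.6789  0.2404  0.4671
        3  40  40  86.8189  0.1808  0.4509
        4  40  40 142.4347  0.2596  0.4628
        5  40  40  90.7753  0.1792  0.5180
        6  40  40 143.1238  0.2461  0.3815
        7  40  40 124.1398  0.1723  0.4906
        8  40  40 116.9386  0.2102  0.5577
--------------------------------------------------
images: 8   mean M_rna1: 0.2113   mean M_rna2: 0.4785
Wilcoxon matched-pairs signed-rank: W = 0.0, two-sided p = 0.007812
(M near 0: biased toward the invasive edge; near 1: toward the nucleus)
```

Each row is one image (one leader cell): `n1`/`n2` are detected spot
counts per RNA type, `L` the cell's normalization length in pixels, and
`M_rna1`/`M_rna2` the polarity indices. Here RNA1 (M ≈ 0.21) is strongly
shifted toward the invasive edge relative to RNA2 (M ≈ 0.48), and the
paired test across the 8 images is significant (p = 0.0078).

The same workflow runs from the shell on TIFF stacks:

```sh
polarfish simulate --out study --n-images 6 --effect 0.25 --seed 1
polarfish measure  --stack study/image_01.tif \
                   --outline study/image_01_outline.csv \
                   --anchors study/image_01_anchors.csv --out out_01
polarfish analyze  --pooled pooled.csv --out analysis
polarfish all      --out demo        # end to end on synthetic data
```

`measure` writes the per-image tables `Spot Distances.txt` (tab-delimited:
`x y z d_nuclear d_side1 d_invasive d_side2 type`), `Spots1.txt` and
`Spots2.txt`; `analyze` consumes a pooled `.csv` (the same columns plus an
`image` column), and writes `image_summaries.csv`, `stats.json` and the
KDE/histogram plots as TIFF.

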