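# pgcolony

Quantitative analysis of primordial germ cell-like cell (PGCLC) patterning
in BMP4-treated micropatterned human pluripotent stem cell (hPSC) colonies.

Micropatterned hPSC colonies treated with BMP4 differentiate into
concentric rings of cell fates — an amnion-like (AmLC) edge, a PGCLC ring,
a primitive-streak-like (PS) ring, and a pluripotent center — and are one
of the most reproducible in vitro systems for studying human germline
specification. Extracting quantitative statements from such colonies
requires single-cell measurements in 3D immunofluorescence stacks and a
model of the signaling logic that positions the rings. `pgcolony`
implements both halves for anyone analysing micropattern imaging data or
studying BMP/Nodal-driven fate decisions:

- **3D nuclear reconstruction**: fusion of two per-slice 2D segmentations
  (an accurate segmenter that misses nuclei plus a complete one that
  merges them), convex decomposition of merged masks, and linking of masks
  across z-slices as a linear assignment problem (LAP) over the block cost
  matrix `[[A, B], [C, Aᵀ]]`, where
  `A(i,j) = min(|Nᵢ|, |Nⱼ|) / |Nᵢ ∩ Nⱼ|` for each mask's three nearest
  neighbours within a centroid cutoff `d_max`, and the diagonals of B and
  C carry the alternative cost `1/IoU` of staying unlinked. Over-long
  chains split at an interior minimum of mask area.
- **Single-cell quantification and gating**: per nucleus and channel, the
  maximum over z of the mean in-mask intensity; `log(1+x)` transform;
  per-marker 1D Gaussian-mixture thresholds with BIC model selection
  (positives = highest-mean component), rescaled so
  `log(1 + x_thresh) = 1`; named population gates (PGCLC strict
  PRDM1⁺TFAP2C⁺, PGCLC broad SOX17⁺TFAP2C⁺, ...).
- **Radial fate maps**: the positive fraction versus radius as a ratio of
  Gaussian kernel density estimates (Nadaraya–Watson regression of the
  positivity indicator on radius), mean ± SD across colonies.
- **A cross-repressive fate network** driven by a static BMP gradient from
  the colony edge and a Nodal wavefront expanding inward at constant
  velocity: four mutually repressive fate modules (Plu, AmLC, PGCLC, PS)
  with switch-like, hysteretic commitment, phase diagrams over constant
  (BMP, Nodal) inputs, a panel of signaling-perturbation conditions, and
  100 µm edge-band summaries.
- **Synthetic colonies**: a generator of 3D multichannel stacks with known
  per-nucleus ground truth (fates, marker positivity, intensities) and
  degraded segmentations, so the entire pipeline is testable end-to-end by
  parameter recovery, without any external data.
- A small scRNA-seq count-matrix QC filter (library size, mitochondrial
  fraction, gene prevalence).

See `docs/methods.md` for the model equations, estimator choices, default
parameters and their rationale, and known limitations.

## Worked example

Generate four synthetic 200 µm colonies in which 50 % of cells are planted
as PGCLCs, degrade the segmentations, and run reconstruction,
quantification, gating and counting:

```python
from pgcolony.pipeline import RunConfig, analyse_colonies
from pgcolony.synthetic import ColonySpec, ring_layout_for_fraction

spec = ColonySpec(diameter=200.0, density=0.007, n_slices=6, pixel_size=1.0,
                  ring_layout=ring_layout_for_fraction(0.5))
cfg = RunConfig(out_dir="run", colony=spec, n_colonies=4,
                miss_rate=0.05, merge_rate=0.05, seed=1)
gated, thresholds, fractions = analyse_colonies(cfg)
print(fractions[["population", "fraction_pooled", "fraction_sd"]])
```

prints

```
     population  fraction_pooled  fraction_sd
0  PGCLC_strict         0.444318     0.018695
1   PGCLC_broad         0.501136     0.008604
2    AmLC_proxy         0.093182     0.014132
```

`PGCLC_broad` (SOX17⁺ TFAP2C⁺) recovers the planted 50 % within sampling
error; `PGCLC_strict` (PRDM1⁺ TFAP2C⁺) is lower because PRDM1 positivity
is planted as a subset of SOX17⁺ cells, mirroring the conservative-gate
convention. The numbers are bit-reproducible for a fixed seed.

Simulating the fate model and summarising the edge band:

```python
from pgcolony.fatemodel import Condition, simulate_fates, edge_band_summary, dominant_ring_order

field = simulate_fates(Condition("WT"))
print(dominant_ring_order(field))   # ['Am', 'PGC', 'PS', 'Plu'] edge -> center
print(edge_band_summary(field))     # mean fate levels within 100 um of the edge
```

Command-line entry points mirror the library stages: `synth-colony`,
`link-nuclei`, `quantify`, `gate`, `radial-profile`, `simulate-fates`,
`phase-diagram`, `qc-counts`, `run-all`.

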