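# Methods

`pgcolony` quantifies cell-fate patterning in BMP4-treated micropatterned
human pluripotent stem cell (hPSC) colonies, with a focus on primordial
germ cell-like cells (PGCLCs), and simulates the underlying fate decisions
with a cross-repressive signaling-driven network.  All computational
stages run end-to-end on synthetic colonies with known ground truth, so
every claim made by the test suite is a statement about recovering planted
structure.

## Synthetic colonies

A colony is a disc of configurable diameter (default 700 µm, the standard
micropattern size; size scans use 100–700 µm).  Nuclei are placed on a
jittered hexagonal lattice clipped to the disc and thinned uniformly to
the requested count.  The lattice guarantees a minimum center separation
(default 2.3 nuclear radii), so per-slice masks never overlap, and —
unlike sequential dart throwing with rejection — it has spatially uniform
density.  This matters: rejection sampling at confluent densities
over-accepts positions near the colony border, which biases ring
occupancies by several percent and would corrupt planted-fraction
recovery tests.  Nuclear density defaults to 0.007 cells/µm²
(≈500 nuclei in a 300 µm colony).

Nuclei are axis-aligned ellipsoids (default 4 µm lateral radius, 3.5 µm
axial, ±15 % jitter).  An ellipsoid's per-slice cross-section area has a
single maximum along z, which is the shape assumption behind the
chain-splitting rule of the linking stage.  Voxel sampling is 0.5 µm/px
laterally and 2 µm between z-slices by default — typical ×40 spinning-disc
confocal sampling.  An optional multilayered edge places half of the cells
within a configurable edge annulus in a second nuclear layer higher in z,
emulating the thickened colony margins seen at later time points.

Fates are assigned by concentric rings given as fractions of the colony
radius (default, for 700 µm: pluripotent center, PS-like ring, PGCLC ring,
amnion-like cell (AmLC) edge band).  Two helpers derive layouts: one
plants an exact PGCLC area fraction (used for parameter-recovery tests),
one anchors ring widths at the edge in µm so that smaller colonies carry
proportionally more edge fate — the geometry behind the colony-size trend.

Marker intensities are lognormal per fate and channel: positive
populations at log-mean 8.3 (≈4000 counts, 16-bit), background at 5.7
(≈300 counts), ≈2.6 SD apart in log(1+x) space — a clean nuclear
transcription-factor stain.  Within the PGCLC fate, SOX17 and TFAP2C
positivity are drawn comonotonically (one programme draw), and PRDM1 is
drawn as a subset of SOX17+ cells, reproducing the observed containment
of PRDM1+ in SOX17+.  Gaussian read noise (default SD 60 counts) is added
to rendered images.

What the generator does *not* emulate: point-spread blur, depth-dependent
attenuation, chromatic shifts, segmentation errors correlated with local
density, cell-cycle intensity variation, or cell shape change at the
colony edge.  Passing recovery tests therefore demonstrates correctness
of the algorithms under idealized imaging, not robustness to every
real-microscope artifact.  The two-segmenter degradation model (random
misses in the primary segmentation, random neighbour merges in the
fallback) is likewise a caricature used to exercise the fusion logic.

## 3D nuclear reconstruction

Two per-slice 2D label stacks are fused giving preference to the primary
segmenter: primary masks are kept verbatim; fallback pixels outside every
primary mask are binarized, cleaned by a morphological opening (radius
1 px), connected components below 20 px are dropped, and insufficiently
convex components (solidity < 0.9) are split by a convex decomposition —
a cut along the chord joining the two deepest, mutually facing boundary
concavities, recursing on the pieces.  Indivisible concave masks are
returned as-is with a logged warning.

Masks in adjacent z-slices are linked by a linear assignment problem over
the block matrix [[A, B], [C, Aᵀ]].  A(i, j) is the smaller of the two
mask areas divided by their overlap, computed only for each mask's three
nearest neighbours (by centroid, both directions) and only within a
centroid distance cutoff `dmax` (default one expected nuclear radius in
pixels); all other entries hold a large finite sentinel (10⁶ × the largest
finite cost) so standard solvers accept the matrix, and sentinel-cost
assignments are post-filtered to "unlinked".  B and C are diagonal with
the alternative cost 1/IoU (default IoU threshold 0.25) of leaving a mask
unlinked.  With the mirrored Aᵀ block, the solved assignment links a pair
if and only if the link is globally cheaper than both masks taking their
alternative costs; the solver's optimum is verified against brute-force
enumeration over all partial matchings in the tests.

Linking runs sequentially over adjacent slice pairs; linked masks form
chains, one chain per nucleus.  Chains longer than the maximum plausible
z-extent (ceil(nuclear diameter / z-spacing), default 4 slices) are split
at an interior local minimum of mask area — the deepest such minimum,
lowest z on ties, with the minimum-area slice assigned to the earlier
chain — recursing until all chains satisfy the bound.

Numerical notes: mask overlaps use sorted linear pixel indices
(`intersect1d`); centroid k-NN queries use a KD-tree; empty slices yield
degenerate matrices in which every mask takes its alternative cost.

## Quantification and gating

Per channel, a nucleus's value is the **maximum over its z-slices of the
mean intensity within that slice's mask** — the slice where the nucleus
is most nearly in focus.  Values are log(1+x) transformed (natural log,
the scRNA-seq convention); raw values are retained.  The colony center is
the centroid of all nucleus centroids; the radial position is the
Euclidean distance to it.  No background subtraction is applied by
default — thresholds absorb a constant background.

For each marker, a 1D Gaussian mixture (full covariance) is fitted to the
transformed values for K = 1…4 components, 10 seeded initialisations each,
and K* is chosen by minimum BIC.  Positive cells belong to the
highest-mean component; K* = 1 means no positive population.  The scalar
threshold x_thresh reported per marker is the point between the top two
component means where the posterior membership of the top component
crosses 0.5 (found by root bracketing; midpoint fallback if the posterior
does not cross).  Tables are rescaled so log(1 + x_thresh) = 1: positivity
becomes "scaled value > 1" in every scatterplot, and gating is invariant
under this (or any monotone) rescaling.  Manual threshold overrides are
supported but always recorded in the output provenance.

Shipped population gates: PGCLC_strict = PRDM1+ TFAP2C+ (conservative),
PGCLC_broad = SOX17+ TFAP2C+ (slightly higher), endoderm = SOX17+ FOXA2+
TFAP2C−, AmLC = ISL1+ (TFAP2C+ SOX17− as proxy when ISL1 is not imaged),
PS-like = TBXT+ (or EOMES+ ISL1−).  Definitions referencing unmeasured
markers are dropped when gating with the default panel and rejected when
gating with an explicit panel.

## Radial profiles

The spatial profile of a population is the **positive fraction versus
radius**: per colony, a ratio of Gaussian kernel density estimates —
KDE of positive cells' radii over KDE of all cells' radii — evaluated on
a 1 µm grid from 0 to the nominal radius + 25 µm (colonies can spread
past the pattern border), kernels reflected at r = 0 against boundary
bias, bandwidth 15 µm by default.  The ratio estimator is equivalent to
Nadaraya–Watson regression of the positivity indicator on radius and
cancels the per-unit-radius versus per-unit-area density convention.
Mean ± SD are taken across colonies.  Fraction profiles make the
magnitudes of different markers comparable and are immune to background
level; the classic kernel-weighted mean-intensity profile is provided for
comparison and the tests demonstrate both failure modes it suffers
(dynamic-range dependence, background domination for rare populations).

## The fate-network model

Cell fates are modelled cell-autonomously downstream of prescribed
signaling fields over (distance from colony edge d, time t), with a 42 h
horizon:

- **BMP** B(d,t): uniform for a short initial transient (2 h), then a
  stable exponential gradient from the edge, decay length 50 µm at the
  reference dose of 50 ng/ml.  Doses map to amplitude through a saturating
  function normalised so 50 ng/ml gives B = 1 at the edge.  Above the
  reference dose the decay length shrinks as (50/dose)^0.4 — BMP-induced
  inhibitor production makes the response range self-limiting — which is
  what caps the benefit of raising the BMP dose in the dose-grid scans.
- **Endogenous Nodal** N(d,t): a plateau (amplitude 1) behind a logistic
  front (width 12 µm) that expands inward at constant velocity from an
  onset time t₀; signaling at a given depth therefore rises over a few
  hours around t₀ + d/v.  Defaults v = 16 µm/h, t₀ = 15 h place
  appreciable Nodal signaling at the edge region around 16–19 h, high
  levels at depth after ~24 h, and carry the front across most of a
  350 µm colony by 42 h.
- **Exogenous Activin** adds an edge gradient (decay length 60 µm) scaled
  by a saturating dose map during its scheduled intervals.  Receptor
  inhibitions (BMPRi, TGFBRi) zero the corresponding field from their
  start time.  Nodal-knockout conditions disable the endogenous wave.

The network has four bounded fate activities — Plu (pluripotency), Am
(amnion-like, TFAP2C-high), PGC (TFAP2C+ SOX17+, with SOX17 and PRDM1
treated as interchangeable), PS (primitive-streak lineage, subsuming the
endodermal outcome of sustained high Nodal) — plus one signal-processing
variable, the integrated Nodal exposure: a low-pass of N with a slow rise
(6.5 h) and a fast fall (1.5 h), standing for the mesendoderm priming
(EOMES accumulation, rapidly lost once signaling stops) that must precede
SOX17 induction.  Dynamics are Hill-type (coefficient 4) activation with
saturating self-activation inside the input (bistable, committed branches
→ hysteresis), multiplicative pairwise repression, and linear relaxation:

- Am is activated by BMP, slowly (τ = 7 h), and requires BMP for
  maintenance.
- PS is activated by instantaneous Nodal (TBXT-like direct response) but
  commits slowly (τ = 13 h) — the duration-encoding arm — and its
  self-activation latch keeps a ring committed after Nodal withdrawal
  once it has grown past roughly a quarter activation.
- PGC is activated by the product of a band-passed BMP input (squared — a
  cooperative requirement, maximal at intermediate BMP) and the
  band-passed integrated Nodal; its maintenance requires sustained BMP
  but not Nodal, so PGCs persist after late Nodal blockade.
- Partially committed Am shadows PS but admits PGC, which shares the
  TFAP2C programme: the Am→PS repression acts on the Am level, the Am→PGC
  repression cooperatively on its square, so only committed Am excludes
  PGC.
- The PGC→PS repression is slightly leaky (completeness 0.74), so
  sustained high Nodal lets the PS programme slowly invade a committed
  PGC state — duration encoding: a 24 h Activin pulse leaves PGCs, 42 h
  converts the edge to PS-lineage output.
- Plu relaxes to the product of the repressions and is the default on
  argmax ties.

Integration is fixed-step RK4 (dt = 0.05 h), bit-identical across runs;
fate activities are clipped to [0, 1] (the RHS is inward-pointing at the
bounds; clipping only removes rounding excursions).  Steady states for
phase diagrams use max |dX/dt| < 10⁻⁶ h⁻¹ or a 500 h cap.  The radial
grid is anchored at the colony **edge** so cells at equal edge distance
see identical inputs in colonies of any radius; without this, band-edge
sampling parity produces spurious non-monotonicity in colony-size scans.

Parameter values (see `ModelParams` / `SignalParams` for the complete
annotated list) were calibrated against the qualitative perturbation
panel in `pgcolony.panel` — ring order, receptor-inhibition and knockout
responses, Activin timing/duration effects, the BMP×Activin dose grid,
and the colony-size trend.  The panel, not any parameter value, is the
model's acceptance surface; an alternative wiring in which BMP reaches
the PGC module through the TFAP2C response is available behind
`bmp_wiring="via_tfap2c"`.  Removing the PGC↔Am and PGC↔PS mutual
repressions (`ModelParams.ablated()`) breaks the panel, which is the
falsification of the simpler non-competitive model.

Eight of the nine panel properties hold with the shipped defaults.  The
exception — late Nodal-receptor inhibition should *reduce* the PGC
readout relative to the untreated colony — fails for a structural reason
in this class of model, and the panel evaluation reports it as such.  A
residual PS ring after Nodal withdrawal requires PS commitment to
self-sustain from partial activation; that same property lets PS claim
every late-arriving radius in the untreated colony, so the untreated
pattern can never out-grow the ring that late inhibition freezes, and
removing PS mid-race can only help an already-latched PGC ring.  In the
experiment the reduced quantity is a growing cell population, not a
saturating per-cell activity; capturing it would need a population-size
layer on top of the fate network (see limitations).

## scRNA-seq QC

`qc_filter_counts` filters a genes × cells count matrix in order: cells
by library size (default lower bound at the barcode-rank knee), cells by
mitochondrial fraction (default median + 3 scaled MADs, genes identified
by an identifier prefix, default "MT-"), then genes expressed in *fewer
than* `min_cells_per_gene` (default 50) of the retained cells — a gene in
exactly the threshold number of cells is kept.  The operation is
idempotent at fixed bounds.  Matrices are read/written as MTX triples or
dense CSV for toys.

## Problem sizes and determinism

Default test and acceptance runs use: 200 random LAP instances against
the brute-force oracle; a 300 µm / ~500-nucleus / 10-slice colony for
reconstruction; 100 mixture replicates at n = 1000 plus one at n = 5000
for gating; four 3000-cell colonies for profile checks; four colonies per
condition at 1 µm/px for end-to-end recovery; and diameters
{100, 200, 300, 700} µm at density 0.005 µm⁻² for the size trend, pooling
enough colonies per diameter (up to 12 of the smallest) to put at least
~400 cells behind every per-marker mixture fit — below that, BIC
occasionally splits the positive mode in two and the highest-mean-component
rule then misplaces the threshold.  These sizes give sampling errors
comfortably below the tolerances they are tested against.  All randomness flows from explicit seeds
(`numpy.random.default_rng`); images, tables, simulations and manifests
are bit-reproducible for a fixed seed.

## Known limitations

- The convex decomposition handles the common two-body merge well;
  three-way merges may need two recursion levels and pathological masks
  are returned undivided (with a warning) rather than over-split.
- The GMM threshold assumes the top component is the positive population;
  markers whose positive cells are a *minority tail of the same* Gaussian
  will not be separated (the method's intrinsic limit, mitigated in
  practice by the manual override).
- The fate model is deterministic and mean-field per radius: it predicts
  band levels and boundaries, not cell-to-cell heterogeneity, %-positive
  readouts, or population growth; comparisons across conditions use mean
  levels within 100 µm of the edge.  Effects that depend on a population
  continuing to accumulate cells over time — such as the reduction in
  PGC numbers when Nodal receptors are blocked late — are outside what
  saturating per-cell activities can express.
- Signal fields are prescribed, not mechanistic: feedbacks of fates onto
  signaling (e.g. Nodal autoactivation) are folded into the front's
  constant velocity.  Wnt and FGF/ERK are not modelled, so their
  perturbations are outside the model's scope.
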