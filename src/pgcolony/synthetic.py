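"""Synthetic micropatterned-colony generator.

Produces 3D multichannel image stacks of disc-shaped hPSC colonies with
concentric fate rings (amnion-like edge, PGCLC ring, primitive-streak-like
ring, pluripotent center), per-nucleus ground truth, and imperfect per-slice
2D segmentations emulating a two-segmenter setting (an accurate segmenter
that misses nuclei, and a complete one that merges neighbours).

Every downstream stage of the pipeline (fusion, z-linking, quantification,
gating, radial profiles) is testable against the ground truth returned here
without any external data.

Geometry convention: colonies are discs of configurable diameter (default
700 um, the standard micropattern size); radial positions are distances
from the colony center in um.  Nuclei are axis-aligned ellipsoids with
jittered radii, so the per-slice mask area has a single maximum along z --
the shape assumption the chain-splitting rule of the linking stage relies
on.  Marker intensities are lognormal per fate and channel, which makes the
log(1+x)-transformed values approximately Gaussian and therefore suitable
for Gaussian-mixture gating.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ColonyConfigError",
    "ColonyPlacementError",
    "ColonySpec",
    "GroundTruth",
    "DEFAULT_RING_LAYOUT",
    "ring_layout_from_edge_bands",
    "ring_layout_for_fraction",
    "size_series_ring_layout",
    "generate_colony",
    "degrade_segmentation",
    "write_colony",
]


class ColonyConfigError(ValueError):
    """Invalid colony specification (ring layout, fractions, geometry)."""


class ColonyPlacementError(RuntimeError):
    """Could not place the requested number of nuclei without overlap."""


#: Default concentric ring layout for a 700 um colony, as fractions of the
#: colony radius: 50 um amnion-like edge band, 50 um PGCLC ring, 75 um
#: PS-like ring, pluripotent center.
DEFAULT_RING_LAYOUT: tuple[tuple[str, float, float], ...] = (
    ("Plu", 0.0, 175.0 / 350.0),
    ("PS", 175.0 / 350.0, 250.0 / 350.0),
    ("PGCLC", 250.0 / 350.0, 300.0 / 350.0),
    ("AmLC", 300.0 / 350.0, 1.0),
)

#: Positive-component log-intensity parameters (mean, sd of log counts) used
#: for every marker unless overridden; background component likewise.  The
#: separation is ~2.6 SD in log(1+x) space, comparable to a clean nuclear
#: transcription-factor stain.
_POS_LOG = (8.3, 0.30)
_BG_LOG = (5.7, 0.35)
_DAPI_LOG = (8.0, 0.25)

DEFAULT_MARKERS = ("SOX17", "TFAP2C", "PRDM1")

#: Fraction of cells of each fate that are positive for each marker.  For
#: markers coupled as "subset" (see ``ColonySpec.couplings``) the value is
#: conditional on the parent marker being positive.
DEFAULT_POSITIVE_FRACTIONS: dict[tuple[str, str], float] = {
    ("PGCLC", "SOX17"): 0.97,
    ("PGCLC", "TFAP2C"): 0.97,
    ("PGCLC", "PRDM1"): 0.88,
    ("AmLC", "SOX17"): 0.03,
    ("AmLC", "TFAP2C"): 0.95,
    ("AmLC", "PRDM1"): 0.01,
    ("AmLC", "ISL1"): 0.95,
    ("PS", "SOX17"): 0.05,
    ("PS", "TFAP2C"): 0.03,
    ("PS", "PRDM1"): 0.01,
    ("PS", "TBXT"): 0.90,
    ("PS", "EOMES"): 0.90,
    ("Plu", "SOX17"): 0.02,
    ("Plu", "TFAP2C"): 0.02,
    ("Plu", "PRDM1"): 0.01,
}

#: (child marker, parent marker, mode).  "comonotone": positivity of both is
#: driven by the same uniform draw, so joint fraction = min of marginals —
#: used for the coherent SOX17/TFAP2C PGCLC programme.  "subset": the child
#: can only be positive where the parent is (PRDM1+ cells are nearly all
#: SOX17+).
DEFAULT_COUPLINGS: tuple[tuple[str, str, str], ...] = (
    ("TFAP2C", "SOX17", "comonotone"),
    ("PRDM1", "SOX17", "subset"),
)

#: Fates for which the couplings above apply (elsewhere markers are
#: independent; e.g. AmLC TFAP2C-high cells must not inherit the SOX17 draw).
_COUPLED_FATES = frozenset({"PGCLC"})


def ring_layout_from_edge_bands(
    diameter: float, bands_um: Sequence[tuple[str, float]], center_fate: str = "Plu"
) -> list[tuple[str, float, float]]:
    """Convert edge-anchored band widths (um, ordered from the edge inward)
    into a radius-fraction ring layout, clipping at the colony center.

    Small colonies truncate interior bands first, which is how fixed-range
    edge signaling produces higher edge-fate fractions at small diameters.
    """
    radius = diameter / 2.0
    layout: list[tuple[str, float, float]] = []
    outer = radius
    for fate, width in bands_um:
        inner = max(0.0, outer - width)
        if outer > inner:
            layout.append((fate, inner / radius, outer / radius))
        outer = inner
        if outer <= 0:
            break
    if outer > 0:
        layout.append((center_fate, 0.0, outer / radius))
    return layout[::-1]


def size_series_ring_layout(diameter: float) -> list[tuple[str, float, float]]:
    """Ring layout used for colony-size scans: an amnion-like edge band of
    min(25 um, 20% of the radius), a 50 um PGCLC ring, a 60 um PS-like ring,
    pluripotent center.  With these fixed edge-anchored ranges the PGCLC
    share of the colony area grows monotonically as the diameter shrinks.
    """
    radius = diameter / 2.0
    am = min(25.0, 0.2 * radius)
    return ring_layout_from_edge_bands(diameter, [("AmLC", am), ("PGCLC", 50.0), ("PS", 60.0)])


def ring_layout_for_fraction(
    pgclc_fraction: float, edge_fraction: float = 0.1
) -> list[tuple[str, float, float]]:
    """Ring layout planting a target PGCLC area fraction.

    The amnion-like ring occupies the outer ``edge_fraction`` of the area,
    the PGCLC annulus the next ``pgclc_fraction``, the rest is pluripotent.
    """
    if not 0 < pgclc_fraction <= 1 - edge_fraction:
        raise ColonyConfigError("pgclc_fraction must fit inside the non-edge area")
    outer = math.sqrt(1.0 - edge_fraction)
    inner = math.sqrt(outer**2 - pgclc_fraction)
    return [
        ("Plu", 0.0, inner),
        ("PGCLC", inner, outer),
        ("AmLC", outer, 1.0),
    ]


@dataclass
class ColonySpec:
    """Configuration of one synthetic colony.

    Lengths in um, intensities in 16-bit counts.  ``ring_layout`` entries are
    ``(fate, inner_radius_fraction, outer_radius_fraction)`` and must tile
    [0, 1] without overlap.  ``n_cells=None`` derives the count from
    ``density`` (cells per um^2 of colony area).
    """

    diameter: float = 700.0
    n_cells: int | None = None
    density: float = 0.007
    n_slices: int = 10
    z_spacing: float = 2.0
    pixel_size: float = 0.5
    ring_layout: Sequence[tuple[str, float, float]] = DEFAULT_RING_LAYOUT
    markers: Sequence[str] = DEFAULT_MARKERS
    marker_model: Mapping[tuple[str, str], tuple[float, float]] | None = None
    background_model: Mapping[str, tuple[float, float]] | None = None
    positive_fractions: Mapping[tuple[str, str], float] | None = None
    couplings: Sequence[tuple[str, str, str]] = DEFAULT_COUPLINGS
    noise_sd: float = 60.0
    background_level: float = 100.0
    multilayer_edge: bool = False
    multilayer_thickness: float = 50.0
    nucleus_radius: float = 4.0
    nucleus_rz: float = 3.5
    radius_jitter: float = 0.15
    min_separation: float | None = None
    margin: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def separation(self) -> float:
        return self.min_separation if self.min_separation is not None else 2.3 * self.nucleus_radius

    @property
    def channels(self) -> list[str]:
        return ["DAPI", *self.markers]

    def cell_count(self) -> int:
        if self.n_cells is not None:
            return int(self.n_cells)
        return int(round(self.density * math.pi * self.radius**2))

    def fates(self) -> list[str]:
        return [fate for fate, _, _ in self.ring_layout]

    def validate(self) -> None:
        if self.diameter <= 0:
            raise ColonyConfigError("diameter must be positive")
        if self.n_slices < 1:
            raise ColonyConfigError("n_slices must be >= 1")
        if self.pixel_size <= 0 or self.z_spacing <= 0:
            raise ColonyConfigError("pixel_size and z_spacing must be positive")
        rings = sorted(self.ring_layout, key=lambda r: r[1])
        if not rings:
            raise ColonyConfigError("ring_layout must not be empty")
        if abs(rings[0][1]) > 1e-9 or abs(rings[-1][2] - 1.0) > 1e-9:
            raise ColonyConfigError("ring layout must tile [0, 1]")
        for (_, _, out_a), (_, in_b, _) in zip(rings, rings[1:]):
            if abs(out_a - in_b) > 1e-9:
                raise ColonyConfigError("ring layout must tile [0, 1] without gaps or overlap")
        for fate, lo, hi in rings:
            if hi <= lo:
                raise ColonyConfigError(f"ring {fate!r} has non-positive width")
        pf = self.positive_fractions if self.positive_fractions is not None else DEFAULT_POSITIVE_FRACTIONS
        for key, frac in pf.items():
            if not 0.0 <= frac <= 1.0:
                raise ColonyConfigError(f"positive fraction {key} outside [0, 1]")

    # -- lookups ------------------------------------------------------------
    def positive_fraction(self, fate: str, marker: str) -> float:
        pf = self.positive_fractions if self.positive_fractions is not None else DEFAULT_POSITIVE_FRACTIONS
        return float(pf.get((fate, marker), 0.0))

    def marker_params(self, fate: str, marker: str) -> tuple[float, float]:
        if self.marker_model is not None and (fate, marker) in self.marker_model:
            return self.marker_model[(fate, marker)]
        return _POS_LOG

    def background_params(self, marker: str) -> tuple[float, float]:
        if self.background_model is not None and marker in self.background_model:
            return self.background_model[marker]
        return _BG_LOG


@dataclass
class GroundTruth:
    """Per-nucleus ground truth of a synthetic colony.

    ``cells`` has one row per nucleus: position (um, relative to the image
    origin), radial position ``r_um`` from the colony center, fate label,
    layer index, ellipsoid radii, per-marker positivity flags ``pos_<m>``
    and true intensities ``int_<m>`` (plus ``int_DAPI``).  ``label_stack``
    is the (z, y, x) int32 ground-truth segmentation (0 = background).
    """

    spec: ColonySpec
    cells: pd.DataFrame
    label_stack: np.ndarray
    center_um: tuple[float, float]
    shape: tuple[int, int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.shape = self.label_stack.shape

    def __len__(self) -> int:
        return len(self.cells)

    def fate_fractions(self) -> pd.Series:
        if len(self.cells) == 0:
            return pd.Series(dtype=float)
        return self.cells["fate"].value_counts(normalize=True)

    def planted_positive_fraction(self, *markers: str) -> float:
        """Exact fraction of nuclei positive for all listed markers."""
        if len(self.cells) == 0:
            return float("nan")
        mask = np.ones(len(self.cells), dtype=bool)
        for m in markers:
            mask &= self.cells[f"pos_{m}"].to_numpy()
        return float(mask.mean())


# ---------------------------------------------------------------------------
# placement and sampling


def _hex_grid_in_disc(radius: float, spacing: float, rng, jitter: float) -> np.ndarray:
    """Jittered hexagonal lattice clipped to the disc: spatially uniform
    density (no edge bias) with guaranteed minimum separation."""
    rows = int(math.ceil(2 * radius / (spacing * math.sqrt(3) / 2))) + 2
    cols = int(math.ceil(2 * radius / spacing)) + 2
    pts = []
    phase = rng.uniform(0, spacing)  # random lattice offset
    phase_y = rng.uniform(0, spacing)
    for i in range(rows):
        y = -radius - spacing + i * spacing * math.sqrt(3) / 2 + phase_y
        x0 = -radius - spacing + (spacing / 2 if i % 2 else 0.0) + phase
        for j in range(cols):
            x = x0 + j * spacing
            if x * x + y * y <= radius * radius:
                pts.append((x, y))
    pts = np.asarray(pts, float)
    if len(pts) and jitter > 0:
        pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
        keep = (pts**2).sum(axis=1) <= radius**2
        pts = pts[keep]
    return pts


def _place_nuclei(spec: ColonySpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.cell_count()
    radius = spec.radius
    sep = spec.separation
    depth = spec.n_slices * spec.z_spacing

    # lattice spacing targeting ~15% surplus, then uniform thinning to n
    spacing = max(sep, math.sqrt(2 * math.pi * radius**2 / (math.sqrt(3) * n * 1.15)))
    jitter = max(0.0, (spacing - sep) / (2 * math.sqrt(2)))
    pts = _hex_grid_in_disc(radius, spacing, rng, jitter)
    shrink = 0
    while len(pts) < n and shrink < 8:
        spacing *= 0.95
        if spacing < sep:
            break
        jitter = max(0.0, (spacing - sep) / (2 * math.sqrt(2)))
        pts = _hex_grid_in_disc(radius, spacing, rng, jitter)
        shrink += 1
    if len(pts) < n:
        raise ColonyPlacementError(
            f"cannot place {n} nuclei with separation {sep:.1f} um in a "
            f"{spec.diameter:.0f} um colony; reduce density or min_separation"
        )
    sel = rng.choice(len(pts), size=n, replace=False)
    xs, ys = pts[sel, 0], pts[sel, 1]

    layers = np.zeros(n, dtype=int)
    if spec.multilayer_edge:
        in_edge = (radius - np.hypot(xs, ys)) < spec.multilayer_thickness
        # half of the edge-annulus cells sit in a second nuclear layer
        layers[in_edge & (rng.random(n) < 0.5)] = 1

    jit = spec.radius_jitter
    rx = spec.nucleus_radius * (1.0 + jit * rng.uniform(-1, 1, n))
    ry = spec.nucleus_radius * (1.0 + jit * rng.uniform(-1, 1, n))
    rz = spec.nucleus_rz * (1.0 + jit * rng.uniform(-1, 1, n))

    if spec.n_slices == 1:
        z0 = np.zeros(n)
    else:
        base = depth / 2.0 if not spec.multilayer_edge else depth * 0.3
        z0 = base + rng.normal(0.0, 0.8, n)
        z0 = np.where(layers == 1, z0 + 2.0 * spec.nucleus_rz + 1.0, z0)
        z0 = np.clip(z0, 0.0, depth - spec.z_spacing)

    r_um = np.hypot(xs, ys)
    frac = np.clip(r_um / radius, 0.0, 1.0)
    fate = np.empty(n, dtype=object)
    for name, lo, hi in spec.ring_layout:
        sel = (frac >= lo) & (frac < hi) if hi < 1.0 else (frac >= lo) & (frac <= hi)
        fate[sel] = name

    return pd.DataFrame(
        {
            "nucleus_id": np.arange(1, n + 1),
            "fate": fate,
            "x_um": xs,
            "y_um": ys,
            "z_um": z0,
            "r_um": r_um,
            "layer": layers,
            "rx_um": rx,
            "ry_um": ry,
            "rz_um": rz,
        }
    )


def _sample_positivity(spec: ColonySpec, cells: pd.DataFrame, rng: np.random.Generator) -> None:
    n = len(cells)
    markers = list(spec.markers)
    draws = {m: rng.random(n) for m in markers}
    coupled_child = {}
    for child, parent, mode in spec.couplings:
        if child in markers and parent in markers:
            coupled_child[child] = (parent, mode)
    fates = cells["fate"].to_numpy()
    pos: dict[str, np.ndarray] = {}

    def marginal(marker: str) -> np.ndarray:
        p = np.array([spec.positive_fraction(f, marker) for f in fates])
        return p

    # resolve parents first (couplings may not chain)
    order = [m for m in markers if m not in coupled_child] + [m for m in markers if m in coupled_child]
    for m in order:
        p = marginal(m)
        if m in coupled_child:
            parent, mode = coupled_child[m]
            in_coupled_fate = np.isin(fates, list(_COUPLED_FATES))
            if mode == "comonotone":
                base = (draws[m] < p)
                shared = (draws[parent] < p)
                pos[m] = np.where(in_coupled_fate, shared, base)
            elif mode == "subset":
                pos[m] = (draws[m] < p) & np.where(in_coupled_fate, pos[parent], True)
            else:
                raise ColonyConfigError(f"unknown coupling mode {mode!r}")
        else:
            pos[m] = draws[m] < p

    for m in markers:
        cells[f"pos_{m}"] = pos[m]


def _sample_intensities(spec: ColonySpec, cells: pd.DataFrame, rng: np.random.Generator) -> None:
    n = len(cells)
    fates = cells["fate"].to_numpy()
    mu_d, sd_d = _DAPI_LOG
    cells["int_DAPI"] = np.exp(rng.normal(mu_d, sd_d, n))
    for m in spec.markers:
        posm = cells[f"pos_{m}"].to_numpy()
        mu = np.empty(n)
        sd = np.empty(n)
        for i, f in enumerate(fates):
            mu[i], sd[i] = spec.marker_params(f, m) if posm[i] else spec.background_params(m)
        cells[f"int_{m}"] = np.exp(rng.normal(mu, sd))


# ---------------------------------------------------------------------------
# rendering


def _render(spec: ColonySpec, cells: pd.DataFrame, rng: np.random.Generator):
    px = spec.pixel_size
    size_px = int(math.ceil((spec.diameter + 2 * spec.margin) / px))
    h = w = size_px
    nz = spec.n_slices
    center = ((spec.diameter / 2 + spec.margin), (spec.diameter / 2 + spec.margin))

    labels = np.zeros((nz, h, w), dtype=np.int32)
    channels = spec.channels
    image = np.full((len(channels), nz, h, w), spec.background_level, dtype=np.float64)

    z_slices_um = np.arange(nz) * spec.z_spacing
    for row in cells.itertuples():
        cx = (row.x_um + center[0]) / px
        cy = (row.y_um + center[1]) / px
        rx_px = row.rx_um / px
        ry_px = row.ry_um / px
        values = [row.int_DAPI] + [getattr(row, f"int_{m}") for m in spec.markers]
        for zi, z_um in enumerate(z_slices_um):
            dz = (z_um - row.z_um) / row.rz_um
            if abs(dz) >= 1.0:
                continue
            scale = math.sqrt(1.0 - dz * dz)
            a, b = rx_px * scale, ry_px * scale
            if a < 0.7 or b < 0.7:
                continue
            r0 = max(int(math.floor(cy - b - 1)), 0)
            r1 = min(int(math.ceil(cy + b + 2)), h)
            c0 = max(int(math.floor(cx - a - 1)), 0)
            c1 = min(int(math.ceil(cx + a + 2)), w)
            if r0 >= r1 or c0 >= c1:
                continue
            yy, xx = np.mgrid[r0:r1, c0:c1]
            mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
            if not mask.any():
                continue
            sub = labels[zi, r0:r1, c0:c1]
            sub[mask] = row.nucleus_id
            for ci, val in enumerate(values):
                image[ci, zi, r0:r1, c0:c1][mask] = val

    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    return image, labels, center


def generate_colony(spec: ColonySpec) -> tuple[np.ndarray, GroundTruth]:
    """Generate one synthetic colony.

    Returns ``(image, truth)`` where ``image`` is a uint16 array of shape
    (n_channels, n_slices, height, width) with channel order
    ``spec.channels`` (DAPI first), and ``truth`` carries the per-nucleus
    table and ground-truth label stack.  Deterministic for a fixed
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.cell_count()
    if n == 0:
        px = spec.pixel_size
        size_px = int(math.ceil((spec.diameter + 2 * spec.margin) / px))
        labels = np.zeros((spec.n_slices, size_px, size_px), dtype=np.int32)
        image = np.full(
            (len(spec.channels), spec.n_slices, size_px, size_px),
            spec.background_level,
        )
        if spec.noise_sd > 0:
            image += rng.normal(0.0, spec.noise_sd, size=image.shape)
        image = np.clip(np.round(image), 0, 65535).astype(np.uint16)
        cells = pd.DataFrame(
            columns=["nucleus_id", "fate", "x_um", "y_um", "z_um", "r_um", "layer",
                     "rx_um", "ry_um", "rz_um"]
        )
        center = (spec.diameter / 2 + spec.margin, spec.diameter / 2 + spec.margin)
        return image, GroundTruth(spec, cells, labels, center)

    cells = _place_nuclei(spec, rng)
    _sample_positivity(spec, cells, rng)
    _sample_intensities(spec, cells, rng)
    image, labels, center = _render(spec, cells, rng)
    return image, GroundTruth(spec, cells, labels, center)


# ---------------------------------------------------------------------------
# segmentation degradation


def degrade_segmentation(
    truth: GroundTruth,
    miss_rate: float = 0.0,
    merge_rate: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Derive two imperfect per-slice 2D segmentations from the ground truth.

    The *primary* stack emulates an accurate segmenter that omits each true
    nucleus with probability ``miss_rate``; the *fallback* stack contains
    every nucleus but merges neighbouring pairs (assigns them one label)
    with probability ``merge_rate``.  Both are (z, y, x) int32 label stacks.
    """
    if not 0.0 <= miss_rate <= 1.0 or not 0.0 <= merge_rate <= 1.0:
        raise ValueError("miss_rate and merge_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = truth.label_stack
    ids = truth.cells["nucleus_id"].to_numpy() if len(truth) else np.array([], dtype=int)

    primary = labels.copy()
    if miss_rate > 0 and len(ids):
        dropped = ids[rng.random(len(ids)) < miss_rate]
        if len(dropped):
            primary[np.isin(primary, dropped)] = 0

    fallback = labels.copy()
    if merge_rate > 0 and len(ids) > 1:
        xy = truth.cells[["x_um", "y_um"]].to_numpy()
        from scipy.spatial import cKDTree

        tree = cKDTree(xy)
        mapping = {int(i): int(i) for i in ids}
        merged = set()
        for idx, nid in enumerate(ids):
            if nid in merged or rng.random() >= merge_rate:
                continue
            dists, neighbors = tree.query(xy[idx], k=2)
            j = int(neighbors[1])
            other = int(ids[j])
            if other in merged or other == int(nid):
                continue
            mapping[other] = mapping[int(nid)]
            merged.add(other)
            merged.add(int(nid))
        if merged:
            lut = np.arange(labels.max() + 1, dtype=np.int32)
            for src, dst in mapping.items():
                lut[src] = dst
            fallback = lut[fallback]

    return primary, fallback


# ---------------------------------------------------------------------------
# I/O


def write_colony(
    out_dir: str | Path,
    image: np.ndarray,
    truth: GroundTruth,
    prefix: str = "colony",
) -> dict[str, str]:
    """Write the image stack (multi-page TIFF, one page per z per channel),
    the ground-truth label stack (int32 TIFF), the per-nucleus table (CSV)
    and a sidecar JSON recording channel order and geometry."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = truth.spec
    paths = {
        "image": str(out / f"{prefix}_stack.tif"),
        "labels": str(out / f"{prefix}_labels.tif"),
        "cells": str(out / f"{prefix}_truth.csv"),
        "sidecar": str(out / f"{prefix}_meta.json"),
    }
    # pages ordered z-major, channel-minor
    pages = image.transpose(1, 0, 2, 3).reshape(-1, image.shape[2], image.shape[3])
    tifffile.imwrite(paths["image"], pages.astype(np.uint16), photometric="minisblack")
    tifffile.imwrite(paths["labels"], truth.label_stack.astype(np.int32), photometric="minisblack")
    truth.cells.to_csv(paths["cells"], index=False)
    meta = {
        "channels": spec.channels,
        "page_order": "z-major, channel-minor",
        "n_slices": spec.n_slices,
        "pixel_size_um": spec.pixel_size,
        "z_spacing_um": spec.z_spacing,
        "diameter_um": spec.diameter,
        "center_um": list(truth.center_um),
        "seed": spec.seed,
    }
    with open(paths["sidecar"], "w") as fh:
        json.dump(meta, fh, indent=2)
    return paths
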