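"""3D nucleus reconstruction from per-slice 2D segmentations.

The reconstruction has four stages:

1. ``fuse_segmentations`` combines two per-slice label stacks, giving
   preference to the primary (accurate) segmenter and recovering nuclei it
   missed from the fallback (complete but merge-prone) segmenter.
2. ``convex_decompose`` splits merged masks along the chord joining the two
   deepest mutually facing boundary concavities, recursing until every
   piece is sufficiently convex.
3. Adjacent z-slices are linked by a linear assignment problem (LAP) over
   the block cost matrix ``[[A, B], [C, A^T]]``: ``A(i, j)`` is the cost of
   linking mask i in slice n to mask j in slice n+1 — the smaller of the
   two mask areas divided by their overlap — computed only for each mask's
   k nearest neighbours in the other slice and only within a centroid
   distance cutoff ``dmax``; the diagonals of B and C carry the
   "alternative cost" 1/IoU of leaving a mask unlinked.
4. ``build_chains`` walks the per-pair links into chains of masks (one
   chain = one nucleus) and splits chains exceeding the maximum plausible
   z-extent at an interior local minimum of the mask area.

A pair of masks is linked only when doing so is cheaper than both taking
their alternative costs, which the block LAP guarantees globally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "SliceMask",
    "LinkParams",
    "CostMatrix",
    "Nucleus3D",
    "masks_from_labels",
    "fuse_segmentations",
    "convex_decompose",
    "link_cost",
    "build_cost_matrix",
    "solve_linking",
    "build_chains",
    "link_stack",
    "nuclei_table",
]


@dataclass
class SliceMask:
    """A single nucleus mask in one z-slice."""

    pixels: np.ndarray          # (k, 2) array of (row, col)
    slice_index: int
    label: int
    width: int                  # image width, for linearised overlap tests
    lin: np.ndarray = field(init=False, repr=False)
    area: int = field(init=False)
    centroid: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.pixels) == 0:
            raise ValueError("SliceMask requires a non-empty pixel set")
        self.area = int(len(self.pixels))
        self.centroid = (float(self.pixels[:, 0].mean()), float(self.pixels[:, 1].mean()))
        self.lin = np.sort(self.pixels[:, 0].astype(np.int64) * self.width + self.pixels[:, 1])

    def overlap(self, other: "SliceMask") -> int:
        return int(len(np.intersect1d(self.lin, other.lin, assume_unique=True)))


@dataclass
class LinkParams:
    """Parameters of the z-linking LAP.

    ``dmax``: centroid-distance cutoff in pixels (default one expected
    nuclear radius).  ``iou_min``: minimum overlap-to-area ratio for a link;
    its reciprocal is the alternative cost of staying unlinked.
    ``k_neighbors``: candidate links per mask (nearest neighbours in the
    adjacent slice, both directions).  ``max_slices``: maximum z-extent of a
    single nucleus, ceil(expected nuclear diameter / z spacing).
    """

    dmax: float = 8.0
    iou_min: float = 0.25
    k_neighbors: int = 3
    max_slices: int = 4

    def __post_init__(self) -> None:
        if self.dmax <= 0:
            raise ValueError("dmax must be > 0")
        if not 0.0 < self.iou_min <= 1.0:
            raise ValueError("iou_min must lie in (0, 1]")
        if self.k_neighbors < 1 or self.max_slices < 1:
            raise ValueError("k_neighbors and max_slices must be >= 1")

    @property
    def alternative_cost(self) -> float:
        return 1.0 / self.iou_min

    @classmethod
    def from_geometry(
        cls, nucleus_diameter_um: float, z_spacing_um: float, pixel_size_um: float, **kw
    ) -> "LinkParams":
        return cls(
            dmax=0.5 * nucleus_diameter_um / pixel_size_um,
            max_slices=max(1, math.ceil(nucleus_diameter_um / z_spacing_um)),
            **kw,
        )


@dataclass
class CostMatrix:
    """Block LAP matrix ``[[A, B], [C, A^T]]`` with a finite sentinel
    standing in for infinity so standard solvers accept it."""

    matrix: np.ndarray
    n: int
    m: int
    alternative_cost: float
    sentinel: float

    @property
    def A(self) -> np.ndarray:
        return self.matrix[: self.n, : self.m]


@dataclass
class Nucleus3D:
    """A chain of per-slice masks reconstructed as one nucleus."""

    nucleus_id: int
    chain: list[SliceMask]
    pixel_size: float = 1.0
    z_spacing: float = 1.0

    def __post_init__(self) -> None:
        zs = [m.slice_index for m in self.chain]
        if zs != sorted(zs) or any(b - a != 1 for a, b in zip(zs, zs[1:])):
            raise ValueError("chain slice indices must be consecutive and increasing")

    @property
    def z_extent(self) -> int:
        return len(self.chain)

    @property
    def slice_indices(self) -> list[int]:
        return [m.slice_index for m in self.chain]

    @property
    def total_area(self) -> int:
        return sum(m.area for m in self.chain)

    @property
    def centroid_3d(self) -> tuple[float, float, float]:
        """Area-weighted centroid (x, y, z) in physical units (um)."""
        w = np.array([m.area for m in self.chain], dtype=float)
        rows = np.array([m.centroid[0] for m in self.chain])
        cols = np.array([m.centroid[1] for m in self.chain])
        zs = np.array([m.slice_index for m in self.chain], dtype=float)
        w /= w.sum()
        return (
            float((cols * w).sum() * self.pixel_size),
            float((rows * w).sum() * self.pixel_size),
            float((zs * w).sum() * self.z_spacing),
        )


# ---------------------------------------------------------------------------
# mask extraction and fusion


def masks_from_labels(label_image: np.ndarray, slice_index: int = 0) -> list[SliceMask]:
    """Extract SliceMask objects from a 2D integer label image."""
    from skimage.measure import regionprops

    h, w = label_image.shape
    out = []
    for rp in regionprops(label_image):
        out.append(SliceMask(pixels=rp.coords, slice_index=slice_index, label=int(rp.label), width=w))
    return out


def _solidity(mask: np.ndarray) -> float:
    from skimage.morphology import convex_hull_image

    area = int(mask.sum())
    if area == 0:
        return 1.0
    hull = convex_hull_image(mask)
    return area / int(hull.sum())


def convex_decompose(mask: np.ndarray, solidity_min: float = 0.9, _depth: int = 0) -> list[np.ndarray]:
    """Split a (possibly merged) binary mask into near-convex pieces.

    Recursively cuts along the chord joining the two deepest mutually
    facing boundary concavities (depth = distance of a boundary point to
    the convex hull) until every piece has solidity >= ``solidity_min`` or
    is indivisible.  The union of the returned boolean masks equals the
    input pixel set and the pieces are pairwise disjoint.
    """
    from skimage.draw import line as draw_line
    from skimage.measure import find_contours, label as cc_label
    from skimage.segmentation import watershed
    from scipy.spatial import ConvexHull

    mask = mask.astype(bool)
    if not mask.any():
        return []
    if _solidity(mask) >= solidity_min or _depth >= 6:
        if _depth >= 6:
            logger.warning("convex_decompose: recursion limit reached; returning concave mask")
        return [mask]

    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        return [mask]
    contour = max(contours, key=len)
    try:
        hull = ConvexHull(contour)
    except Exception:
        return [mask]
    hull_pts = contour[hull.vertices]

    # distance of every contour point to the hull polygon
    depths = np.full(len(contour), np.inf)
    for a, b in zip(hull_pts, np.roll(hull_pts, -1, axis=0)):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d = np.linalg.norm(contour - a, axis=1)
        else:
            t = np.clip((contour - a) @ ab / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.linalg.norm(contour - proj, axis=1)
        depths = np.minimum(depths, d)

    i1 = int(np.argmax(depths))
    if depths[i1] < 1.0:
        logger.warning("convex_decompose: concave mask with no usable concavity; returned as-is")
        return [mask]
    L = len(contour)
    idx = np.arange(L)
    arc = np.minimum(np.abs(idx - i1), L - np.abs(idx - i1))
    facing = arc > max(L // 6, 2)
    if not facing.any():
        return [mask]
    cand = np.where(facing)[0]
    i2 = int(cand[np.argmax(depths[cand])])
    if depths[i2] < 0.5:
        logger.warning("convex_decompose: no mutually facing concavity; returned as-is")
        return [mask]

    p1 = np.round(contour[i1]).astype(int)
    p2 = np.round(contour[i2]).astype(int)
    p1 = np.clip(p1, 0, np.array(mask.shape) - 1)
    p2 = np.clip(p2, 0, np.array(mask.shape) - 1)
    rr, cc = draw_line(p1[0], p1[1], p2[0], p2[1])
    cut = mask.copy()
    cut[rr, cc] = False
    comps = cc_label(cut, connectivity=1)
    n_comp = comps.max()
    if n_comp < 2:
        logger.warning("convex_decompose: cut did not separate the mask; returned as-is")
        return [mask]
    # two largest components seed a geodesic assignment of all mask pixels
    sizes = np.bincount(comps.ravel())[1:]
    order = np.argsort(sizes)[::-1] + 1
    markers = np.zeros_like(comps)
    markers[comps == order[0]] = 1
    markers[comps == order[1]] = 2
    filled = watershed(np.zeros_like(markers), markers=markers, mask=mask)
    parts = [filled == 1, filled == 2]
    if not all(p.any() for p in parts):
        return [mask]
    out: list[np.ndarray] = []
    for p in parts:
        out.extend(convex_decompose(p, solidity_min, _depth + 1))
    return out


def fuse_segmentations(
    primary: np.ndarray,
    fallback: np.ndarray,
    opening_radius: int = 1,
    min_area: int = 20,
    solidity_min: float = 0.9,
) -> np.ndarray:
    """Fuse two per-slice label stacks, giving preference to the primary.

    Per slice: every primary mask is kept unchanged; pixels of fallback
    masks not covered by any primary mask are binarised, cleaned by a
    morphological opening, connected components below ``min_area`` are
    discarded, and insufficiently convex components are split by
    ``convex_decompose``.  Accepts (z, y, x) stacks or single 2D slices.
    """
    from scipy.ndimage import binary_opening
    from skimage.measure import label as cc_label
    from skimage.morphology import disk

    if primary.shape != fallback.shape:
        raise ValueError(f"shape mismatch: {primary.shape} vs {fallback.shape}")
    squeeze = primary.ndim == 2
    p3 = primary[None] if squeeze else primary
    f3 = fallback[None] if squeeze else fallback

    fused = p3.astype(np.int32).copy()
    footprint = disk(opening_radius) if opening_radius > 0 else None
    for z in range(p3.shape[0]):
        extra = (f3[z] > 0) & (p3[z] == 0)
        if footprint is not None:
            extra = binary_opening(extra, structure=footprint)
        if not extra.any():
            continue
        comps = cc_label(extra, connectivity=1)
        next_label = int(fused[z].max()) + 1
        for lbl in range(1, comps.max() + 1):
            comp = comps == lbl
            if int(comp.sum()) < min_area:
                continue
            for piece in convex_decompose(comp, solidity_min):
                if int(piece.sum()) < min_area:
                    continue
                fused[z][piece] = next_label
                next_label += 1
    return fused[0] if squeeze else fused


# ---------------------------------------------------------------------------
# LAP construction and solution


def link_cost(a: SliceMask, b: SliceMask, params: LinkParams) -> float:
    """Cost of linking two masks in adjacent slices:
    min(|N_a|, |N_b|) / |N_a intersect N_b|.

    Returns ``inf`` when the centroid distance exceeds ``dmax`` or when the
    masks do not overlap (a non-overlapping pair must never out-compete the
    alternative cost).
    """
    d = math.hypot(a.centroid[0] - b.centroid[0], a.centroid[1] - b.centroid[1])
    if d > params.dmax:
        return math.inf
    ov = a.overlap(b)
    if ov == 0:
        return math.inf
    return min(a.area, b.area) / ov


def build_cost_matrix(
    slice_n: Sequence[SliceMask],
    slice_n1: Sequence[SliceMask],
    params: LinkParams,
) -> CostMatrix:
    """Assemble the block LAP matrix for one adjacent slice pair.

    ``A`` is populated only for candidate pairs — each mask's
    ``k_neighbors`` nearest neighbours (by centroid) in the other slice,
    taken in both directions — and only where the link cost is finite.
    All other entries, including the off-diagonals of B and C, hold a
    finite sentinel (1e6 x the largest finite cost).
    """
    n, m = len(slice_n), len(slice_n1)
    alt = params.alternative_cost

    candidates: set[tuple[int, int]] = set()
    if n and m:
        cen_n = np.array([s.centroid for s in slice_n])
        cen_m = np.array([s.centroid for s in slice_n1])
        k_f = min(params.k_neighbors, m)
        k_b = min(params.k_neighbors, n)
        tree_m = cKDTree(cen_m)
        tree_n = cKDTree(cen_n)
        _, nb_f = tree_m.query(cen_n, k=k_f)
        _, nb_b = tree_n.query(cen_m, k=k_b)
        nb_f = np.atleast_2d(nb_f.T).T if nb_f.ndim == 1 else nb_f
        nb_b = np.atleast_2d(nb_b.T).T if nb_b.ndim == 1 else nb_b
        for i in range(n):
            for j in np.atleast_1d(nb_f[i]):
                candidates.add((i, int(j)))
        for j in range(m):
            for i in np.atleast_1d(nb_b[j]):
                candidates.add((int(i), j))

    costs: dict[tuple[int, int], float] = {}
    max_finite = alt
    for i, j in candidates:
        c = link_cost(slice_n[i], slice_n1[j], params)
        if math.isfinite(c):
            costs[(i, j)] = c
            max_finite = max(max_finite, c)
    sentinel = 1e6 * max(max_finite, 1.0)

    size = n + m
    full = np.full((size, size), sentinel, dtype=float)
    for (i, j), c in costs.items():
        full[i, j] = c
        full[n + j, m + i] = c  # A^T block
    for i in range(n):
        full[i, m + i] = alt  # B diagonal
    for j in range(m):
        full[n + j, j] = alt  # C diagonal
    return CostMatrix(matrix=full, n=n, m=m, alternative_cost=alt, sentinel=sentinel)


def solve_linking(cost: CostMatrix) -> list[tuple[int, int]]:
    """Solve the block LAP and return the accepted links (i, j).

    A pair is reported only when the optimal assignment matched mask i of
    slice n to mask j of slice n+1 at sub-sentinel cost; assignments at
    sentinel cost are post-filtered to "unlinked".
    """
    if cost.matrix.size == 0:
        return []
    rows, cols = linear_sum_assignment(cost.matrix)
    links = []
    for r, c in zip(rows, cols):
        if r < cost.n and c < cost.m and cost.matrix[r, c] < 0.5 * cost.sentinel:
            links.append((int(r), int(c)))
    return sorted(links)


# ---------------------------------------------------------------------------
# chain assembly


def _split_chain(chain: list[SliceMask], max_slices: int) -> list[list[SliceMask]]:
    if len(chain) <= max_slices:
        return [chain]
    areas = [m.area for m in chain]
    interior = list(range(1, len(chain) - 1))
    if not interior:
        return [chain[:1], chain[1:]]
    minima = [i for i in interior if areas[i] <= areas[i - 1] and areas[i] <= areas[i + 1]]
    pool = minima if minima else interior
    k = min(pool, key=lambda i: (areas[i], i))
    # the minimum-area slice is assigned to the earlier (lower-z) chain
    return _split_chain(chain[: k + 1], max_slices) + _split_chain(chain[k + 1 :], max_slices)


def build_chains(
    links_per_pair: Sequence[Iterable[tuple[int, int]]],
    slice_masks: Sequence[Sequence[SliceMask]],
    params: LinkParams,
    pixel_size: float = 1.0,
    z_spacing: float = 1.0,
) -> list[Nucleus3D]:
    """Assemble per-pair link lists into Nucleus3D chains.

    ``links_per_pair[z]`` holds links between ``slice_masks[z]`` and
    ``slice_masks[z + 1]``.  Every input mask ends up in exactly one
    nucleus; chains longer than ``params.max_slices`` are recursively split
    at an interior local minimum of the mask area (deepest minimum first,
    lowest z on ties).
    """
    nz = len(slice_masks)
    succ: dict[tuple[int, int], tuple[int, int]] = {}
    has_pred: set[tuple[int, int]] = set()
    for z, links in enumerate(links_per_pair):
        for i, j in links:
            succ[(z, i)] = (z + 1, j)
            has_pred.add((z + 1, j))

    nuclei: list[Nucleus3D] = []
    next_id = 1
    for z in range(nz):
        for i in range(len(slice_masks[z])):
            if (z, i) in has_pred:
                continue
            chain = [slice_masks[z][i]]
            cur = (z, i)
            while cur in succ:
                cur = succ[cur]
                chain.append(slice_masks[cur[0]][cur[1]])
            for part in _split_chain(chain, params.max_slices):
                nuclei.append(
                    Nucleus3D(next_id, part, pixel_size=pixel_size, z_spacing=z_spacing)
                )
                next_id += 1
    return nuclei


def link_stack(
    label_stack: np.ndarray,
    params: LinkParams,
    pixel_size: float = 1.0,
    z_spacing: float = 1.0,
) -> list[Nucleus3D]:
    """Run the full z-linking on a (z, y, x) label stack."""
    nz = label_stack.shape[0]
    slice_masks = [masks_from_labels(label_stack[z], z) for z in range(nz)]
    links_per_pair = []
    for z in range(nz - 1):
        cost = build_cost_matrix(slice_masks[z], slice_masks[z + 1], params)
        links_per_pair.append(solve_linking(cost))
    return build_chains(links_per_pair, slice_masks, params, pixel_size, z_spacing)


def nuclei_table(nuclei: Sequence[Nucleus3D], colony_id: int = 0) -> "pd.DataFrame":
    """Summary table of reconstructed nuclei (coordinates in um)."""
    import pandas as pd

    rows = []
    for nuc in nuclei:
        x, y, z = nuc.centroid_3d
        rows.append(
            {
                "nucleus_id": nuc.nucleus_id,
                "colony_id": colony_id,
                "x_um": x,
                "y_um": y,
                "z_um": z,
                "z_extent": nuc.z_extent,
                "area_px": nuc.total_area,
            }
        )
    return pd.DataFrame(rows)
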