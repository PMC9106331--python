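"""Per-nucleus marker quantification.

For every reconstructed nucleus the value of a channel is the maximum over
its z-slices of the mean intensity within that slice's mask — the slice in
which the nucleus was most nearly in focus.  Values are then
log(1 + x)-transformed (natural log, the scRNA-seq convention) for gating
and visualisation; raw values are retained.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .linking import Nucleus3D

logger = logging.getLogger(__name__)

__all__ = ["fit_colony_center", "measure_nuclei", "transform_table", "CELL_TABLE_SCHEMA"]

CELL_TABLE_SCHEMA = """\
nucleus_id   integer, unique within a colony
colony_id    integer
x_um, y_um   nucleus centroid, um, image frame
z_um         area-weighted z centroid, um
z_extent     number of z-slices spanned
r_um         radial position, um from the colony center
<CH>_raw     max-over-z mean intensity of channel CH
<CH>_log     log(1 + raw)
<CH>_scaled  log(1 + raw) / log(1 + x_thresh)   (after rescaling)
"""


def fit_colony_center(xy: np.ndarray) -> tuple[float, float]:
    """Colony center fitted as the centroid of all nucleus centroids.

    A circle fit to the convex hull is available as an alternative for
    colonies with strongly asymmetric cell loss::

        fit_colony_center(xy_hull_method(xy))
    """
    if len(xy) == 0:
        raise ValueError("cannot fit a center to zero nuclei")
    return float(np.mean(xy[:, 0])), float(np.mean(xy[:, 1]))


def measure_nuclei(
    image: np.ndarray,
    nuclei: Sequence[Nucleus3D],
    channel_names: Sequence[str],
    center_um: tuple[float, float] | None = None,
    colony_id: int = 0,
) -> pd.DataFrame:
    """Measure per-nucleus, per-channel intensities and radial positions.

    ``image`` has shape (n_channels, n_slices, h, w); nuclei carry their own
    pixel size / z spacing.  Per channel, the nucleus value is the max over
    its slices of the mean intensity inside that slice's mask.  The radial
    position is the Euclidean distance of the (x, y) centroid to
    ``center_um`` (fitted as the centroid of centroids when not given).
    Nuclei with masks outside the image bounds are logged and skipped.
    """
    n_ch, nz, h, w = image.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length must match the image channel axis")
    flat = image.reshape(n_ch, nz, -1)

    rows = []
    centroids = []
    kept_nuclei = []
    for nuc in nuclei:
        ok = True
        for m in nuc.chain:
            if (
                m.slice_index < 0
                or m.slice_index >= nz
                or m.pixels[:, 0].max() >= h
                or m.pixels[:, 1].max() >= w
                or m.width != w
            ):
                logger.warning("nucleus %d outside image bounds; skipped", nuc.nucleus_id)
                ok = False
                break
        if not ok:
            continue
        kept_nuclei.append(nuc)
        centroids.append(nuc.centroid_3d)

    if not kept_nuclei:
        cols = ["nucleus_id", "colony_id", "x_um", "y_um", "z_um", "z_extent", "r_um"]
        cols += [f"{ch}_raw" for ch in channel_names]
        return pd.DataFrame(columns=cols)

    xy = np.array([(c[0], c[1]) for c in centroids])
    if center_um is None:
        center_um = fit_colony_center(xy)

    for nuc, (x, y, z) in zip(kept_nuclei, centroids):
        rec = {
            "nucleus_id": nuc.nucleus_id,
            "colony_id": colony_id,
            "x_um": x,
            "y_um": y,
            "z_um": z,
            "z_extent": nuc.z_extent,
            "r_um": float(np.hypot(x - center_um[0], y - center_um[1])),
        }
        for ci, ch in enumerate(channel_names):
            best = -np.inf
            for m in nuc.chain:
                mean_val = float(flat[ci, m.slice_index][m.lin].mean())
                best = max(best, mean_val)
            rec[f"{ch}_raw"] = best
        rows.append(rec)
    return pd.DataFrame(rows)


def transform_table(table: pd.DataFrame, channels: Sequence[str] | None = None) -> pd.DataFrame:
    """Add log(1 + x) columns for every measured channel; raw is retained."""
    out = table.copy()
    if channels is None:
        channels = [c[: -len("_raw")] for c in table.columns if c.endswith("_raw")]
    for ch in channels:
        raw = out[f"{ch}_raw"].to_numpy(dtype=float)
        if (raw < 0).any():
            raise ValueError(f"negative intensities in channel {ch!r}")
        out[f"{ch}_log"] = np.log1p(raw)
    return out
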