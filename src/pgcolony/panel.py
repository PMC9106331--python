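"""Qualitative regression panel for the fate-network model.

Nine properties of the simulated fate patterns that the model is required
to reproduce, mirroring the measured responses to Nodal/Activin/BMP
perturbations and colony-size changes:

a. WT: dominant-fate rings ordered edge -> center as Am, PGC, PS, Plu.
b. Nodal/Activin receptor inhibition from 0 h: no PGCs.
c. Inhibition from 24 h: PGC reduced relative to WT, but a nonzero
   PS ring remains.
d. BMP receptor inhibition at 24 h: PGCs lost (sustained BMP requirement).
e. High Activin for the full 42 h: PS-lineage output dominates the edge
   band (the SOX17+ FOXA2+ conversion), over both PGC and Am.
f. Nodal blocked 0-24 h then high Activin 24-42 h: PGC comparable to WT.
g. High Activin 0-24 h then receptor inhibition: PGC edge-band level at
   least 1.5x WT (the doubling manoeuvre).
h. 5x5 BMP x Activin dose grid (NodalKO): PGC edge-band readout maximal
   at an interior grid point; adding Activin decreases PGC at the lowest
   BMP dose but increases it at higher doses.
i. Colony-size series: the PGC-dominant share of colony area rises
   monotonically as the radius shrinks, maximal at the smallest.

``evaluate_panel`` returns {name: (passed, details)}.  Ablating the
PGC<->Am and PGC<->PS mutual repressions (``ModelParams.ablated()``) must
break at least one property — the simpler-model falsification.
"""

from __future__ import annotations

import numpy as np

from .fatemodel import (
    ModelParams,
    SignalParams,
    condition_panel,
    dominant_ring_order,
    edge_band_summary,
    simulate_fates,
)

__all__ = ["evaluate_panel", "PANEL_PROPERTIES"]

PANEL_PROPERTIES = (
    "wt_ring_order",
    "tgfbri0_no_pgc",
    "tgfbri24_reduced_pgc_with_ps_ring",
    "bmpri24_pgc_lost",
    "activin_42h_ps_dominates_edge",
    "activin_24_42_comparable_wt",
    "activin_0_24_boosts_pgc",
    "dose_grid_interior_max_and_sign_flip",
    "size_trend_monotone",
)


def _pgc_band(field) -> float:
    return edge_band_summary(field)["PGC"]


def evaluate_panel(
    model_params: ModelParams | None = None,
    signal_params: SignalParams | None = None,
) -> dict[str, tuple[bool, object]]:
    mp = model_params or ModelParams()
    sp = signal_params or SignalParams()
    panel = condition_panel()

    fields = {
        name: simulate_fates(panel[name], sp, mp)
        for name in (
            "WT",
            "BMPRi@24",
            "TGFBRi@0",
            "TGFBRi@24",
            "Activin100_0-42",
            "TGFBRi_0-24_then_Activin100",
            "Activin100_0-24_then_TGFBRi",
        )
    }
    wt = fields["WT"]
    wt_pgc = _pgc_band(wt)
    out: dict[str, tuple[bool, object]] = {}

    order = dominant_ring_order(wt)
    out["wt_ring_order"] = (order == ["Am", "PGC", "PS", "Plu"], order)

    v = float(fields["TGFBRi@0"].final[2].max())
    out["tgfbri0_no_pgc"] = (v < 0.05, v)

    c = fields["TGFBRi@24"]
    c_pgc, c_ps = _pgc_band(c), float(c.final[3].max())
    out["tgfbri24_reduced_pgc_with_ps_ring"] = (
        c_pgc < wt_pgc and c_ps > 0.1,
        {"pgc": c_pgc, "wt_pgc": wt_pgc, "ps_max": c_ps},
    )

    v = float(fields["BMPRi@24"].final[2].max())
    out["bmpri24_pgc_lost"] = (v < 0.05, v)

    eb = edge_band_summary(fields["Activin100_0-42"])
    out["activin_42h_ps_dominates_edge"] = (eb["PS"] > eb["PGC"] and eb["PS"] > eb["Am"], eb)

    f_pgc = _pgc_band(fields["TGFBRi_0-24_then_Activin100"])
    out["activin_24_42_comparable_wt"] = (
        0.5 * wt_pgc <= f_pgc <= 2.0 * wt_pgc,
        {"pgc": f_pgc, "wt_pgc": wt_pgc},
    )

    g_pgc = _pgc_band(fields["Activin100_0-24_then_TGFBRi"])
    out["activin_0_24_boosts_pgc"] = (g_pgc >= 1.5 * wt_pgc, {"pgc": g_pgc, "wt_pgc": wt_pgc})

    bdoses = (10.0, 25.0, 50.0, 100.0, 200.0)
    adoses = (1.0, 3.0, 10.0, 30.0, 100.0)
    grid = np.zeros((len(bdoses), len(adoses)))
    for i, b in enumerate(bdoses):
        for j, a in enumerate(adoses):
            grid[i, j] = _pgc_band(simulate_fates(panel[f"grid_B{b:g}_A{a:g}"], sp, mp))
    imax = np.unravel_index(int(np.argmax(grid)), grid.shape)
    interior = 0 < imax[0] < grid.shape[0] - 1 and 0 < imax[1] < grid.shape[1] - 1
    decreases_low_b = grid[0, 2] < grid[0, 1]   # A10 vs A3 at the lowest BMP
    increases_high_b = any(grid[i, 2] > grid[i, 1] for i in (2, 3, 4))
    out["dose_grid_interior_max_and_sign_flip"] = (
        interior and decreases_low_b and increases_high_b,
        {"argmax": tuple(int(k) for k in imax), "grid": grid.round(4).tolist()},
    )

    fracs = []
    for radius in (50.0, 75.0, 100.0, 150.0, 350.0):
        fld = simulate_fates(panel[f"WT_r{radius:g}"], sp, mp)
        dom = fld.dominant()
        w = np.maximum(fld.r_grid, 1e-9)
        fracs.append(float(w[dom == "PGC"].sum() / w.sum()))
    out["size_trend_monotone"] = (
        all(a > b for a, b in zip(fracs, fracs[1:])),
        fracs,
    )
    return out
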