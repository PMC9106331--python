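"""Cross-repressive BMP/Nodal cell-fate network on micropatterned colonies.

The model is cell-autonomous: all spatial structure enters through
prescribed signaling fields over (distance from colony edge, time).

Signaling inputs
----------------
* BMP: uniform activation for a short transient, then a stable exponential
  gradient from the colony edge with decay length ``lambda_B``.
* Endogenous Nodal: a region of high signaling that expands into the colony
  from the edge at constant velocity ``v`` starting around ``t0``; the
  front is a logistic of width ``front_width`` (sharp steps destabilise
  fixed-step integration and are biologically implausible).
* Exogenous Activin: an edge gradient ``exp(-d / lambda_A)`` scaled by a
  saturating dose->amplitude map, active during its scheduled intervals.
* A pathway inhibition (BMPRi or TGFBRi) forces the corresponding field to
  zero from its start time.

Fate network
------------
Four bounded activities in [0, 1] per cell: Plu (pluripotency), Am
(amnion-like, TFAP2C-high), PGC (TFAP2C+ SOX17+; SOX17 and PRDM1 treated
as interchangeable) and PS (primitive-streak lineage, subsuming
late-endoderm outcomes of sustained high Nodal).  Hill-type activation
(coefficient 4), saturating self-activation inside the input (switch-like
commitment with hysteresis), multiplicative pairwise repression between
the differentiated fates, and linear relaxation:

* Am is activated by BMP and requires it for maintenance.
* PS is activated by Nodal only (no direct BMP requirement).
* PGC is activated by the product of BMP and Nodal (both required), and its
  maintenance also requires sustained BMP.
* All differentiated fates repress each other and Plu; Plu relaxes to the
  product of the repressions (1 when nothing is induced).
* The PGC->PS repression is slightly leaky, so sustained high Nodal lets
  the PS programme slowly invade a committed PGC state — this is how
  long-duration high Activin converts the edge to SOX17+ FOXA2+ output
  while a 24 h pulse does not.

An alternative wiring where BMP feeds the PGC module through the
TFAP2C-response (instead of directly) is available via
``ModelParams.bmp_wiring = "via_tfap2c"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FATES",
    "SignalParams",
    "ModelParams",
    "Condition",
    "FateField",
    "signal_input",
    "simulate_fates",
    "phase_diagram",
    "edge_band_summary",
    "dominant_ring_order",
    "condition_panel",
]

FATES = ("Plu", "Am", "PGC", "PS")
_AM, _PGC, _PS = 1, 2, 3  # state indices (Plu = 0)


class ConditionError(ValueError):
    pass


@dataclass
class SignalParams:
    """Parameters of the prescribed BMP / Nodal-Activin signaling fields.

    Amplitudes are in arbitrary units normalised so that 50 ng/ml BMP4 at
    the colony edge gives B = 1.  Lengths in um, times in hours.
    """

    bmp_amp_max: float = 2.2          # saturating dose->amplitude ceiling
    bmp_half_dose: float = 60.0       # ng/ml at half-max
    lambda_B: float = 50.0            # BMP gradient decay length at the reference dose
    bmp_reference_dose: float = 50.0  # ng/ml at which lambda_B applies
    lambda_B_dose_exponent: float = 0.4  # inhibitor production sharpens the
    # gradient at higher doses: lambda = lambda_B * (ref/dose)^exponent
    bmp_uniform_duration: float = 2.0  # initial uniform-BMP transient
    N_amp: float = 1.0                # endogenous Nodal plateau amplitude
    v: float = 16.0                   # Nodal wavefront velocity, um/hr
    t0: float = 15.0                  # wavefront onset (half-max at the edge)
    front_width: float = 12.0         # logistic front width, um
    activin_amp_max: float = 3.2
    activin_half_dose: float = 30.0
    lambda_A: float = 60.0            # Activin response decay length
    T_end: float = 42.0               # simulation horizon, hr

    def __post_init__(self) -> None:
        for name in ("lambda_B", "v", "front_width", "lambda_A", "T_end"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def bmp_amplitude(self, dose: float) -> float:
        return self.bmp_amp_max * dose / (dose + self.bmp_half_dose) if dose > 0 else 0.0

    def activin_amplitude(self, dose: float) -> float:
        return self.activin_amp_max * dose / (dose + self.activin_half_dose) if dose > 0 else 0.0


@dataclass
class Condition:
    """One experimental condition: doses, schedules, knockouts, geometry."""

    name: str
    bmp_dose: float = 50.0
    activin_schedule: tuple[tuple[float, float, float], ...] = ()  # (start, end, dose ng/ml)
    endogenous_nodal: bool = True
    inhibitions: tuple[tuple[str, float], ...] = ()  # (pathway, start hr); pathway in {BMP, Nodal/Activin}
    radius: float = 350.0

    def validate(self, params: SignalParams) -> None:
        for start, end, dose in self.activin_schedule:
            if not (0 <= start < end <= params.T_end + 1e-9):
                raise ConditionError(f"{self.name}: Activin interval [{start}, {end}] outside [0, T_end]")
            if dose < 0:
                raise ConditionError(f"{self.name}: negative Activin dose")
        if self.bmp_dose < 0:
            raise ConditionError(f"{self.name}: negative BMP dose")
        for pathway, start in self.inhibitions:
            if pathway not in ("BMP", "Nodal/Activin"):
                raise ConditionError(f"{self.name}: unknown pathway {pathway!r}")
            if start < 0:
                raise ConditionError(f"{self.name}: negative inhibition start")


@dataclass
class ModelParams:
    """Fate-network parameters.  Gains are dimensionless; taus in hours.

    ``self_*`` feed back through a saturating sigmoid inside the input,
    which creates a committed (bistable) branch for each differentiated
    fate; ``rep`` / ``rho`` set the strength and completeness of the
    pairwise repressions.  ``rho_pgc_on_ps < 1`` is the leak that lets
    sustained high Nodal convert PGC to PS-lineage output.
    """

    hill_n: float = 4.0
    # Am: activated by BMP, maintenance requires BMP
    bmp_to_am: float = 1.2
    self_am: float = 2.0
    tau_am: float = 7.0
    # PGC: activated by (band-passed BMP)^2 x (band-passed integrated
    # Nodal), maintenance requires BMP.  The Nodal input is low-passed with
    # time constant tau_nodal_integration — the mesendoderm priming step
    # (EOMES accumulation) that must precede SOX17 induction — which delays
    # PGC commitment relative to the fast direct Nodal targets of PS.
    pgc_gain: float = 6.0
    pgc_bmp_K: float = 1.35            # BMP level of maximal PGC response
    pgc_nodal_K: float = 1.6          # integrated-Nodal level above which PGC input falls off
    tau_nodal_integration: float = 6.5
    tau_nodal_decay: float = 1.5      # rapid loss of priming once signaling stops
    self_pgc: float = 2.2
    tau_pgc: float = 3.0
    # PS: activated by Nodal only, slower (duration-encoding) dynamics
    nodal_to_ps: float = 1.2
    self_ps: float = 3.5
    self_sharpness_ps: float = 3.0
    tau_ps: float = 13.0
    # Plu readout
    tau_plu: float = 2.0
    # repression gains (how strongly each fate shuts down the others).
    # Partially committed Am (the TFAP2C-high competence zone) shuts PS out
    # strongly but admits PGC, which shares the TFAP2C programme.
    rep_am_on_pgc: float = 4.0
    rep_am_on_ps: float = 3.5
    rep_pgc: float = 2.5
    rep_ps: float = 3.0
    rep_on_plu: float = 2.0
    # completeness of the PGC->PS repression (< 1 = leaky)
    rho_pgc_on_ps: float = 0.74
    rep_pgc_on_ps: float = 2.4
    # self-activation sigmoid gain
    self_sharpness: float = 2.0
    bmp_wiring: str = "direct"  # or "via_tfap2c"
    # PGC <-> Am and PGC <-> PS mutual repression switch (ablation control)
    pgc_cross_repression: bool = True

    def ablated(self) -> "ModelParams":
        """The simpler model without PGC<->Am and PGC<->PS mutual repression."""
        return replace(self, pgc_cross_repression=False)


# ---------------------------------------------------------------------------
# signal fields


def signal_input(
    cond: Condition, params: SignalParams
) -> tuple[Callable[[np.ndarray, float], np.ndarray], Callable[[np.ndarray, float], np.ndarray]]:
    """Return callables ``B(d, t)`` and ``N(d, t)`` over edge distance (um)
    and time (hr).  ``d`` is an array of distances from the colony edge."""
    cond.validate(params)
    bmp_amp = params.bmp_amplitude(cond.bmp_dose)
    bmp_inhib = min((s for p, s in cond.inhibitions if p == "BMP"), default=math.inf)
    nodal_inhib = min((s for p, s in cond.inhibitions if p == "Nodal/Activin"), default=math.inf)
    # BMP-induced inhibitor production sharpens the gradient above the
    # reference dose; below it the baseline inhibitor sets the range
    if cond.bmp_dose > params.bmp_reference_dose:
        lam_b = params.lambda_B * (params.bmp_reference_dose / cond.bmp_dose) ** params.lambda_B_dose_exponent
    else:
        lam_b = params.lambda_B

    def B(d: np.ndarray, t: float) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if t >= bmp_inhib:
            return np.zeros_like(d)
        if t < params.bmp_uniform_duration:
            return np.full_like(d, bmp_amp)
        return bmp_amp * np.exp(-d / lam_b)

    def N(d: np.ndarray, t: float) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        out = np.zeros_like(d)
        if t >= nodal_inhib:
            return out
        if cond.endogenous_nodal:
            front = params.v * (t - params.t0)
            out = out + params.N_amp / (1.0 + np.exp(-(front - d) / params.front_width))
        for start, end, dose in cond.activin_schedule:
            if start <= t < end:
                out = out + params.activin_amplitude(dose) * np.exp(-d / params.lambda_A)
        return out

    return B, N


# ---------------------------------------------------------------------------
# dynamics


def _hill(u: np.ndarray, n: float) -> np.ndarray:
    u = np.maximum(u, 0.0)
    un = u**n
    return un / (1.0 + un)


def _rhs(state: np.ndarray, B: np.ndarray, N: np.ndarray, mp: ModelParams) -> np.ndarray:
    """d(state)/dt for state shape (5, n_cells): the four fate modules plus
    the integrated-Nodal priming variable."""
    plu, am, pgc, ps, n_int = state
    n = mp.hill_n
    f = lambda u: _hill(u, n)
    sb = mp.self_sharpness

    # cooperative: only committed (high) Am excludes the other programmes;
    # the partially induced TFAP2C-high state remains permissive
    rep_am_on_pgc = 1.0 - f(mp.rep_am_on_pgc * am**2)
    rep_am_on_ps = 1.0 - f(mp.rep_am_on_ps * am)
    rep_pgc = 1.0 - f(mp.rep_pgc * pgc)
    rep_ps = 1.0 - f(mp.rep_ps * ps)
    rep_pgc_on_ps = 1.0 - mp.rho_pgc_on_ps * f(mp.rep_pgc_on_ps * pgc)
    if not mp.pgc_cross_repression:
        one = np.ones_like(am)
        rep_am_on_pgc, rep_ps_on_pgc = one, one
        rep_pgc_on_am = one
        rep_pgc_on_ps = one
    else:
        rep_ps_on_pgc = rep_ps
        rep_pgc_on_am = rep_pgc

    # Am: BMP-gated induction and maintenance
    u_am = B * (mp.bmp_to_am + mp.self_am * f(sb * am))
    d_am = (f(u_am) * rep_pgc_on_am * rep_ps - am) / mp.tau_am

    # PGC: requires BMP AND Nodal; BMP also gates maintenance.  The BMP
    # input is band-passed (maximal response at B = pgc_bmp_K) and enters
    # squared — a cooperative requirement for the BMP-response programme —
    # so the PGC optimum sits at intermediate BMP.
    if mp.bmp_wiring == "via_tfap2c":
        b_raw = 2.0 * f(mp.bmp_to_am * B)
    else:
        b_raw = B
    b_eff = b_raw / (1.0 + (b_raw / mp.pgc_bmp_K) ** 4)
    n_eff = n_int / (1.0 + (n_int / mp.pgc_nodal_K) ** 4)
    u_pgc = mp.pgc_gain * b_eff**2 * (n_eff + mp.self_pgc * f(sb * pgc))
    d_pgc = (f(u_pgc) * rep_am_on_pgc * rep_ps_on_pgc - pgc) / mp.tau_pgc

    # integrated Nodal (mesendoderm priming upstream of SOX17): accumulates
    # slowly under signaling, lost rapidly once signaling stops
    tau_e = np.where(N >= n_int, mp.tau_nodal_integration, mp.tau_nodal_decay)
    d_n_int = (N - n_int) / tau_e

    # PS: Nodal only
    u_ps = mp.nodal_to_ps * N + mp.self_ps * f(mp.self_sharpness_ps * ps)
    d_ps = (f(u_ps) * rep_am_on_ps * rep_pgc_on_ps - ps) / mp.tau_ps

    # Plu: relaxes to the product of repressions
    target = (
        (1.0 - f(mp.rep_on_plu * am))
        * (1.0 - f(mp.rep_on_plu * pgc))
        * (1.0 - f(mp.rep_on_plu * ps))
    )
    d_plu = (target - plu) / mp.tau_plu

    return np.stack([d_plu, d_am, d_pgc, d_ps, d_n_int])


def _integrate(
    state: np.ndarray,
    drive: Callable[[float], tuple[np.ndarray, np.ndarray]],
    mp: ModelParams,
    t_start: float,
    t_end: float,
    dt: float,
    record_times: Sequence[float] | None = None,
):
    """Fixed-step RK4 (deterministic, bit-identical across runs)."""
    records = []
    rec_iter = iter(sorted(record_times)) if record_times is not None else None
    next_rec = next(rec_iter, None) if rec_iter else None
    t = t_start
    n_steps = int(round((t_end - t_start) / dt))
    for step in range(n_steps):
        if next_rec is not None and t >= next_rec - 1e-9:
            records.append((t, state.copy()))
            next_rec = next(rec_iter, None)
        B1, N1 = drive(t)
        k1 = _rhs(state, B1, N1, mp)
        Bh, Nh = drive(t + dt / 2)
        k2 = _rhs(state + dt / 2 * k1, Bh, Nh, mp)
        k3 = _rhs(state + dt / 2 * k2, Bh, Nh, mp)
        B2, N2 = drive(t + dt)
        k4 = _rhs(state + dt * k3, B2, N2, mp)
        state = state + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        state[:4] = np.clip(state[:4], 0.0, 1.0)   # fate activities are bounded
        state[4:] = np.clip(state[4:], 0.0, None)  # integrated signal is not
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(
                f"non-finite state at t={t + dt:.3f} h; min={np.nanmin(state)}, max={np.nanmax(state)}"
            )
        t = t_start + (step + 1) * dt
    if next_rec is not None:
        records.append((t, state.copy()))
    return state, records


@dataclass
class FateField:
    """Fate levels over (radius, time) for one condition."""

    condition: Condition
    r_grid: np.ndarray              # um from colony center
    t_grid: np.ndarray              # recorded times, hr
    levels: np.ndarray              # (4, n_t, n_r), FATES order
    radius: float

    @property
    def final(self) -> np.ndarray:
        """(4, n_r) levels at the last recorded time."""
        return self.levels[:, -1, :]

    def dominant(self, t_index: int = -1) -> np.ndarray:
        """Dominant-fate label per radius; Plu wins ties (including the
        all-low state)."""
        lv = self.levels[:, t_index, :]
        best = np.argmax(lv, axis=0)
        top = lv[best, np.arange(lv.shape[1])]
        best = np.where(np.isclose(lv[0], top), 0, best)
        return np.array([FATES[i] for i in best], dtype=object)


def simulate_fates(
    cond: Condition,
    signal_params: SignalParams | None = None,
    model_params: ModelParams | None = None,
    dr: float = 2.0,
    dt: float = 0.05,
    record_every: float = 2.0,
) -> FateField:
    """Integrate the fate network at every radius of one colony.

    Cells are independent (cell-autonomous); the radial grid spans
    [0, radius] with spacing ``dr``.  Initial state: Plu = 1, others 0.
    Deterministic for fixed integrator settings.
    """
    sp = signal_params or SignalParams()
    mp = model_params or ModelParams()
    cond.validate(sp)
    # grid anchored at the colony edge so that cells at equal edge distance
    # see identical inputs regardless of colony radius
    d_grid = np.arange(0.0, cond.radius + dr / 2, dr)
    r = (cond.radius - d_grid)[::-1]
    d_edge = cond.radius - r
    Bf, Nf = signal_input(cond, sp)
    drive = lambda t: (Bf(d_edge, t), Nf(d_edge, t))

    state = np.zeros((5, len(r)))
    state[0] = 1.0
    rec_times = list(np.arange(0.0, sp.T_end + 1e-9, record_every))
    if rec_times[-1] < sp.T_end:
        rec_times.append(sp.T_end)
    state, records = _integrate(state, drive, mp, 0.0, sp.T_end, dt, rec_times)
    records.append((sp.T_end, state.copy()))
    # deduplicate recorded times
    seen = {}
    for t, s in records:
        seen[round(t, 6)] = s
    t_grid = np.array(sorted(seen))
    levels = np.stack([seen[t][:4] for t in sorted(seen)], axis=1)
    return FateField(cond, r, t_grid, levels, cond.radius)


def phase_diagram(
    B_grid: np.ndarray,
    N_grid: np.ndarray,
    model_params: ModelParams | None = None,
    dt: float = 0.1,
    t_max: float = 500.0,
    tol: float = 1e-6,
    check_every: float = 10.0,
) -> np.ndarray:
    """Dominant steady-state fate for constant, spatially uniform inputs.

    Integrates from the pluripotent state until max |dX/dt| < ``tol`` per
    hour or ``t_max``; returns an (len(B_grid), len(N_grid)) array of fate
    labels.
    """
    mp = model_params or ModelParams()
    BB, NN = np.meshgrid(np.asarray(B_grid, float), np.asarray(N_grid, float), indexing="ij")
    Bflat, Nflat = BB.ravel(), NN.ravel()
    state = np.zeros((5, len(Bflat)))
    state[0] = 1.0
    drive = lambda t: (Bflat, Nflat)
    t = 0.0
    while t < t_max:
        t_next = min(t + check_every, t_max)
        state, _ = _integrate(state, drive, mp, t, t_next, dt)
        rate = np.abs(_rhs(state, Bflat, Nflat, mp)).max()
        t = t_next
        if rate < tol:
            break
    fates = state[:4]
    best = np.argmax(fates, axis=0)
    top = fates[best, np.arange(fates.shape[1])]
    best = np.where(np.isclose(fates[0], top), 0, best)
    labels = np.array([FATES[i] for i in best], dtype=object)
    return labels.reshape(BB.shape)


def edge_band_summary(field: FateField, band_width: float = 100.0) -> dict[str, float]:
    """Area-weighted mean fate levels within ``band_width`` um of the colony
    edge at the final time (mean expression in the edge band is the
    readout compared across conditions instead of % PGCs, since the model
    does not simulate individual cells)."""
    if not 0 < band_width <= field.radius + 1e-9:
        raise ValueError("band width must lie in (0, colony radius]")
    r = field.r_grid
    sel = r >= field.radius - band_width
    w = np.maximum(r[sel], 1e-9)  # annulus area weight ~ r dr
    lv = field.final[:, sel]
    means = (lv * w).sum(axis=1) / w.sum()
    return {fate: float(m) for fate, m in zip(FATES, means)}


def dominant_ring_order(field: FateField, min_run: int = 2) -> list[str]:
    """Collapsed sequence of dominant fates from the colony edge inward,
    ignoring runs shorter than ``min_run`` grid points."""
    dom = field.dominant()[::-1]  # edge -> center
    order: list[str] = []
    run_label, run_len = None, 0
    for lab in dom:
        if lab == run_label:
            run_len += 1
        else:
            if run_label is not None and run_len >= min_run and (not order or order[-1] != run_label):
                order.append(run_label)
            run_label, run_len = lab, 1
    if run_label is not None and run_len >= min_run and (not order or order[-1] != run_label):
        order.append(run_label)
    return order


# ---------------------------------------------------------------------------
# the canonical condition panel


def condition_panel(
    dose_grid_bmp: Sequence[float] = (10.0, 25.0, 50.0, 100.0, 200.0),
    dose_grid_activin: Sequence[float] = (1.0, 3.0, 10.0, 30.0, 100.0),
    small_radii: Sequence[float] = (50.0, 75.0, 100.0, 150.0),
) -> dict[str, Condition]:
    """The shipped named condition panel.

    Includes the signaling perturbations (receptor inhibitions, Nodal
    knockout, Activin timing/duration variants), a 5x5 BMP x Activin dose
    grid in the NodalKO background, and the colony-size series.
    """
    T = 42.0
    panel: dict[str, Condition] = {}

    def add(c: Condition) -> None:
        panel[c.name] = c

    add(Condition("WT"))
    add(Condition("BMPRi@24", inhibitions=(("BMP", 24.0),)))
    add(Condition("TGFBRi@0", inhibitions=(("Nodal/Activin", 0.0),)))
    add(Condition("TGFBRi@24", inhibitions=(("Nodal/Activin", 24.0),)))
    add(Condition("NodalKO", endogenous_nodal=False))
    for dose in (1.0, 3.0, 10.0, 30.0, 100.0):
        add(
            Condition(
                f"NodalKO+A{dose:g}",
                endogenous_nodal=False,
                activin_schedule=((0.0, T, dose),),
            )
        )
    add(
        Condition(
            "Activin100_0-42",
            endogenous_nodal=False,
            activin_schedule=((0.0, T, 100.0),),
        )
    )
    add(
        Condition(
            "TGFBRi_0-24_then_Activin100",
            endogenous_nodal=False,
            activin_schedule=((24.0, T, 100.0),),
        )
    )
    add(
        Condition(
            "Activin100_0-24_then_TGFBRi",
            endogenous_nodal=False,
            activin_schedule=((0.0, 24.0, 100.0),),
            inhibitions=(("Nodal/Activin", 24.0),),
        )
    )
    for b in dose_grid_bmp:
        for a in dose_grid_activin:
            add(
                Condition(
                    f"grid_B{b:g}_A{a:g}",
                    bmp_dose=b,
                    endogenous_nodal=False,
                    activin_schedule=((0.0, T, a),),
                )
            )
    for radius in (*small_radii, 350.0):
        add(Condition(f"WT_r{radius:g}", radius=radius))
    return panel
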