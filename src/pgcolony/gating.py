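"""Marker positivity gating by per-gene Gaussian-mixture thresholds.

For each marker a 1D Gaussian mixture is fitted to the log(1 + x)
transformed intensities; the number of components is selected by BIC and
positive cells are those belonging to the highest-mean component.  The
scalar threshold reported for a marker is the point between the top two
component means where the posterior membership of the top component crosses
0.5 — consistent with membership gating and deterministic.  Tables are then
rescaled so that the transformed threshold equals exactly 1, which makes
positivity equivalent to a scaled value above 1 in every scatterplot.

Thresholds occasionally require manual fine-tuning on real data; the
``manual_override`` hook applies an explicit raw-intensity threshold and is
always recorded in the output provenance, never silent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

__all__ = [
    "GatingError",
    "Threshold",
    "GateDefinition",
    "DEFAULT_GATES",
    "fit_threshold",
    "fit_thresholds",
    "rescale_to_threshold",
    "gate_populations",
    "population_fractions",
    "save_thresholds",
    "load_thresholds",
]


class GatingError(ValueError):
    pass


@dataclass
class Threshold:
    """Positivity threshold for one marker.

    ``boundary_log`` is the threshold on the log(1 + x) scale;
    ``x_thresh = exp(boundary_log) - 1`` is the raw-intensity threshold.
    ``boundary_log`` is ``None`` when BIC selected a single component
    (no positive population).
    """

    marker: str
    boundary_log: float | None
    n_components: int
    bic: dict[int, float] = field(default_factory=dict)
    means: tuple[float, ...] = ()
    weights: tuple[float, ...] = ()
    manual_override: float | None = None
    override_note: str = ""

    @property
    def x_thresh(self) -> float | None:
        if self.manual_override is not None:
            return self.manual_override
        if self.boundary_log is None:
            return None
        return float(np.expm1(self.boundary_log))

    @property
    def effective_boundary_log(self) -> float | None:
        if self.manual_override is not None:
            return float(np.log1p(self.manual_override))
        return self.boundary_log

    def classify(self, values_log: np.ndarray) -> np.ndarray:
        b = self.effective_boundary_log
        if b is None:
            return np.zeros(len(values_log), dtype=bool)
        return np.asarray(values_log) > b


@dataclass
class GateDefinition:
    """A named cell population defined by required-positive and
    required-negative markers (sets must be disjoint)."""

    name: str
    positive: tuple[str, ...]
    negative: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.positive) & set(self.negative):
            raise GatingError(f"gate {self.name!r}: positive/negative marker sets overlap")


#: Canonical population definitions.  PGCLC_strict (PRDM1+ TFAP2C+) is the
#: conservative estimate; PGCLC_broad (SOX17+ TFAP2C+) the slightly higher
#: one.  Definitions referencing unmeasured markers are dropped by
#: ``gate_populations`` only when ``strict=False``.
DEFAULT_GATES: tuple[GateDefinition, ...] = (
    GateDefinition("PGCLC_strict", ("PRDM1", "TFAP2C")),
    GateDefinition("PGCLC_broad", ("SOX17", "TFAP2C")),
    GateDefinition("Endoderm", ("SOX17", "FOXA2"), ("TFAP2C",)),
    GateDefinition("AmLC", ("ISL1",)),
    GateDefinition("AmLC_proxy", ("TFAP2C",), ("SOX17",)),
    GateDefinition("PS_like", ("TBXT",)),
    GateDefinition("PS_like_eomes", ("EOMES",), ("ISL1",)),
)


def fit_threshold(
    values: np.ndarray,
    marker: str = "",
    k_max: int = 4,
    seed: int = 0,
    n_init: int = 10,
) -> Threshold:
    """Fit a 1D Gaussian mixture to transformed intensities of one marker.

    Mixtures with K = 1..k_max components are fitted (10 seeded
    initialisations each, best likelihood kept) and K* chosen by minimum
    BIC.  Positives belong to the highest-mean component; the scalar
    boundary is where its posterior membership crosses 0.5 between the top
    two means.  K* = 1 means no positive population.
    """
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 50:
        raise GatingError(f"need >= 50 values to fit a threshold, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise GatingError("values must be finite")
    if np.std(x) == 0:
        raise GatingError("degenerate zero-variance data")

    X = x[:, None]
    bics: dict[int, float] = {}
    models: dict[int, GaussianMixture] = {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=n_init, random_state=seed
        )
        gm.fit(X)
        bics[k] = float(gm.bic(X))
        models[k] = gm
    k_star = min(bics, key=bics.get)
    gm = models[k_star]
    means = gm.means_.ravel()
    order = np.argsort(means)
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()

    if k_star == 1:
        return Threshold(marker, None, 1, bics, tuple(means), tuple(weights))

    top = order[-1]
    second = order[-2]

    def post_top(t: float) -> float:
        comp = weights * norm.pdf(t, means, sds)
        s = comp.sum()
        return comp[top] / s if s > 0 else 0.0

    lo, hi = float(means[second]), float(means[top])
    f_lo, f_hi = post_top(lo) - 0.5, post_top(hi) - 0.5
    if f_lo * f_hi < 0:
        boundary = float(brentq(lambda t: post_top(t) - 0.5, lo, hi, xtol=1e-10))
    else:
        # posterior does not cross 0.5 between the means (e.g. a dominant
        # top component); fall back to the midpoint
        boundary = 0.5 * (lo + hi)
    return Threshold(
        marker,
        boundary,
        int(k_star),
        bics,
        tuple(float(m) for m in means[order]),
        tuple(float(w) for w in weights[order]),
    )


def fit_thresholds(
    table: pd.DataFrame,
    markers: Sequence[str],
    k_max: int = 4,
    seed: int = 0,
    overrides: Mapping[str, float] | None = None,
) -> dict[str, Threshold]:
    """Fit thresholds for several markers from a cell table (``<m>_log``)."""
    out = {}
    for m in markers:
        th = fit_threshold(table[f"{m}_log"].to_numpy(), marker=m, k_max=k_max, seed=seed)
        if overrides and m in overrides:
            th.manual_override = float(overrides[m])
            th.override_note = "manual raw-intensity override supplied in config"
        out[m] = th
    return out


def rescale_to_threshold(
    table: pd.DataFrame, thresholds: Mapping[str, Threshold]
) -> pd.DataFrame:
    """Rescale transformed values so log(1 + x_thresh) = 1 per channel.

    Adds ``<m>_scaled = <m>_log / log(1 + x_thresh)``; positivity becomes
    ``scaled > 1``.  Rank order is preserved, and the positive set is
    identical before and after rescaling.
    """
    out = table.copy()
    for m, th in thresholds.items():
        b = th.effective_boundary_log
        if b is None or b <= 0:
            raise GatingError(f"no finite positive-population threshold for marker {m!r}")
        out[f"{m}_scaled"] = out[f"{m}_log"].to_numpy(dtype=float) / b
    return out


def gate_populations(
    table: pd.DataFrame,
    thresholds: Mapping[str, Threshold],
    definitions: Sequence[GateDefinition] | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Apply positivity thresholds and named population gates.

    Adds per-marker boolean columns ``<m>_pos``, per-gate boolean columns
    ``gate_<name>`` and a ``population`` label (first matching definition,
    else "other").  With ``strict=True`` an unknown marker in a definition
    raises; with ``strict=False`` such definitions are dropped, which lets
    the shipped default panel adapt to the measured channel set.
    """
    out = table.copy()
    measured = set(thresholds)
    for m, th in thresholds.items():
        out[f"{m}_pos"] = th.classify(out[f"{m}_log"].to_numpy(dtype=float))

    if definitions is None:
        definitions = DEFAULT_GATES
        strict = False
    applied: list[GateDefinition] = []
    for d in definitions:
        missing = (set(d.positive) | set(d.negative)) - measured
        if missing:
            if strict:
                raise GatingError(f"gate {d.name!r} references unmeasured markers {sorted(missing)}")
            continue
        applied.append(d)
        col = np.ones(len(out), dtype=bool)
        for m in d.positive:
            col &= out[f"{m}_pos"].to_numpy()
        for m in d.negative:
            col &= ~out[f"{m}_pos"].to_numpy()
        out[f"gate_{d.name}"] = col

    label = np.full(len(out), "other", dtype=object)
    for d in reversed(applied):
        label[out[f"gate_{d.name}"].to_numpy()] = d.name
    out["population"] = label
    return out


def population_fractions(
    gated: pd.DataFrame,
    populations: Sequence[str] | None = None,
    group_by: str = "colony_id",
) -> pd.DataFrame:
    """Per-population fractions: pooled, per-colony mean, and SD across
    colonies."""
    if len(gated) == 0:
        raise GatingError("empty table")
    if populations is None:
        populations = [c[len("gate_") :] for c in gated.columns if c.startswith("gate_")]
    rows = []
    groups = list(gated.groupby(group_by))
    for pop in populations:
        col = gated[f"gate_{pop}"].to_numpy(dtype=bool)
        per_colony = np.array([g[f"gate_{pop}"].mean() for _, g in groups], dtype=float)
        rows.append(
            {
                "population": pop,
                "n_colonies": len(groups),
                "fraction_pooled": float(col.mean()),
                "fraction_mean": float(per_colony.mean()),
                "fraction_sd": float(per_colony.std(ddof=1)) if len(groups) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence


def save_thresholds(thresholds: Mapping[str, Threshold], path: str | Path) -> None:
    payload = {}
    for m, th in thresholds.items():
        payload[m] = {
            "marker": th.marker,
            "x_thresh": th.x_thresh,
            "boundary_log": th.boundary_log,
            "n_components": th.n_components,
            "bic": {str(k): v for k, v in th.bic.items()},
            "means": list(th.means),
            "weights": list(th.weights),
            "manual_override": th.manual_override,
            "override_note": th.override_note,
        }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_thresholds(path: str | Path) -> dict[str, Threshold]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for m, d in payload.items():
        out[m] = Threshold(
            marker=d["marker"],
            boundary_log=d["boundary_log"],
            n_components=d["n_components"],
            bic={int(k): v for k, v in d["bic"].items()},
            means=tuple(d["means"]),
            weights=tuple(d["weights"]),
            manual_override=d["manual_override"],
            override_note=d.get("override_note", ""),
        )
    return out
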