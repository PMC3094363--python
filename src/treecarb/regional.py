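"""Regional assessment: envelopes x inventory, uncertainty metrics, experiments.

Scaling is by per-tree expansion factors: each inventoried tree record
represents ``expansion_factor`` trees in the population, so a regional
bound is the expansion-weighted sum of the envelope bound at each tree's
1-cm DBH class, reported in Tg C (1 Tg = 1e9 kg).

The uncertainty metric throughout is *half the range as a percent of the
midpoint*::

    uncertainty% = 100 * ((hi - lo) / 2) / ((hi + lo) / 2)

Also implemented here are the auxiliary analyses that probe where
model-selection uncertainty comes from and how it could be reduced:
envelope subdivision, developmental-range-distance categories, a
delta-method DBH measurement-error estimate, single-source point
estimates, and the local-vs-standard equation-form agreement table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import AllometricEquation, dbh_derivative, evaluate
from .envelopes import Envelope, point_envelope, UNITS_CARBON
from .heights import HeightParams, predict_height
from .roadmap import POSITIVE, Roadmap, total_tree_envelope

__all__ = [
    "KG_PER_TG",
    "RegionalEstimate",
    "SubdivisionResult",
    "uncertainty_percent",
    "round_half_away",
    "assign_dbh_class",
    "apply_envelope",
    "regional_estimate",
    "species_shares",
    "subdivision_experiment",
    "dev_range_distance_experiment",
    "dbh_measurement_error",
    "single_source_estimate",
    "form_agreement",
]

KG_PER_TG = 1.0e9

INVENTORY_COLUMNS = ["species", "dbh_cm", "expansion_factor"]


def uncertainty_percent(lo: float, hi: float) -> float:
    """Half the [lo, hi] range as a percent of its midpoint."""
    lo, hi = float(lo), float(hi)
    if lo > hi:
        raise ValueError(f"lo > hi: ({lo}, {hi})")
    mid = (lo + hi) / 2.0
    if mid <= 0:
        raise ValueError(f"midpoint must be positive, got {mid}")
    return 100.0 * (hi - lo) / 2.0 / mid


def round_half_away(x: float) -> int:
    """Round to integer, halves away from zero (presentation convention)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def assign_dbh_class(dbh) -> np.ndarray:
    """Map measured DBH (cm) to its 1-cm class label (nearest integer)."""
    return np.rint(np.asarray(dbh, dtype=float))


def _check_inventory(inventory: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in INVENTORY_COLUMNS if c not in inventory.columns]
    if missing:
        raise ValueError(f"inventory lacks columns {missing}")
    if len(inventory) and (inventory["dbh_cm"] <= 0).any():
        raise ValueError("inventory DBH must be positive")
    if len(inventory) and (inventory["expansion_factor"] <= 0).any():
        raise ValueError("expansion factors must be positive")
    return inventory


def apply_envelope(
    inventory: pd.DataFrame, envelopes: Mapping[str, Envelope]
) -> pd.DataFrame:
    """Expansion-weighted per-species carbon bounds, in Tg C.

    Every tree's DBH class must be defined in its species envelope;
    otherwise the offending (species, class) pairs are listed in the
    error — under approach 2 such gaps are real and the caller must
    either restrict the inventory or fill gaps from another approach.
    """
    _check_inventory(inventory)
    unknown = sorted(set(inventory["species"]) - set(envelopes))
    if unknown:
        raise KeyError(f"no envelope for species {unknown}")
    rows = []
    offenders: list[tuple[str, float]] = []
    for sp, grp in inventory.groupby("species", sort=True):
        env = envelopes[sp]
        if env.units != UNITS_CARBON:
            raise ValueError(f"envelope for {sp} is in {env.units!r}, expected kg C")
        classes = assign_dbh_class(grp["dbh_cm"].to_numpy())
        idx = np.searchsorted(env.grid, classes)
        ok = (idx < env.grid.size) & (env.grid[np.minimum(idx, env.grid.size - 1)] == classes)
        ok &= np.where(ok, env.defined[np.minimum(idx, env.grid.size - 1)], False)
        if not ok.all():
            offenders += [(sp, c) for c in sorted(set(classes[~ok]))]
            continue
        e = grp["expansion_factor"].to_numpy(dtype=float)
        rows.append(
            {
                "species": sp,
                "min_tg": float(np.sum(e * env.lower[idx])) / KG_PER_TG,
                "max_tg": float(np.sum(e * env.upper[idx])) / KG_PER_TG,
            }
        )
    if offenders:
        raise ValueError(
            "envelope undefined at inventory classes: "
            + ", ".join(f"{sp}@{int(c)}cm" for sp, c in offenders)
        )
    if not rows:
        return pd.DataFrame(columns=["min_tg", "max_tg"], dtype=float)
    return pd.DataFrame(rows).set_index("species")


def species_shares(bounds) -> pd.DataFrame:
    """Per-species shares of total uncertainty and of the midpoint estimate.

    ``uncertainty_share_pct`` = species half-width / sum of half-widths;
    ``midpoint_share_pct`` = species midpoint / sum of midpoints.  Each
    column sums to 100 up to rounding.
    """
    df = _bounds_frame(bounds)
    half = (df["max_tg"] - df["min_tg"]) / 2.0
    mid = (df["max_tg"] + df["min_tg"]) / 2.0
    if len(df) == 0 or half.sum() <= 0:
        raise ValueError("shares undefined: no species or all intervals degenerate")
    return pd.DataFrame(
        {
            "uncertainty_share_pct": 100.0 * half / half.sum(),
            "midpoint_share_pct": 100.0 * mid / mid.sum(),
        }
    )


def _bounds_frame(bounds) -> pd.DataFrame:
    if isinstance(bounds, pd.DataFrame):
        if not {"min_tg", "max_tg"} <= set(bounds.columns):
            raise ValueError("bounds frame needs min_tg/max_tg columns")
        return bounds[["min_tg", "max_tg"]].astype(float)
    rows = {sp: {"min_tg": lo, "max_tg": hi} for sp, (lo, hi) in dict(bounds).items()}
    return pd.DataFrame.from_dict(rows, orient="index").astype(float)


@dataclass
class RegionalEstimate:
    """Per-species and total carbon bounds with uncertainty and shares."""

    per_species: pd.DataFrame  # index species; min_tg, max_tg, uncertainty_pct
    total_min_tg: float
    total_max_tg: float
    total_uncertainty_pct: float
    shares: pd.DataFrame

    def table(self) -> pd.DataFrame:
        """Species rows plus a total row (minima/maxima sum exactly)."""
        out = self.per_species.copy()
        out.loc["total"] = [self.total_min_tg, self.total_max_tg, self.total_uncertainty_pct]
        return out


def regional_estimate(
    inventory: pd.DataFrame, envelopes: Mapping[str, Envelope]
) -> RegionalEstimate:
    per = apply_envelope(inventory, envelopes)

    def _unc(lo, hi):
        # extreme extrapolation (approach 1) can push a midpoint to or
        # below zero, where the percent metric is undefined
        return uncertainty_percent(lo, hi) if lo + hi > 0 else float("nan")

    per = per.assign(
        uncertainty_pct=[_unc(lo, hi) for lo, hi in zip(per["min_tg"], per["max_tg"])]
        if len(per)
        else []
    )
    tmin = float(per["min_tg"].sum())
    tmax = float(per["max_tg"].sum())
    return RegionalEstimate(
        per_species=per,
        total_min_tg=tmin,
        total_max_tg=tmax,
        total_uncertainty_pct=_unc(tmin, tmax) if len(per) else 0.0,
        shares=species_shares(per) if len(per) else pd.DataFrame(),
    )


@dataclass
class SubdivisionResult:
    k: int
    full_min_tg: float
    full_max_tg: float
    sub_min_tg: float
    sub_max_tg: float

    @property
    def ratio(self) -> float:
        """Subdivided uncertainty% over full-envelope uncertainty%."""
        return uncertainty_percent(self.sub_min_tg, self.sub_max_tg) / uncertainty_percent(
            self.full_min_tg, self.full_max_tg
        )


def subdivision_experiment(
    envelope: Envelope, inventory: pd.DataFrame, k: int
) -> SubdivisionResult:
    """Split the envelope into k equal-width bands and trees into k groups.

    Emulates knowing which of k hypothetical equations applies to each
    tree: per class, [lo, hi] is divided into k equal-width
    sub-intervals; the class's trees are partitioned into k groups in
    index order (remainder trees go to the leading groups); group j uses
    sub-interval j.  Group bounds are expansion-weighted, summed, and
    recombined.  When every class's trees divide evenly the uncertainty
    ratio is exactly 1/k.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    _check_inventory(inventory)
    sp = set(inventory["species"])
    if sp - {envelope.species}:
        raise ValueError(f"inventory species {sorted(sp)} do not match envelope {envelope.species!r}")
    classes = assign_dbh_class(inventory["dbh_cm"].to_numpy())
    expansion = inventory["expansion_factor"].to_numpy(dtype=float)
    full_min = full_max = sub_min = sub_max = 0.0
    for cls in np.unique(classes):
        lo, hi = envelope.value_at(cls)
        w = hi - lo
        e = expansion[classes == cls]
        full_min += e.sum() * lo
        full_max += e.sum() * hi
        n = e.size
        base, rem = divmod(n, k)
        start = 0
        for j in range(k):
            size = base + (1 if j < rem else 0)
            ej = e[start : start + size].sum()
            start += size
            sub_min += ej * (lo + j * w / k)
            sub_max += ej * (lo + (j + 1) * w / k)
    return SubdivisionResult(
        k=k,
        full_min_tg=full_min / KG_PER_TG,
        full_max_tg=full_max / KG_PER_TG,
        sub_min_tg=sub_min / KG_PER_TG,
        sub_max_tg=sub_max / KG_PER_TG,
    )


CATEGORY_SPANNING = "spanning"
CATEGORY_ENDS_AT_HALF = "ends-at-half"
CATEGORY_STARTS_AT_DOUBLE = "starts-at-double"


def dev_range_distance_experiment(
    catalog: Sequence[AllometricEquation],
    target_dbhs: Sequence[float] = (20.0, 60.0, 100.0),
    *,
    height_params: HeightParams | None = None,
) -> pd.DataFrame:
    """Prediction spread by distance of the developmental range from a target.

    For each target DBH, equations are grouped by whether their
    developmental range (1) spans the target, (2) ends at or below half
    of it, or (3) starts at or above twice it; each group is evaluated
    *at* the target (extrapolating for groups 2 and 3).  Returns one row
    per (target, category): n, min, max, midpoint.  Distant categories
    are expected to yield wider ranges with shifted midpoints.
    """
    if not catalog:
        raise ValueError("empty catalog")
    rows = []
    any_hit = False
    for t in target_dbhs:
        t = float(t)
        groups = {
            CATEGORY_SPANNING: [
                e for e in catalog if e.has_dev_range and e.dev_min_cm <= t <= e.dev_max_cm
            ],
            CATEGORY_ENDS_AT_HALF: [
                e for e in catalog if e.has_dev_range and e.dev_max_cm <= t / 2.0
            ],
            CATEGORY_STARTS_AT_DOUBLE: [
                e for e in catalog if e.has_dev_range and e.dev_min_cm >= 2.0 * t
            ],
        }
        for cat, eqs in groups.items():
            if eqs:
                any_hit = True
                h = (
                    predict_height(height_params, t)
                    if any(e.needs_height for e in eqs)
                    else None
                )
                preds = [evaluate(e, t, h) for e in eqs]
                lo, hi = min(preds), max(preds)
                rows.append(
                    dict(target_dbh=t, category=cat, n=len(eqs), min=lo, max=hi,
                         midpoint=(lo + hi) / 2.0)
                )
            else:
                rows.append(
                    dict(target_dbh=t, category=cat, n=0, min=np.nan, max=np.nan,
                         midpoint=np.nan)
                )
    if not any_hit:
        raise ValueError("no equation falls in any developmental-range category")
    return pd.DataFrame(rows)


def dbh_measurement_error(
    inventory: pd.DataFrame,
    eq: AllometricEquation,
    rel_error: float = 0.02,
    *,
    z: float = 1.96,
) -> float:
    """Delta-method standard error of the regional total from DBH error.

    Measurement variation is taken as ``rel_error`` of diameter expressed
    as a 95% confidence interval, so per tree ``sd(D) = rel_error*D/z``
    and ``SE(y) = |dy/dD| * sd(D)``.  Per-tree errors are independent, so
    ``SE_total = sqrt(sum((expansion * SE_tree)^2))`` in the equation's
    response units.
    """
    if eq.needs_height:
        raise ValueError(f"{eq.id}: measurement-error estimate requires a DBH-only equation")
    _check_inventory(inventory)
    if rel_error < 0:
        raise ValueError("rel_error must be >= 0")
    d = inventory["dbh_cm"].to_numpy(dtype=float)
    e = inventory["expansion_factor"].to_numpy(dtype=float)
    if d.size == 0:
        return 0.0
    sd = rel_error * d / z
    se_tree = np.abs(dbh_derivative(eq, d)) * sd
    return float(np.sqrt(np.sum((e * se_tree) ** 2)))


def single_source_estimate(
    equation_set: Mapping[str, Mapping[str, AllometricEquation]],
    inventory: pd.DataFrame,
    *,
    roadmap: Roadmap | None = None,
    height_params: Mapping[str, HeightParams] | None = None,
    densities: Mapping[tuple[str, str], float] | None = None,
    carbon_fraction: float = 0.5,
    grid=None,
) -> float:
    """Point regional total (Tg C) from one complete per-component set.

    ``equation_set[species][component]`` supplies one equation per
    roadmap component; volume equations are converted with the single
    density ``densities[(species, component)]``.  Biomass is converted
    to carbon with one fraction (both bounds alike), so the result is a
    point estimate that, by construction, lies inside the
    positive-correlation approach-1 envelope of any catalog containing
    the set.
    """
    _check_inventory(inventory)
    roadmap = roadmap or Roadmap.default()
    if grid is None:
        classes = assign_dbh_class(inventory["dbh_cm"].to_numpy())
        grid = np.arange(classes.min(), classes.max() + 1)
    grid = np.asarray(grid, dtype=float)
    envelopes: dict[str, Envelope] = {}
    for sp, comps in equation_set.items():
        point_envs: dict[str, Envelope] = {}
        for comp, eq in comps.items():
            hp = height_params.get(sp) if height_params else None
            h = predict_height(hp, grid) if (eq.needs_height and hp) else None
            if eq.needs_height and h is None:
                raise ValueError(f"{eq.id}: height parameters required for {sp}")
            pred = np.asarray(evaluate(eq, grid, h), dtype=float)
            if eq.response_kind == "volume":
                if densities is None or (sp, comp) not in densities:
                    raise ValueError(f"density required for volume equation {eq.id}")
                pred = pred * float(densities[(sp, comp)])
            point_envs[comp] = point_envelope(sp, comp, UNITS_CARBON, grid,
                                              pred * carbon_fraction, eq_id=eq.id)
        total, _ = total_tree_envelope(roadmap, point_envs, POSITIVE, strict=False)
        envelopes[sp] = total
    bounds = apply_envelope(inventory, envelopes)
    return float((bounds["min_tg"].sum() + bounds["max_tg"].sum()) / 2.0)


def form_agreement(
    equations: Sequence[AllometricEquation],
    *,
    height_params: HeightParams,
    dbh_grid=None,
    axes: Sequence[str] = ("D", "H", "D2H"),
) -> pd.DataFrame:
    """Spread of local (DBH-only) vs standard (DBH+height) predictions.

    Evaluates each subset over a DBH grid (heights from the height
    model) and reports, per axis value, the spread ``(max - min)`` of
    predictions, both absolute and relative to the midpoint.  If
    incorporating height made standard equations more universal, their
    predictions would converge when plotted against D^2*H; no such
    convergence is asserted here — the table is the diagnostic.
    """
    if dbh_grid is None:
        dbh_grid = np.arange(5.0, 67.0)
    d = np.asarray(dbh_grid, dtype=float)
    h = predict_height(height_params, d)
    subsets = {
        "local": [e for e in equations if not e.needs_height],
        "standard": [e for e in equations if e.needs_height],
    }
    for name, eqs in subsets.items():
        if len(eqs) < 2:
            raise ValueError(f"need at least 2 {name} equations, got {len(eqs)}")
    axis_values = {"D": d, "H": h, "D2H": d * d * h}
    rows = []
    for name, eqs in subsets.items():
        preds = np.vstack([np.asarray(evaluate(e, d, h)) for e in eqs])
        lo = preds.min(axis=0)
        hi = preds.max(axis=0)
        mid = (lo + hi) / 2.0
        for axis in axes:
            if axis not in axis_values:
                raise ValueError(f"unknown axis {axis!r}")
            for j in range(d.size):
                rows.append(
                    dict(
                        subset=name,
                        axis=axis,
                        axis_value=float(axis_values[axis][j]),
                        dbh=float(d[j]),
                        y_min=float(lo[j]),
                        y_max=float(hi[j]),
                        spread_abs=float(hi[j] - lo[j]),
                        spread_rel=float((hi[j] - lo[j]) / mid[j]) if mid[j] != 0 else np.nan,
                    )
                )
    return pd.DataFrame(rows)
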