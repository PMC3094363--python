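"""Prediction envelopes on 1-cm DBH classes, and interval unit conversions.

A prediction envelope records, per species x component x 1-cm DBH class,
the interval between the lowest and highest predictions given by all
admissible equations (and, for volume equations, both density bounds).
Which predictions are admissible at a class depends on the extrapolation
policy:

approach 1
    every equation over the whole grid, no corrections (negative
    predictions are retained);
approach 2
    each equation only within its developmental DBH range — classes with
    no in-range equation are undefined;
approach 3
    every equation over the whole grid, passed through an ordered list of
    modification rules (by default: clip negative predictions to zero,
    then truncate crown components above a species-specific DBH).

Envelopes carry a coverage mask and per-class provenance (which equation
set each bound), and serialise to CSV lookup tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    BIOMASS,
    VOLUME,
    AllometricEquation,
    DensityRecord,
    evaluate,
    find_density,
)
from .heights import HeightParams, predict_height

__all__ = [
    "Envelope",
    "ApproachPolicy",
    "UnitError",
    "component_envelope",
    "point_envelope",
    "volume_to_biomass",
    "biomass_to_carbon",
    "apply_crown_truncation",
    "write_envelopes",
    "read_envelopes",
    "CROWN_COMPONENTS",
    "UNITS_VOLUME",
    "UNITS_BIOMASS",
    "UNITS_CARBON",
    "CARBON_FRACTION_MIN",
    "CARBON_FRACTION_MAX",
]

UNITS_VOLUME = "m3"
UNITS_BIOMASS = "kg"
UNITS_CARBON = "kg C"
_UNITS = (UNITS_VOLUME, UNITS_BIOMASS, UNITS_CARBON)

#: Biomass-to-carbon factors: minima x 48%, maxima x 52%, bracketing the
#: spread of measured carbon contents (about 50 +/- 2% of dry biomass).
CARBON_FRACTION_MIN = 0.48
CARBON_FRACTION_MAX = 0.52

#: Components whose mass plateaus at maturity and may be truncated.
CROWN_COMPONENTS = frozenset(
    {"branches live", "branches dead", "branches total", "foliage", "live crown"}
)

MOD_CLIP_NEGATIVE = "clip-negative"
MOD_CROWN_TRUNCATION = "crown-truncation"


class UnitError(ValueError):
    """Operands carry incompatible units."""


@dataclass
class Envelope:
    """Per-class [lower, upper] bounds for one species x component.

    ``lower``/``upper`` are NaN wherever ``defined`` is False (approach-2
    classes with no admissible equation).  ``lower_eq_id``/``upper_eq_id``
    record which equation set each bound per class.
    """

    species: str
    component: str
    units: str
    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    defined: np.ndarray | None = None
    lower_eq_id: np.ndarray | None = None
    upper_eq_id: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.units not in _UNITS:
            raise UnitError(f"unknown units {self.units!r}")
        if self.grid.ndim != 1 or np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be 1-d and strictly increasing")
        if self.lower.shape != self.grid.shape or self.upper.shape != self.grid.shape:
            raise ValueError("bound arrays must match the grid")
        if self.defined is None:
            self.defined = np.isfinite(self.lower) & np.isfinite(self.upper)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.defined.shape != self.grid.shape:
            raise ValueError("defined mask must match the grid")
        self.lower = np.where(self.defined, self.lower, np.nan)
        self.upper = np.where(self.defined, self.upper, np.nan)
        bad = self.defined & (self.lower > self.upper + 1e-9 * np.abs(self.upper))
        if np.any(bad):
            raise ValueError(
                f"{self.species}/{self.component}: lower > upper at classes "
                f"{self.grid[bad].tolist()}"
            )
        for attr in ("lower_eq_id", "upper_eq_id"):
            ids = getattr(self, attr)
            if ids is not None:
                ids = np.asarray(ids, dtype=object)
                if ids.shape != self.grid.shape:
                    raise ValueError(f"{attr} must match the grid")
                setattr(self, attr, ids)

    # -- derived quantities -------------------------------------------------
    def midpoint(self) -> np.ndarray:
        return (self.lower + self.upper) / 2.0

    def half_width(self) -> np.ndarray:
        return (self.upper - self.lower) / 2.0

    def relative_half_width(self) -> np.ndarray:
        """Half-width over midpoint (the per-class uncertainty fraction)."""
        return self.half_width() / self.midpoint()

    def class_index(self, dbh_class) -> int:
        idx = int(np.searchsorted(self.grid, float(dbh_class)))
        if idx >= self.grid.size or self.grid[idx] != float(dbh_class):
            raise KeyError(f"DBH class {dbh_class} not on the grid")
        return idx

    def value_at(self, dbh_class) -> tuple[float, float]:
        i = self.class_index(dbh_class)
        if not self.defined[i]:
            raise KeyError(f"{self.species}/{self.component}: class {dbh_class} undefined")
        return float(self.lower[i]), float(self.upper[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "component": self.component,
                "units": self.units,
                "dbh_class": self.grid,
                "lower": self.lower,
                "upper": self.upper,
                "defined": self.defined,
                "lower_eq_id": self.lower_eq_id
                if self.lower_eq_id is not None
                else np.full(self.grid.shape, None, dtype=object),
                "upper_eq_id": self.upper_eq_id
                if self.upper_eq_id is not None
                else np.full(self.grid.shape, None, dtype=object),
            }
        )


@dataclass(frozen=True)
class ApproachPolicy:
    """Extrapolation policy for envelope construction.

    ``crown_truncation_dbh`` maps species to the DBH class (cm) above
    which crown-component predictions are held constant (approach 3
    only); a scalar applies to every species.  ``modifications`` is the
    ordered approach-3 rule list.
    """

    approach: int
    crown_truncation_dbh: Mapping[str, float] | float | None = None
    modifications: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.approach not in (1, 2, 3):
            raise ValueError(f"approach must be 1, 2 or 3, got {self.approach}")
        mods = self.modifications
        if mods is None:
            mods = (MOD_CLIP_NEGATIVE, MOD_CROWN_TRUNCATION) if self.approach == 3 else ()
        mods = tuple(mods)
        if self.approach in (1, 2) and mods:
            raise ValueError(f"approach {self.approach} applies no modifications")
        unknown = [m for m in mods if m not in (MOD_CLIP_NEGATIVE, MOD_CROWN_TRUNCATION)]
        if unknown:
            raise ValueError(f"unknown modification rules {unknown}")
        object.__setattr__(self, "modifications", mods)

    def truncation_for(self, species: str) -> float | None:
        t = self.crown_truncation_dbh
        if t is None:
            return None
        if isinstance(t, Mapping):
            return t.get(species)
        return float(t)


def apply_crown_truncation(values, grid, truncation_dbh, *, component: str | None = None):
    """Hold predictions constant above a truncation DBH (flat extension).

    Crown mass (branches, foliage) is not expected to keep increasing
    after maturity; predictions at classes beyond ``truncation_dbh`` are
    replaced by the value at ``truncation_dbh``.
    """
    if component is not None and component not in CROWN_COMPONENTS:
        raise ValueError(f"crown truncation does not apply to component {component!r}")
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float).copy()
    t = float(truncation_dbh)
    if t < grid[0] or t > grid[-1]:
        raise ValueError(f"truncation DBH {t} outside grid [{grid[0]}, {grid[-1]}]")
    idx = int(np.searchsorted(grid, t, side="right")) - 1
    values[idx + 1 :] = values[idx]
    return values


def component_envelope(
    equations: Sequence[AllometricEquation],
    species: str,
    component: str,
    grid,
    policy: ApproachPolicy,
    *,
    height_params: HeightParams | None = None,
    densities: Sequence[DensityRecord] | None = None,
    correct_log_bias: bool = False,
) -> Envelope:
    """Build the prediction envelope for one species x component.

    Per class, lower/upper are the min/max over all admissible
    predictions; a volume equation contributes two biomass candidates
    (its prediction times ``rho_min`` and ``rho_max``) before the
    min/max, so the result is in kg biomass whenever a density table is
    supplied (or any biomass equation is present).  Provenance records
    the argmin/argmax equation ids per class.
    """
    eqs = [e for e in equations if e.species == species and e.component == component]
    if not eqs:
        raise ValueError(f"no equations for {species}/{component}")
    grid = np.asarray(grid, dtype=float)

    kinds = {e.response_kind for e in eqs}
    convert_volume = VOLUME in kinds and (densities is not None or BIOMASS in kinds)
    if VOLUME in kinds and BIOMASS in kinds and densities is None:
        raise UnitError(
            f"{species}/{component}: catalog mixes volume and biomass responses; "
            "a density table is required"
        )
    units = UNITS_BIOMASS if (BIOMASS in kinds or convert_volume) else UNITS_VOLUME

    heights = None
    if any(e.needs_height for e in eqs):
        if height_params is None:
            raise ValueError(
                f"{species}/{component}: a standard equation is present; "
                "height parameters are required"
            )
        heights = predict_height(height_params, grid)

    truncation = policy.truncation_for(species)
    candidates: list[np.ndarray] = []
    cand_ids: list[str] = []
    admissible: list[np.ndarray] = []
    for eq in eqs:
        pred = np.asarray(evaluate(eq, grid, heights, correct_log_bias=correct_log_bias))
        for rule in policy.modifications:
            if rule == MOD_CLIP_NEGATIVE:
                pred = np.maximum(pred, 0.0)
            elif rule == MOD_CROWN_TRUNCATION:
                if component in CROWN_COMPONENTS and truncation is not None:
                    pred = apply_crown_truncation(pred, grid, truncation, component=component)
        if policy.approach == 2 and eq.has_dev_range:
            mask = (grid >= eq.dev_min_cm) & (grid <= eq.dev_max_cm)
        else:
            # Approaches 1 and 3 extrapolate everywhere; so do equations
            # whose developmental-range requirement was waived.
            mask = np.ones_like(grid, dtype=bool)
        if eq.response_kind == VOLUME and convert_volume:
            rho = find_density(densities, species, component)
            candidates += [pred * rho.rho_min, pred * rho.rho_max]
            cand_ids += [eq.id, eq.id]
            admissible += [mask, mask]
        else:
            candidates.append(pred)
            cand_ids.append(eq.id)
            admissible.append(mask)

    cand = np.vstack(candidates)
    mask = np.vstack(admissible)
    if not mask.any():
        raise ValueError(f"{species}/{component}: no admissible prediction on any class")
    masked = np.where(mask, cand, np.nan)
    defined = mask.any(axis=0)
    lower = np.full(grid.shape, np.nan)
    upper = np.full(grid.shape, np.nan)
    lower[defined] = np.nanmin(masked[:, defined], axis=0)
    upper[defined] = np.nanmax(masked[:, defined], axis=0)
    ids = np.asarray(cand_ids, dtype=object)
    lo_id = np.full(grid.shape, None, dtype=object)
    hi_id = np.full(grid.shape, None, dtype=object)
    cols = np.where(defined)[0]
    lo_id[cols] = ids[np.nanargmin(masked[:, cols], axis=0)]
    hi_id[cols] = ids[np.nanargmax(masked[:, cols], axis=0)]
    return Envelope(
        species=species,
        component=component,
        units=units,
        grid=grid,
        lower=lower,
        upper=upper,
        defined=defined,
        lower_eq_id=lo_id,
        upper_eq_id=hi_id,
        meta={"approach": policy.approach, "n_equations": len(eqs)},
    )


def point_envelope(species, component, units, grid, values, **meta) -> Envelope:
    """Degenerate envelope with lower = upper = ``values`` (a point estimate)."""
    values = np.asarray(values, dtype=float)
    return Envelope(
        species=species,
        component=component,
        units=units,
        grid=np.asarray(grid, dtype=float),
        lower=values.copy(),
        upper=values.copy(),
        meta=dict(meta),
    )


def volume_to_biomass(env: Envelope, density: DensityRecord) -> Envelope:
    """Convert a volume envelope to biomass: lower*rho_min, upper*rho_max."""
    if env.units != UNITS_VOLUME:
        raise UnitError(f"expected a volume envelope, got units {env.units!r}")
    if (density.species, density.component) != (env.species, env.component):
        raise ValueError(
            f"density record {density.species}/{density.component} does not match "
            f"envelope {env.species}/{env.component}"
        )
    return Envelope(
        species=env.species,
        component=env.component,
        units=UNITS_BIOMASS,
        grid=env.grid.copy(),
        # lower*rho_min / upper*rho_max; the min/max keep lower <= upper
        # when a bound is negative (retained under approach 1)
        lower=np.minimum(env.lower * density.rho_min, env.lower * density.rho_max),
        upper=np.maximum(env.upper * density.rho_min, env.upper * density.rho_max),
        defined=env.defined.copy(),
        lower_eq_id=None if env.lower_eq_id is None else env.lower_eq_id.copy(),
        upper_eq_id=None if env.upper_eq_id is None else env.upper_eq_id.copy(),
        meta=dict(env.meta),
    )


def biomass_to_carbon(
    env: Envelope,
    c_min: float = CARBON_FRACTION_MIN,
    c_max: float = CARBON_FRACTION_MAX,
) -> Envelope:
    """Convert biomass bounds to carbon: minima x c_min, maxima x c_max.

    Using different fractions for the two bounds folds carbon-content
    uncertainty into the envelope; it strictly widens the relative
    half-width of any non-degenerate positive interval.
    """
    if env.units != UNITS_BIOMASS:
        raise UnitError(f"expected a biomass envelope, got units {env.units!r}")
    if not (0 < c_min <= c_max):
        raise ValueError("need 0 < c_min <= c_max")
    return Envelope(
        species=env.species,
        component=env.component,
        units=UNITS_CARBON,
        grid=env.grid.copy(),
        # minima*c_min / maxima*c_max; min/max guard negative bounds
        lower=np.minimum(env.lower * c_min, env.lower * c_max),
        upper=np.maximum(env.upper * c_min, env.upper * c_max),
        defined=env.defined.copy(),
        lower_eq_id=None if env.lower_eq_id is None else env.lower_eq_id.copy(),
        upper_eq_id=None if env.upper_eq_id is None else env.upper_eq_id.copy(),
        meta=dict(env.meta),
    )


def write_envelopes(path, envelopes: Iterable[Envelope]) -> None:
    """Serialise envelopes to one CSV lookup table."""
    frames = [e.to_frame() for e in envelopes]
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)


def read_envelopes(path) -> list[Envelope]:
    df = pd.read_csv(Path(path))
    out = []
    for (sp, comp, units), grp in df.groupby(["species", "component", "units"], sort=False):
        grp = grp.sort_values("dbh_class")
        out.append(
            Envelope(
                species=sp,
                component=comp,
                units=units,
                grid=grp["dbh_class"].to_numpy(dtype=float),
                lower=grp["lower"].to_numpy(dtype=float),
                upper=grp["upper"].to_numpy(dtype=float),
                defined=grp["defined"].to_numpy(dtype=bool),
                lower_eq_id=grp["lower_eq_id"].astype(object).where(grp["lower_eq_id"].notna(), None).to_numpy(),
                upper_eq_id=grp["upper_eq_id"].astype(object).where(grp["upper_eq_id"].notna(), None).to_numpy(),
            )
        )
    return out
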