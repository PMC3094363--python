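"""Allometric equation catalogs: data model, file I/O, inclusion rules, evaluation.

A published allometric equation predicts stem volume (m^3) or oven-dry
biomass (kg) of a named tree component from diameter at breast height
(DBH, cm) and, for "standard" equations, total height (m).  Published
libraries are heterogeneous: equations come in several algebraic forms,
were fit over different "developmental" DBH ranges (the DBH interval of
the trees used to fit them), and follow different stump-height and
top-diameter conventions.  This module gives those conventions a concrete
data model, evaluates equations in natural units, and implements the
screening rules used to decide which equations may enter a prediction
envelope.

Four equation families cover the local, standard and combined-variable
forms common in regional volume/biomass compilations:

``linear-combination``
    DBH-only: a polynomial in D, ``y = c0 + c1*D + c2*D^2 + ...``.
    With height: ``y = c0 + c1*D + c2*H + c3*D^2*H`` (coefficients may be
    truncated from the right).
``power``
    ``y = c0 * D**c1`` or ``y = c0 * D**c1 * H**c2``.
``log-log``
    ``ln y = c0 + c1*ln D (+ c2*ln H)``; evaluation exponentiates back to
    natural units.  The lognormal back-transformation correction
    ``exp(mse_log / 2)`` is available but applied only on request.
``combined-variable``
    ``y = c0 + c1 * D^2 H`` (always requires height).

Units are fixed throughout the package: cm (DBH), m (height), m^3
(volume), kg oven-dry (biomass).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AllometricEquation",
    "DensityRecord",
    "CatalogError",
    "evaluate",
    "dbh_derivative",
    "apply_inclusion_rules",
    "log_bias_factor",
    "additivity_error",
    "load_catalog",
    "write_catalog",
    "load_densities",
    "write_densities",
    "find_density",
]

VOLUME = "volume"
BIOMASS = "biomass"
RESPONSE_KINDS = (VOLUME, BIOMASS)

FORM_LINEAR = "linear-combination"
FORM_POWER = "power"
FORM_LOGLOG = "log-log"
FORM_COMBINED = "combined-variable"
FORMS = (FORM_LINEAR, FORM_POWER, FORM_LOGLOG, FORM_COMBINED)

PREDICTORS_DBH = "dbh-only"
PREDICTORS_DBH_HEIGHT = "dbh-and-height"
PREDICTORS_OTHER = "other"
PREDICTORS = (PREDICTORS_DBH, PREDICTORS_DBH_HEIGHT, PREDICTORS_OTHER)

#: Stump-height conventions admitted by the inclusion rules (~4, 6, 12 in).
ALLOWED_STUMP_HEIGHTS_CM = (10.0, 15.0, 30.0)

REASON_EXTRA_PREDICTOR = "extra-predictor"
REASON_NO_DEV_RANGE = "no-dev-range"
REASON_BAD_STUMP = "bad-stump-height"
REASON_NOT_TO_TOP = "not-to-top"
EXCLUSION_REASONS = (
    REASON_EXTRA_PREDICTOR,
    REASON_NO_DEV_RANGE,
    REASON_BAD_STUMP,
    REASON_NOT_TO_TOP,
)


class CatalogError(ValueError):
    """A catalog or density file failed to parse or validate."""


@dataclass(frozen=True)
class AllometricEquation:
    """One published volume or biomass regression.

    Parameters
    ----------
    id : str
        Opaque identifier, unique within a catalog.
    species : str
        Species code or binomial.
    component : str
        Controlled-vocabulary component name (``"stem wood"``,
        ``"stem bark"``, ``"branches total"``, ``"foliage"``,
        ``"live crown"``, ``"aboveground total"``, ``"roots coarse"``, ...).
    response_kind : {"volume", "biomass"}
        Determines the response units exactly: m^3 or kg oven-dry.
    form_id : str
        One of the four form families (module docstring).
    coefficients : sequence of float
        Ordered coefficients for the chosen form.
    predictors : {"dbh-only", "dbh-and-height", "other"}
        ``"other"`` marks equations relying on variables beyond DBH and
        height; they cannot be evaluated and are excluded by the
        inclusion rules.
    dev_min_cm, dev_max_cm : float or None
        Developmental DBH range; ``None`` when the source does not report
        one.
    stump_height_cm : float or None
        Stump-height convention of a stem equation; ``None`` = not
        applicable.
    extends_to_top : bool
        Whether a stem equation extends to the top of the stem.
    log_base_e : bool
        Response modelled on the natural-log scale (implied by the
        log-log form).
    mse_log : float or None
        Residual mean square on the log scale, when reported; needed for
        the back-transformation correction.
    dev_range_waived : bool
        Per-record waiver of the developmental-range requirement (used in
        practice for inventory-programme workhorse equations whose range
        was never published).
    source : str
        Citation key.
    """

    id: str
    species: str
    component: str
    response_kind: str
    form_id: str
    coefficients: tuple[float, ...]
    predictors: str = PREDICTORS_DBH
    dev_min_cm: float | None = None
    dev_max_cm: float | None = None
    stump_height_cm: float | None = None
    extends_to_top: bool = True
    log_base_e: bool = False
    mse_log: float | None = None
    dev_range_waived: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        if not self.id:
            raise CatalogError("equation id must be non-empty")
        if self.response_kind not in RESPONSE_KINDS:
            raise CatalogError(f"{self.id}: unknown response_kind {self.response_kind!r}")
        if self.form_id not in FORMS:
            raise CatalogError(f"{self.id}: unknown form_id {self.form_id!r}")
        if self.predictors not in PREDICTORS:
            raise CatalogError(f"{self.id}: unknown predictors {self.predictors!r}")
        if not self.coefficients:
            raise CatalogError(f"{self.id}: no coefficients")
        if not all(math.isfinite(c) for c in self.coefficients):
            raise CatalogError(f"{self.id}: non-finite coefficient")
        if (self.dev_min_cm is None) != (self.dev_max_cm is None):
            raise CatalogError(f"{self.id}: developmental range must give both ends")
        if self.dev_min_cm is not None:
            if not (0 < self.dev_min_cm < self.dev_max_cm):
                raise CatalogError(
                    f"{self.id}: developmental range must satisfy 0 < min < max, "
                    f"got [{self.dev_min_cm}, {self.dev_max_cm}]"
                )
        if self.form_id == FORM_LOGLOG and not self.log_base_e:
            raise CatalogError(f"{self.id}: log-log form implies log_base_e")
        if self.form_id == FORM_COMBINED:
            if len(self.coefficients) != 2:
                raise CatalogError(f"{self.id}: combined-variable form takes 2 coefficients")
            if self.predictors != PREDICTORS_DBH_HEIGHT:
                raise CatalogError(f"{self.id}: combined-variable form requires height")
        if self.form_id in (FORM_POWER, FORM_LOGLOG):
            want = 3 if self.predictors == PREDICTORS_DBH_HEIGHT else 2
            if len(self.coefficients) != want:
                raise CatalogError(
                    f"{self.id}: {self.form_id} with predictors={self.predictors} "
                    f"takes {want} coefficients"
                )
        if self.mse_log is not None and self.mse_log < 0:
            raise CatalogError(f"{self.id}: mse_log must be >= 0")

    @property
    def needs_height(self) -> bool:
        return self.predictors == PREDICTORS_DBH_HEIGHT

    @property
    def has_dev_range(self) -> bool:
        return self.dev_min_cm is not None

    @property
    def dev_range(self) -> tuple[float, float] | None:
        if self.dev_min_cm is None:
            return None
        return (self.dev_min_cm, self.dev_max_cm)


@dataclass(frozen=True)
class DensityRecord:
    """Wood-density bounds (kg m^-3) for one species x component.

    Libraries report a spread of density values; envelope construction
    retains the lowest and highest per species and component so each
    volume equation yields two biomass predictions.
    """

    species: str
    component: str
    rho_min: float
    rho_max: float

    def __post_init__(self) -> None:
        if not (0 < self.rho_min <= self.rho_max):
            raise CatalogError(
                f"density for {self.species}/{self.component}: "
                f"need 0 < rho_min <= rho_max, got [{self.rho_min}, {self.rho_max}]"
            )


def log_bias_factor(eq: AllometricEquation) -> float:
    """Multiplicative back-transformation correction for a log-scale fit.

    A regression fitted on ln(y) and exponentiated predicts the median,
    not the mean, of a lognormal response; the standard correction is
    ``exp(mse_log / 2)``.  Uncorrected estimates are biased downward.
    The correction is opt-in throughout the package.
    """
    if not eq.log_base_e:
        raise ValueError(f"{eq.id}: not a log-scale equation")
    if eq.mse_log is None:
        raise ValueError(f"{eq.id}: mse_log not reported; cannot correct")
    return math.exp(eq.mse_log / 2.0)


def evaluate(
    eq: AllometricEquation,
    dbh,
    height=None,
    *,
    correct_log_bias: bool = False,
):
    """Evaluate an equation at DBH (cm) and optional height (m).

    Returns predictions in the equation's response units (m^3 or kg).
    Log-log forms are exponentiated to natural units; the lognormal
    correction is applied only when ``correct_log_bias`` is set.

    Accepts scalars or arrays; vectorised over DBH (and height).
    """
    if eq.predictors == PREDICTORS_OTHER:
        raise ValueError(f"{eq.id}: relies on predictors other than DBH and height")
    d = np.asarray(dbh, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    if np.any(d < 0):
        raise ValueError("DBH must be non-negative")
    if eq.needs_height:
        if height is None:
            raise ValueError(f"{eq.id}: standard equation requires height")
        h = np.atleast_1d(np.asarray(height, dtype=float))
        h = np.broadcast_to(h, d.shape)
    else:
        h = None

    c = eq.coefficients
    if eq.form_id == FORM_LINEAR:
        if eq.needs_height:
            basis = [np.ones_like(d), d, h, d * d * h]
            y = sum(ci * bi for ci, bi in zip(c, basis[: len(c)]))
        else:
            y = np.polynomial.polynomial.polyval(d, c)
    elif eq.form_id == FORM_POWER:
        y = c[0] * d ** c[1]
        if eq.needs_height:
            y = y * h ** c[2]
    elif eq.form_id == FORM_LOGLOG:
        if np.any(d <= 0):
            raise ValueError(f"{eq.id}: log-log form requires DBH > 0")
        ln_y = c[0] + c[1] * np.log(d)
        if eq.needs_height:
            ln_y = ln_y + c[2] * np.log(h)
        y = np.exp(ln_y)
    elif eq.form_id == FORM_COMBINED:
        y = c[0] + c[1] * d * d * h
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown form {eq.form_id!r}")

    y = np.asarray(y, dtype=float)
    if correct_log_bias and eq.log_base_e:
        y = y * log_bias_factor(eq)
    if not np.all(np.isfinite(y)):
        raise ArithmeticError(f"{eq.id}: non-finite prediction")
    return float(y[0]) if scalar else y


def dbh_derivative(eq: AllometricEquation, dbh):
    """Analytic d(prediction)/d(DBH) for a DBH-only equation.

    Used by the delta-method DBH measurement-error estimate.
    """
    if eq.needs_height:
        raise ValueError(f"{eq.id}: derivative only defined for DBH-only equations")
    if eq.predictors == PREDICTORS_OTHER:
        raise ValueError(f"{eq.id}: relies on predictors other than DBH and height")
    d = np.asarray(dbh, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    c = eq.coefficients
    if eq.form_id == FORM_LINEAR:
        dc = np.polynomial.polynomial.polyder(np.asarray(c))
        g = np.polynomial.polynomial.polyval(d, dc)
    elif eq.form_id == FORM_POWER:
        g = c[0] * c[1] * d ** (c[1] - 1.0)
    elif eq.form_id == FORM_LOGLOG:
        y = np.exp(c[0] + c[1] * np.log(d))
        g = y * c[1] / d
    else:  # pragma: no cover - combined-variable always needs height
        raise ValueError(f"{eq.id}: no DBH-only derivative for form {eq.form_id}")
    g = np.asarray(g, dtype=float)
    return float(g[0]) if scalar else g


def _exclusion_reason(eq: AllometricEquation) -> str | None:
    # Rules are checked in their published order; the first violation is
    # the recorded reason, so the partition carries exactly one code each.
    if eq.predictors == PREDICTORS_OTHER:
        return REASON_EXTRA_PREDICTOR
    if not eq.has_dev_range and not eq.dev_range_waived:
        return REASON_NO_DEV_RANGE
    if eq.stump_height_cm is not None and eq.stump_height_cm not in ALLOWED_STUMP_HEIGHTS_CM:
        return REASON_BAD_STUMP
    if not eq.extends_to_top:
        return REASON_NOT_TO_TOP
    return None


def apply_inclusion_rules(
    catalog: Iterable[AllometricEquation],
) -> tuple[list[AllometricEquation], list[tuple[AllometricEquation, str]]]:
    """Partition a catalog into admitted equations and exclusions.

    Equations are excluded when they (1) rely on variables other than DBH
    and height, (2) lack a developmental DBH range (unless waived per
    record), (3) use a stump height other than 10, 15 or 30 cm, or
    (4) do not extend to the top of the stem.  Every exclusion carries
    exactly one machine-readable reason code; the partition is exhaustive
    and disjoint, and re-applying it to its own union is a no-op.
    """
    included: list[AllometricEquation] = []
    excluded: list[tuple[AllometricEquation, str]] = []
    for eq in catalog:
        reason = _exclusion_reason(eq)
        if reason is None:
            included.append(eq)
        else:
            excluded.append((eq, reason))
    return included, excluded


def additivity_error(
    component_eqs: Sequence[AllometricEquation],
    aggregate_eq: AllometricEquation,
    grid,
    *,
    height_params=None,
) -> tuple[float, float]:
    """Percent deviation of summed component predictions from an aggregate.

    Component equations fitted independently rarely sum exactly to an
    independently fitted aggregate equation for the same trees
    (nonadditivity).  Per DBH class ``d``::

        deviation(d) = 100 * (sum_components(d) - aggregate(d)) / aggregate(d)

    Returns ``(mean deviation, max |deviation|)`` over the grid.  The
    grid must lie within every equation's developmental range (where one
    is reported).
    """
    eqs = list(component_eqs) + [aggregate_eq]
    species = {e.species for e in eqs}
    if len(species) != 1:
        raise ValueError(f"equations span multiple species: {sorted(species)}")
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty DBH grid")
    lo = max((e.dev_min_cm for e in eqs if e.has_dev_range), default=None)
    hi = min((e.dev_max_cm for e in eqs if e.has_dev_range), default=None)
    if lo is not None and (lo > hi or grid.min() < lo or grid.max() > hi):
        raise ValueError(
            f"grid [{grid.min()}, {grid.max()}] not within the developmental-range "
            f"intersection [{lo}, {hi}]"
        )
    heights = _heights_for(eqs, grid, height_params)
    agg = evaluate(aggregate_eq, grid, heights)
    if np.any(agg <= 0):
        raise ValueError("aggregate prediction <= 0 on the grid")
    total = np.zeros_like(grid)
    for e in component_eqs:
        total = total + evaluate(e, grid, heights)
    dev = 100.0 * (total - agg) / agg
    return float(np.mean(dev)), float(np.max(np.abs(dev)))


def _heights_for(eqs, grid, height_params):
    if not any(e.needs_height for e in eqs):
        return None
    if height_params is None:
        raise ValueError("height parameters required: a standard equation is present")
    from .heights import predict_height

    return predict_height(height_params, grid)


# ---------------------------------------------------------------------------
# File I/O
#
# Catalogs are CSV (one row per equation, coefficients as a ';'-delimited
# list) with a validated JSON alternative; both are diff-able and
# hand-editable.  Headers are checked strictly.

CATALOG_COLUMNS = [
    "id",
    "species",
    "component",
    "response_kind",
    "form_id",
    "coefficients",
    "predictors",
    "dev_min_cm",
    "dev_max_cm",
    "stump_height_cm",
    "extends_to_top",
    "log_base_e",
    "mse_log",
    "source",
]
OPTIONAL_CATALOG_COLUMNS = ["dev_range_waived"]
DENSITY_COLUMNS = ["species", "component", "rho_min", "rho_max"]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _parse_bool(text: str, *, default: bool, where: str) -> bool:
    t = text.strip().lower()
    if t == "" :
        return default
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise CatalogError(f"{where}: cannot parse boolean {text!r}")


def _parse_optional_float(text: str) -> float | None:
    t = text.strip()
    return None if t == "" else float(t)


def _record_to_equation(rec: dict, where: str) -> AllometricEquation:
    try:
        coeffs = rec["coefficients"]
        if isinstance(coeffs, str):
            coeffs = [float(t) for t in coeffs.replace(",", ";").split(";") if t.strip()]
        return AllometricEquation(
            id=str(rec["id"]).strip(),
            species=str(rec["species"]).strip(),
            component=str(rec["component"]).strip(),
            response_kind=str(rec["response_kind"]).strip(),
            form_id=str(rec["form_id"]).strip(),
            coefficients=tuple(float(c) for c in coeffs),
            predictors=str(rec["predictors"]).strip(),
            dev_min_cm=_opt_num(rec.get("dev_min_cm")),
            dev_max_cm=_opt_num(rec.get("dev_max_cm")),
            stump_height_cm=_opt_num(rec.get("stump_height_cm")),
            extends_to_top=_opt_bool(rec.get("extends_to_top"), True, where),
            log_base_e=_opt_bool(rec.get("log_base_e"), False, where),
            mse_log=_opt_num(rec.get("mse_log")),
            dev_range_waived=_opt_bool(rec.get("dev_range_waived"), False, where),
            source=str(rec.get("source", "")).strip(),
        )
    except (KeyError, ValueError, TypeError) as err:
        if isinstance(err, CatalogError):
            raise
        raise CatalogError(f"{where}: malformed equation record: {err}") from err


def _opt_num(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, str):
        return _parse_optional_float(value)
    return float(value)


def _opt_bool(value, default: bool, where: str) -> bool:
    if value is None:
        return default
    if isinstance(value, bool):
        return value
    if isinstance(value, str):
        return _parse_bool(value, default=default, where=where)
    raise CatalogError(f"{where}: cannot parse boolean {value!r}")


def _check_header(found: list[str] | None, required: list[str], optional: list[str], path) -> None:
    if found is None:
        raise CatalogError(f"{path}: empty file")
    found = [f.strip() for f in found]
    if found[: len(required)] != required or any(
        c not in optional for c in found[len(required) :]
    ):
        raise CatalogError(
            f"{path}: bad header; expected {required} (optionally + {optional}), got {found}"
        )


def load_catalog(path) -> list[AllometricEquation]:
    """Load an equation catalog from CSV or JSON (by file extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(doc, dict) or not isinstance(doc.get("equations"), list):
            raise CatalogError(f"{path}: JSON catalog must be {{'equations': [...]}}")
        eqs = [
            _record_to_equation(rec, f"{path}[{i}]") if isinstance(rec, dict)
            else _bad_record(path, i)
            for i, rec in enumerate(doc["equations"])
        ]
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            _check_header(reader.fieldnames, CATALOG_COLUMNS, OPTIONAL_CATALOG_COLUMNS, path)
            eqs = [
                _record_to_equation(row, f"{path}:{i + 2}")
                for i, row in enumerate(reader)
            ]
    ids = [e.id for e in eqs]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise CatalogError(f"{path}: duplicate equation ids {sorted(dupes)}")
    return eqs


def _bad_record(path, i):
    raise CatalogError(f"{path}[{i}]: equation record must be an object")


def write_catalog(path, equations: Iterable[AllometricEquation]) -> None:
    """Write a catalog as CSV (coefficients ';'-delimited)."""
    path = Path(path)
    cols = CATALOG_COLUMNS + OPTIONAL_CATALOG_COLUMNS
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for eq in equations:
            writer.writerow(
                [
                    eq.id,
                    eq.species,
                    eq.component,
                    eq.response_kind,
                    eq.form_id,
                    ";".join(repr(c) for c in eq.coefficients),
                    eq.predictors,
                    "" if eq.dev_min_cm is None else repr(eq.dev_min_cm),
                    "" if eq.dev_max_cm is None else repr(eq.dev_max_cm),
                    "" if eq.stump_height_cm is None else repr(eq.stump_height_cm),
                    str(eq.extends_to_top).lower(),
                    str(eq.log_base_e).lower(),
                    "" if eq.mse_log is None else repr(eq.mse_log),
                    eq.source,
                    str(eq.dev_range_waived).lower(),
                ]
            )


def load_densities(path) -> list[DensityRecord]:
    """Load a wood-density table (CSV: species, component, rho_min, rho_max)."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, DENSITY_COLUMNS, [], path)
        out = []
        for i, row in enumerate(reader):
            try:
                out.append(
                    DensityRecord(
                        species=row["species"].strip(),
                        component=row["component"].strip(),
                        rho_min=float(row["rho_min"]),
                        rho_max=float(row["rho_max"]),
                    )
                )
            except (ValueError, KeyError) as err:
                if isinstance(err, CatalogError):
                    raise
                raise CatalogError(f"{path}:{i + 2}: malformed density record: {err}") from err
    return out


def write_densities(path, densities: Iterable[DensityRecord]) -> None:
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DENSITY_COLUMNS)
        for rec in densities:
            writer.writerow([rec.species, rec.component, repr(rec.rho_min), repr(rec.rho_max)])


def find_density(
    densities: Iterable[DensityRecord], species: str, component: str
) -> DensityRecord:
    for rec in densities:
        if rec.species == species and rec.component == component:
            return rec
    raise KeyError(f"no density record for {species}/{component}")
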