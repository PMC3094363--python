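"""End-to-end estimator: equation catalog -> envelopes -> regional bounds.

``CarbonEnvelopeModel`` is the package's front door, organised as a
scikit-learn estimator: ``fit`` screens a catalog, builds per-component
prediction envelopes on a 1-cm DBH grid under the chosen extrapolation
approach, converts volume -> biomass -> carbon as interval operations,
and folds the component envelopes through the aggregation roadmap under
the chosen correlation mode; ``predict`` applies the fitted total-tree
envelopes to an inventory and returns regional carbon bounds,
uncertainty percents and species shares.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .catalog import AllometricEquation, DensityRecord, apply_inclusion_rules
from .envelopes import (
    ApproachPolicy,
    Envelope,
    UNITS_BIOMASS,
    biomass_to_carbon,
    component_envelope,
)
from .heights import HeightParams
from .regional import RegionalEstimate, regional_estimate
from .roadmap import Roadmap, total_tree_envelope

logger = logging.getLogger(__name__)

__all__ = ["CarbonEnvelopeModel"]


class CarbonEnvelopeModel(BaseEstimator):
    """Prediction-envelope model of model-selection uncertainty.

    Parameters
    ----------
    approach : {1, 2, 3}, default 2
        Extrapolation policy: 1 = every equation everywhere, no
        corrections; 2 = equations only within their developmental DBH
        ranges; 3 = extrapolation with modification rules (clip
        negatives, truncate crown components).
    correlation : {"positive", "negative"}, default "positive"
        Correlation assumed between components at every addition step.
    carbon_fraction_min, carbon_fraction_max : float
        Biomass-to-carbon factors applied to envelope minima and maxima.
    grid_min, grid_max : int
        Inclusive 1-cm DBH class range of the lookup grid.
    roadmap : Roadmap or None
        Aggregation scheme; ``None`` uses the packaged default.
    crown_truncation_dbh : mapping, float or None
        Per-species truncation class for crown components (approach 3).
        ``None`` defaults each species to the middle of the grid range.
    apply_inclusion : bool, default True
        Screen the catalog with the inclusion rules before building.
    skip_missing_alternatives : bool, default True
        Drop roadmap OR pathways for which a species has no equations
        (an error is still raised if no pathway reaches the total).
    correct_log_bias : bool, default False
        Apply the lognormal back-transformation factor to log-scale
        equations that report a residual mean square.

    Attributes
    ----------
    envelopes_ : dict
        ``envelopes_[species][component]`` — leaf envelopes in kg C.
    total_envelopes_ : dict
        ``total_envelopes_[species]`` — terminal total-tree envelope.
    intermediates_ : dict
        Every roadmap node's envelope, per species.
    excluded_ : list of (equation, reason)
        Catalog records rejected by the inclusion rules.

    Examples
    --------
    >>> from treecarb.synthetic import TrueAllometry, LibrarySpec, generate_catalog
    >>> truth = TrueAllometry.default(["Pseudotsuga menziesii"])
    >>> cat, dens = generate_catalog(truth, LibrarySpec(), seed=7)
    >>> model = CarbonEnvelopeModel(approach=2).fit(cat, densities=dens)
    >>> env = model.total_envelopes_["Pseudotsuga menziesii"]
    >>> bool((env.lower <= env.upper).all())
    True
    """

    def __init__(
        self,
        *,
        approach: int = 2,
        correlation: str = "positive",
        carbon_fraction_min: float = 0.48,
        carbon_fraction_max: float = 0.52,
        grid_min: int = 3,
        grid_max: int = 66,
        roadmap: Roadmap | None = None,
        crown_truncation_dbh=None,
        apply_inclusion: bool = True,
        skip_missing_alternatives: bool = True,
        correct_log_bias: bool = False,
    ):
        self.approach = approach
        self.correlation = correlation
        self.carbon_fraction_min = carbon_fraction_min
        self.carbon_fraction_max = carbon_fraction_max
        self.grid_min = grid_min
        self.grid_max = grid_max
        self.roadmap = roadmap
        self.crown_truncation_dbh = crown_truncation_dbh
        self.apply_inclusion = apply_inclusion
        self.skip_missing_alternatives = skip_missing_alternatives
        self.correct_log_bias = correct_log_bias

    # ------------------------------------------------------------------
    def fit(
        self,
        X: Sequence[AllometricEquation],
        y=None,
        *,
        densities: Sequence[DensityRecord] | None = None,
        height_params: Mapping[str, HeightParams] | None = None,
    ):
        """Build per-species total-tree carbon envelopes from a catalog.

        ``height_params`` defaults to the packaged NWOR height fits for
        species they cover; species needing heights but lacking
        parameters raise.
        """
        catalog = list(X)
        if not catalog:
            raise ValueError("empty equation catalog")
        if self.apply_inclusion:
            included, self.excluded_ = apply_inclusion_rules(catalog)
            for eq, reason in self.excluded_:
                logger.info("excluded %s: %s", eq.id, reason)
        else:
            included, self.excluded_ = catalog, []
        if not included:
            raise ValueError("no equations pass the inclusion rules")
        if height_params is None:
            from .synthetic import nwor_height_params

            height_params = nwor_height_params()

        roadmap = self.roadmap if self.roadmap is not None else Roadmap.default()
        grid = np.arange(int(self.grid_min), int(self.grid_max) + 1, dtype=float)
        leaves = set(roadmap.leaves())
        species_list = sorted({e.species for e in included})

        self.roadmap_ = roadmap
        self.grid_ = grid
        self.envelopes_ = {}
        self.total_envelopes_ = {}
        self.intermediates_ = {}
        for sp in species_list:
            policy = ApproachPolicy(
                approach=self.approach,
                crown_truncation_dbh=self._truncation_map(sp),
            )
            comp_envs: dict[str, Envelope] = {}
            components = sorted({e.component for e in included if e.species == sp} & leaves)
            for comp in components:
                env = component_envelope(
                    included,
                    sp,
                    comp,
                    grid,
                    policy,
                    height_params=height_params.get(sp),
                    densities=densities,
                    correct_log_bias=self.correct_log_bias,
                )
                if env.units != UNITS_BIOMASS:
                    raise ValueError(
                        f"{sp}/{comp}: envelope is in {env.units!r}; supply a density "
                        "table to reach biomass before carbon conversion"
                    )
                comp_envs[comp] = biomass_to_carbon(
                    env, self.carbon_fraction_min, self.carbon_fraction_max
                )
            if not comp_envs:
                logger.warning("no roadmap-leaf equations for %s; species skipped", sp)
                continue
            total, inter = total_tree_envelope(
                roadmap,
                comp_envs,
                self.correlation,
                strict=not self.skip_missing_alternatives,
            )
            n_undef = int((~total.defined).sum())
            if n_undef:
                logger.info(
                    "%s: total-tree envelope undefined at %d of %d classes",
                    sp,
                    n_undef,
                    total.grid.size,
                )
            self.envelopes_[sp] = comp_envs
            self.total_envelopes_[sp] = total
            self.intermediates_[sp] = inter
        if not self.total_envelopes_:
            raise ValueError("no species could be assembled to a total-tree envelope")
        return self

    def _truncation_map(self, species: str):
        t = self.crown_truncation_dbh
        if self.approach != 3:
            return None
        if t is None:
            # default: middle of the regional DBH range
            return {species: float((self.grid_min + self.grid_max) // 2)}
        if isinstance(t, Mapping):
            default = float((self.grid_min + self.grid_max) // 2)
            return {species: float(t.get(species, default))}
        return {species: float(t)}

    # ------------------------------------------------------------------
    def predict(self, X: pd.DataFrame) -> RegionalEstimate:
        """Apply fitted total-tree envelopes to an inventory tree list."""
        if not hasattr(self, "total_envelopes_"):
            raise AttributeError("model is not fitted")
        return regional_estimate(X, self.total_envelopes_)
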