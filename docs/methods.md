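# Methods

## The problem

Live-tree carbon for a region is usually estimated by applying published
allometric regressions — biomass or volume as a function of diameter at
breast height (DBH) and sometimes height — to inventory tree lists, then
scaling by expansion factors.  For most species several equations can be
plausibly justified as locally applicable, and they disagree.  The
spread of estimates attributable solely to that choice is
*model-selection uncertainty*; unlike sampling, measurement or
regression error it is systematic, cannot be averaged away over trees,
and is rarely reported.  treecarb quantifies it by sensitivity analysis:
rather than pick one model, it carries the full interval of predictions
through every stage of the calculation.

## Prediction envelopes

For each species × component × 1-cm DBH class, the *prediction envelope*
is the interval between the lowest and highest predictions over all
admissible equations.  Volume equations contribute two biomass
candidates each (prediction × lowest and × highest published wood
density for that species/component) before the min/max.  Envelopes carry
a per-class coverage mask and the ids of the bounding equations.

Admissibility is governed by three extrapolation policies:

* **approach 1** — every equation over the whole grid, no corrections;
  negative predictions are retained.  Deliberately worst-case: it shows
  what uncritical extrapolation costs.
* **approach 2** — each equation only within its developmental DBH range
  (the range of the trees it was fit to).  Classes with no in-range
  equation are undefined; where only one equation is in range the
  envelope collapses, which *understates* uncertainty.
* **approach 3** — extrapolation passed through an ordered modification
  list, by default `[clip-negative, crown-truncation]`.  Crown
  truncation holds crown-component (branches, foliage, live-crown)
  predictions constant above a species-specific DBH — crown mass
  plateaus at maturity — defaulting to the middle of the regional DBH
  range (54 cm is the shipped value for red alder; other species'
  modifications start above the 3–66 cm comparison window).

Equations enter the candidate pool only if they pass the inclusion
screen: DBH/height predictors only; a reported developmental range
(waivable per record for inventory-programme workhorse equations);
stump height in {10, 15, 30} cm; extends to the stem top.  Each
exclusion carries exactly one machine-readable reason.

Log-scale regressions are exponentiated without back-transformation
correction by default, matching common (largely uncorrected) practice in
the compiled libraries; the standard lognormal factor `exp(mse_log/2)`
is available as an opt-in flag where the residual mean square is
reported.

## Carbon conversion

Biomass envelope minima are multiplied by 0.48 and maxima by 0.52,
bracketing the measured spread of carbon content (≈ 50 ± 2% of dry
mass).  For a point biomass value this forces a relative half-width of
(0.52 − 0.48)/(0.52 + 0.48) = 4% exactly.  When a bound is negative
(possible under approach 1) the conversion takes the min/max over the
factor pair per bound, which is identical to the simple rule on positive
intervals and keeps lower ≤ upper in general; the same guard applies to
the density conversion.

## Aggregation roadmap and correlation modes

Totals are assembled along a DAG of components whose processing steps
are addition (+) and comparison (OR).  The shipped default is

    stem wood + stem bark                  -> bole
    branches total + foliage               -> crown
    crown OR live crown (direct)           -> live crown f
    bole + live crown f                    -> aboveground
    aboveground OR aboveground total       -> aboveground f
    aboveground f + roots coarse           -> total tree

Adding intervals requires an assumption about how components co-vary
within a tree:

* **positive** correlation: `[la,ua] + [lb,ub] = [la+lb, ua+ub]` —
  extremes co-occur, widest sums;
* **negative** correlation: the sum is the interval between the two
  cross-pairings `la+ub` and `ua+lb`, width `|wa − wb|` — allocation to
  one component at the expense of another.  Never wider than the
  positive sum, typically roughly halving aggregate widths.

Neither is claimed realistic; they bracket the possibilities.
Negative-mode addition is not associative, so ADD steps fold
left-to-right in the roadmap's declared order, recorded in output
metadata.  OR retains the outer bounds over the defined alternatives
(per-class union): alternative pathways are evidence about the same
quantity, and the envelope philosophy keeps the outermost predictions.
Under positive correlation the folded total provably equals the
exhaustive min/max over every pathway × equation-choice combination
(tested by enumeration on small catalogs).

Strictly, every roadmap leaf needs an envelope; the model front-end
relaxes this the way a real assessment must (not every species has
equations for every pathway): an OR drops alternatives with no
envelope, an ADD with a missing input marks its output unavailable, and
only a species with *no* route to the total is an error.

## Regional scaling and the uncertainty metric

Each inventory record (species, DBH, expansion factor) is mapped to its
1-cm class (nearest integer); the species bound is the
expansion-weighted sum of envelope bounds, reported in Tg C (10⁹ kg).
Species minima/maxima sum exactly to the regional bounds.  Uncertainty
is everywhere *half the range as a percent of the midpoint*:

    U% = 100 · ((hi − lo)/2) / ((hi + lo)/2)

The midpoint is a point of comparison, not a claim about the most
likely value.  Printed percents use round-half-away-from-zero; full
precision is kept internally.  A species whose approach-1 midpoint
falls to or below zero gets `NaN` rather than a meaningless percent.
Species shares are `half-width / Σ half-widths` and
`midpoint / Σ midpoints`.

## Height model

Standard equations need height, which the tree list lacks, so heights
come from the Chapman–Richards curve `h = b0·(1 − exp(b1·d))^b2`
(`b0` asymptotic maximum height in m, `b1 < 0` steepness per cm, `b2`
curvature).  `h(0) = 0`: no breast-height offset is added.  Fitting is
nonlinear least squares on (DBH class, mean height) pairs weighted by
DBH⁻¹, with the fixed start `(1.05·max h, −0.02, 1.0)` and box
constraints keeping the parameter signs admissible; non-convergence
raises.  Fitted northwest-Oregon parameters for the five target species
ship as a fixture (e.g. Douglas fir: 63.054, −0.016, 1.0711; at 50 cm
this predicts 33.3 m).

## Auxiliary analyses

* **Subdivision**: per class, the total-tree envelope is cut into k
  equal-width bands and the class's trees into k equal groups (remainder
  trees to the leading groups, in index order).  With divisible groups
  the regional uncertainty ratio is exactly 1/k — the gain available if
  equations could be correctly assigned to subpopulations.
* **Developmental-range distance**: equations are classed per target DBH
  (20/60/100 cm) as spanning it, ending at or below half of it, or
  starting at or above twice it, and each class evaluated at the
  target; distant classes give wider, shifted prediction ranges.
* **DBH measurement error**: ±2% of diameter read as a 95% CI
  (`sd = 0.02·D/1.96`), propagated by the delta method through a
  DBH-only equation and aggregated as independent per-tree errors,
  `SE = sqrt(Σ (e·SE_tree)²)`.  Independence makes this term tiny next
  to model selection.
* **Single-source estimates**: one complete equation set per component,
  a flat 50% carbon fraction, producing a point total that by
  construction lies inside the positive approach-1 envelope of any
  catalog containing the set.
* **Form agreement**: spreads of DBH-only versus DBH+height predictions
  along D, H and D²H axes.  The table is the diagnostic; no convergence
  is asserted (adding height does not, in practice, make equations
  agree more).

## Synthetic study conditions

The generators replace the proprietary inventory and the hand-compiled
equation library with statistically analogous inputs:

* **Truth**: per species, leaf-component power laws `a·D^b`
  (stem wood 0.030·D^2.65, stem bark 0.0060·D^2.55, branches
  0.012·D^2.30, foliage 0.025·D^1.80, coarse roots 0.014·D^2.45, scale
  jittered ±25% per species), additive by construction; true stem
  densities near 450–520 kg m⁻³.
* **Libraries**: each synthetic equation refits the truth on
  log-normally noised pseudodata (default sd 0.15, a typical allometric
  residual) over a sampled developmental range.  Ranges skew toward
  small start diameters with a long upper tail, as published equations
  do; one equation per component always spans the full 3–250 cm domain
  (a log-log "workhorse", so approach 2 has full coverage under default
  conditions).  Form mix defaults to 40% power / 40% log-log / 20%
  combined-variable, with combined-variable drawn only for stem
  components — D²H is a stem-volume variable and fits crown/root power
  laws pathologically.  Densities are jittered within ±10% of truth.
  Equations default to biomass response; `volume_fraction` routes stem
  wood through the density table.
* **Inventories**: DBH ~ Weibull(shape 1.3, scale 18 cm) truncated to
  3–66 cm (right-skewed; the range holding the bulk of the target-species
  trees), lognormal expansion factors, species mix mirroring the five
  target species' prevalence (55/22/13/5/5%).

Everything derives from one integer seed.  What the generators do *not*
emulate: spatial/plot structure, ownership strata, real equation-form
idiosyncrasies (stump-height variants, crown-part taxonomies),
between-component residual correlation.  Passing tests therefore
demonstrate the arithmetic and its laws, and a qualitatively faithful
response to library heterogeneity (approach 1 widest, approach 2
narrowest, negative correlation narrower) — not the regional magnitudes
of any particular real inventory, which depend on the real library and
tree list.

## Numerical choices

* Grid: integer 1-cm class labels, default 3–66; the class label itself
  is the DBH input (no midpoint offset); trees map to the nearest label.
* Envelope bounds at a class are exact min/max over candidates; no
  smoothing across classes.
* Height fit tolerances 1e-14 (recovers noiseless parameters to ~1e-9
  relative); reproducible from the fixed start.
* Ties in provenance (two equations equal at a class) resolve to the
  first in catalog order.
* Subdivision with non-divisible counts assigns remainder trees to the
  leading sub-envelopes in index order.

## Known limitations

* OR-as-union discards central-tendency information across pathways by
  design; the envelope characterises the possible range, not a
  distribution, and is not amenable to probabilistic statements.
* Approach-3's modification list ships with the two rules named above;
  real assessments may need species-specific rules.
* The negative-correlation cross-pairing is one realisation of
  "allocation at the expense of other components"; other couplings
  would give different (never wider) sums.
* Envelope width under approach 2 shrinks where few equations are in
  range — scarcity masquerading as agreement.
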