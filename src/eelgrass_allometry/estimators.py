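"""Shoot- and campaign-level leaf growth rate estimators.

Four estimators of the mean shoot leaf-growth rate (g dry weight per day)
are implemented:

* **in situ** — total dry-weight gain of all leaves on a shoot divided by
  the interval length; needs weights at marking time, so it is available
  only for simulated data;
* **allometric** — the same sum with every biomass increment projected
  from leaf lengths through ``w = alpha * l**beta``;
* **leaf marking** — the biomass of tissue produced above the reference
  mark; three constructions are offered (see :func:`shoot_rate_marking`);
* **plastochrone** — the dry weight of the third-youngest leaf divided by
  the plastochrone interval ``p``.
"""

from __future__ import annotations

import numpy as np

from .allometry import biomass_increment_allometric, leaf_biomass
from .exceptions import (
    EmptyCampaignError,
    MissingThirdLeafError,
    UndefinedIntervalError,
    UnobservableRateError,
)
from .types import AllometricParams, Campaign, CampaignRates, ShootSample

__all__ = [
    "shoot_rate_in_situ",
    "shoot_rate_allometric",
    "shoot_rate_marking",
    "plastochrone_interval",
    "shoot_rate_plastochrone",
    "campaign_rates",
]

MARKING_MODES = ("formal", "field", "subtraction")


def shoot_rate_in_situ(shoot: ShootSample, delta_t: float) -> float:
    """Mean leaf growth rate of one shoot from measured dry weights:
    ``sum_j (w_j(t+dt) - w_j(t)) / dt``.

    Raises :class:`UnobservableRateError` when any leaf lacks a
    marking-time dry weight (the field situation); the allometric
    surrogate should be used instead.
    """
    if not shoot.has_start_weights:
        raise UnobservableRateError(
            f"shoot {shoot.shoot_id}: dry weights at marking are unobservable; "
            "use shoot_rate_allometric as the surrogate"
        )
    gain = sum(lf.dry_weight_end - lf.dry_weight_start for lf in shoot.leaves)
    return gain / delta_t


def shoot_rate_allometric(
    shoot: ShootSample, params: AllometricParams, delta_t: float
) -> float:
    """Allometric surrogate of the in situ rate: the per-leaf biomass
    increments projected from lengths, summed and divided by ``delta_t``."""
    total = sum(biomass_increment_allometric(lf, params) for lf in shoot.leaves)
    return total / delta_t


def _segment_scale(leaf, params: AllometricParams) -> float:
    """Measured-to-allometric weight ratio of a leaf, used to apportion
    its measured dry weight onto tissue segments."""
    if leaf.length_end <= 0:
        return 1.0
    return leaf.dry_weight_end / leaf_biomass(leaf.length_end, params)


def shoot_rate_marking(
    shoot: ShootSample,
    params: AllometricParams,
    delta_t: float,
    mode: str = "field",
) -> float:
    """Leaf-marking estimate of the shoot growth rate.

    mode="formal"
        ``sum_j alpha * dl_j**beta / dt`` — the allometric biomass of the
        length increments themselves (the new-tissue terms of the
        maturation decomposition).
    mode="field"
        the allometric rate computed on the above-mark increments only,
        i.e. below-mark (within-sheath) production is excluded; never
        exceeds the full allometric rate.
    mode="subtraction"
        the in situ rate minus the measured within-sheath production
        (each leaf's measured weight apportioned allometrically onto the
        below-mark part of its new tissue).  Requires marking-time
        weights, so it is available for simulated data only.
    """
    if mode not in MARKING_MODES:
        raise ValueError(f"unknown marking mode {mode!r}; expected one of {MARKING_MODES}")
    alpha, beta = params.alpha, params.beta
    if mode == "formal":
        total = sum(alpha * float(lf.increment) ** beta for lf in shoot.leaves)
        return total / delta_t
    if mode == "field":
        total = 0.0
        for lf in shoot.leaves:
            above = float(lf.increment_above_mark)
            total += leaf_biomass(lf.length_end, params) - leaf_biomass(
                lf.length_end - above, params
            )
        return total / delta_t
    # subtraction: in situ minus measured below-mark new tissue
    in_situ = shoot_rate_in_situ(shoot, delta_t)
    missed = 0.0
    for lf in shoot.leaves:
        below = float(lf.increment) - float(lf.increment_above_mark)
        if below > 0:
            missed += _segment_scale(lf, params) * alpha * below ** beta
    return in_situ - missed / delta_t


def plastochrone_interval(n_marked: int, new_leaves: int, delta_t: float) -> float:
    """Plastochrone interval (days per new leaf per shoot):
    ``n_marked * delta_t / new_leaves``.

    Raises :class:`UndefinedIntervalError` when no leaf appearance was
    observed.
    """
    if n_marked <= 0 or delta_t <= 0:
        raise ValueError("n_marked and delta_t must be positive")
    if new_leaves <= 0:
        raise UndefinedIntervalError(
            "no new leaves observed; plastochrone interval undefined"
        )
    return n_marked * delta_t / new_leaves


def shoot_rate_plastochrone(shoot: ShootSample, p: float) -> float:
    """Plastochrone estimate: dry weight of the rank-3 leaf divided by
    the plastochrone interval.

    Raises :class:`MissingThirdLeafError` (a skip-shoot signal) when the
    shoot holds fewer than three leaves.
    """
    if not p > 0:
        raise ValueError(f"plastochrone interval must be > 0, got {p}")
    third = shoot.leaf(3)
    if third is None:
        raise MissingThirdLeafError(
            f"shoot {shoot.shoot_id}: no rank-3 leaf ({shoot.n_leaves} leaves)"
        )
    return third.dry_weight_end / p


def campaign_rates(
    campaign: Campaign,
    params: AllometricParams,
    marking_mode: str = "auto",
) -> CampaignRates:
    """Per-shoot rate vectors and campaign means for all four methods.

    The plastochrone interval is taken from ``campaign.p`` when set and
    otherwise estimated from the campaign's leaf-appearance counts (with
    the retrieved-shoot count as the denominator, since new leaves can
    only be counted on retrieved shoots).  Shoots without a rank-3 leaf
    are excluded from the plastochrone mean (NaN in the vector); every
    mean averages over its contributing shoots.

    ``marking_mode="auto"`` resolves to "subtraction" when marking-time
    weights are available and "field" otherwise.
    """
    if campaign.n_retrieved == 0:
        raise EmptyCampaignError(f"campaign {campaign.date}: no shoots retrieved")
    p = campaign.p
    if p is None:
        p = plastochrone_interval(campaign.n_retrieved, campaign.new_leaves, campaign.delta_t)

    weights_ok = all(s.has_start_weights for s in campaign.shoots)
    if marking_mode == "auto":
        marking_mode = "subtraction" if weights_ok else "field"

    dt = campaign.delta_t
    n = campaign.n_retrieved
    lga_s = np.array([shoot_rate_allometric(s, params, dt) for s in campaign.shoots])
    lgm_s = np.array(
        [shoot_rate_marking(s, params, dt, mode=marking_mode) for s in campaign.shoots]
    )
    lgm_formal_s = np.array(
        [shoot_rate_marking(s, params, dt, mode="formal") for s in campaign.shoots]
    )
    lg_s = None
    lg = None
    if weights_ok:
        lg_s = np.array([shoot_rate_in_situ(s, dt) for s in campaign.shoots])
        lg = float(np.mean(lg_s))

    lgp_s = np.full(n, np.nan)
    lgp_a_s = np.full(n, np.nan)
    for i, s in enumerate(campaign.shoots):
        third = s.leaf(3)
        if third is None:
            continue
        lgp_s[i] = third.dry_weight_end / p
        lgp_a_s[i] = leaf_biomass(third.length_end, params) / p
    eligible = ~np.isnan(lgp_s)
    if not eligible.any():
        raise EmptyCampaignError(
            f"campaign {campaign.date}: no shoot holds a rank-3 leaf"
        )

    return CampaignRates(
        delta_t=dt,
        p=float(p),
        lg_s=lg_s,
        lga_s=lga_s,
        lgm_s=lgm_s,
        lgp_s=lgp_s,
        lgm_formal_s=lgm_formal_s,
        lgp_allometric_s=lgp_a_s,
        lg=lg,
        lga=float(np.mean(lga_s)),
        lgm=float(np.mean(lgm_s)),
        lgp=float(np.mean(lgp_s[eligible])),
        marking_mode=marking_mode,
        n_plastochrone_excluded=int(n - eligible.sum()),
    )
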