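"""Bias algebra relating the plastochrone, marking and in situ rates.

For a shoot with a rank-3 leaf the allometric shoot rate splits exactly as

    Lga_s = Csap * Lgp_s^a + Rsap,

where ``Csap = delta_3 * p / dt``, ``Lgp_s^a`` is the plastochrone rate
built from the *allometric* third-leaf biomass, and ``Rsap`` collects the
growth of every other leaf.  Averaging over shoots gives the campaign
identity ``Lga = Cap * Lgp^a + Bap`` with ``Cap`` the plastochrone-rate
weighted mean of the ``Csap``.  The same algebra with the new-tissue
terms of the maturation decomposition links the formal marking rate:
``Lgm_formal_s = Csap * Lgp_s^a + Rsmp`` with ``Rsmp = Rsap - Rsma``.

These identities are exact whenever dry weights are exact allometric
transforms of lengths; on noisy data the residuals quantify the
allometric estimation error and are reported, not enforced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .allometry import delta_factor, growth_decomposition, leaf_biomass
from .estimators import campaign_rates
from .exceptions import MissingThirdLeafError, UndefinedCoefficientError
from .types import (
    AllometricParams,
    Campaign,
    CampaignBias,
    CampaignRates,
    ShootDecomposition,
    ShootSample,
)

__all__ = [
    "shoot_decomposition",
    "campaign_bias",
    "identity_audit",
    "AuditReport",
]


def shoot_decomposition(
    shoot: ShootSample,
    params: AllometricParams,
    p: float,
    delta_t: float,
) -> ShootDecomposition:
    """Per-shoot terms of the bias algebra.

    Biomasses inside the remainders are allometric transforms of the
    retrieval lengths, so the decomposition identities hold exactly by
    construction.  Raises :class:`MissingThirdLeafError` when the shoot
    has no rank-3 leaf.
    """
    third = shoot.leaf(3)
    if third is None:
        raise MissingThirdLeafError(
            f"shoot {shoot.shoot_id}: no rank-3 leaf; cannot decompose"
        )
    beta = params.beta
    delta3 = delta_factor(third.increment, third.length_end, beta)
    csap = delta3 * p / delta_t

    rsap = 0.0
    rsma = 0.0
    for lf in shoot.leaves:
        _, maturation = growth_decomposition(lf, params)
        rsma += maturation
        if lf.rank != 3:
            delta_j = delta_factor(lf.increment, lf.length_end, beta)
            rsap += delta_j * leaf_biomass(lf.length_end, params)
    rsap /= delta_t
    rsma /= delta_t

    return ShootDecomposition(
        shoot_id=shoot.shoot_id,
        csap=float(csap),
        rsap=float(rsap),
        rsma=float(rsma),
        rsmp=float(rsap - rsma),
        lgp_allometric=float(leaf_biomass(third.length_end, params) / p),
    )


def campaign_bias(
    campaign: Campaign,
    rates: CampaignRates,
    decomps: Sequence[ShootDecomposition],
) -> CampaignBias:
    """Campaign-level bias terms and the bounds on the plastochrone bias.

    ``cap`` is the ``Lgp_s``-weighted mean of the ``csap`` (weights are
    the allometric per-shoot plastochrone rates, matching the exact
    identity); ``bap`` and ``bmp`` are the plain means of ``rsap`` and
    ``rsmp`` over the contributing shoots.  The direct biases
    ``bp = Lg - Lgp``, ``ba = Lg - Lga`` and ``bm = Lg - Lgm`` are
    computed from the campaign means when the in situ rate is available.

    The bounds ``blap = bap - Lgp^a`` and ``bp_upper = blap +
    (p/dt) * Lgp^a`` are consequences of ``0 <= Cap <= p/dt`` and
    therefore constrain the allometrically coherent plastochrone bias
    ``bp_allometric = Lga - Lgp^a`` (restricted to the contributing
    shoots); the direct ``bp`` obeys them only insofar as dry weights
    follow the allometric law, which is how the derivation obtains them.
    """
    if not decomps:
        raise MissingThirdLeafError(
            f"campaign {campaign.date}: no shoot contributes a decomposition"
        )
    csap = np.array([d.csap for d in decomps])
    lgp_a = np.array([d.lgp_allometric for d in decomps])
    wsum = lgp_a.sum()
    if wsum <= 0:
        raise UndefinedCoefficientError(
            f"campaign {campaign.date}: all plastochrone rates vanish; Cap undefined"
        )
    cap = float(np.sum(csap * lgp_a) / wsum)
    n = len(decomps)
    bap = float(np.mean([d.rsap for d in decomps]))
    bmp = float(np.mean([d.rsmp for d in decomps]))

    bp = ba = bm = rswa = None
    if rates.lg is not None:
        bp = rates.lg - rates.lgp
        ba = rates.lg - rates.lga
        bm = rates.lg - rates.lgm
        rswa = float(np.mean(np.abs(rates.lg_s - rates.lga_s)))

    # allometric side: means restricted to the contributing shoots
    by_id = {d.shoot_id: d for d in decomps}
    lga_r = float(
        np.mean(
            [rates.lga_s[i] for i, s in enumerate(campaign.shoots) if s.shoot_id in by_id]
        )
    )
    lgp_a = float(np.mean(lgp_a))
    bp_allometric = lga_r - lgp_a
    blap = bap - lgp_a
    bp_upper = blap + (rates.p / rates.delta_t) * lgp_a
    return CampaignBias(
        cap=cap, bap=bap, bmp=bmp, bp=bp, ba=ba, bm=bm,
        blap=float(blap), bp_upper=float(bp_upper),
        bp_allometric=float(bp_allometric), rswa=rswa,
    )


@dataclass(frozen=True)
class AuditReport:
    """Maximum absolute residuals of the decomposition identities.

    All residuals are in g/day.  On data whose dry weights are exact
    allometric transforms of lengths every residual is zero to machine
    precision; on noisy data ``rswa_mean``/``ba`` quantify the
    allometric estimation error and the identity residuals stay at
    machine precision because both sides are built from lengths.
    """

    max_shoot_residual: float
    campaign_residual: float
    max_marking_residual: float
    campaign_marking_residual: float
    rswa_mean: Optional[float]
    ba: Optional[float]
    n_shoots_audited: int


def identity_audit(
    campaign: Campaign,
    params: AllometricParams,
    rates: Optional[CampaignRates] = None,
) -> AuditReport:
    """Audit the shoot-level, campaign-level and marking identities on
    one campaign, returning the maximum absolute residuals.

    Campaign-level identities are evaluated over the shoots that hold a
    rank-3 leaf (the only ones the algebra covers).
    """
    if rates is None:
        rates = campaign_rates(campaign, params)
    dt, p = rates.delta_t, rates.p

    decomps = []
    idx = []
    for i, shoot in enumerate(campaign.shoots):
        try:
            decomps.append(shoot_decomposition(shoot, params, p, dt))
            idx.append(i)
        except MissingThirdLeafError:
            continue
    idx = np.asarray(idx, dtype=int)
    csap = np.array([d.csap for d in decomps])
    rsap = np.array([d.rsap for d in decomps])
    rsmp = np.array([d.rsmp for d in decomps])
    lgp_a = np.array([d.lgp_allometric for d in decomps])

    lga_s = rates.lga_s[idx]
    lgm_f = rates.lgm_formal_s[idx]
    shoot_resid = np.abs(lga_s - (csap * lgp_a + rsap))
    marking_resid = np.abs(lgm_f - (csap * lgp_a + rsmp))

    bias = campaign_bias(campaign, rates, decomps)
    lga_mean = float(np.mean(lga_s))
    lgm_mean = float(np.mean(lgm_f))
    lgp_a_mean = float(np.mean(lgp_a))
    campaign_resid = abs(lga_mean - (bias.cap * lgp_a_mean + bias.bap))
    campaign_marking_resid = abs(lgm_mean - (bias.cap * lgp_a_mean + bias.bmp))

    rswa_mean = None
    ba = None
    if rates.lg is not None:
        rswa_mean = float(np.mean(np.abs(rates.lg_s - rates.lga_s)))
        ba = rates.lg - rates.lga

    return AuditReport(
        max_shoot_residual=float(shoot_resid.max()),
        campaign_residual=float(campaign_resid),
        max_marking_residual=float(marking_resid.max()),
        campaign_marking_residual=float(campaign_marking_resid),
        rswa_mean=rswa_mean,
        ba=ba,
        n_shoots_audited=len(decomps),
    )
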