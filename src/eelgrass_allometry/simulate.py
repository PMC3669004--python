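"""Synthetic shoot-marking campaign generator.

The generator emulates the structure of a biweekly eelgrass marking
study: on each campaign ~40 shoots are marked, a fraction is lost before
retrieval, and every retrieved shoot yields per-leaf lengths at both
endpoints, the above-mark length increment, and dry weights.

Mechanisms (all parameters in :class:`SimulationConfig`):

* **Leaf demography.**  Leaves appear on a plastochrone clock: a shoot
  with phase ``u`` produces ``floor(dt/p + u)`` new leaves over the
  interval, so the expected appearance rate is ``dt/p``.  Ranks count
  from the youngest leaf outward; leaf ages follow from rank and ``p``.
* **Elongation.**  A leaf born on day ``b`` grows as
  ``l(a) = L * (1 - exp(-a/tau))`` with per-leaf asymptote ``L`` set by
  the seasonal cycle at birth and a lognormal shoot-size factor.  With
  ``tau`` comparable to the leaf lifespan, elongation declines with rank
  but every leaf keeps growing — which is what makes the single-leaf
  plastochrone proxy an underestimate.  An interval-level lognormal
  factor (light/temperature forcing) scales each campaign's elongation.
* **Seasonality.**  A sinusoid (period 365 d) modulates the leaf
  asymptote (peak midsummer) and the true plastochrone interval; the
  appearance cycle leads the elongation cycle by ``p_phase_lag_days``
  (leaf initiation peaks in spring).  Campaign-level lognormal jitter
  and per-shoot heterogeneity are added to ``p``, and field recognition
  of "new" leaves suffers symmetric per-shoot miscounts.
* **Dry weights.**  ``w = alpha * l**beta * h(age) * exp(eps)`` with one
  noise draw per leaf (shared by the two endpoints) and an age-dependent
  tissue factor ``h`` combining the lower weight-to-length ratio of
  immature tissue (deficit ``c`` recovering over ``tau_d``) with a slow,
  saturating thickening of maturing blades (rate ``m`` over ``tau_m``,
  sharing the metabolic forcing of elongation).  Length-based projection
  cannot see the thickening flux, which is what gives the allometric
  method its positive bias on field-like data.  With ``sigma = 0``,
  ``c = 0`` and ``m = 0`` (see :meth:`SimulationConfig.exact_allometry`)
  weights are exact allometric transforms and every decomposition
  identity holds at machine precision.
* **Sheath.**  The reference mark sits at the top of the sheath; leaves
  that had not yet emerged at marking contribute only the part of their
  growth above the sheath, so below-mark production is missed by the
  marking method.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, fields as _dc_fields, replace
from typing import Optional, Sequence

import numpy as np

from .exceptions import ValidationError
from .types import AllometricParams, Campaign, LeafObservation, ShootSample

__all__ = [
    "SimulationConfig",
    "CampaignTruth",
    "SimulatedCampaign",
    "simulate_campaigns",
    "true_campaign_rate",
    "allometry_sample",
    "export_fixtures",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and biology parameters of the synthetic meadow.

    Defaults describe a biweekly survey of ~40 marked shoots per campaign
    over 16 months, with site-reference allometric parameters typical of
    a temperate estuarine meadow (alpha = 2e-5 g/mm^beta, beta = 1.3).
    """

    n_campaigns: int = 35
    shoots_per_campaign: int = 40
    delta_t: float = 14.0
    start_date: _dt.date = _dt.date(1999, 3, 1)
    leaves_at_marking: tuple[int, int] = (4, 4)
    alpha: float = 2e-5
    beta: float = 1.3
    l_max_mm: float = 600.0
    seasonal_amplitude: float = 0.15
    peak_day_of_year: int = 196
    elongation_tau_days: float = 60.0
    growth_jitter_sigma: float = 0.10
    p_mean_days: float = 14.5
    p_amplitude_days: float = 4.5
    p_phase_lag_days: float = 80.0
    p_jitter_sigma: float = 0.15
    p_shoot_sigma: float = 0.06
    sheath_mean_mm: float = 35.0
    sheath_sd_mm: float = 7.0
    sheath_min_mm: float = 15.0
    density_deficit: float = 0.4
    density_tau_days: float = 15.0
    maturation_gain_per_day: float = 0.009
    maturation_tau_days: float = 25.0
    miscount_prob: float = 0.3
    shoot_size_sigma: float = 0.25
    weight_noise_sigma: float = 0.2
    retrieval_loss: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if isinstance(self.start_date, str):
            object.__setattr__(self, "start_date", _dt.date.fromisoformat(self.start_date))
        if isinstance(self.leaves_at_marking, list):
            object.__setattr__(self, "leaves_at_marking", tuple(self.leaves_at_marking))
        for name in ("n_campaigns", "shoots_per_campaign", "delta_t", "alpha",
                     "beta", "l_max_mm", "elongation_tau_days", "p_mean_days",
                     "density_tau_days", "sheath_min_mm", "maturation_tau_days"):
            if not getattr(self, name) > 0:
                problems.append(f"{name} must be > 0")
        lo, hi = self.leaves_at_marking
        if not (1 <= lo <= hi):
            problems.append("leaves_at_marking must be a well-ordered range >= 1")
        if not (0 <= self.retrieval_loss < 1):
            problems.append("retrieval_loss must lie in [0, 1)")
        if not (0 <= self.seasonal_amplitude < 1):
            problems.append("seasonal_amplitude must lie in [0, 1)")
        if not (0 <= self.p_amplitude_days < self.p_mean_days):
            problems.append("p_amplitude_days must lie in [0, p_mean_days)")
        if not (0 <= self.density_deficit < 1):
            problems.append("density_deficit must lie in [0, 1)")
        if self.maturation_gain_per_day < 0:
            problems.append("maturation_gain_per_day must be >= 0")
        if not (0 <= self.miscount_prob < 1):
            problems.append("miscount_prob must lie in [0, 1)")
        for name in ("weight_noise_sigma", "p_jitter_sigma", "shoot_size_sigma",
                     "sheath_sd_mm", "growth_jitter_sigma", "p_shoot_sigma"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if problems:
            raise ValidationError("invalid SimulationConfig: " + "; ".join(problems))

    @property
    def true_params(self) -> AllometricParams:
        return AllometricParams(alpha=self.alpha, beta=self.beta)

    def exact_allometry(self, **overrides) -> "SimulationConfig":
        """A copy of this config in the exact-allometry regime: no weight
        noise and no age-dependent tissue density, so every dry weight
        equals its allometric transform."""
        return replace(
            self,
            weight_noise_sigma=0.0,
            density_deficit=0.0,
            maturation_gain_per_day=0.0,
            **overrides,
        )

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in _dc_fields(cls))


@dataclass(frozen=True)
class CampaignTruth:
    """Ground-truth channel of one simulated campaign."""

    p_true: float
    lg_s: np.ndarray          # per-shoot in situ rates, g/day
    lg: float                 # campaign mean in situ rate, g/day
    below_mark_rate: float    # campaign mean below-mark production, g/day
    new_leaves_per_shoot: float


@dataclass(frozen=True)
class SimulatedCampaign:
    campaign: Campaign
    truth: CampaignTruth


def _season(day: float, cfg: SimulationConfig) -> float:
    doy = day % 365.0
    return 1.0 + cfg.seasonal_amplitude * math.cos(
        2.0 * math.pi * (doy - cfg.peak_day_of_year) / 365.0
    )


def _p_seasonal(day: float, cfg: SimulationConfig) -> float:
    # the leaf-appearance cycle leads the elongation cycle (appearance
    # peaks in spring, elongation midsummer), hence the phase lag
    doy = day % 365.0
    return cfg.p_mean_days - cfg.p_amplitude_days * math.cos(
        2.0 * math.pi * (doy - (cfg.peak_day_of_year - cfg.p_phase_lag_days)) / 365.0
    )


def _length(age: float, l_asym: float, tau: float) -> float:
    if age <= 0:
        return 0.0
    return l_asym * (1.0 - math.exp(-age / tau))


def simulate_campaigns(config: SimulationConfig) -> list[SimulatedCampaign]:
    """Generate the full campaign sequence; deterministic given the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    alpha, beta = cfg.alpha, cfg.beta
    tau = cfg.elongation_tau_days
    sims: list[SimulatedCampaign] = []

    for c in range(cfg.n_campaigns):
        mark_day = c * cfg.delta_t
        retrieval_date = cfg.start_date + _dt.timedelta(days=round((c + 1) * cfg.delta_t))
        p_true = _p_seasonal(mark_day, cfg)
        if cfg.p_jitter_sigma > 0:
            p_true *= math.exp(rng.normal(0.0, cfg.p_jitter_sigma))
        # interval-specific environmental forcing (light/temperature)
        # scales elongation over this interval only
        growth_factor = 1.0
        if cfg.growth_jitter_sigma > 0:
            growth_factor = math.exp(rng.normal(0.0, cfg.growth_jitter_sigma))

        retrieved = rng.random(cfg.shoots_per_campaign) >= cfg.retrieval_loss
        if retrieved.sum() < 1:       # degenerate configs: keep one shoot
            retrieved[0] = True

        shoots: list[ShootSample] = []
        lg_s: list[float] = []
        total_new = 0
        counted_new = 0
        below_mark_total = 0.0

        for i in range(cfg.shoots_per_campaign):
            # draws happen for every marked shoot so the stream is stable
            u = rng.random()
            size = math.exp(rng.normal(0.0, cfg.shoot_size_sigma))
            n0 = int(rng.integers(cfg.leaves_at_marking[0], cfg.leaves_at_marking[1] + 1))
            sheath = max(cfg.sheath_min_mm, rng.normal(cfg.sheath_mean_mm, cfg.sheath_sd_mm))
            # shoots differ in their individual plastochrone interval
            p_shoot = p_true
            if cfg.p_shoot_sigma > 0:
                p_shoot *= math.exp(rng.normal(0.0, cfg.p_shoot_sigma))
            k_new = int(math.floor(cfg.delta_t / p_shoot + u))
            n_total = n0 + k_new
            eps = rng.normal(0.0, cfg.weight_noise_sigma, size=n_total)
            if not retrieved[i]:
                continue

            leaves: list[LeafObservation] = []
            shoot_gain = 0.0
            shoot_below = 0.0
            for j in range(1, n_total + 1):  # rank 1 = youngest at retrieval
                if j <= k_new:
                    birth = mark_day + (1.0 - u) * p_shoot + (k_new - j) * p_shoot
                else:
                    birth = mark_day - ((j - k_new - 1) + u) * p_shoot
                a_start = mark_day - birth
                a_end = a_start + cfg.delta_t
                l_asym = size * cfg.l_max_mm * _season(birth, cfg)
                l_start = _length(a_start, l_asym, tau)
                inc = growth_factor * (_length(a_end, l_asym, tau) - l_start)
                l_end = l_start + inc
                if l_start >= sheath:
                    above = inc
                else:
                    above = max(0.0, l_end - sheath)

                noise = math.exp(eps[j - 1])

                # maturation shares the metabolic forcing of elongation
                m_leaf = (
                    cfg.maturation_gain_per_day * _season(mark_day, cfg) * growth_factor
                )

                def dens(age: float) -> float:
                    # immature tissue is lighter per unit length; blades
                    # keep thickening as they mature, saturating with age
                    if age <= 0:
                        return 1.0
                    deficit = 1.0 - cfg.density_deficit * math.exp(-age / cfg.density_tau_days)
                    gain = 1.0 + m_leaf * cfg.maturation_tau_days * (
                        1.0 - math.exp(-age / cfg.maturation_tau_days)
                    )
                    return deficit * gain

                w_start = alpha * l_start ** beta * dens(a_start) * noise
                w_end = alpha * l_end ** beta * dens(a_end) * noise
                shoot_gain += w_end - w_start
                below = inc - above
                if below > 0:
                    shoot_below += dens(a_end) * noise * alpha * below ** beta
                leaves.append(
                    LeafObservation(
                        rank=j,
                        length_start=l_start,
                        length_end=l_end,
                        increment=inc,
                        increment_above_mark=above,
                        dry_weight_end=w_end,
                        dry_weight_start=w_start,
                    )
                )
            shoots.append(ShootSample(shoot_id=f"c{c:02d}s{i:02d}", leaves=tuple(leaves)))
            lg_s.append(shoot_gain / cfg.delta_t)
            below_mark_total += shoot_below / cfg.delta_t
            total_new += k_new
            # recognising which leaves appeared after marking is
            # error-prone in the field: symmetric per-shoot miscounts
            k_counted = k_new
            if cfg.miscount_prob > 0:
                v = rng.random()
                if v < cfg.miscount_prob / 2:
                    k_counted = k_new + 1
                elif v < cfg.miscount_prob:
                    k_counted = max(0, k_new - 1)
            counted_new += k_counted

        n_ret = len(shoots)
        campaign = Campaign(
            date=retrieval_date,
            delta_t=cfg.delta_t,
            shoots=tuple(shoots),
            n_marked=cfg.shoots_per_campaign,
            new_leaves=max(counted_new, 1) if cfg.miscount_prob > 0 else total_new,
            p=None,
        )
        truth = CampaignTruth(
            p_true=float(p_true),
            lg_s=np.asarray(lg_s),
            lg=float(np.mean(lg_s)),
            below_mark_rate=below_mark_total / n_ret,
            new_leaves_per_shoot=total_new / n_ret,
        )
        sims.append(SimulatedCampaign(campaign=campaign, truth=truth))
    return sims


def true_campaign_rate(sim: SimulatedCampaign) -> float:
    """The exact campaign-mean in situ rate (g/day) from the ground-truth
    biomass increments — the reference all estimator biases are measured
    against."""
    return sim.truth.lg


def allometry_sample(
    n: int,
    params: AllometricParams,
    sigma: float,
    seed: int | np.random.Generator = 0,
    length_range: tuple[float, float] = (50.0, 600.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Length/weight pairs ``w = alpha * l**beta * exp(eps)`` with lengths
    uniform on ``length_range`` — the fixture for parameter-recovery
    studies."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = rng.uniform(*length_range, size=n)
    eps = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
    weights = params.alpha * lengths ** params.beta * np.exp(eps)
    return lengths, weights


def export_fixtures(sims: Sequence[SimulatedCampaign], path) -> dict:
    """Write the CSV leaf table, the campaign sidecar and a ground-truth
    sidecar under ``path``; returns the file paths.  Round-trips
    losslessly through :func:`eelgrass_allometry.io.read_leaf_table`."""
    from . import io as _io
    from pathlib import Path
    import pandas as pd

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    leaf_path = path / "leaves.csv"
    sidecar_path = path / "campaigns.csv"
    truth_path = path / "truth.csv"
    _io.write_leaf_table([s.campaign for s in sims], leaf_path, sidecar_path)
    pd.DataFrame(
        {
            "campaign_date": [s.campaign.date.isoformat() for s in sims],
            "p_true_days": [s.truth.p_true for s in sims],
            "lg_true_g_per_day": [s.truth.lg for s in sims],
            "below_mark_rate_g_per_day": [s.truth.below_mark_rate for s in sims],
        }
    ).to_csv(truth_path, index=False)
    return {"leaves": leaf_path, "campaigns": sidecar_path, "truth": truth_path}
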