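"""Bias algebra: per-shoot and campaign decompositions, bounds, and the
identity audit."""

import numpy as np
import pytest

from eelgrass_allometry import (
    AllometricParams,
    Campaign,
    ShootSample,
    campaign_bias,
    campaign_rates,
    identity_audit,
    shoot_decomposition,
)
from eelgrass_allometry.exceptions import MissingThirdLeafError
from eelgrass_allometry import SimulationConfig, simulate_campaigns

from conftest import make_leaf


def _linear_params():
    # beta = 1 makes delta = lambda = dl/l_end and biomass = alpha * l,
    # so decomposition terms can be written down by hand
    return AllometricParams(alpha=1.0, beta=1.0)


class TestShootDecomposition:
    def test_csap_is_delta3_times_p_over_dt(self):
        p_lin = _linear_params()
        # third leaf: delta_3 = 28/56 = 0.5
        shoot = ShootSample(
            "s",
            (make_leaf(1, 0, 10, params=p_lin), make_leaf(2, 5, 20, params=p_lin),
             make_leaf(3, 28, 56, params=p_lin)),
        )
        d = shoot_decomposition(shoot, p_lin, p=21.0, delta_t=14.0)
        assert d.csap == pytest.approx(0.5 * 21.0 / 14.0)

    def test_rsap_hand_value(self):
        """Leaves 1-2 with delta 0.5, 0.2 and end-biomasses 0.001, 0.002:
        Rsap = (0.5*0.001 + 0.2*0.002)/14."""
        p_lin = _linear_params()
        shoot = ShootSample(
            "s",
            (
                make_leaf(1, 0.0005, 0.001, params=p_lin),   # delta = 0.5
                make_leaf(2, 0.0016, 0.002, params=p_lin),   # delta = 0.2
                make_leaf(3, 0.003, 0.004, params=p_lin),
            ),
        )
        d = shoot_decomposition(shoot, p_lin, p=14.0, delta_t=14.0)
        assert d.rsap == pytest.approx((0.5 * 0.001 + 0.2 * 0.002) / 14.0, rel=1e-12)
        # beta = 1: no maturation, so Rsmp = Rsap
        assert d.rsma == pytest.approx(0.0, abs=1e-18)
        assert d.rsmp == pytest.approx(d.rsap, rel=1e-12)

    def test_rsap_zero_when_only_third_leaf_grew(self, params):
        shoot = ShootSample(
            "s",
            (make_leaf(1, 50, 50), make_leaf(2, 120, 120), make_leaf(3, 200, 260)),
        )
        d = shoot_decomposition(shoot, params, p=14.0, delta_t=14.0)
        assert d.rsap == 0.0
        assert d.csap > 0

    def test_shoot_identity(self, params, simple_shoot):
        """Lga_s = Csap * Lgp_s^a + Rsap exactly."""
        from eelgrass_allometry import shoot_rate_allometric

        d = shoot_decomposition(simple_shoot, params, p=11.0, delta_t=14.0)
        lga_s = shoot_rate_allometric(simple_shoot, params, 14.0)
        assert lga_s == pytest.approx(d.csap * d.lgp_allometric + d.rsap, rel=1e-12)

    def test_missing_third_leaf(self, params):
        shoot = ShootSample("s", (make_leaf(1, 0, 40),))
        with pytest.raises(MissingThirdLeafError):
            shoot_decomposition(shoot, params, p=14.0, delta_t=14.0)


class TestCampaignBias:
    def _campaign_of(self, shoots, p=14.0):
        return Campaign(date="1999-06-01", delta_t=14.0, shoots=tuple(shoots),
                        n_marked=len(shoots), new_leaves=len(shoots), p=p)

    def test_cap_of_constant_csap_is_that_constant(self, params):
        shoots = []
        for k, scale in enumerate([1.0, 0.6, 1.7]):
            shoots.append(
                ShootSample(
                    f"s{k}",
                    (
                        make_leaf(1, 0, 40 * scale),
                        make_leaf(2, 60 * scale, 90 * scale),
                        make_leaf(3, 100 * scale, 200 * scale),  # same lambda => same delta
                    ),
                )
            )
        camp = self._campaign_of(shoots)
        rates = campaign_rates(camp, params)
        decomps = [shoot_decomposition(s, params, rates.p, 14.0) for s in shoots]
        bias = campaign_bias(camp, rates, decomps)
        assert bias.cap == pytest.approx(decomps[0].csap, rel=1e-12)

    def test_cap_weighted_mean(self):
        """csap = 1 and 0.5 with equal plastochrone weights -> cap = 0.75."""
        p_lin = _linear_params()
        # equal third-leaf end lengths (equal Lgp^a weights), deltas 1 and 0.5
        s1 = ShootSample(
            "a", (make_leaf(1, 0, 10, params=p_lin), make_leaf(2, 0, 20, params=p_lin),
                  make_leaf(3, 0, 100, params=p_lin)))
        s2 = ShootSample(
            "b", (make_leaf(1, 0, 10, params=p_lin), make_leaf(2, 0, 20, params=p_lin),
                  make_leaf(3, 50, 100, params=p_lin)))
        camp = self._campaign_of([s1, s2])
        rates = campaign_rates(camp, p_lin)
        decomps = [shoot_decomposition(s, p_lin, 14.0, 14.0) for s in (s1, s2)]
        bias = campaign_bias(camp, rates, decomps)
        assert bias.cap == pytest.approx(0.75, rel=1e-12)

    def test_bounds_formulas_and_exact_identity(self, exact_sims, params):
        """On exact-allometry data: blap = bap - Lgp^a, the Eq-29-style
        reconstruction matches the direct bias, and blap <= Bp <= upper."""
        sim = exact_sims[5]
        rates = campaign_rates(sim.campaign, params)
        decomps = [
            shoot_decomposition(s, params, rates.p, rates.delta_t)
            for s in sim.campaign.shoots
        ]
        bias = campaign_bias(sim.campaign, rates, decomps)
        lgp_a = np.mean([d.lgp_allometric for d in decomps])
        assert bias.blap == pytest.approx(bias.bap - lgp_a, rel=1e-12)
        assert bias.bp_upper == pytest.approx(
            bias.blap + (rates.p / rates.delta_t) * lgp_a, rel=1e-12
        )
        # reconstruction (cap - 1) * Lgp^a + bap equals the coherent bias
        assert bias.bp_allometric == pytest.approx(
            (bias.cap - 1) * lgp_a + bias.bap, rel=1e-10
        )
        assert bias.blap - 1e-15 <= bias.bp_allometric <= bias.bp_upper + 1e-15

    def test_direct_biases_are_differences(self, exact_sims, params):
        sim = exact_sims[3]
        rates = campaign_rates(sim.campaign, params)
        decomps = [
            shoot_decomposition(s, params, rates.p, rates.delta_t)
            for s in sim.campaign.shoots
        ]
        bias = campaign_bias(sim.campaign, rates, decomps)
        assert bias.bp == pytest.approx(rates.lg - rates.lgp, rel=1e-12)
        assert bias.ba == pytest.approx(rates.lg - rates.lga, abs=1e-15)
        assert bias.bm == pytest.approx(rates.lg - rates.lgm, rel=1e-12)


class TestIdentityAudit:
    def test_exact_season_residuals_vanish(self, exact_sims, params):
        for sim in exact_sims[:8]:
            audit = identity_audit(sim.campaign, params)
            assert audit.max_shoot_residual < 1e-10
            assert audit.campaign_residual < 1e-10
            assert audit.max_marking_residual < 1e-10
            assert audit.campaign_marking_residual < 1e-10
            assert abs(audit.ba) < 1e-10

    def test_noisy_data_reports_positive_estimation_residuals(self, default_sims, params):
        audit = identity_audit(default_sims[0].campaign, params)
        # identities are built from lengths, so they still hold ...
        assert audit.max_shoot_residual < 1e-10
        # ... while the weight-side residuals are genuinely nonzero
        assert audit.rswa_mean > 0

    def test_single_shoot_campaign_identity_reduces_to_shoot(self, simple_campaign, params):
        audit = identity_audit(simple_campaign, params)
        assert audit.n_shoots_audited == 1
        assert audit.campaign_residual == pytest.approx(audit.max_shoot_residual, abs=1e-15)


class TestStructuralInequalities:
    def test_inequality_suite_on_default_season(self, default_sims, params):
        """0 <= Csap, Cap <= p/dt; Bap > 0; coherent Bp within bounds."""
        for sim in default_sims:
            rates = campaign_rates(sim.campaign, params)
            ratio = rates.p / rates.delta_t
            decomps = [
                shoot_decomposition(s, params, rates.p, rates.delta_t)
                for s in sim.campaign.shoots
            ]
            for d in decomps:
                assert -1e-12 <= d.csap <= ratio + 1e-9
                assert d.rsap >= 0
            bias = campaign_bias(sim.campaign, rates, decomps)
            assert -1e-12 <= bias.cap <= ratio + 1e-9
            assert bias.bap > 0
            assert bias.blap - 1e-12 <= bias.bp_allometric <= bias.bp_upper + 1e-12

    def test_long_interval_obstruction(self, params):
        """If dt > p then Csap < 1 for every shoot, hence Cap < 1."""
        cfg = SimulationConfig(seed=3)
        for sim in simulate_campaigns(cfg):
            rates = campaign_rates(sim.campaign, params)
            if rates.p >= rates.delta_t:
                continue
            decomps = [
                shoot_decomposition(s, params, rates.p, rates.delta_t)
                for s in sim.campaign.shoots
            ]
            assert all(d.csap < 1.0 for d in decomps)
            bias = campaign_bias(sim.campaign, rates, decomps)
            assert bias.cap < 1.0

    def test_rsmp_consistency_on_exact_data(self, exact_sims, params):
        """Rsap - Rsma = Rsmp and the formal marking identity holds."""
        from eelgrass_allometry import shoot_rate_marking

        sim = exact_sims[10]
        rates = campaign_rates(sim.campaign, params)
        for shoot in sim.campaign.shoots:
            d = shoot_decomposition(shoot, params, rates.p, rates.delta_t)
            assert d.rsmp == pytest.approx(d.rsap - d.rsma, rel=1e-12, abs=1e-18)
            lgm_f = shoot_rate_marking(shoot, params, rates.delta_t, mode="formal")
            assert lgm_f == pytest.approx(
                d.csap * d.lgp_allometric + d.rsmp, rel=1e-10, abs=1e-14
            )
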