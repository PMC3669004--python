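"""Shoot- and campaign-level growth rate estimators."""

import numpy as np
import pytest

from eelgrass_allometry import (
    AllometricParams,
    Campaign,
    ShootSample,
    campaign_rates,
    leaf_biomass,
    plastochrone_interval,
    shoot_rate_allometric,
    shoot_rate_in_situ,
    shoot_rate_marking,
    shoot_rate_plastochrone,
)
from eelgrass_allometry.exceptions import (
    EmptyCampaignError,
    MissingThirdLeafError,
    UndefinedIntervalError,
    UnobservableRateError,
)

from conftest import make_leaf


class TestInSitu:
    def test_hand_sum(self):
        shoot = ShootSample(
            "s",
            (
                make_leaf(1, 0, 50, weight_end=0.0015, weight_start=0.001),
                make_leaf(2, 0, 80, weight_end=0.003, weight_start=0.002),
            ),
        )
        assert shoot_rate_in_situ(shoot, 14.0) == pytest.approx(0.0015 / 14.0)

    def test_no_change_is_zero(self):
        shoot = ShootSample(
            "s", (make_leaf(1, 100, 100, weight_end=0.004, weight_start=0.004),)
        )
        assert shoot_rate_in_situ(shoot, 7.0) == 0.0

    def test_single_leaf_unit_interval(self):
        shoot = ShootSample(
            "s", (make_leaf(1, 0, 60, weight_end=0.0042, weight_start=0.0),)
        )
        assert shoot_rate_in_situ(shoot, 1.0) == pytest.approx(0.0042)

    def test_missing_start_weights_fail_loudly(self):
        shoot = ShootSample("s", (make_leaf(1, 0, 60, weight_end=0.004),))
        with pytest.raises(UnobservableRateError, match="surrogate"):
            shoot_rate_in_situ(shoot, 14.0)


class TestAllometric:
    def test_single_leaf_value(self, params):
        shoot = ShootSample("s", (make_leaf(1, 80.0, 100.0),))
        want = params.alpha * (100 ** 1.3 - 80 ** 1.3) / 14  # ~1.432e-4 g/day
        assert shoot_rate_allometric(shoot, params, 14.0) == pytest.approx(want, rel=1e-12)

    def test_matches_in_situ_on_exact_weights(self, simple_shoot, params):
        lga = shoot_rate_allometric(simple_shoot, params, 14.0)
        lg = shoot_rate_in_situ(simple_shoot, 14.0)
        assert lga == pytest.approx(lg, rel=1e-12)

    def test_zero_increments(self, params):
        shoot = ShootSample("s", (make_leaf(1, 90, 90), make_leaf(2, 200, 200)))
        assert shoot_rate_allometric(shoot, params, 14.0) == 0.0


class TestMarking:
    def test_formal_hand_value(self, params):
        shoot = ShootSample("s", (make_leaf(1, 80, 100), make_leaf(2, 190, 200)))
        want = params.alpha * (20.0 ** 1.3 + 10.0 ** 1.3) / 14  # ~9.87e-5 g/day
        got = shoot_rate_marking(shoot, params, 14.0, mode="formal")
        assert got == pytest.approx(want, rel=1e-12)

    def test_field_zero_when_all_growth_below_mark(self, params):
        shoot = ShootSample("s", (make_leaf(1, 10, 30, above=0.0),))
        assert shoot_rate_marking(shoot, params, 14.0, mode="field") == 0.0

    def test_field_equals_formal_for_wholly_new_leaf(self, params):
        # a leaf entirely above the mark: l_start = 0, increment = l_end
        shoot = ShootSample("s", (make_leaf(1, 0.0, 120.0),))
        field = shoot_rate_marking(shoot, params, 14.0, mode="field")
        formal = shoot_rate_marking(shoot, params, 14.0, mode="formal")
        assert field == pytest.approx(formal, rel=1e-12)

    def test_field_never_exceeds_allometric(self, params):
        rng = np.random.default_rng(7)
        for _ in range(200):
            l_end = rng.uniform(10, 500)
            l_start = l_end * rng.uniform(0, 1)
            inc = l_end - l_start
            above = inc * rng.uniform(0, 1)
            shoot = ShootSample("s", (make_leaf(1, l_start, l_end, above=above),))
            field = shoot_rate_marking(shoot, params, 14.0, mode="field")
            lga = shoot_rate_allometric(shoot, params, 14.0)
            assert field <= lga + 1e-15

    def test_subtraction_mode_needs_weights(self, params):
        shoot = ShootSample("s", (make_leaf(1, 0, 60, above=20.0),))
        with pytest.raises(UnobservableRateError):
            shoot_rate_marking(shoot, params, 14.0, mode="subtraction")

    def test_unknown_mode(self, simple_shoot, params):
        with pytest.raises(ValueError, match="unknown marking mode"):
            shoot_rate_marking(simple_shoot, params, 14.0, mode="sideways")


class TestPlastochroneInterval:
    @pytest.mark.parametrize(
        "n,new,dt,expected", [(40, 40, 14, 14.0), (20, 28, 14, 10.0), (1, 1, 21, 21.0)]
    )
    def test_values(self, n, new, dt, expected):
        assert plastochrone_interval(n, new, dt) == pytest.approx(expected)

    def test_no_appearance_is_undefined(self):
        with pytest.raises(UndefinedIntervalError):
            plastochrone_interval(40, 0, 14)


class TestPlastochroneRate:
    def test_third_leaf_over_p(self, params):
        w3 = leaf_biomass(100.0, params)  # ~0.0079621 g
        shoot = ShootSample(
            "s",
            (make_leaf(1, 0, 40), make_leaf(2, 0, 70), make_leaf(3, 90, 100, weight_end=w3)),
        )
        assert shoot_rate_plastochrone(shoot, 14.0) == pytest.approx(w3 / 14.0)

    def test_missing_third_leaf_skips(self, params):
        shoot = ShootSample("s", (make_leaf(1, 0, 40), make_leaf(2, 0, 70)))
        with pytest.raises(MissingThirdLeafError):
            shoot_rate_plastochrone(shoot, 14.0)


class TestCampaignRates:
    def test_single_shoot_means_equal_shoot_rates(self, simple_campaign, params):
        rates = campaign_rates(simple_campaign, params)
        assert rates.lg == pytest.approx(rates.lg_s[0])
        assert rates.lga == pytest.approx(rates.lga_s[0])
        assert rates.lgp == pytest.approx(rates.lgp_s[0])
        # exact allometric weights: in situ equals allometric, Ba = 0
        assert rates.lg == pytest.approx(rates.lga, rel=1e-12)

    def test_plastochrone_mean_averages_shoots(self, simple_shoot, params):
        other = ShootSample(
            "s2",
            tuple(
                make_leaf(lf.rank, lf.length_start * 0.5, lf.length_end * 0.5)
                for lf in simple_shoot.leaves
            ),
        )
        camp = Campaign(
            date="1999-03-15", delta_t=14.0, shoots=(simple_shoot, other),
            n_marked=2, new_leaves=2, p=12.0,
        )
        rates = campaign_rates(camp, params)
        assert rates.lgp == pytest.approx(np.mean([rates.lgp_s[0], rates.lgp_s[1]]))

    def test_shoots_without_third_leaf_are_excluded(self, simple_shoot, params):
        two_leaf = ShootSample("s2", (make_leaf(1, 0, 40), make_leaf(2, 10, 60)))
        camp = Campaign(
            date="1999-03-15", delta_t=14.0, shoots=(simple_shoot, two_leaf),
            n_marked=2, new_leaves=1, p=14.0,
        )
        rates = campaign_rates(camp, params)
        assert rates.n_plastochrone_excluded == 1
        assert np.isnan(rates.lgp_s[1])
        assert rates.lgp == pytest.approx(rates.lgp_s[0])

    def test_empty_campaign_is_an_error(self, params):
        with pytest.raises(EmptyCampaignError):
            campaign_rates(
                Campaign(date="1999-03-15", delta_t=14.0, shoots=(),
                         n_marked=5, new_leaves=1, p=14.0),
                params,
            )

    def test_p_estimated_from_counts_when_unset(self, simple_shoot, params):
        camp = Campaign(
            date="1999-03-15", delta_t=14.0, shoots=(simple_shoot,),
            n_marked=2, new_leaves=2, p=None,
        )
        rates = campaign_rates(camp, params)
        assert rates.p == pytest.approx(1 * 14.0 / 2)  # retrieved shoots in numerator
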