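import datetime as dt

import numpy as np
import pandas as pd
import pytest

from oge.ingest import PolicyEvent
from oge.intervention import (
    Z_CRIT,
    ArmaxIntervention,
    ScanError,
    build_policy_indicators,
    count_significant_responses,
    fit_armax,
    intervention_zscores,
    regress_effect_sizes,
    scan_armax,
)


def date_range(start: dt.date, n: int) -> list[dt.date]:
    return [start + dt.timedelta(days=i) for i in range(n)]


def simulate_armax(rng, n, alpha=0.5, beta=0.0, impulse_at=None, sd=0.3):
    """AR(1) series with an optional additive impulse, plus its indicator."""
    e = rng.standard_normal(n) * sd
    y = np.empty(n)
    y[0] = e[0] / np.sqrt(1 - alpha**2)
    for t in range(1, n):
        y[t] = alpha * y[t - 1] + e[t]
    z = np.zeros((n, 1))
    if impulse_at is not None:
        z[impulse_at, 0] = 1.0
        y[impulse_at] += beta
    return y, z


WINDOW = date_range(dt.date(2020, 2, 26), 66)  # Feb 26 .. May 1


class TestPolicyIndicators:
    def _events(self, shelter_end=dt.date(2020, 4, 30)):
        return [
            PolicyEvent(k=1, kind="impulse", scope="federal", date=dt.date(2020, 3, 13)),
            PolicyEvent(k=2, kind="impulse", scope="federal", date=dt.date(2020, 3, 29)),
            PolicyEvent(k=3, kind="impulse", scope="federal", date=dt.date(2020, 4, 16)),
            PolicyEvent(k=4, kind="step", scope="local", city="Austin",
                        start=dt.date(2020, 3, 23), end=shelter_end),
        ]

    def test_impulse_columns_have_a_single_one_on_the_event_date(self):
        z = build_policy_indicators(self._events(), "Austin", WINDOW)
        assert z["national_emergency"].sum() == 1
        assert z.loc[dt.date(2020, 3, 13), "national_emergency"] == 1
        assert z["distancing_extension"].sum() == 1
        assert z["reopening_guidelines"].sum() == 1

    def test_step_spans_the_inclusive_interval(self):
        z = build_policy_indicators(self._events(), "Austin", WINDOW)
        assert z["shelter_in_place"].sum() == 39  # Mar 23 .. Apr 30 inclusive
        ones = np.flatnonzero(z["shelter_in_place"].to_numpy())
        assert (np.diff(ones) == 1).all()  # a single contiguous run

    def test_open_interval_extends_to_window_end(self):
        z = build_policy_indicators(self._events(shelter_end=None), "Austin", WINDOW)
        assert z.loc[WINDOW[-1], "shelter_in_place"] == 1

    def test_other_city_gets_all_zero_step_column(self):
        z = build_policy_indicators(self._events(), "Boston", WINDOW)
        assert z["shelter_in_place"].sum() == 0

    def test_event_outside_window_yields_zero_column(self):
        events = [PolicyEvent(k=1, kind="impulse", scope="federal",
                              date=dt.date(2021, 1, 1))]
        z = build_policy_indicators(events, "Austin", WINDOW)
        assert z["national_emergency"].sum() == 0


class TestFitArmax:
    def test_impulse_coefficient_recovery(self):
        rng = np.random.default_rng(11)
        betas = []
        for _ in range(20):
            y, z = simulate_armax(rng, 300, alpha=0.5, beta=-0.8, impulse_at=150)
            model = fit_armax(y, z, 1, 0)
            betas.append(model.beta_.iloc[0])
        assert np.mean(betas) == pytest.approx(-0.8, abs=0.1)

    def test_all_zero_indicators_reduce_to_plain_arma(self):
        rng = np.random.default_rng(12)
        y, _ = simulate_armax(rng, 200)
        model = fit_armax(y, np.zeros((200, 2)), 1, 0)
        assert len(model.beta_) == 0
        assert model.dropped_exog_ == ["0", "1"]
        assert len(model.ar_coeffs_) == 1

    def test_white_noise_prefers_the_empty_model_by_bic(self):
        rng = np.random.default_rng(13)
        wins = 0
        for _ in range(20):
            y = rng.standard_normal(200)
            bic00 = fit_armax(y, None, 0, 0).bic_
            bic11 = fit_armax(y, None, 1, 1).bic_
            wins += bic00 < bic11
        assert wins >= 16  # >= 80%

    def test_ma_sign_follows_the_minus_convention(self):
        # y_t = eps_t - gamma * eps_{t-1} with gamma = 0.6
        rng = np.random.default_rng(14)
        e = rng.standard_normal(2001)
        y = e[1:] - 0.6 * e[:-1]
        model = fit_armax(y, None, 0, 1)
        assert model.ma_coeffs_[0] == pytest.approx(0.6, abs=0.1)

    def test_series_too_short_is_rejected(self):
        y = np.arange(10.0) % 3
        z = np.zeros((10, 1))
        z[4, 0] = 1.0
        with pytest.raises(ValueError, match="too short"):
            fit_armax(y, z, 3, 3)


class TestScanArmax:
    def test_modal_order_selection_on_ar1_data(self):
        rng = np.random.default_rng(15)
        picks = []
        for _ in range(10):
            y, z = simulate_armax(rng, 300, alpha=0.6, beta=-0.5, impulse_at=120)
            model = scan_armax(y, z, p_max=2, q_max=2)
            picks.append((model.p_, model.q_))
        assert max(set(picks), key=picks.count) == (1, 0)

    def test_bic_ties_break_toward_parsimony(self):
        model = ArmaxIntervention()
        model.scan_table_ = None
        from oge.intervention import _bic_better

        # identical BIC within tolerance: smaller p+q wins, then smaller q
        assert _bic_better((100.0, 1, 0), (100.0 + 5e-10, 2, 1))
        assert _bic_better((100.0, 2, 0), (100.0, 2, 1))
        assert not _bic_better((100.0, 2, 1), (100.0, 2, 0))

    def test_constant_series_fails_the_scan(self):
        with pytest.raises((ScanError, ValueError)):
            scan_armax(np.ones(50), None, p_max=1, q_max=1)

    def test_bic_selection_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(16)
        y, z = simulate_armax(rng, 250, alpha=0.5, beta=-0.6, impulse_at=100)
        m1 = scan_armax(y, z, p_max=1, q_max=1)
        m2 = scan_armax(3.0 * y + 7.0, 3.0 * z, p_max=1, q_max=1)
        assert (m1.p_, m1.q_) == (m2.p_, m2.q_)


class TestEffects:
    def _effects(self, zs, city="Austin", topic="overall"):
        return pd.DataFrame(
            {
                "city": city,
                "topic": topic,
                "k": range(1, len(zs) + 1),
                "event": [f"e{k}" for k in range(1, len(zs) + 1)],
                "z": zs,
            }
        )

    def test_zscore_arithmetic_and_significance(self):
        rng = np.random.default_rng(17)
        y, z = simulate_armax(rng, 300, alpha=0.5, beta=-0.8, impulse_at=150)
        model = fit_armax(y, z, 1, 0)
        eff = intervention_zscores(model, "Austin", "overall")
        assert eff.loc[0, "z"] == pytest.approx(
            eff.loc[0, "beta_hat"] / eff.loc[0, "se"]
        )
        assert eff.loc[0, "significant"] == (abs(eff.loc[0, "z"]) >= Z_CRIT)

    @pytest.mark.parametrize(
        "zs,expected",
        [((2.5, 0.3, -2.2, 1.0), 2), ((0.1, -0.2, 1.1, 1.9), 0), ((3, -3, 4, -4), 4)],
    )
    def test_count_significant_responses(self, zs, expected):
        assert count_significant_responses(self._effects(zs), "Austin") == expected

    def test_effect_regression_identity_and_anticorrelation(self):
        rng = np.random.default_rng(18)
        zx = rng.standard_normal(20)
        frames = []
        for i, zx_i in enumerate(zx):
            frames.append(self._effects((zx_i, 0.0, 0.0, zx_i), city=f"c{i}"))
        effects = pd.concat(frames, ignore_index=True)
        slope, intercept, r, p, n = regress_effect_sizes(effects, "overall", 1, 4)
        assert (slope, r, n) == pytest.approx((1.0, 1.0, 20))
        effects.loc[effects["k"] == 4, "z"] *= -1
        slope, _, r, _, _ = regress_effect_sizes(effects, "overall", 1, 4)
        assert (slope, r) == pytest.approx((-1.0, -1.0))

    def test_outliers_are_omitted_from_the_regression(self):
        rng = np.random.default_rng(19)
        zx = rng.standard_normal(15)
        frames = [self._effects((z, 0, 0, z), city=f"c{i}") for i, z in enumerate(zx)]
        frames.append(self._effects((50.0, 0, 0, -50.0), city="outlier"))
        *_, n = regress_effect_sizes(pd.concat(frames, ignore_index=True),
                                     "overall", 1, 4)
        assert n == 15

    def test_too_few_cities_after_cut_is_an_error(self):
        effects = pd.concat(
            [self._effects((1.0, 0, 0, 1.0), city="a"),
             self._effects((2.0, 0, 0, 2.0), city="b")],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="cities"):
            regress_effect_sizes(effects, "overall", 1, 4)


class TestIndicatorDynamics:
    """Impulse vs step behaviour on noiseless differenced traces."""

    def test_impulse_on_a_level_reverts_after_differencing(self):
        level = np.zeros(30)
        level[10] += 1.0  # one-day impulse in the level
        diff = np.diff(level)
        assert diff[9] == 1.0 and diff[10] == -1.0  # reverts, no level shift
        assert level[-1] == 0.0

    def test_step_on_a_level_persists(self):
        level = np.zeros(30)
        level[10:20] += 1.0
        diff = np.diff(level)
        assert diff[9] == 1.0 and diff[19] == -1.0
        assert (diff[10:19] == 0).all()
        assert level[15] == 1.0  # the shift persists over the interval
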