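"""FCS/NARFCS engine: offset semantics, MAR reduction, reproducibility,
and recovery of the exposure effect when imputing at the true delta."""

import numpy as np
import pandas as pd
import pytest

import mnarpba as m
from mnarpba.fcs_engine import (
    ImputationModelSpec,
    ParamDraw,
    default_imputation_specs,
    draw_model_params,
    impute_variable,
    visit_order,
)
from mnarpba.pooling import rubin_pool


def _pooled_beta_x(obs, imputations):
    ests, variances = [], []
    for imp in imputations:
        est = m.fit_substantive(imp.data, obs.roles, method="mi")
        ests.append(est.estimate)
        variances.append(est.se**2)
    return rubin_pool(ests, variances, n_obs=obs.n, n_params=6)


class TestSpecs:
    def test_own_indicator_only_via_offset(self):
        with pytest.raises(ValueError):
            ImputationModelSpec("Y", "logistic", ("X", "m_y"))
        with pytest.raises(ValueError):
            ImputationModelSpec("Y", "logistic", ("X",), offset_indicator="m_x")
        with pytest.raises(ValueError):
            ImputationModelSpec("Y", "logistic", ("Y", "X"))

    def test_default_specs_cover_partially_observed(self):
        targets = {s.target for s in default_imputation_specs()}
        assert targets == {"Y", "X", "W", "D"}
        y_spec = next(s for s in default_imputation_specs() if s.target == "Y")
        assert y_spec.offset_indicator == "m_y"
        mar = next(s for s in default_imputation_specs(mnar_outcome=False)
                   if s.target == "Y")
        assert mar.offset_indicator is None


class TestImputeVariable:
    @pytest.fixture()
    def filled(self, small_pair):
        _, obs = small_pair
        df = obs.data.copy()
        for v in ("Y", "X", "W", "D"):
            df[v] = df[v].fillna(0.0)
        return obs, df

    def test_saturated_negative_offset_forces_zeros(self, filled, rng):
        obs, df = filled
        spec = ImputationModelSpec("Y", "logistic", ("X",), offset_indicator="m_y")
        draw = ParamDraw(coefficients=np.array([0.0, 0.0]))
        col = impute_variable(df, spec, draw, delta=-20.0, rng=rng)
        assert (col[df["m_y"] == 1] == 0.0).all()

    def test_positive_offset_raises_imputed_prevalence(self, filled):
        obs, df = filled
        spec = ImputationModelSpec("Y", "logistic", ("X",), offset_indicator="m_y")
        draw = ParamDraw(coefficients=np.array([-1.0, 0.3]))
        rates = []
        for delta in (0.0, 2.0):
            col = impute_variable(df, spec, draw, delta,
                                  np.random.default_rng(5))
            rates.append(col[df["m_y"] == 1].mean())
        assert rates[1] > rates[0]

    def test_observed_rows_untouched(self, filled, rng):
        obs, df = filled
        spec = ImputationModelSpec("W", "logistic", ("X", "Z1"))
        draw = ParamDraw(coefficients=np.zeros(3))
        col = impute_variable(df, spec, draw, 0.0, rng)
        keep = df["m_w"] == 0
        np.testing.assert_array_equal(col[keep], df.loc[keep, "W"])

    def test_delta_without_offset_rejected(self, filled, rng):
        obs, df = filled
        spec = ImputationModelSpec("W", "logistic", ("X",))
        with pytest.raises(ValueError):
            impute_variable(df, spec, ParamDraw(np.zeros(2)), 1.0, rng)


class TestDrawModelParams:
    def test_too_few_observed_rows(self, rng):
        df = pd.DataFrame({"Y": [1.0, 0.0, np.nan, np.nan],
                           "X": [0.1, 0.2, 0.3, 0.4],
                           "m_y": [0, 0, 1, 1]})
        spec = ImputationModelSpec("Y", "logistic", ("X",))
        with pytest.raises(ValueError, match="observed rows"):
            draw_model_params(df, spec, rng)

    def test_degenerate_observed_outcome_yields_finite_draw(self, rng):
        n = 50
        df = pd.DataFrame({"Y": np.r_[np.zeros(25), np.full(25, np.nan)],
                           "X": np.linspace(-1, 1, n),
                           "m_y": np.r_[np.zeros(25), np.ones(25)]})
        spec = ImputationModelSpec("Y", "logistic", ("X",))
        draw = draw_model_params(df, spec, rng)
        assert np.all(np.isfinite(draw.coefficients))


class TestRunFCS:
    def test_no_missing_data_returns_copies(self, demo):
        complete = m.generate_sm_complete(400, demo, seed=1)
        complete["m_y"] = 0
        mech = m.MARMechanism(coef={t: np.r_[-50.0, np.zeros(5)]
                                    for t in ("X", "W", "D")})
        obs = m.apply_missingness(complete, mech, seed=2)
        imps = m.run_fcs(obs, delta=1.5, K=3, seed=3)
        assert len(imps) == 3
        for imp in imps:
            pd.testing.assert_frame_equal(imp.data, obs.data)

    def test_delta_zero_is_bitwise_mar_fcs(self, small_pair):
        """NARFCS at delta=0 and MAR FCS give identical imputations
        under matched seeds."""
        _, obs = small_pair
        narfcs = m.run_fcs(obs, default_imputation_specs(True), delta=0.0,
                           n_burn=3, K=2, seed=9)
        mar = m.run_fcs(obs, default_imputation_specs(False), delta=0.0,
                        n_burn=3, K=2, seed=9)
        for a, b in zip(narfcs, mar):
            pd.testing.assert_frame_equal(a.data, b.data)

    def test_seed_reproducibility(self, small_pair):
        _, obs = small_pair
        a = m.run_fcs(obs, delta=-3.0, n_burn=2, K=1, seed=13)[0]
        b = m.run_fcs(obs, delta=-3.0, n_burn=2, K=1, seed=13)[0]
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_observed_entries_unchanged_and_binary_imputed(self, small_pair):
        _, obs = small_pair
        imp = m.run_fcs(obs, delta=-2.0, n_burn=2, K=1, seed=14)[0].data
        for v in ("Y", "W", "D"):
            mask = obs.data[f"m_{v.lower()}"] == 0
            np.testing.assert_array_equal(imp.loc[mask, v],
                                          obs.data.loc[mask, v])
            assert set(np.unique(imp[v])) <= {0.0, 1.0}
        assert not imp[["Y", "X", "W", "D"]].isna().any().any()

    def test_between_imputation_variance_positive(self, small_pair, truth):
        _, obs = small_pair
        imps = m.run_fcs(obs, delta=truth.delta_narfcs_true, n_burn=3, K=4,
                         seed=15)
        pooled = _pooled_beta_x(obs, imps)
        assert pooled.between_variance > 0
        assert pooled.total_variance > pooled.within_variance

    def test_visit_order_least_missing_first(self, small_pair):
        _, obs = small_pair
        ordered = [s.target for s in visit_order(obs, default_imputation_specs())]
        assert ordered[-1] == "Y"  # ~80% missing, always last
        fracs = [obs.missing_fraction(t) for t in ordered]
        assert fracs == sorted(fracs)

    def test_visit_order_permutation_agrees_stochastically(self, small_pair, truth):
        _, obs = small_pair
        specs = default_imputation_specs()
        a = _pooled_beta_x(obs, m.run_fcs(obs, specs, truth.delta_narfcs_true,
                                          n_burn=5, K=8, seed=16,
                                          order="missingness"))
        b = _pooled_beta_x(obs, m.run_fcs(obs, list(reversed(specs)),
                                          truth.delta_narfcs_true,
                                          n_burn=5, K=8, seed=17,
                                          order="declared"))
        pooled_se = max(a.se, b.se)
        assert abs(a.estimate - b.estimate) < 3 * pooled_se

    def test_recovers_exposure_effect_at_true_delta(self, demo, truth):
        """Imputing at the true pattern-mixture delta recovers beta_x."""
        complete = m.generate_sm_complete(20_000, demo, seed=21)
        obs = m.apply_missingness(complete, seed=22)
        imps = m.run_fcs(obs, delta=truth.delta_narfcs_true, n_burn=10, K=5,
                         seed=23)
        pooled = _pooled_beta_x(obs, imps)
        assert abs(pooled.estimate - truth.beta_x_true) < 3 * pooled.se
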