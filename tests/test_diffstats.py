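"""Effect sizes, G0-association testing, BH correction, ANOVA, fold-changes."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mixdeconv.diffstats import (
    bh_adjust,
    dynamic_fold_change,
    effect_size,
    effect_size_table,
    g0_association,
    stimulus_anova,
)


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """Exhaustive tail-sum P(X >= k), independent of scipy."""
    denom = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    ) / denom


class TestEffectSize:
    def test_hand_computed_value(self):
        # pooled = sqrt((9+16)/2) = sqrt(12.5); d = 6/sqrt(12.5)
        assert effect_size(10, 4, 4, 3) == pytest.approx(1.6971, abs=1e-4)

    def test_zero_when_equal(self):
        assert effect_size(5.0, 5.0, 1.0, 2.0) == 0.0

    @given(
        st.floats(0.1, 100), st.floats(0.1, 100),
        st.floats(0.1, 10), st.floats(0.1, 10),
    )
    def test_antisymmetry(self, aq, ap, sq, sp):
        assert effect_size(aq, ap, sq, sp) == pytest.approx(-effect_size(ap, aq, sp, sq))

    @given(
        st.floats(0.1, 100), st.floats(0.1, 100),
        st.floats(0.1, 10), st.floats(0.1, 10),
        st.floats(0.01, 1000),
    )
    def test_scale_invariance(self, aq, ap, sq, sp, c):
        assert effect_size(c * aq, c * ap, c * sq, c * sp) == pytest.approx(
            effect_size(aq, ap, sq, sp), rel=1e-9
        )

    def test_zero_pooled_sd_undefined(self):
        assert np.isnan(effect_size(3.0, 1.0, 0.0, 0.0))

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            effect_size(1, 1, -1, 1)

    def test_table_sign_matches_coefficient_order(self):
        profile = pd.DataFrame(
            [
                {"ion": "i", "cell_line": "c", "stimulus": "s",
                 "population": "P", "alpha": 4.0, "sd": 3.0},
                {"ion": "i", "cell_line": "c", "stimulus": "s",
                 "population": "Q", "alpha": 10.0, "sd": 4.0},
            ]
        )
        table = effect_size_table(profile)
        assert table["d"].iloc[0] == pytest.approx(1.6971, abs=1e-4)


def _effects_frame(d_matrix):
    n_ions, n_cond = d_matrix.shape
    return pd.DataFrame(
        {"ion": np.repeat([f"ion{i}" for i in range(n_ions)], n_cond),
         "d": d_matrix.ravel()}
    )


class TestG0Association:
    def test_toy_table_matches_enumeration_oracle(self):
        # pooled positive entries: 40, of which 10 exceed the threshold;
        # the focal ion draws 18 conditions and sees 9 exceed it
        d = np.zeros((3, 18))
        d[0, :9] = 5.0          # focal ion: 9 entries beyond t=3, 9 below
        d[0, 9:] = 0.5
        d[1, 0] = 5.0           # one more above t, 12 positives below, 5 negative
        d[1, 1:13] = 0.5
        d[1, 13:] = -0.5
        d[2, :9] = 0.5          # 9 positive below t, 9 negative
        d[2, 9:] = -0.5
        effects = _effects_frame(d)
        pos = effects["d"][effects["d"] > 0]
        assert len(pos) == 40 and (pos > 3).sum() == 10
        res = g0_association(effects, thresholds=[3.0]).set_index("ion")
        expected = hypergeom_tail_oracle(9, 40, 10, 18)
        assert res.loc["ion0", "p_value"] == pytest.approx(expected, abs=1e-12)

    def test_random_tables_match_oracle(self, rng):
        for _ in range(20):
            d = rng.normal(0, 3, size=(4, 12))
            effects = _effects_frame(d)
            res = g0_association(effects, thresholds=[3.0]).set_index("ion")
            pos = d[d > 0]
            neg = -d[d < 0]
            for ion_idx in range(4):
                row = res.loc[f"ion{ion_idx}"]
                if row["direction"] == 0:
                    assert row["p_value"] == 1.0
                    continue
                pool = pos if row["direction"] > 0 else neg
                N, K = len(pool), int((pool > 3.0).sum())
                n = min(12, N)
                expected = hypergeom_tail_oracle(int(row["n_passing"]), N, K, n)
                assert row["p_value"] == pytest.approx(expected, abs=1e-12)

    def test_no_passing_conditions_gives_p_one(self):
        d = np.full((2, 18), 0.5)
        res = g0_association(_effects_frame(d), thresholds=[3.0])
        assert (res["p_value"] == 1.0).all()
        assert (res["g0_association"] == 0.0).all()

    def test_degenerate_everything_passes_gives_p_one(self):
        d = np.full((3, 18), 9.0)
        res = g0_association(_effects_frame(d), thresholds=[3.0])
        assert np.allclose(res["p_value"], 1.0)
        assert (res["g0_association"] == 1.0).all()

    def test_null_calibration_bh_discovery_rate(self, rng):
        d = rng.normal(0, 4.0, size=(1000, 18))
        res = g0_association(_effects_frame(d))
        assert np.mean(res["p_adjusted"] < 0.01) <= 0.02

    def test_consistent_ion_detected_with_direction(self, rng):
        d = rng.normal(0, 2.0, size=(50, 18))
        d[0] = -8.0  # consistently depleted in G0
        res = g0_association(_effects_frame(d), thresholds=[3.0, 4.0, 5.0]).set_index("ion")
        assert res.loc["ion0", "direction"] == -1
        assert res.loc["ion0", "g0_association"] == 1.0
        assert res.loc["ion0", "p_adjusted"] < 0.01


class TestBH:
    def test_step_up_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.04, 0.04, 0.04]) == pytest.approx([0.04, 0.04, 0.04])

    def test_nan_excluded_from_family(self):
        adj = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(adj[1])
        assert adj[0] == pytest.approx(0.02)  # m = 2, not 3

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_adjusted_dominates_raw_and_capped(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)


class TestStimulusAnova:
    def test_planted_shift_detected(self, rng):
        rows = []
        for i in range(30):
            for st_name, mu in (("a", 0.0), ("b", 0.0), ("c", 8.0 if i == 0 else 0.0)):
                for _ in range(6):
                    rows.append({"ion": f"ion{i}", "stimulus": st_name,
                                 "value": mu + rng.normal()})
        res = stimulus_anova(pd.DataFrame(rows)).set_index("ion")
        assert res.loc["ion0", "p_adjusted"] < 0.05
        assert (res.drop("ion0")["p_adjusted"] > 0.05).mean() > 0.8

    def test_minimum_group_size_enforced(self):
        df = pd.DataFrame(
            {"ion": ["i"] * 3, "stimulus": ["a", "a", "b"], "value": [1.0, 2.0, 3.0]}
        )
        res = stimulus_anova(df)
        assert np.isnan(res["p_value"].iloc[0])


class TestDynamicFoldChange:
    @staticmethod
    def _steady(rng, slope=100.0, intercept=50.0, n=8):
        conf = np.linspace(0.2, 0.9, n)
        table = pd.DataFrame({"ion": intercept + slope * conf})
        return table, conf

    def test_sample_on_steady_state_model_gives_zero(self, rng):
        steady, conf = self._steady(rng)
        measured = pd.DataFrame({"ion": [50.0 + 100.0 * 0.5]}, index=["t1"])
        out = dynamic_fold_change(measured, [0.5], steady, conf)
        assert out["log2fc"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_doubling_gives_log2fc_one(self, rng):
        steady, conf = self._steady(rng)
        measured = pd.DataFrame({"ion": [2 * (50.0 + 100.0 * 0.5)]}, index=["t1"])
        out = dynamic_fold_change(measured, [0.5], steady, conf)
        assert out["log2fc"].iloc[0] == pytest.approx(1.0)

    def test_planted_depletion_recovered_with_significance(self, rng):
        steady, conf = self._steady(rng)
        q_conf = np.full(6, 0.5)
        expected = 50.0 + 100.0 * 0.5
        measured = pd.DataFrame(
            {"ion": np.r_[expected * np.exp(rng.normal(0, 0.02, 3)),
                          0.25 * expected * np.exp(rng.normal(0, 0.02, 3))]},
            index=[f"s{i}" for i in range(6)],
        )
        out = dynamic_fold_change(
            measured, q_conf, steady, conf,
            groups=["ctrl"] * 3 + ["treated"] * 3,
            unperturbed=[True] * 3 + [False] * 3,
        )
        treated = out[out["group"] == "treated"]
        assert treated["log2fc"].mean() == pytest.approx(-2.0, abs=0.2)
        assert (treated["p_adjusted"] < 0.05).all()

    def test_extrapolation_flagged(self, rng):
        steady, conf = self._steady(rng)
        measured = pd.DataFrame({"ion": [500.0]}, index=["t1"])
        out = dynamic_fold_change(measured, [0.99], steady, conf)
        assert out["extrapolated"].iloc[0]

    def test_nonpositive_expected_flagged_undefined(self, rng):
        steady, conf = self._steady(rng, slope=-100.0, intercept=60.0)
        measured = pd.DataFrame({"ion": [10.0]}, index=["t1"])
        out = dynamic_fold_change(measured, [0.9], steady, conf)
        assert out["undefined"].iloc[0] and np.isnan(out["log2fc"].iloc[0])
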