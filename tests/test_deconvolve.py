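"""Mixture regression: design construction, constrained fits, bootstrap, purification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mixdeconv.deconvolve import (
    MIX_FRACTIONS,
    bootstrap_errors,
    build_design_matrix,
    build_mix_design,
    compare_to_reference,
    fit_alphas,
    purify_intensities,
)
from mixdeconv.simulate import MeasurementModel, make_truth, simulate_mix_experiment


class TestMixDesign:
    def test_counts_arithmetic(self):
        design = build_mix_design(1e4, [0.55], 0.1, 0.6, replicates=1)
        assert design["n_q"].iloc[0] == pytest.approx(3250.0)
        assert design["n_p"].iloc[0] == pytest.approx(6750.0)

    def test_pure_extract_endpoint(self):
        design = build_mix_design(1e4, [1.0], 0.1, 0.6, replicates=1)
        assert design["n_q"].iloc[0] == pytest.approx(1e4 * 0.1)

    def test_full_design_row_count(self):
        design = build_mix_design(1e4, MIX_FRACTIONS, 0.1, 0.8, replicates=3)
        assert len(design) == 24

    def test_total_cells_constant_across_mixes(self):
        design = build_mix_design(5e3, MIX_FRACTIONS, 0.2, 0.7, replicates=1)
        assert np.allclose(design["n_p"] + design["n_q"], 5e3)

    def test_equal_g0_fractions_refused(self):
        with pytest.raises(ValueError, match="rank-deficient"):
            build_mix_design(1e4, MIX_FRACTIONS, 0.5, 0.5)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_mix_design(1e4, [1.2], 0.1, 0.6)
        with pytest.raises(ValueError):
            build_mix_design(-5, MIX_FRACTIONS, 0.1, 0.6)


class TestDesignMatrix:
    def test_single_condition_shape(self):
        design = build_mix_design(1e4, MIX_FRACTIONS, 0.1, 0.8, replicates=3)
        X, conditions = build_design_matrix(design)
        assert X.shape == (24, 2)
        assert conditions == [("cellline1", "stimulus1")]

    def test_two_conditions_block_structure(self):
        design = build_mix_design(
            1e4, MIX_FRACTIONS, 0.1, 0.8,
            conditions=[("a", "x"), ("b", "x")], replicates=1,
        )
        X, _ = build_design_matrix(design)
        assert X.shape == (16, 4)
        assert (np.count_nonzero(X, axis=1) == 2).all()

    def test_column_order_p_then_q(self):
        design = build_mix_design(1e4, [1.0], 0.1, 0.8, replicates=1)
        X, _ = build_design_matrix(design)
        assert X[0, 0] == pytest.approx(design["n_p"].iloc[0])
        assert X[0, 1] == pytest.approx(design["n_q"].iloc[0])


def _normal_equations(X, y):
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFit:
    def test_noise_free_recovery(self, random_truth):
        exp = simulate_mix_experiment(random_truth)
        fit = fit_alphas(exp.intensities, exp.design)
        merged = fit.profile.merge(
            random_truth, on=["cell_line", "stimulus", "population", "ion"],
            suffixes=("_fit", "_true"),
        )
        rel = np.abs(merged["alpha_fit"] - merged["alpha_true"]) / merged["alpha_true"]
        assert rel.max() < 1e-8

    def test_equal_alphas_fit_equal(self):
        truth = pd.DataFrame(
            [
                {"cell_line": "c", "stimulus": "s", "population": p, "ion": "i", "alpha": 7.0}
                for p in ("P", "Q")
            ]
        )
        exp = simulate_mix_experiment(truth)
        fit = fit_alphas(exp.intensities, exp.design)
        alphas = fit.profile["alpha"].to_numpy()
        assert alphas == pytest.approx([7.0, 7.0], rel=1e-8)

    def test_active_constraint_matches_grid_oracle(self, rng):
        # planted alpha_Q = 0 with noise pushing the unconstrained optimum
        # negative: the constrained solution must hit the bound exactly and
        # agree with a brute-force profile over the one free parameter
        design = build_mix_design(1e4, MIX_FRACTIONS, 0.1, 0.8, replicates=3)
        X = np.column_stack([design["n_p"], design["n_q"]])
        y = X @ np.array([5.0, 0.0]) + rng.normal(0, 2000.0, len(design))
        assert _normal_equations(X, y)[1] < 0, "noise draw must push Q negative"
        intens = pd.DataFrame({"i": y}, index=[f"s{k}" for k in range(len(y))])
        fit = fit_alphas(intens, design)
        a_p = fit.profile.set_index("population").loc["P", "alpha"]
        a_q = fit.profile.set_index("population").loc["Q", "alpha"]
        assert a_q == 0.0
        # with alpha_Q pinned at 0 the best alpha_P is the 1-D least-squares solution
        best_p = (X[:, 0] @ y) / (X[:, 0] @ X[:, 0])
        assert a_p == pytest.approx(best_p, rel=1e-10)

    def test_rank_deficient_block_flagged(self):
        design = build_mix_design(1e4, [0.3, 0.3], 0.1, 0.8, replicates=1)
        intens = pd.DataFrame({"i": [1.0, 1.0]}, index=["a", "b"])
        fit = fit_alphas(intens, design)
        assert not fit.profile["identifiable"].any()
        assert fit.profile["alpha"].isna().all()

    @given(st.integers(0, 10_000))
    def test_oracle_equivalence_on_interior_blocks(self, seed):
        # constrained solution == closed-form normal equations whenever the
        # unconstrained optimum is already nonnegative
        rng = np.random.default_rng(seed)
        design = build_mix_design(1e4, MIX_FRACTIONS, 0.1, 0.8, replicates=3)
        X = np.column_stack([design["n_p"], design["n_q"]])
        truth = rng.uniform(1.0, 50.0, 2)
        y = X @ truth + rng.normal(0, 1000.0, len(design))
        unconstrained = _normal_equations(X, y)
        if np.any(unconstrained < 0):
            return
        intens = pd.DataFrame({"i": y}, index=[f"s{k}" for k in range(len(y))])
        fit = fit_alphas(intens, design)
        fitted = fit.profile.sort_values("population")["alpha"].to_numpy()
        assert np.allclose(fitted, unconstrained, rtol=1e-10)

    def test_scale_equivariance(self, random_truth):
        model = MeasurementModel(background=500.0)
        exp = simulate_mix_experiment(random_truth, model=model)
        fit1 = fit_alphas(exp.intensities, exp.design, background=500.0)
        fit2 = fit_alphas(exp.intensities * 3.0, exp.design, background=1500.0)
        assert np.allclose(fit2.profile["alpha"], 3.0 * fit1.profile["alpha"])

    def test_block_independence(self):
        truth = make_truth(5, conditions=[("a", "x"), ("b", "x")], seed=40)
        exp = simulate_mix_experiment(truth)
        fit_ref = fit_alphas(exp.intensities, exp.design)
        perturbed = exp.intensities.copy()
        rows_b = (exp.design["cell_line"] == "b").to_numpy()
        perturbed.iloc[rows_b] *= 5.0
        fit_pert = fit_alphas(perturbed, exp.design)
        mask_a = fit_ref.profile["cell_line"] == "a"
        assert np.allclose(
            fit_pert.profile.loc[mask_a, "alpha"], fit_ref.profile.loc[mask_a, "alpha"]
        )


class TestBootstrap:
    def test_zero_residuals_give_zero_sd(self, random_truth):
        exp = simulate_mix_experiment(random_truth)
        fit = bootstrap_errors(fit_alphas(exp.intensities, exp.design), 20, seed=1)
        assert fit.profile["sd"].max() < 1e-10

    def test_seed_determinism(self, random_truth):
        exp = simulate_mix_experiment(
            random_truth, model=MeasurementModel(noise_cv=0.1, seed=2)
        )
        sd1 = bootstrap_errors(fit_alphas(exp.intensities, exp.design), 30, seed=3).profile["sd"]
        sd2 = bootstrap_errors(fit_alphas(exp.intensities, exp.design), 30, seed=3).profile["sd"]
        assert sd1.equals(sd2)

    def test_too_few_reps_refused(self, random_truth):
        exp = simulate_mix_experiment(random_truth)
        with pytest.raises(ValueError):
            bootstrap_errors(fit_alphas(exp.intensities, exp.design), 1)

    def test_calibration_against_analytic_se(self):
        # homoscedastic additive noise: bootstrap SD should track the OLS
        # coefficient SE sigma*sqrt(diag((X'X)^-1)) on interior solutions
        sigma = 2000.0
        truth = make_truth(60, alpha_scale=50.0, alpha_sigma=0.3, seed=41)
        exp = simulate_mix_experiment(
            truth, model=MeasurementModel(noise_floor_sd=sigma, seed=42)
        )
        fit = bootstrap_errors(fit_alphas(exp.intensities, exp.design), 100, seed=43)
        X = fit.block_X[fit.conditions[0]]
        se = sigma * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        ratios = []
        for pop, se_pop in zip(("P", "Q"), se):
            sds = fit.profile.loc[fit.profile["population"] == pop, "sd"].to_numpy()
            ratios.append(sds / se_pop)
        ratios = np.concatenate(ratios)
        assert abs(np.median(ratios) - 1.0) < 0.3


class TestPurify:
    def test_identity_when_other_population_absent(self):
        truth = pd.DataFrame(
            [
                {"cell_line": "c", "stimulus": "s", "population": "P", "ion": "i", "alpha": 0.0},
                {"cell_line": "c", "stimulus": "s", "population": "Q", "ion": "i", "alpha": 4.0},
            ]
        )
        exp = simulate_mix_experiment(truth, fractions=[0.0], replicates=1)
        pur = purify_intensities(exp.intensities, exp.design, truth, endpoint="96h")
        assert pur["purified"].iloc[0] == pytest.approx(exp.intensities.iloc[0, 0])

    def test_noise_free_roundtrip_recovers_per_cell_abundance(self, random_truth):
        exp = simulate_mix_experiment(random_truth)
        fit = fit_alphas(exp.intensities, exp.design)
        mask = (exp.design["fraction"] == 0.0).to_numpy()
        pur = purify_intensities(
            exp.intensities[mask], exp.design[mask].reset_index(drop=True),
            fit.profile, endpoint="96h",
        )
        truth_q = random_truth[random_truth["population"] == "Q"].set_index("ion")["alpha"]
        per_cell = pur.groupby("ion")["per_cell"].mean()
        rel = np.abs(per_cell - truth_q.reindex(per_cell.index)) / truth_q.reindex(per_cell.index)
        assert rel.max() < 1e-8

    def test_zero_focal_population_refused(self, two_pop_truth):
        exp = simulate_mix_experiment(
            two_pop_truth, fractions=[1.0], g0_at_8h=0.0, g0_at_96h=0.5, replicates=1
        )
        fit = fit_alphas(exp.intensities, exp.design)
        with pytest.raises(ValueError, match="normalization undefined"):
            purify_intensities(exp.intensities, exp.design, fit.profile, endpoint="96h")

    def test_negative_purified_floored_and_flagged(self, two_pop_truth):
        exp = simulate_mix_experiment(two_pop_truth, replicates=1)
        deflated = exp.intensities * 0.0  # measured far below the model prediction
        fit = fit_alphas(exp.intensities, exp.design)
        pur = purify_intensities(deflated, exp.design, fit.profile, endpoint="96h")
        assert (pur["purified"] == 0.0).all()
        assert pur["floored"].all()


class TestReferenceComparison:
    def test_self_comparison_gives_perfect_correlation(self, rng):
        profile = pd.DataFrame(
            rng.lognormal(3, 1, (10, 5)),
            index=[f"ion{i}" for i in range(10)],
            columns=[f"cl{j}" for j in range(5)],
        )
        result, _ = compare_to_reference(profile, profile, n_permutations=10, seed=0)
        assert np.allclose(result["spearman_r"], 1.0)

    def test_scrambled_null_centred_at_zero(self, rng):
        profile = pd.DataFrame(
            rng.lognormal(3, 1, (20, 6)),
            index=[f"ion{i}" for i in range(20)],
            columns=[f"cl{j}" for j in range(6)],
        )
        reference = pd.DataFrame(
            rng.lognormal(3, 1, (20, 6)), index=profile.index, columns=profile.columns
        )
        _, null = compare_to_reference(profile, reference, n_permutations=200, seed=1)
        assert abs(np.nanmean(null)) < 3 / np.sqrt(len(null))

    def test_too_few_shared_lines_refused(self, rng):
        profile = pd.DataFrame(rng.random((4, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="3 shared"):
            compare_to_reference(profile, profile)
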