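"""Allelic-series model: indicator coding, OLS fit, inference, interpretation."""

import numpy as np
import pandas as pd
import pytest

from erphagy import allelic, synthetic
from erphagy.allelic import (
    adjust_coefficients,
    build_design,
    fit_allelic_model,
    fitted_genotype_means,
    interpret_step,
)
from erphagy.differential import NormalizedAbundance
from erphagy.errors import DesignError

from conftest import make_truth


def norm_from_matrix(log2_matrix: pd.DataFrame) -> NormalizedAbundance:
    return NormalizedAbundance(
        data=log2_matrix, reference="WT", reference_channels=[]
    )


@pytest.fixture()
def balanced_design():
    return build_design(synthetic.allelic_design(replicates=3))


class TestBuildDesign:
    def test_indicator_patterns(self):
        design = build_design(synthetic.allelic_design(replicates=2))
        by_geno = design.X.groupby(design.genotypes).first()
        assert by_geno.loc["WT"].tolist() == [1, 0, 0, 0, 0]
        assert by_geno.loc["DKO"].tolist() == [1, 1, 0, 0, 0]
        # the TKO "contains" the double knockout, so x1 stays on
        assert by_geno.loc["TKO"].tolist() == [1, 1, 1, 0, 0]
        assert by_geno.loc["QKO"].tolist() == [1, 1, 1, 1, 0]
        assert by_geno.loc["PKO"].tolist() == [1, 1, 1, 1, 1]

    def test_cumulative_nesting_invariant(self):
        design = build_design(synthetic.allelic_design(replicates=3))
        x = design.X[["x1", "x2", "x3", "x4"]].to_numpy()
        assert (np.diff(x, axis=1) <= 0).all()

    def test_non_series_channels_excluded_with_reason(self):
        table = synthetic.make_design(
            ["WT", "DKO", "TKO", "QKO", "PKO", "ATG12_KO", "FAM134A_KO"],
            replicates=2,
        )
        design = build_design(table)
        assert len(design.excluded) == 4
        assert design.excluded["reason"].str.contains("outside allelic").all()

    def test_treated_samples_excluded(self):
        base = synthetic.allelic_design(replicates=2)
        treated = synthetic.make_design(["WT"], replicates=2, treatment="Torin1")
        treated["channel_id"] = ["ch_90", "ch_91"]
        design = build_design(pd.concat([base, treated], ignore_index=True))
        assert set(design.excluded["channel_id"]) == {"ch_90", "ch_91"}

    def test_missing_genotype_named(self):
        table = synthetic.make_design(["WT", "DKO", "TKO", "QKO"], replicates=3)
        with pytest.raises(DesignError, match="PKO"):
            build_design(table)

    def test_full_rank(self, balanced_design):
        assert np.linalg.matrix_rank(balanced_design.X.to_numpy()) == 5


def response_from_group_means(design, means, noise=None):
    """Build a 1-protein response from per-genotype means."""
    y = design.genotypes.map(means).astype(float)
    if noise is not None:
        y = y + noise
    return norm_from_matrix(pd.DataFrame([y.to_numpy()], columns=design.X.index,
                                         index=["A"]))


class TestFit:
    def test_noiseless_saturated_means(self, balanced_design):
        means = {"WT": 0.0, "DKO": 1.0, "TKO": 1.0, "QKO": 1.0, "PKO": 2.0}
        fits = fit_allelic_model(response_from_group_means(balanced_design, means),
                                 balanced_design)
        row = fits.loc["A"]
        assert row["beta0"] == pytest.approx(0.0, abs=1e-12)
        assert [row[f"beta{k}"] for k in range(1, 5)] == pytest.approx(
            [1.0, 0.0, 0.0, 1.0], abs=1e-10
        )

    def test_receptor_deletion_pattern(self, balanced_design):
        # a protein absent from every knockout line: step 1 carries the whole
        # depression, later steps are 0 (the deleted-receptor sanity pattern)
        means = {"WT": 0.0, "DKO": -2.5, "TKO": -2.5, "QKO": -2.5, "PKO": -2.5}
        fits = fit_allelic_model(response_from_group_means(balanced_design, means),
                                 balanced_design)
        row = fits.loc["A"]
        assert row["beta1"] == pytest.approx(-2.5, abs=1e-10)
        assert [row["beta2"], row["beta3"], row["beta4"]] == pytest.approx(
            [0.0, 0.0, 0.0], abs=1e-10
        )

    def test_balanced_betas_equal_successive_group_mean_differences(self, rng):
        design = build_design(synthetic.allelic_design(replicates=4))
        Y = pd.DataFrame(
            rng.normal(0, 1, (50, design.n_samples)),
            columns=design.X.index,
            index=[f"P{i}" for i in range(50)],
        )
        fits = fit_allelic_model(norm_from_matrix(Y), design)
        gmeans = Y.T.groupby(design.genotypes).mean().T
        diffs = np.column_stack([
            gmeans["DKO"] - gmeans["WT"],
            gmeans["TKO"] - gmeans["DKO"],
            gmeans["QKO"] - gmeans["TKO"],
            gmeans["PKO"] - gmeans["QKO"],
        ])
        assert np.allclose(fits[allelic.BETA_COLUMNS].to_numpy(), diffs, atol=1e-8)
        assert np.allclose(fits["beta0"], gmeans["WT"], atol=1e-8)

    def test_matches_explicit_normal_equations_solve(self, rng):
        # independent brute-force least-squares oracle per protein
        design = build_design(synthetic.allelic_design(replicates=3))
        Y = pd.DataFrame(
            rng.normal(0, 0.5, (50, design.n_samples)),
            columns=design.X.index,
            index=[f"P{i}" for i in range(50)],
        )
        fits = fit_allelic_model(norm_from_matrix(Y), design)
        X = design.X.to_numpy()
        for i, pid in enumerate(Y.index):
            beta_oracle = np.linalg.solve(X.T @ X, X.T @ Y.iloc[i].to_numpy())
            got = [fits.loc[pid, "beta0"]] + [
                fits.loc[pid, f"beta{k}"] for k in range(1, 5)
            ]
            assert np.allclose(got, beta_oracle, atol=1e-8)

    def test_matches_statsmodels_inference(self, rng):
        import statsmodels.api as sm

        design = build_design(synthetic.allelic_design(replicates=3))
        y = rng.normal(0, 0.3, design.n_samples)
        fits = fit_allelic_model(
            norm_from_matrix(pd.DataFrame([y], columns=design.X.index, index=["A"])),
            design,
        )
        res = sm.OLS(y, design.X.to_numpy()).fit()
        row = fits.loc["A"]
        assert np.allclose(
            [row[f"beta{k}"] for k in range(1, 5)], res.params[1:], atol=1e-10
        )
        assert np.allclose(
            [row[f"se{k}"] for k in range(1, 5)], res.bse[1:], atol=1e-10
        )
        assert np.allclose(
            [row[f"p{k}"] for k in range(1, 5)], res.pvalues[1:], atol=1e-10
        )
        assert row["df"] == res.df_resid

    def test_telescoping_fitted_means(self, rng):
        design = build_design(synthetic.allelic_design(replicates=3))
        Y = pd.DataFrame(
            rng.normal(0, 1, (10, design.n_samples)),
            columns=design.X.index,
            index=[f"P{i}" for i in range(10)],
        )
        fits = fit_allelic_model(norm_from_matrix(Y), design)
        means = fitted_genotype_means(fits)
        gmeans = Y.T.groupby(design.genotypes).mean().T
        assert np.allclose(means["WT"], gmeans["WT"], atol=1e-8)
        assert np.allclose(means["PKO"], gmeans["PKO"], atol=1e-8)

    def test_no_intercept_variant(self, balanced_design):
        means = {"WT": 0.0, "DKO": 0.5, "TKO": 0.5, "QKO": 0.5, "PKO": 0.5}
        norm = response_from_group_means(balanced_design, means)
        fits = fit_allelic_model(norm, balanced_design, fit_intercept=False)
        assert fits.loc["A", "beta0"] == 0.0
        assert fits.loc["A", "beta1"] == pytest.approx(0.5, abs=1e-10)

    def test_parameter_recovery_unbiased(self):
        # planted step effects recovered without bias; empirical SD of the
        # estimates matches the analytic OLS standard error
        seed, n, reps, sd = 5, 400, 4, 0.2
        delta = np.tile([0.25, 0.5, 1.0, 0.0], n // 4 + 1)[:n]
        steps = np.column_stack([delta, delta, delta, delta])
        truth = make_truth([f"P{i:04d}" for i in range(n)], np.zeros(n), steps,
                           noise_sd=sd)
        design_table = synthetic.allelic_design(replicates=reps)
        mat = synthetic.simulate_protein_matrix(truth, design_table, seed=seed)
        design = build_design(design_table)
        fits = fit_allelic_model(norm_from_matrix(mat), design)
        analytic_se = sd * np.sqrt(2.0 / reps)
        for k in range(1, 5):
            err = fits[f"beta{k}"].to_numpy() - delta
            mc_se = err.std(ddof=1) / np.sqrt(n)
            assert abs(err.mean()) < 3 * mc_se
            assert abs(err.std(ddof=1) / analytic_se - 1) < 0.15


class TestAdjustAndInterpret:
    def make_fits(self, p_by_protein):
        n = len(p_by_protein)
        fits = pd.DataFrame(
            {
                "beta0": 0.0,
                **{f"beta{k}": 1.0 for k in range(1, 5)},
                **{f"se{k}": 0.1 for k in range(1, 5)},
                **{f"p{k}": p_by_protein for k in range(1, 5)},
                "sigma2": 0.01,
                "df": 10,
            },
            index=[f"P{i}" for i in range(n)],
        )
        return fits

    def test_single_protein_q_equals_p(self):
        fits = adjust_coefficients(self.make_fits([0.03]))
        assert fits.loc["P0", ["q1", "q2", "q3", "q4"]].tolist() == [0.03] * 4

    def test_families_are_per_coefficient(self):
        fits = self.make_fits([0.01, 0.02, 0.03, 0.04])
        fits.loc[:, "p2"] = [0.5, 0.6, 0.7, 0.8]
        adj = adjust_coefficients(fits)
        # coefficient-1 family: the hand step-up collapses all four to 0.04
        assert np.allclose(adj["q1"], 0.04)
        # coefficient-2 family is corrected independently
        assert np.allclose(adj["q2"], [0.8, 0.8, 0.8, 0.8])

    def test_interpret_receptor_labels_and_direction(self):
        fits = adjust_coefficients(self.make_fits([0.001]))
        s3 = interpret_step(fits, "P0", 3)
        assert s3.receptor == "TEX264"
        assert s3.direction == "up"
        fits.loc["P0", "q2"] = 0.5
        s2 = interpret_step(fits, "P0", 2)
        assert s2.receptor == "FAM134B" and s2.direction == "ns"

    def test_interpret_step_range_checked(self):
        fits = adjust_coefficients(self.make_fits([0.5]))
        with pytest.raises(ValueError):
            interpret_step(fits, "P0", 5)

    def test_null_calibration_per_family(self):
        rng = np.random.default_rng(21)
        n, reps = 1500, 4
        truth = make_truth([f"P{i:04d}" for i in range(n)], np.zeros(n),
                           np.zeros((n, 4)), noise_sd=0.2)
        design_table = synthetic.allelic_design(replicates=reps)
        mat = synthetic.simulate_protein_matrix(truth, design_table, seed=33)
        fits = adjust_coefficients(
            fit_allelic_model(norm_from_matrix(mat), build_design(design_table))
        )
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)
        for k in range(1, 5):
            assert (fits[f"q{k}"] < 0.05).mean() <= bound
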