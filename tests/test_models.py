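"""Parameter table, split-plot mixed models, and PGLS."""

import numpy as np
import pandas as pd
import pytest

from frphylo.design import records_to_frame
from frphylo.fixtures import STUDY_CONTROL_VARIATION, STUDY_SPECIES, familiar_species, novel_species, study_design
from frphylo.frfit import fit_fr_frame
from frphylo.models import (
    average_over_temperature,
    build_parameter_table,
    fit_pgls,
    fit_splitplot_lmm,
    pgls_by_temperature,
    phylo_covariate,
    splitplot_denominator_dfs,
)
from frphylo.phylo import read_newick, study_tree
from frphylo.synthetic import NoiseModel, default_truth, simulate_brownian_traits, simulate_experiment, substream


@pytest.fixture(scope="module")
def study_table():
    """Parameter table from one study-shaped synthetic run."""
    design = study_design()
    truth = default_truth()
    noise = NoiseModel(STUDY_CONTROL_VARIATION, 0.05)
    trials = records_to_frame(simulate_experiment(design, truth, noise, seed=42))
    params = fit_fr_frame(trials, design.duration_hr)
    dist = phylo_covariate(study_tree(), familiar_species(), novel_species())
    return build_parameter_table(params, list(STUDY_SPECIES), dist)


class TestParameterTable:
    def test_study_shape_is_50_rows_25_familiar(self, study_table):
        assert len(study_table) == 50
        assert (study_table["origin"] == "familiar").sum() == 25
        assert study_table["tank"].nunique() == 5

    def test_log_max_is_negated_log_h(self, study_table):
        np.testing.assert_array_equal(
            study_table["log_max"].to_numpy(), -study_table["log_h"].to_numpy()
        )

    def test_unit_handling_time_gives_zero_log(self):
        params = pd.DataFrame(
            {"species": ["Lactuca sativa"], "temperature_C": [30.0],
             "a": [0.05], "h": [1.0], "max_rate": [1.0],
             "n_points": [21], "converged": [True], "sse": [0.0]}
        )
        table = build_parameter_table(params, list(STUDY_SPECIES), None)
        assert table.loc[0, "log_h"] == 0.0

    def test_nonpositive_parameter_rejected(self):
        params = pd.DataFrame(
            {"species": ["Lactuca sativa"], "temperature_C": [30.0],
             "a": [0.05], "h": [0.0], "max_rate": [np.inf],
             "n_points": [21], "converged": [True], "sse": [0.0]}
        )
        with pytest.raises(ValueError, match="log"):
            build_parameter_table(params, list(STUDY_SPECIES), None)


class TestSplitPlotLMM:
    def test_denominator_df_rule(self):
        assert splitplot_denominator_dfs(50, 5, 1, 2) == (3, 43)
        assert splitplot_denominator_dfs(25, 5, 1, 2) == (3, 18)

    def test_temp_origin_model_reports_table_dfs(self, study_table):
        fit = fit_splitplot_lmm(study_table, "log_h", fixed="temp_origin")
        assert fit.term("Temp").df_den == 3
        assert fit.term("Origin").df_den == 43
        assert fit.term("Temp:Origin").df_den == 43

    def test_temp_phylo_model_reports_df_18(self, study_table):
        fit = fit_splitplot_lmm(study_table, "log_h", fixed="temp_phylo")
        assert fit.term("Phylo").df_den == 18
        assert fit.term("Temp:Phylo").df_den == 18
        assert fit.term("Temp").df_den == 3

    def test_h_and_max_tests_are_equivalent(self, study_table):
        """log max = −log h, so every F statistic must coincide."""
        fit_h = fit_splitplot_lmm(study_table, "log_h")
        fit_m = fit_splitplot_lmm(study_table, "log_max")
        for th, tm in zip(fit_h.terms, fit_m.terms):
            assert th.F == pytest.approx(tm.F, rel=1e-6)

    def test_zero_tank_variance_matches_ols(self):
        """With no tank effect in truth, fixed effects agree with ordinary
        regression to high precision."""
        rng = substream(21, "lmm-ols")
        temps = np.repeat([26.0, 28.0, 30.0, 32.0, 34.0], 10)
        origin = np.tile(np.repeat([0.0, 1.0], 5), 5)
        species = np.tile([f"sp{i}" for i in range(10)], 5)
        y = 1.0 - 0.1 * temps + 0.5 * origin + 0.02 * temps * origin
        y = y + rng.normal(0, 0.05, y.size)
        table = pd.DataFrame(
            {"species": species, "temperature_C": temps,
             "tank": [f"tank{t:g}" for t in temps],
             "origin": np.where(origin == 1, "novel", "familiar"),
             "dist_to_novel": np.nan, "log_a": y, "log_h": y, "log_max": -y}
        )
        fit = fit_splitplot_lmm(table, "log_h")
        X = np.column_stack([np.ones_like(temps), temps, origin, temps * origin])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.params, beta, atol=1e-4)

    def test_interaction_slopes_equal_subset_slopes_without_tank_variance(self):
        rng = substream(33, "slopes")
        temps = np.repeat([26.0, 28.0, 30.0, 32.0, 34.0], 10)
        origin = np.tile(np.repeat([0.0, 1.0], 5), 5)
        y = 2.0 - 0.129 * temps * (1 - origin) + 0.004 * temps * origin
        y = y + rng.normal(0, 0.02, y.size)
        table = pd.DataFrame(
            {"species": np.tile([f"sp{i}" for i in range(10)], 5),
             "temperature_C": temps, "tank": [f"tank{t:g}" for t in temps],
             "origin": np.where(origin == 1, "novel", "familiar"),
             "dist_to_novel": np.nan, "log_a": y, "log_h": y, "log_max": -y}
        )
        fit = fit_splitplot_lmm(table, "log_h")
        for label, mask in [("Familiar: Temp", origin == 0), ("Novel: Temp", origin == 1)]:
            slope = np.polyfit(temps[mask], y[mask], 1)[0]
            assert fit.contrast(label).estimate == pytest.approx(slope, abs=1e-3)

    def test_degenerate_covariate_rejected(self, study_table):
        broken = study_table.copy()
        broken["origin"] = "familiar"
        with pytest.raises(ValueError):
            fit_splitplot_lmm(broken, "log_h", fixed="temp_origin")


class TestPGLS:
    def test_star_tree_reduces_to_ols(self):
        newick = "(" + ",".join(f"t{i}:1" for i in range(8)) + ");"
        tree = read_newick(newick)
        rng = substream(3, "pgls-star")
        x = pd.Series(rng.normal(size=8), index=[f"t{i}" for i in range(8)])
        y = 2.0 + 0.5 * x + pd.Series(rng.normal(0, 0.3, 8), index=x.index)
        res = fit_pgls(y, x, tree)
        X = np.column_stack([np.ones(8), x.to_numpy()])
        beta = np.linalg.lstsq(X, y.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(res.coefficients["estimate"].to_numpy(), beta, atol=1e-10)

    def test_scale_invariance_of_estimates_and_t(self):
        tree = study_tree()
        scaled = read_newick(
            # multiply every branch length by 10 via dendropy
            _rescale_newick(tree, 10.0)
        )
        rng = substream(4, "pgls-scale")
        y = simulate_brownian_traits(tree, 1.0, 0.0, rng)
        x = pd.Series(
            [1.0 if s in novel_species() else 0.0 for s in y.index], index=y.index
        )
        r1 = fit_pgls(y, x, tree)
        r2 = fit_pgls(y, x, scaled)
        np.testing.assert_allclose(
            r1.coefficients["estimate"], r2.coefficients["estimate"], rtol=1e-9
        )
        np.testing.assert_allclose(r1.coefficients["t"], r2.coefficients["t"], rtol=1e-9)

    def test_missing_tip_value_raises(self):
        tree = study_tree()
        y = pd.Series([1.0], index=["Lactuca sativa"])
        with pytest.raises(ValueError, match="missing"):
            fit_pgls(y, y, tree)

    def test_by_temperature_yields_one_fit_per_level_plus_mean(self, study_table):
        results = pgls_by_temperature(study_table, study_tree(), "log_h")
        assert [r.level for r in results] == ["26", "28", "30", "32", "34", "mean"]
        assert all(r.df_resid == 8 for r in results)


class TestAverageOverTemperature:
    def test_study_table_yields_ten_species(self, study_table):
        means = average_over_temperature(study_table)
        assert len(means) == 10

    def test_equals_groupby_oracle(self, study_table):
        means = average_over_temperature(study_table)
        for species in ("Lactuca sativa", "Pistia stratiotes"):
            sub = study_table[study_table["species"] == species]
            assert means.loc[species, "log_h"] == pytest.approx(sub["log_h"].mean())

    def test_constant_species_returns_constant(self, study_table):
        table = study_table.copy()
        table.loc[table["species"] == "Lactuca sativa", "log_h"] = 1.5
        means = average_over_temperature(table)
        assert means.loc["Lactuca sativa", "log_h"] == pytest.approx(1.5)

    def test_missing_cell_raises(self, study_table):
        broken = study_table.iloc[1:]
        with pytest.raises(ValueError, match="missing"):
            average_over_temperature(broken)


def _rescale_newick(tree, factor):
    clone = tree.tree.clone(depth=1)
    for edge in clone.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    return clone.as_string(schema="newick", suppress_rooting=True)
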