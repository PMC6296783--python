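"""Split-plot Type III ANOVA, correlations, path model, monoculture tops."""

import itertools

import numpy as np
import pandas as pd
import pytest

import soilmultifun as smf
from soilmultifun.errors import AliasingError, InvalidInputError
from soilmultifun.inference import (
    DEFAULT_PATHS,
    ModelSpec,
    compare_paths,
    fit_path_model,
    pearson_matrix,
    top_monoculture,
    type3_anova,
)


def balanced_design(reps_per_cell=3, rng=None):
    """Fully balanced split-plot frame: every ring carries the same
    richness x N composition, so all terms are mutually orthogonal."""
    rows = []
    i = 0
    for co2, rings in (("ambient", (1, 2, 3)), ("elevated", (4, 5, 6))):
        for ring in rings:
            for n in ("ambient", "enriched"):
                for richness in (1, 4, 9, 16):
                    for _ in range(reps_per_cell):
                        i += 1
                        rows.append(
                            {
                                "plot_id": f"B{i:03d}",
                                "ring": ring,
                                "co2": co2,
                                "n": n,
                                "sown_richness": richness,
                            }
                        )
    df = pd.DataFrame(rows).set_index("plot_id")
    if rng is not None:
        df["y"] = rng.normal(size=len(df))
    return df


def sequential_ss(data, response, order):
    """Oracle: sequential (Type I) sums of squares via incremental RSS."""
    from soilmultifun.inference import _design_columns, _rss

    terms = _design_columns(data, ModelSpec(response=response))
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    current = np.ones((n, 1))
    rss_prev = _rss(current, y)
    out = {}
    for name in order:
        current = np.hstack([current, terms[name]])
        rss_new = _rss(current, y)
        out[name] = rss_prev - rss_new
        rss_prev = rss_new
    return out


class TestType3Anova:
    def test_balanced_type3_equals_sequential(self):
        rng = np.random.default_rng(0)
        data = balanced_design(rng=rng)
        result = type3_anova(data, ModelSpec(response="y"))
        seq = sequential_ss(
            data, "y",
            ["co2", "ring(co2)", "n", "psr", "co2:n", "co2:psr", "n:psr", "co2:n:psr"],
        )
        for term, ss in seq.items():
            assert result.table.loc[term, "SS"] == pytest.approx(ss)

    def test_tiny_unbalanced_ss_match_reduced_model_refits(self):
        """Oracle: statsmodels OLS refits with and without each term."""
        import statsmodels.api as sm
        from soilmultifun.inference import _design_columns

        rng = np.random.default_rng(1)
        data = balanced_design(reps_per_cell=1).sample(20, random_state=3)
        data["y"] = rng.normal(size=len(data)) + 0.3 * np.log(data["sown_richness"])
        spec = ModelSpec(response="y")
        result = type3_anova(data, spec)
        terms = _design_columns(data, spec)
        y = data["y"].to_numpy(dtype=float)
        full_cols = np.hstack([np.ones((len(data), 1))] + list(terms.values()))
        rss_full = sm.OLS(y, full_cols).fit().ssr
        for name in terms:
            reduced = np.hstack(
                [np.ones((len(data), 1))]
                + [terms[t] for t in terms if t != name]
            )
            ss = sm.OLS(y, reduced).fit().ssr - rss_full
            assert result.table.loc[name, "SS"] == pytest.approx(ss, abs=1e-8)

    def test_co2_tested_against_ring_mean_square(self):
        rng = np.random.default_rng(2)
        data = balanced_design(rng=rng)
        result = type3_anova(data, ModelSpec(response="y"))
        t = result.table
        assert t.loc["co2", "denominator"] == "ring(co2)"
        assert t.loc["co2", "F"] == pytest.approx(
            t.loc["co2", "MS"] / t.loc["ring(co2)", "MS"]
        )
        assert t.loc["co2", "den_df"] == 4
        assert (t.drop("co2")["denominator"] == "residual").all()

    def test_df_bookkeeping_matches_both_conventions(self):
        rng = np.random.default_rng(3)
        data = balanced_design(rng=rng)  # n = 144
        result = type3_anova(data, ModelSpec(response="y"))
        assert result.model_df == 11  # conventional: ring(co2) has 4 df
        assert result.model_df_caption == 13  # block counted as 6 df
        assert result.residual_df == len(data) - 12
        assert result.residual_df_caption == len(data) - 14

    def test_satterthwaite_reduces_to_classical_when_balanced(self):
        rng = np.random.default_rng(4)
        data = balanced_design(rng=rng)
        classical = type3_anova(data, ModelSpec(response="y"))
        satt = type3_anova(data, ModelSpec(response="y", satterthwaite=True))
        assert satt.table.loc["co2", "F"] == pytest.approx(
            classical.table.loc["co2", "F"]
        )
        assert satt.table.loc["co2", "den_df"] == pytest.approx(4.0, abs=1e-6)

    def test_aliased_design_rejected(self):
        rng = np.random.default_rng(5)
        data = balanced_design(rng=rng)
        data["n"] = data["co2"].map({"ambient": "ambient", "elevated": "enriched"})
        with pytest.raises(AliasingError):
            type3_anova(data, ModelSpec(response="y"))

    def test_exclude_monocultures_drops_richness_one(self):
        rng = np.random.default_rng(6)
        data = balanced_design(rng=rng)
        result = type3_anova(
            data, ModelSpec(response="y", exclude_monocultures=True)
        )
        assert result.n == (data["sown_richness"] > 1).sum()

    def test_richness_effect_detected_on_synthetic_defaults(self, analysis):
        result = type3_anova(analysis, ModelSpec(response="root_biomass"))
        assert result.table.loc["psr", "p"] < 0.001
        assert result.table.loc["psr", "F"] > 10


class TestPearson:
    def test_self_and_antilinear(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        t["b"] = t["a"]
        t["c"] = -2.0 * t["a"] + 5
        out = pearson_matrix(t).set_index(["var1", "var2"])
        assert out.loc[("a", "b"), "r"] == pytest.approx(1.0)
        assert out.loc[("a", "c"), "r"] == pytest.approx(-1.0)

    def test_toy_table_against_covariance_formula(self):
        rng = np.random.default_rng(7)
        t = pd.DataFrame(rng.normal(size=(5, 2)), columns=["x", "y"])
        out = pearson_matrix(t)
        x, y = t["x"].to_numpy(), t["y"].to_numpy()
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert out["r"].iloc[0] == pytest.approx(r_hand)

    def test_zero_variance_column_marked_undefined(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        out = pearson_matrix(t)
        assert np.isnan(out["r"].iloc[0])


def simulate_path_data(n, rng, b1=0.9, b2=0.35, g1=0.4, g2=0.45, noise=1.0):
    x = rng.choice(np.log([1, 4, 9, 16]), size=n)
    m1 = b1 * x + noise * 0.4 * rng.normal(size=n)
    m2 = b2 * x + noise * 0.5 * rng.normal(size=n)
    y = g1 * m1 + g2 * m2 + noise * 0.3 * rng.normal(size=n)
    return pd.DataFrame(
        {"ln_psr": x, "fdis": m1, "evenness_func": m2, "avg_multifunctionality": y}
    )


def exact_path_data(rng, n=100, b1=0.9, b2=0.35, g1=0.4, g2=0.45):
    """Data satisfying the default path model's covariance constraints
    exactly: each residual is orthogonalised (in sample) against the
    variables the model requires it to be uncorrelated with."""

    def residualize(e, *basis):
        b = np.column_stack([np.ones(len(e))] + list(basis))
        return e - b @ np.linalg.lstsq(b, e, rcond=None)[0]

    x = rng.choice(np.log([1, 4, 9, 16]), size=n)
    e1 = residualize(rng.normal(size=n), x)
    m1 = b1 * x + e1
    e2 = residualize(rng.normal(size=n), x, e1)
    m2 = b2 * x + e2
    ey = residualize(rng.normal(size=n), x, m1, m2)
    y = g1 * m1 + g2 * m2 + ey
    return pd.DataFrame(
        {"ln_psr": x, "fdis": m1, "evenness_func": m2, "avg_multifunctionality": y}
    )


class TestPathModel:
    def test_default_model_df_is_two(self):
        # oracle: 10 covariance moments of 4 variables minus 8 free
        # parameters (4 paths, 3 residual variances, 1 exogenous variance)
        rng = np.random.default_rng(8)
        fit = fit_path_model(simulate_path_data(200, rng))
        assert fit.n_params == 8
        assert fit.df == 10 - 8 == 2

    def test_exact_model_data_recovered_to_machine_precision(self):
        """Residuals orthogonalised in-sample to the model's predictors:
        the covariance constraints hold exactly, so the coefficients are
        identified without error and the discrepancy chi2 vanishes."""
        data = exact_path_data(np.random.default_rng(9), n=100)
        fit = fit_path_model(data, polish=False)
        assert fit.coefficients[("ln_psr", "fdis")] == pytest.approx(0.9, abs=1e-10)
        assert fit.coefficients[("fdis", "avg_multifunctionality")] == pytest.approx(
            0.4, abs=1e-10
        )
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)

    def test_closed_form_is_ml_optimum(self):
        """The equation-wise solution should already minimise the ML
        discrepancy; numerical polishing must not move it."""
        rng = np.random.default_rng(10)
        data = simulate_path_data(300, rng)
        raw = fit_path_model(data, polish=False)
        polished = fit_path_model(data, polish=True)
        for key in raw.coefficients:
            assert polished.coefficients[key] == pytest.approx(
                raw.coefficients[key], abs=1e-4
            )
        assert polished.chi2 == pytest.approx(raw.chi2, abs=1e-6)

    def test_chi2_invariant_to_rescaling_and_standardized_scale_free(self):
        rng = np.random.default_rng(11)
        data = simulate_path_data(250, rng)
        fit = fit_path_model(data, polish=False)
        scaled = data.copy()
        scaled["fdis"] = 100.0 * scaled["fdis"]
        scaled["avg_multifunctionality"] = 0.01 * scaled["avg_multifunctionality"]
        fit2 = fit_path_model(scaled, polish=False)
        assert fit2.chi2 == pytest.approx(fit.chi2, rel=1e-8)
        for key in fit.standardized:
            assert fit2.standardized[key] == pytest.approx(fit.standardized[key])

    def test_indirect_effects_sum_to_implied_total_association(self):
        rng = np.random.default_rng(12)
        fit = fit_path_model(simulate_path_data(300, rng), polish=False)
        c = fit.coefficients
        sigma = fit.implied_cov
        # raw path tracing: cov(x, y) implied by the chains through the
        # two mediators
        indirect_raw = (
            c[("ln_psr", "fdis")] * c[("fdis", "avg_multifunctionality")]
            + c[("ln_psr", "evenness_func")]
            * c[("evenness_func", "avg_multifunctionality")]
        ) * sigma.loc["ln_psr", "ln_psr"]
        assert indirect_raw == pytest.approx(
            sigma.loc["ln_psr", "avg_multifunctionality"], abs=1e-10
        )
        # standardized on the implied scale: equals the implied correlation
        implied_sd = {v: np.sqrt(sigma.loc[v, v]) for v in fit.variables}
        indirect_std = indirect_raw / (
            implied_sd["ln_psr"] * implied_sd["avg_multifunctionality"]
        )
        implied_r = sigma.loc["ln_psr", "avg_multifunctionality"] / (
            implied_sd["ln_psr"] * implied_sd["avg_multifunctionality"]
        )
        assert indirect_std == pytest.approx(implied_r, abs=1e-12)

    def test_delta_aic_plus_two_for_truly_zero_extra_path(self):
        data = exact_path_data(np.random.default_rng(13), n=150)
        delta = compare_paths(
            data, DEFAULT_PATHS, ("ln_psr", "avg_multifunctionality")
        )
        # one extra parameter, no chi2 gain available
        assert delta == pytest.approx(2.0, abs=1e-3)

    def test_adding_generating_path_improves_aic(self):
        rng = np.random.default_rng(14)
        data = simulate_path_data(400, rng)
        data["avg_multifunctionality"] += 0.5 * data["ln_psr"]  # real direct path
        delta = compare_paths(
            data, DEFAULT_PATHS, ("ln_psr", "avg_multifunctionality")
        )
        assert delta < 0

    def test_duplicate_candidate_path_rejected(self):
        rng = np.random.default_rng(15)
        data = simulate_path_data(100, rng)
        with pytest.raises(InvalidInputError):
            compare_paths(data, DEFAULT_PATHS, ("ln_psr", "fdis"))


class TestTopMonoculture:
    def test_dominant_species_wins_every_cell(self, design):
        functions = pd.DataFrame(index=design.index)
        mono = design["sown_richness"] == 1
        first = design.loc[mono, "sown_species"].map(lambda s: s[0])
        functions["f"] = 1.0
        functions.loc[mono[mono].index, "f"] = np.where(
            first == "Achillea millefolium", 100.0, 1.0
        )
        out = top_monoculture(functions[["f"]], design)
        assert (out["species"] == "Achillea millefolium").all()

    def test_matches_bruteforce_groupby_maximum(self, design, functions):
        out = top_monoculture(functions, design).set_index(["function", "co2", "n"])
        mono = design[design["sown_richness"] == 1].copy()
        mono["species"] = mono["sown_species"].map(lambda s: s[0])
        merged = mono.join(functions)
        for func in functions.columns:
            for co2 in ("ambient", "elevated"):
                for n in ("ambient", "enriched"):
                    cell = merged[(merged["co2"] == co2) & (merged["n"] == n)]
                    means = cell.groupby("species")[func].mean()
                    expected = means[means == means.max()].index.min()
                    assert out.loc[(func, co2, n), "species"] == expected

    def test_tie_flagged_and_broken_lexicographically(self):
        design = pd.DataFrame(
            {
                "ring": [1, 1],
                "co2": ["ambient", "ambient"],
                "n": ["ambient", "ambient"],
                "sown_richness": [1, 1],
                "sown_species": [("Zed species",), ("Abel species",)],
            },
            index=["p1", "p2"],
        )
        functions = pd.DataFrame({"f": [5.0, 5.0]}, index=["p1", "p2"])
        out = top_monoculture(functions, design)
        row = out[(out["co2"] == "ambient") & (out["n"] == "ambient")].iloc[0]
        assert row["species"] == "Abel species"
        assert bool(row["tie"])
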