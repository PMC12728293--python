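"""Factorial-statistics tests: brute-force oracles, known equivalences, and
Monte-Carlo operating characteristics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import ectophys as ep
from ectophys.stats import (
    DesignSpec,
    WelchAnovaResult,
    check_assumptions,
    compact_letters,
    fit_linear_model,
    pearson_correlation,
    percent_change,
    tukey_hsd,
    welch_games_howell,
)


def _design_a(seed=0, n=8, temp_effect=(0.0, 0.2, 0.4), ph_effect=0.0, sd=0.1):
    rng = np.random.default_rng(seed)
    rows = []
    for ti, temp in enumerate(("2", "6", "10")):
        for ph in ("7.75", "7.40"):
            for _ in range(n):
                wm = rng.uniform(7.0, 11.0)
                y = 10 ** (
                    -0.45 + temp_effect[ti] + (ph_effect if ph == "7.40" else 0.0)
                    + 0.6 * np.log10(wm / 9.0) + rng.normal(0, sd)
                )
                rows.append({"temperature": temp, "ph": ph, "smr": y, "wet_mass": wm})
    return pd.DataFrame(rows)


def _design_b(seed=0, n=9, means=(1.66, 0.75, 2.09, 1.23), sd=0.25):
    rng = np.random.default_rng(seed)
    rows = []
    for code, mu in zip(("2C", "2CH", "10A", "10AH"), means):
        for _ in range(n):
            rows.append(
                {"treatment": code,
                 "mmr": max(0.05, rng.normal(mu, sd)),
                 "wet_mass": rng.uniform(7.0, 11.0)}
            )
    return pd.DataFrame(rows)


# --- model fitting ----------------------------------------------------------


def test_one_way_f_matches_scipy_oracle():
    df = _design_b(seed=1)
    spec = DesignSpec(design="B", response="mmr")
    fit = fit_linear_model(df, spec)
    groups = [g["mmr"].values for _, g in df.groupby("treatment")]
    f_ref, p_ref = sps.f_oneway(*groups)
    row = fit.anova_table.loc["C(treatment)"]
    assert row["F"] == pytest.approx(f_ref, rel=1e-9)
    assert row["PR(>F)"] == pytest.approx(p_ref, rel=1e-9)


def test_balanced_type2_equals_brute_force_projection():
    """On balanced crossed data, the Type-II F for each term equals the
    residual-SS drop computed directly with least squares."""
    df = _design_a(seed=2, n=8)
    df["_y"] = np.log10(df["smr"])
    spec = DesignSpec(design="A", response="smr", transform="log10")
    fit = fit_linear_model(df, spec)

    def rss(cols):
        X = np.column_stack([np.ones(len(df))] + cols)
        resid = df["_y"].values - X @ np.linalg.lstsq(X, df["_y"].values, rcond=None)[0]
        return float(resid @ resid)

    t_dum = [(df["temperature"] == lv).astype(float).values for lv in ("6", "10")]
    p_dum = [(df["ph"] == "7.75").astype(float).values]
    inter = [t * p for t in t_dum for p in p_dum]
    full = rss(t_dum + p_dum + inter)
    df_resid = len(df) - 6
    mse = full / df_resid
    # Type II: each term against the model containing all others respecting
    # marginality (interaction excluded when testing main effects)
    f_temp = ((rss(p_dum) - rss(t_dum + p_dum)) / 2) / mse
    f_ph = ((rss(t_dum) - rss(t_dum + p_dum)) / 1) / mse
    f_int = ((rss(t_dum + p_dum) - full) / 2) / mse
    assert fit.anova_table.loc["C(temperature)", "F"] == pytest.approx(f_temp, rel=1e-6)
    assert fit.anova_table.loc["C(ph)", "F"] == pytest.approx(f_ph, rel=1e-6)
    assert fit.anova_table.loc["C(temperature):C(ph)", "F"] == pytest.approx(f_int, rel=1e-6)


def test_balanced_type2_equals_sequential_type1():
    df = _design_a(seed=3, n=8)
    spec = DesignSpec(design="A", response="smr", transform="log10")
    fit = fit_linear_model(df, spec)
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    work = df.copy()
    work["_y"] = np.log10(work["smr"])
    seq = anova_lm(smf.ols("_y ~ C(temperature) * C(ph)", data=work).fit(), typ=1)
    for term in ("C(temperature)", "C(ph)", "C(temperature):C(ph)"):
        assert fit.anova_table.loc[term, "F"] == pytest.approx(
            seq.loc[term, "F"], rel=1e-9
        )


def test_empty_cell_raises_naming_cell():
    df = _design_a(seed=4, n=4)
    df = df[~((df["temperature"] == "6") & (df["ph"] == "7.40"))]
    with pytest.raises(ValueError, match="empty design cell"):
        fit_linear_model(df, DesignSpec(design="A", response="smr"))


def test_constant_response_flagged():
    df = _design_b(seed=5)
    df["mmr"] = 1.0
    fit = fit_linear_model(df, DesignSpec(design="B", response="mmr"))
    assert "degenerate_zero_variance" in fit.flags


def test_temperature_only_effect_detected_with_nominal_ph_type1():
    """With a pure temperature effect the temperature term is significant
    and pH/interaction reject at roughly the nominal rate over seeds."""
    temp_sig, ph_rej, int_rej = 0, 0, 0
    n_rep = 60
    for seed in range(n_rep):
        df = _design_a(seed=100 + seed, temp_effect=(0.0, 0.25, 0.5), ph_effect=0.0)
        fit = fit_linear_model(
            df, DesignSpec(design="A", response="smr", transform="log10",
                           covariate="wet_mass")
        )
        tab = fit.anova_table
        temp_sig += tab.loc["C(temperature)", "PR(>F)"] < 0.05
        ph_rej += tab.loc["C(ph)", "PR(>F)"] < 0.05
        int_rej += tab.loc["C(temperature):C(ph)", "PR(>F)"] < 0.05
    assert temp_sig == n_rep
    assert ph_rej / n_rep < 0.15
    assert int_rej / n_rep < 0.15


def test_slope_homogeneity_check_accepts_common_slope_at_nominal_rate():
    ps = []
    for seed in range(30):
        df = _design_a(seed=300 + seed)
        fit = fit_linear_model(
            df, DesignSpec(design="A", response="smr", transform="log10",
                           covariate="wet_mass")
        )
        f, dfn, dfd, p = fit.slope_homogeneity
        assert dfn == 3  # temperature x covariate (2) + ph x covariate (1)
        ps.append(p)
    # slopes generated homogeneous -> roughly nominal rejection
    assert np.mean(np.asarray(ps) < 0.05) <= 0.15


def test_ancova_with_null_covariate_reproduces_anova_f():
    df = _design_b(seed=7)
    plain = fit_linear_model(df, DesignSpec(design="B", response="mmr"))
    # a covariate unrelated to the response barely perturbs the factor F
    with_cov = fit_linear_model(
        df, DesignSpec(design="B", response="mmr", covariate="wet_mass")
    )
    f1 = plain.anova_table.loc["C(treatment)", "F"]
    f2 = with_cov.anova_table.loc["C(treatment)", "F"]
    assert f2 == pytest.approx(f1, rel=0.15)


# --- assumptions ------------------------------------------------------------


def test_assumption_checks_nominal_rejection_rates():
    sw_rej, bf_ps = 0, []
    n_rep = 150
    for seed in range(n_rep):
        rng = np.random.default_rng(1000 + seed)
        df = _design_b(seed=2000 + seed, sd=0.25)
        fit = fit_linear_model(df, DesignSpec(design="B", response="mmr"))
        rep = check_assumptions(fit)
        sw_rej += rep.shapiro[1] < 0.05
        bf_ps.append(rep.brown_forsythe[1])
    assert sw_rej / n_rep == pytest.approx(0.05, abs=0.04)
    # equal variances by construction -> Brown-Forsythe p uniform
    assert sps.kstest(bf_ps, "uniform").pvalue > 0.01


def test_constant_residuals_degenerate():
    df = _design_b(seed=8)
    df["mmr"] = 2.0
    fit = fit_linear_model(df, DesignSpec(design="B", response="mmr"))
    rep = check_assumptions(fit)
    assert "degenerate_constant_residuals" in rep.flags


# --- Tukey ------------------------------------------------------------------


def test_two_group_tukey_equals_pooled_t_test():
    rng = np.random.default_rng(9)
    df = pd.DataFrame(
        {"treatment": ["A"] * 10 + ["B"] * 10,
         "mmr": np.r_[rng.normal(1.0, 0.2, 10), rng.normal(1.3, 0.2, 10)]}
    )
    fit = fit_linear_model(df, DesignSpec(design="B", response="mmr"))
    post = tukey_hsd(fit, "treatment")
    t_res = sps.ttest_ind(
        df.loc[df.treatment == "A", "mmr"], df.loc[df.treatment == "B", "mmr"]
    )
    assert post.table["p_adjusted"].iloc[0] == pytest.approx(t_res.pvalue, rel=1e-6)


def test_three_identical_groups_no_significant_pairs():
    rng = np.random.default_rng(10)
    df = pd.DataFrame(
        {"treatment": np.repeat(["A", "B", "C"], 12),
         "mmr": rng.normal(1.0, 0.2, 36)}
    )
    fit = fit_linear_model(df, DesignSpec(design="B", response="mmr"))
    post = tukey_hsd(fit, "treatment")
    assert not post.table["significant"].any()
    assert len(set(post.letters.values())) == 1


def test_distinct_temperature_means_get_ordered_letters():
    """A strong monotone temperature effect (the metabolic-rate pattern)
    separates all three levels into letters a/b/c ordered by mean."""
    df = _design_a(seed=11, temp_effect=(0.0, 0.35, 0.7), sd=0.05)
    fit = fit_linear_model(
        df, DesignSpec(design="A", response="smr", transform="log10",
                       covariate="wet_mass")
    )
    post = tukey_hsd(fit, "temperature")
    assert post.table["significant"].all()
    assert post.letters["10"] == "a"  # highest mean
    assert post.letters["6"] == "b"
    assert post.letters["2"] == "c"


def test_tukey_p_at_least_unadjusted_and_bonferroni_at_least_tukey():
    df = _design_b(seed=12, means=(1.0, 1.1, 1.25, 1.4), sd=0.3)
    fit = fit_linear_model(df, DesignSpec(design="B", response="mmr"))
    post = tukey_hsd(fit, "treatment")
    mse = float(np.sum(fit.residuals**2) / fit.result.df_resid)
    m = len(post.table)
    for _, row in post.table.iterrows():
        ga = df.loc[df.treatment == row.level_a, "mmr"]
        gb = df.loc[df.treatment == row.level_b, "mmr"]
        se = np.sqrt(mse * (1 / len(ga) + 1 / len(gb)))
        t = abs(ga.mean() - gb.mean()) / se
        p_unadj = 2 * sps.t.sf(t, fit.result.df_resid)
        assert row.p_adjusted >= p_unadj - 1e-12
        assert min(1.0, p_unadj * m) >= row.p_adjusted - 1e-12


# --- Welch / Games-Howell ---------------------------------------------------


def test_two_group_games_howell_equals_welch_t_test():
    rng = np.random.default_rng(13)
    df = pd.DataFrame(
        {"treatment": ["A"] * 12 + ["B"] * 12,
         "y": np.r_[rng.normal(1.0, 0.1, 12), rng.normal(1.4, 0.5, 12)]}
    )
    res = welch_games_howell(df, "y", "treatment")
    welch_p = sps.ttest_ind(
        df.loc[df.treatment == "A", "y"], df.loc[df.treatment == "B", "y"],
        equal_var=False,
    ).pvalue
    assert res.posthoc.table["p_adjusted"].iloc[0] == pytest.approx(welch_p, rel=1e-6)
    assert res.p == pytest.approx(welch_p, rel=1e-6)


def test_welch_approaches_classical_anova_with_equal_variances():
    rng = np.random.default_rng(14)
    df = pd.DataFrame(
        {"treatment": np.repeat(["A", "B", "C"], 60),
         "y": rng.normal(np.repeat([1.0, 1.1, 1.2], 60), 0.3)}
    )
    res = welch_games_howell(df, "y", "treatment")
    f, p = sps.f_oneway(*[g["y"].values for _, g in df.groupby("treatment")])
    assert res.f == pytest.approx(f, rel=0.15)
    assert (res.p < 0.05) == (p < 0.05)


def test_cs_cox_like_pattern_separates_extremes_only():
    """Highest ratio in the reference treatment, lowest under combined
    drivers, overlapping middles: only the extreme pair separates."""
    rng = np.random.default_rng(15)
    rows = []
    for code, mu, sd, n in (
        ("2C", 3.37, 0.5, 9), ("2CH", 2.81, 0.8, 9),
        ("10A", 3.01, 1.8, 9), ("10AH", 1.97, 0.7, 9),
    ):
        for _ in range(n):
            rows.append({"treatment": code, "cs_cox": max(0.2, rng.normal(mu, sd))})
    df = pd.DataFrame(rows)
    res = welch_games_howell(df, "cs_cox", "treatment", transform="log10")
    tab = res.posthoc.table.set_index(["level_a", "level_b"])

    def sig(a, b):
        key = (a, b) if (a, b) in tab.index else (b, a)
        return bool(tab.loc[key, "significant"])

    assert sig("2C", "10AH")
    assert not sig("2CH", "10A")
    assert not sig("2C", "2CH")


def test_zero_variance_group_rejected():
    df = pd.DataFrame({"treatment": ["A"] * 3 + ["B"] * 3, "y": [1, 1, 1, 2, 3, 4]})
    with pytest.raises(ValueError, match="zero-variance"):
        welch_games_howell(df, "y", "treatment")


# --- letters ----------------------------------------------------------------


def test_compact_letters_consistent_with_significance():
    levels = ["a1", "a2", "b1", "b2"]
    means = {"a1": 4.0, "a2": 3.8, "b1": 1.0, "b2": 0.9}
    sig = [("a1", "b1"), ("a1", "b2"), ("a2", "b1"), ("a2", "b2")]
    letters = compact_letters(levels, means, sig)
    for x, y in sig:
        assert not set(letters[x]) & set(letters[y])
    assert set(letters["a1"]) & set(letters["a2"])
    assert set(letters["b1"]) & set(letters["b2"])


# --- correlations and percent change ----------------------------------------


def test_pearson_perfect_and_null():
    x = np.arange(20.0)
    r, p = pearson_correlation(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    rng = np.random.default_rng(16)
    rs = [
        pearson_correlation(rng.normal(size=50), rng.normal(size=50))[0]
        for _ in range(50)
    ]
    assert abs(np.mean(rs)) < 0.05


def test_pearson_rejects_degenerate_input():
    with pytest.raises(ValueError):
        pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        pearson_correlation([1.0, 2.0], [1.0, 2.0])


def test_percent_change_reference_cases():
    assert percent_change(0.38, 0.72) == pytest.approx(89.47, abs=0.01)
    assert percent_change(1.66, 1.23) == pytest.approx(-25.90, abs=0.01)
    assert percent_change(1.0, 1.0) == 0.0
    with pytest.raises(ValueError):
        percent_change(0.0, 1.0)
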