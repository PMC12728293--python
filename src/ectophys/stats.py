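"""Fixed-effects treatment statistics for the multi-driver design.

Two designs are analysed.  Design A crosses temperature (3 levels) with pH
(2 levels) under normoxia, with the interaction term; Design B treats the
four corner treatments (low/high temperature × normoxia/hypoxia at matched
pH) as a one-way factor.  Metabolic responses are log10-transformed with
log10 wet mass as covariate (ANCOVA); enzyme responses use plain ANOVA with
per-response transforms.  F tests use Type-II sums of squares.  Post-hoc
machinery: Tukey–Kramer on covariate-adjusted means (studentized range),
Welch's heteroscedastic ANOVA with Games–Howell where variances are unequal,
and compact letter displays throughout.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "DesignSpec",
    "ModelFit",
    "AssumptionReport",
    "PosthocResult",
    "TRANSFORM_REGISTRY",
    "fit_linear_model",
    "check_assumptions",
    "tukey_hsd",
    "welch_games_howell",
    "pearson_correlation",
    "percent_change",
    "compact_letters",
]

#: Response -> transform, mirroring the published analysis: metabolic rates
#: and wet mass on log10; enzyme activities identity except COX (Design A
#: only), ETS and CS:COX which need log10 for normality.
TRANSFORM_REGISTRY: dict[str, str] = {
    "smr": "log10",
    "mmr": "log10",
    "aerobic_scope": "log10",
    "wet_mass": "log10",
    "ETS": "log10",
    "CS:COX": "log10",
}


@dataclass
class DesignSpec:
    """What to fit: design, response, transform and optional mass covariate.

    ``design`` "A" expects ``temperature`` and ``ph`` columns (crossed, with
    interaction); "B" expects a ``treatment`` column (one-way).
    """

    design: str  # "A" or "B"
    response: str
    transform: str | None = None  # None or "log10"
    covariate: str | None = None  # column holding wet mass, log10-applied

    def __post_init__(self) -> None:
        if self.design not in ("A", "B"):
            raise ValueError("design must be 'A' or 'B'")
        if self.transform not in (None, "log10"):
            raise ValueError("transform must be None or 'log10'")

    @property
    def factors(self) -> tuple[str, ...]:
        return ("temperature", "ph") if self.design == "A" else ("treatment",)


@dataclass
class ModelFit:
    spec: DesignSpec
    result: object  # statsmodels RegressionResults
    anova_table: pd.DataFrame  # Type-II F table
    data: pd.DataFrame  # internal frame with _y/_x columns
    slope_homogeneity: tuple[float, float, float, float] | None = None  # F, dfn, dfd, p
    flags: set[str] = field(default_factory=set)

    @property
    def residuals(self) -> np.ndarray:
        return np.asarray(self.result.resid)


def _prepare(data: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    df = data.copy()
    missing = [c for c in (*spec.factors, spec.response) if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    y = df[spec.response].astype(float)
    if spec.transform == "log10":
        if (y <= 0).any():
            raise ValueError(
                f"log10 transform requires positive {spec.response} values"
            )
        y = np.log10(y)
    df["_y"] = y
    if spec.covariate is not None:
        x = df[spec.covariate].astype(float)
        if (x <= 0).any():
            raise ValueError("covariate must be positive for the log10 transform")
        df["_x"] = np.log10(x)
    for f in spec.factors:
        df[f] = df[f].astype(str)
    return df


def _formula(spec: DesignSpec, *, slopes: bool = False) -> str:
    if spec.design == "A":
        rhs = "C(temperature) * C(ph)"
    else:
        rhs = "C(treatment)"
    if spec.covariate is not None:
        rhs += " + _x"
        if slopes:
            for f in spec.factors:
                rhs += f" + C({f}):_x"
    return "_y ~ " + rhs


def fit_linear_model(data: pd.DataFrame, spec: DesignSpec) -> ModelFit:
    """Least-squares fit with Type-II F tests and a slope-homogeneity check.

    The homogeneity of regression slopes (an ANCOVA prerequisite) is checked
    by adding factor×covariate interactions and testing them jointly against
    the base model.  Empty design cells raise, naming the cell; a constant
    response is flagged ``degenerate_zero_variance``.
    """
    df = _prepare(data, spec)
    counts = df.groupby(list(spec.factors), observed=True).size()
    full_index = list(itertools.product(*(sorted(df[f].unique()) for f in spec.factors)))
    for cell in full_index:
        key = cell if len(cell) > 1 else cell[0]
        if key not in counts.index:
            raise ValueError(f"empty design cell: {dict(zip(spec.factors, cell))}")
        if counts.loc[key] < 2:
            warnings.warn(
                f"design cell {dict(zip(spec.factors, cell))} has a single "
                "observation",
                stacklevel=2,
            )
    res = smf.ols(_formula(spec), data=df).fit()
    if res.df_resid <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")
    flags: set[str] = set()
    if np.isclose(float(np.var(df["_y"])), 0.0):
        flags.add("degenerate_zero_variance")
        table = pd.DataFrame()
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = anova_lm(res, typ=2)
    slope_hom = None
    if spec.covariate is not None and "degenerate_zero_variance" not in flags:
        res_aug = smf.ols(_formula(spec, slopes=True), data=df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmp = anova_lm(res, res_aug)
        slope_hom = (
            float(cmp["F"].iloc[1]),
            float(cmp["df_diff"].iloc[1]),
            float(cmp["df_resid"].iloc[1]),
            float(cmp["Pr(>F)"].iloc[1]),
        )
    return ModelFit(
        spec=spec,
        result=res,
        anova_table=table,
        data=df,
        slope_homogeneity=slope_hom,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# assumption checks


@dataclass
class AssumptionReport:
    shapiro: tuple[float, float] | None
    brown_forsythe: tuple[float, float] | None
    fligner: tuple[float, float] | None
    flags: set[str] = field(default_factory=set)


def check_assumptions(fit: ModelFit) -> AssumptionReport:
    """Shapiro–Wilk on residuals; Brown–Forsythe (median-centred Levene) and
    Fligner–Killeen on residuals across design cells.

    Cells with fewer than 2 residuals are excluded with a warning; constant
    residuals make every test degenerate and are flagged instead of tested.
    """
    resid = fit.residuals
    flags: set[str] = set()
    if np.allclose(resid, resid[0]):
        flags.add("degenerate_constant_residuals")
        return AssumptionReport(None, None, None, flags)
    sw = _sps.shapiro(resid)
    cells = fit.data.groupby(list(fit.spec.factors), observed=True)
    groups = []
    for key, idx in cells.groups.items():
        g = resid[fit.data.index.get_indexer(idx)]
        if g.size < 2:
            warnings.warn(f"cell {key} has < 2 residuals; excluded", stacklevel=2)
            continue
        groups.append(g)
    bf = fl = None
    if len(groups) >= 2:
        bf_res = _sps.levene(*groups, center="median")
        fl_res = _sps.fligner(*groups)
        bf = (float(bf_res.statistic), float(bf_res.pvalue))
        fl = (float(fl_res.statistic), float(fl_res.pvalue))
    return AssumptionReport(
        shapiro=(float(sw.statistic), float(sw.pvalue)),
        brown_forsythe=bf,
        fligner=fl,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# post-hoc comparisons


@dataclass
class PosthocResult:
    method: str  # tukey_hsd | games_howell
    term: str
    table: pd.DataFrame  # level_a, level_b, estimate, ci_low, ci_high, p_adjusted, significant
    letters: dict[str, str]
    adjusted_means: dict[str, float]


def _adjusted_mean_rows(fit: ModelFit, term: str) -> dict[str, np.ndarray]:
    """Design-matrix row whose product with beta is the covariate-adjusted
    marginal mean of each ``term`` level (other factors averaged, covariate
    at its grand mean)."""
    from patsy import build_design_matrices

    spec = fit.spec
    df = fit.data
    design_info = fit.result.model.data.design_info
    others = [f for f in spec.factors if f != term]
    rows: dict[str, np.ndarray] = {}
    for level in sorted(df[term].unique()):
        grid = {term: [level]}
        for o in others:
            grid[o] = sorted(df[o].unique())
        combos = pd.DataFrame(
            list(itertools.product(*grid.values())), columns=list(grid.keys())
        )
        if spec.covariate is not None:
            combos["_x"] = float(df["_x"].mean())
        (mat,) = build_design_matrices([design_info], combos)
        rows[level] = np.asarray(mat).mean(axis=0)
    return rows


def tukey_hsd(fit: ModelFit, term: str, alpha: float = 0.05) -> PosthocResult:
    """Tukey HSD (Tukey–Kramer under imbalance) on a fitted model's factor.

    Pairwise differences of covariate-adjusted marginal means with standard
    errors from the model's coefficient covariance; p-values from the
    studentized-range distribution with the model's residual df.  With a
    covariate present this is the adjusted-means comparison an ANCOVA calls
    for.  Includes a compact letter display ordered by adjusted mean.
    """
    if term not in fit.spec.factors:
        raise ValueError(f"{term!r} is not a factor of this model")
    rows = _adjusted_mean_rows(fit, term)
    levels = list(rows.keys())
    k = len(levels)
    if k < 2:
        raise ValueError("post-hoc needs at least 2 levels")
    df_resid = float(fit.result.df_resid)
    beta = np.asarray(fit.result.params)
    cov = np.asarray(fit.result.cov_params())
    means = {lv: float(rows[lv] @ beta) for lv in levels}
    recs = []
    sig_pairs = []
    for a, b in itertools.combinations(levels, 2):
        c = rows[a] - rows[b]
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        q = abs(est) / (se / np.sqrt(2.0)) if se > 0 else np.inf
        p = float(_sps.studentized_range.sf(q, k, df_resid))
        q_crit = float(_sps.studentized_range.ppf(1 - alpha, k, df_resid))
        half = q_crit * se / np.sqrt(2.0)
        sig = p < alpha
        if sig:
            sig_pairs.append((a, b))
        recs.append((a, b, est, est - half, est + half, p, sig))
    table = pd.DataFrame(
        recs,
        columns=[
            "level_a", "level_b", "estimate", "ci_low", "ci_high",
            "p_adjusted", "significant",
        ],
    )
    letters = compact_letters(levels, means, sig_pairs)
    return PosthocResult("tukey_hsd", term, table, letters, means)


@dataclass
class WelchAnovaResult:
    f: float
    df_num: float
    df_den: float
    p: float
    posthoc: PosthocResult


def welch_games_howell(
    data: pd.DataFrame,
    response: str,
    group: str,
    transform: str | None = None,
    alpha: float = 0.05,
) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA with Games–Howell post-hocs.

    Used where the homoscedasticity checks fail (in this pipeline, the
    CS:COX ratio).  Welch's F uses Satterthwaite degrees of freedom; each
    Games–Howell pair has its own Welch df and a studentized-range p-value.
    """
    import pingouin as pg

    df = data[[group, response]].dropna().copy()
    df[group] = df[group].astype(str)
    y = df[response].astype(float)
    if transform == "log10":
        if (y <= 0).any():
            raise ValueError("log10 transform requires positive values")
        y = np.log10(y)
    df["_y"] = y
    sizes = df.groupby(group)["_y"].agg(["size", "var"])
    if (sizes["size"] < 2).any():
        raise ValueError("every group needs at least 2 observations")
    if np.isclose(sizes["var"], 0.0).any():
        raise ValueError("zero-variance group: Welch ANOVA undefined")
    w = pg.welch_anova(data=df, dv="_y", between=group)
    gh = pg.pairwise_gameshowell(data=df, dv="_y", between=group)
    means = df.groupby(group)["_y"].mean().to_dict()
    levels = sorted(means.keys())
    recs = []
    sig_pairs = []
    for _, r in gh.iterrows():
        a, b = str(r["A"]), str(r["B"])
        est = float(r["diff"])
        se = float(r["se"])
        dfp = float(r["df"])
        p = float(r["pval"])
        q_crit = float(_sps.studentized_range.ppf(1 - alpha, len(levels), dfp))
        half = q_crit * se / np.sqrt(2.0)
        sig = p < alpha
        if sig:
            sig_pairs.append((a, b))
        recs.append((a, b, est, est - half, est + half, p, sig))
    table = pd.DataFrame(
        recs,
        columns=[
            "level_a", "level_b", "estimate", "ci_low", "ci_high",
            "p_adjusted", "significant",
        ],
    )
    letters = compact_letters(levels, means, sig_pairs)
    post = PosthocResult("games_howell", group, table, letters, means)
    return WelchAnovaResult(
        f=float(w["F"].iloc[0]),
        df_num=float(w["ddof1"].iloc[0]),
        df_den=float(w["ddof2"].iloc[0]),
        p=float(w["p_unc"].iloc[0]),
        posthoc=post,
    )


def compact_letters(
    levels: list[str],
    means: dict[str, float],
    significant_pairs: list[tuple[str, str]],
) -> dict[str, str]:
    """Compact letter display via insert-and-absorb.

    Levels sharing a letter are not significantly different; every
    significant pair shares no letter.  Letters are assigned in descending
    order of group mean so 'a' marks the highest-mean homogeneous set.
    """
    groups: list[set[str]] = [set(levels)]
    for a, b in significant_pairs:
        nxt: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                nxt.append(g - {a})
                nxt.append(g - {b})
            else:
                nxt.append(g)
        # absorb duplicates and subsets
        nxt = [g for g in nxt if g]
        groups = []
        for g in nxt:
            if any(g < h for h in nxt) or g in groups:
                continue
            groups.append(g)
    groups.sort(key=lambda g: -max(means[lv] for lv in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lv: "" for lv in levels}
    for letter, g in zip(alphabet, groups):
        for lv in g:
            out[lv] += letter
    return {lv: "".join(sorted(s)) for lv, s in out.items()}


# ---------------------------------------------------------------------------
# simple summaries


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if np.isclose(x.var(), 0.0) or np.isclose(y.var(), 0.0):
        raise ValueError("zero variance: correlation undefined")
    r, p = _sps.pearsonr(x, y)
    return float(r), float(p)


def percent_change(reference_mean: float, comparison_mean: float) -> float:
    """Signed percent change 100·(comparison − reference)/reference."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (comparison_mean - reference_mean) / reference_mean
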