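"""Longitudinal and cross-sectional group statistics.

One linear mixed model per region — genotype, time and genotype x time as
fixed effects, subject as random intercept, REML — with Tukey-Kramer
adjusted pairwise comparisons of the genotype x time cell means, plus
ordinary two-way ANOVA with Bonferroni post-hoc tests for cross-sectional
(in-vitro) endpoints, and percent-difference summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range, t as t_dist

from .core import ConfigurationError

__all__ = [
    "LongitudinalFit",
    "fit_longitudinal_model",
    "percent_difference",
    "twoway_anova_bonferroni",
    "simulate_longitudinal_table",
]


@dataclass
class LongitudinalFit:
    """Mixed-model fit for one region."""

    region: str
    cell_means: pd.DataFrame          # genotype, age_months, estimate, se
    contrasts: pd.DataFrame           # pairwise cells, Tukey-Kramer adjusted
    fixed_effects: pd.Series
    random_intercept_sd: float
    residual_sd: float
    degenerate: bool
    n_subjects: int
    n_obs: int


def _tukey_kramer_p(diff: float, se: float, k: int, df: float) -> float:
    """Tukey-Kramer adjusted p for one of k(k-1)/2 pairwise comparisons."""
    if se <= 0 or df <= 0:
        return np.nan
    q = np.sqrt(2.0) * abs(diff) / se
    return float(studentized_range.sf(q, k, df))


def fit_longitudinal_model(
    table: pd.DataFrame,
    region: str | None = None,
    outcome: str = "vt",
) -> LongitudinalFit:
    """REML mixed model of ``outcome ~ genotype * time`` with random subject.

    ``table`` needs columns ``subject``, ``genotype``, ``age_months``,
    optionally ``region``, and the outcome. Missing subject-age observations
    are permitted. All pairwise comparisons among the genotype x age cell
    means are returned with Tukey-Kramer adjustment; degrees of freedom use
    a containment-style approximation (between-subject contrasts:
    n_subjects - 2; within-subject: n_obs - n_subjects - 4; mixed: the
    smaller). A vanishing random-intercept variance or non-convergence is
    flagged as degenerate, not raised.
    """
    data = table.copy()
    if region is not None:
        if "region" not in data.columns:
            raise ConfigurationError("table has no region column")
        data = data[data.region == region]
    if data.empty:
        raise ConfigurationError("no observations to fit")
    data = data.dropna(subset=[outcome])
    for genotype, sub in data.groupby("genotype"):
        if sub.subject.nunique() < 2:
            raise ConfigurationError(f"need >= 2 subjects per genotype ({genotype})")

    model = smf.mixedlm(
        f"{outcome} ~ C(genotype) * C(age_months)", data, groups=data["subject"]
    )
    with np.errstate(all="ignore"):
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            res = model.fit(reml=True)

    var_re = float(np.squeeze(res.cov_re))
    var_resid = float(res.scale)
    # one observation per subject cannot separate the variance components
    no_replication = int(data.groupby("subject").size().max()) == 1
    degenerate = (
        (not res.converged)
        or no_replication
        or var_re < 1e-8 * max(var_resid, 1e-12)
    )

    genotypes = sorted(data.genotype.unique())
    ages = sorted(data.age_months.unique())
    cells = [(g, a) for g in genotypes for a in ages]
    design_info = model.data.design_info
    from patsy import build_design_matrices

    fe_names = model.exog_names
    beta = res.fe_params.values
    cov = res.cov_params().loc[fe_names, fe_names].values

    rows = []
    lvecs = {}
    for g, a in cells:
        (mat,) = build_design_matrices(
            [design_info], pd.DataFrame({"genotype": [g], "age_months": [a]})
        )
        lv = np.asarray(mat)[0]
        lvecs[(g, a)] = lv
        est = float(lv @ beta)
        se = float(np.sqrt(lv @ cov @ lv))
        rows.append({"genotype": g, "age_months": a, "estimate": est, "se": se})
    cell_means = pd.DataFrame(rows)

    n_subjects = data.subject.nunique()
    n_obs = len(data)
    df_between = max(n_subjects - 2, 1)
    df_within = max(n_obs - n_subjects - 4, 1)
    k = len(cells)

    crows = []
    for i in range(k):
        for j in range(i + 1, k):
            (g1, a1), (g2, a2) = cells[i], cells[j]
            lv = lvecs[(g1, a1)] - lvecs[(g2, a2)]
            diff = float(lv @ beta)
            se = float(np.sqrt(lv @ cov @ lv))
            if g1 == g2:
                df = df_within
            elif a1 == a2:
                df = df_between
            else:
                df = min(df_between, df_within)
            p_raw = float(2.0 * t_dist.sf(abs(diff) / se, df)) if se > 0 else np.nan
            crows.append({
                "contrast": f"{g1}:{a1}M - {g2}:{a2}M",
                "type": "within-genotype" if g1 == g2 else (
                    "between-genotype" if a1 == a2 else "crossed"),
                "estimate": diff,
                "se": se,
                "df": df,
                "p_unadjusted": p_raw,
                "p_adjusted": _tukey_kramer_p(diff, se, k, df),
                "method": "Tukey-Kramer",
            })

    return LongitudinalFit(
        region=region if region is not None else "",
        cell_means=cell_means,
        contrasts=pd.DataFrame(crows),
        fixed_effects=res.fe_params,
        random_intercept_sd=float(np.sqrt(max(var_re, 0.0))),
        residual_sd=float(np.sqrt(var_resid)),
        degenerate=bool(degenerate),
        n_subjects=n_subjects,
        n_obs=n_obs,
    )


def percent_difference(mean_het: float, mean_wt: float) -> float:
    """Percent difference of the HET mean relative to the WT baseline.

    100 * (mean_het - mean_wt) / mean_wt, reported to one decimal truncated
    toward zero, the convention of the summary tables this mirrors (e.g.
    7.61 vs 6.61 -> +15.1%, 6.66 vs 5.66 -> +17.6%); WT is always the
    baseline.
    """
    if mean_wt == 0:
        raise ConfigurationError("baseline (WT) mean must be nonzero")
    pd_exact = 100.0 * (mean_het - mean_wt) / mean_wt
    return float(np.trunc(pd_exact * 10.0) / 10.0)


def twoway_anova_bonferroni(
    table: pd.DataFrame,
    outcome: str = "value",
    between: str = "genotype",
    across: str = "region",
) -> dict:
    """Two-way ANOVA with Bonferroni-adjusted per-level group comparisons.

    Fits ``outcome ~ between * across`` by OLS, reports the type-II ANOVA
    F-tests, and compares the two ``between`` groups within each level of
    ``across`` using the pooled residual error; raw p-values are multiplied
    by the number of levels (capped at 1).
    """
    data = table.dropna(subset=[outcome])
    counts = data.groupby([between, across], observed=True)[outcome].count()
    full = pd.MultiIndex.from_product(
        [data[between].unique(), data[across].unique()], names=[between, across]
    )
    counts = counts.reindex(full, fill_value=0)
    if (counts < 2).any():
        raise ConfigurationError("every genotype x region cell needs >= 2 observations")

    ols = smf.ols(f"{outcome} ~ C({between}) * C({across})", data).fit()
    anova = sm.stats.anova_lm(ols, typ=2)
    mse = float(ols.mse_resid)
    dfres = float(ols.df_resid)

    groups = sorted(data[between].unique())
    if len(groups) != 2:
        raise ConfigurationError("Bonferroni post-hoc implemented for exactly 2 groups")
    g1, g2 = groups
    levels = list(data[across].unique())
    m = len(levels)
    rows = []
    for lev in levels:
        sub = data[data[across] == lev]
        x1 = sub.loc[sub[between] == g1, outcome]
        x2 = sub.loc[sub[between] == g2, outcome]
        diff = float(x2.mean() - x1.mean())
        se = float(np.sqrt(mse * (1.0 / len(x1) + 1.0 / len(x2))))
        p_raw = float(2.0 * t_dist.sf(abs(diff) / se, dfres))
        rows.append({
            "contrast": f"{g2} - {g1} @ {lev}",
            "level": lev,
            "estimate": diff,
            "se": se,
            "df": dfres,
            "p_unadjusted": p_raw,
            "p_adjusted": min(1.0, m * p_raw),
            "method": "Bonferroni",
        })
    return {"anova": anova, "contrasts": pd.DataFrame(rows)}


def simulate_longitudinal_table(
    cell_means: dict[tuple[str, int], float],
    n_per_genotype: int,
    sd_subject: float,
    sd_residual: float,
    seed,
    region: str = "cerebellum",
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate a longitudinal outcome table under the mixed-model data law.

    Each subject carries a shared Normal(0, sd_subject) intercept across
    ages plus independent Normal(0, sd_residual) residuals; observations are
    dropped completely at random at ``missing_rate``. Used for type-I-error
    and power calibration of :func:`fit_longitudinal_model`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genotypes = sorted({g for g, _ in cell_means})
    ages = sorted({a for _, a in cell_means})
    rows = []
    for g in genotypes:
        for i in range(n_per_genotype):
            subj = f"{g}{i + 1:02d}"
            u = rng.normal(0.0, sd_subject)
            for a in ages:
                if missing_rate > 0 and rng.uniform() < missing_rate:
                    continue
                rows.append({
                    "subject": subj, "genotype": g, "age_months": a, "region": region,
                    "vt": cell_means[(g, a)] + u + rng.normal(0.0, sd_residual),
                })
    return pd.DataFrame(rows)
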