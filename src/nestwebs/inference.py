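"""Stability regressions and the four-scenario comparison.

Per scenario, nest-level stability responses log|mean Re(lambda_1)| are
modelled by an ordinary (Gaussian) linear model

    response ~ age_class + community_size + age_class:community_size

on nests whose local web has at least six members (smaller communities occur
only among new nests and would confound the age contrast), with sequential
(type-I) F tests per term.  The scenario report condenses the four fits into
the study's qualitative claim: an age effect under observed abundances that
vanishes once abundances are evened out, and a negative community-size
effect everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["StabilityGlmResult", "stability_glm", "scenario_report"]


@dataclass(frozen=True)
class StabilityGlmResult:
    scenario_id: str
    coefficients: pd.Series
    std_errors: pd.Series
    anova: pd.DataFrame  # per-term df, sum_sq, F, PR(>F)
    n_used: int
    excluded_nests: tuple[str, ...]

    def term_f(self, term: str) -> float:
        return float(self.anova.loc[term, "F"])

    def term_p(self, term: str) -> float:
        return float(self.anova.loc[term, "PR(>F)"])


def stability_glm(
    results: pd.DataFrame,
    min_size: int = 6,
    anova_type: int = 2,
) -> StabilityGlmResult:
    """Fit response ~ age * community size for one scenario's results table.

    ``results`` needs columns nest_id, scenario, n, response, age_class and
    must contain a single scenario.  Nests with community size below
    ``min_size`` are excluded and reported.  ``anova_type`` 2 (default)
    gives marginal tests respecting marginality (each main effect adjusted
    for the other, car::Anova-style); 1 gives sequential tests.  Marginal
    tests are the default because community size and age class are
    correlated by construction of the system — old nests host more groups —
    and a sequential age-first test would conflate the two.
    """
    scenarios = results["scenario"].unique()
    if len(scenarios) != 1:
        raise ValueError(f"expected one scenario, got {list(scenarios)}")
    unstable = results[results["response"].isna() & (results.get("error", "") == "")]
    if not unstable.empty:
        raise ValueError(
            f"nests with nonnegative mean Re(lambda1): {list(unstable['nest_id'])}"
        )
    keep = results[results["n"] >= min_size].dropna(subset=["response"])
    excluded = tuple(sorted(set(results["nest_id"]) - set(keep["nest_id"])))
    counts = keep["age_class"].value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError(
            f"need >= 2 nests per age class after the size filter, got {counts.to_dict()}"
        )
    df = keep.rename(columns={"n": "size"}).copy()
    df["age"] = (df["age_class"] == "old").astype(int)
    fit = smf.ols("response ~ age + size + age:size", data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=anova_type)
    anova = anova.rename(index={"age:size": "age:size"})
    return StabilityGlmResult(
        scenario_id=str(scenarios[0]),
        coefficients=fit.params,
        std_errors=fit.bse,
        anova=anova,
        n_used=len(df),
        excluded_nests=excluded,
    )


def scenario_report(
    glms: dict[str, StabilityGlmResult],
    alpha: float = 0.05,
) -> dict:
    """Compare the four scenario fits and issue the qualitative verdicts.

    Verdicts at significance level ``alpha``:

    * ``age_effect_obs_abundance`` — age term significant in both
      observed-abundance scenarios;
    * ``age_effect_even_abundance`` — age term significant in either
      even-abundance scenario (the study's claim is that it is *not*);
    * ``size_effect_negative_everywhere`` — community-size term significant
      with a negative slope in all four scenarios;
    * ``pattern_matches`` — age effect present under observed abundances,
      absent under even abundances, size effect negative everywhere.
    """
    required = {"observed/observed", "observed/randomized", "even/observed", "even/randomized"}
    missing = required - set(glms)
    if missing:
        raise ValueError(f"missing scenario(s): {sorted(missing)}")

    table = {}
    for sid, g in glms.items():
        table[sid] = {
            "age_F": g.term_f("age"),
            "age_p": g.term_p("age"),
            "size_F": g.term_f("size"),
            "size_p": g.term_p("size"),
            "size_slope": float(g.coefficients["size"]),
            "interaction_F": g.term_f("age:size"),
            "interaction_p": g.term_p("age:size"),
            "n_used": g.n_used,
        }
    obs_age = all(table[s]["age_p"] < alpha for s in ("observed/observed", "observed/randomized"))
    even_age = any(table[s]["age_p"] < alpha for s in ("even/observed", "even/randomized"))
    size_neg = all(
        table[s]["size_p"] < alpha and table[s]["size_slope"] < 0 for s in required
    )
    verdicts = {
        "age_effect_obs_abundance": bool(obs_age),
        "age_effect_even_abundance": bool(even_age),
        "size_effect_negative_everywhere": bool(size_neg),
        "pattern_matches": bool(obs_age and not even_age and size_neg),
    }
    return {"alpha": alpha, "scenarios": table, "verdicts": verdicts}


def fit_all_scenarios(results: pd.DataFrame, min_size: int = 6) -> dict[str, StabilityGlmResult]:
    """One GLM per scenario from a long-format run_scenarios table."""
    out = {}
    for sid, sub in results.groupby("scenario"):
        out[str(sid)] = stability_glm(sub, min_size=min_size)
    return out


def residual_diagnostics(glm: StabilityGlmResult, results: pd.DataFrame, min_size: int = 6) -> dict:
    """Shapiro normality and Breusch-Pagan heteroscedasticity on residuals.

    Reported for inspection only; never gates the fit.
    """
    from scipy import stats as sps
    from statsmodels.stats.diagnostic import het_breuschpagan

    keep = results[(results["scenario"] == glm.scenario_id) & (results["n"] >= min_size)].dropna(
        subset=["response"]
    )
    df = keep.rename(columns={"n": "size"}).copy()
    df["age"] = (df["age_class"] == "old").astype(int)
    x = np.column_stack([np.ones(len(df)), df["age"], df["size"], df["age"] * df["size"]])
    resid = df["response"].to_numpy() - x @ np.linalg.lstsq(x, df["response"].to_numpy(), rcond=None)[0]
    sw = sps.shapiro(resid)
    bp = het_breuschpagan(resid, x)
    return {
        "shapiro_w": float(sw.statistic),
        "shapiro_p": float(sw.pvalue),
        "breusch_pagan_lm_p": float(bp[1]),
    }
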