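"""Prey mortality summaries and quasi-binomial tests of vulnerability.

Mortality of prey *p* under predator *k* is the proportion of offered
individuals consumed, ``r_pk / n_p0``, using control-corrected consumption
and the original (uninflated) offers.  Whether vulnerability differs across
predators is tested per prey with a quasi-binomial GLM: a binomial-logit fit
on replicate-level proportions weighted by their denominators, a Pearson
chi-square dispersion estimate, and an analysis-of-deviance F test for the
predator factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .experiment import ControlSummary, FeedingTrial
from .selectivity import correct_for_control_mortality

__all__ = [
    "mortality_table", "MortalityTable", "quasibinomial_glm_factor",
    "GlmResult", "vulnerability_tests",
]


@dataclass(frozen=True)
class MortalityTable:
    """Mean proportion consumed per (prey x predator stage), plus grand means."""

    mean: pd.DataFrame        # prey x predator
    se: pd.DataFrame          # prey x predator
    grand_mean: pd.Series     # per prey, equal-weight mean over predator stages

    def to_frame(self) -> pd.DataFrame:
        out = self.mean.copy()
        out["grand_mean"] = self.grand_mean
        return out


def replicate_mortality(
    trials: list[FeedingTrial], controls: ControlSummary
) -> pd.DataFrame:
    """Tidy replicate-level mortality: one row per (trial x prey).

    Columns: predator stage, replicate, prey, offered ``n0``, corrected
    consumption ``r`` and the proportion ``r / n0``.
    """
    rows = []
    for t in trials:
        cv = correct_for_control_mortality(t, controls)
        for prey, r, n0 in zip(cv.prey_ids, cv.r, cv.n0):
            rows.append((t.predator_stage_id, t.replicate_id, prey, n0, r, r / n0))
    return pd.DataFrame(
        rows,
        columns=["predator_stage_id", "replicate_id", "prey_id", "n0", "r", "proportion"],
    )


def mortality_table(
    trials: list[FeedingTrial], controls: ControlSummary
) -> MortalityTable:
    """Average replicate proportions per predator stage; grand mean per prey
    weights every predator stage equally."""
    rep = replicate_mortality(trials, controls)
    g = rep.groupby(["prey_id", "predator_stage_id"])["proportion"]
    mean = g.mean().unstack()
    se = (g.std(ddof=1) / np.sqrt(g.count())).unstack()
    # preserve encounter order of the input rather than alphabetical
    prey_order = list(dict.fromkeys(rep["prey_id"]))
    stage_order = list(dict.fromkeys(rep["predator_stage_id"]))
    mean = mean.loc[prey_order, stage_order]
    se = se.loc[prey_order, stage_order]
    return MortalityTable(mean=mean, se=se, grand_mean=mean.mean(axis=1))


@dataclass(frozen=True)
class GlmResult:
    """Quasi-binomial analysis of deviance for a single factor."""

    params: pd.Series         # logit-scale coefficients
    dispersion: float         # Pearson chi-square / residual df
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    converged: bool
    separation_flag: bool     # some fitted proportions on the 0/1 boundary


def quasibinomial_glm_factor(
    proportions: np.ndarray,
    denominators: np.ndarray,
    factor: np.ndarray | list,
) -> GlmResult:
    """Binomial-logit IRLS fit of proportion ~ factor with free dispersion.

    ``proportions`` may be fractional (control-corrected counts over offers);
    each observation is weighted by its binomial denominator.  The factor
    effect is tested by ``F = (drop in deviance / drop in df) / dispersion``
    against an F reference distribution.  Complete separation (fitted values
    on the boundary) is flagged; the p-value is still reported.
    """
    y = np.asarray(proportions, dtype=float)
    n = np.asarray(denominators, dtype=float)
    fac = pd.Categorical([str(v) for v in factor])
    if len(fac.categories) < 2:
        raise ValueError("factor needs at least 2 levels")
    if (n <= 0).any():
        raise ValueError("denominators must be positive")
    x = pd.get_dummies(pd.Series(fac), drop_first=True, dtype=float)
    x.insert(0, "const", 1.0)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", sm.tools.sm_exceptions.PerfectSeparationWarning)
        model = sm.GLM(y, x.to_numpy(), family=sm.families.Binomial(), var_weights=n)
        fit = model.fit()
        null = sm.GLM(
            y, np.ones_like(y), family=sm.families.Binomial(), var_weights=n
        ).fit()
    df_num = int(null.df_resid - fit.df_resid)
    df_den = int(fit.df_resid)
    if df_den <= 0:
        raise ValueError("no residual degrees of freedom for the dispersion estimate")
    dispersion = float(fit.pearson_chi2 / fit.df_resid)
    dev_drop = float(null.deviance - fit.deviance)
    # degenerate fits (identical proportions everywhere) leave only floating-
    # point residue in both the deviance drop and the dispersion
    if dev_drop < 1e-10:
        dev_drop = 0.0
    if dispersion < 1e-10:
        dispersion = 1.0
    f_stat = max(float(dev_drop / df_num / dispersion), 0.0)
    p = float(stats.f.sf(f_stat, df_num, df_den))
    mu = fit.fittedvalues
    separation = bool((mu < 1e-8).any() or (mu > 1 - 1e-8).any())
    names = ["const"] + [f"level[{c}]" for c in list(fac.categories)[1:]]
    return GlmResult(
        params=pd.Series(fit.params, index=names),
        dispersion=dispersion,
        f_statistic=f_stat,
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        converged=bool(fit.converged),
        separation_flag=separation,
    )


def vulnerability_tests(
    trials: list[FeedingTrial], controls: ControlSummary
) -> dict[str, GlmResult]:
    """Per-prey quasi-binomial GLMs with predator stage as the factor."""
    rep = replicate_mortality(trials, controls)
    out: dict[str, GlmResult] = {}
    for prey, g in rep.groupby("prey_id", sort=False):
        out[str(prey)] = quasibinomial_glm_factor(
            g["proportion"].to_numpy(), g["n0"].to_numpy(),
            g["predator_stage_id"].to_numpy(),
        )
    return out
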