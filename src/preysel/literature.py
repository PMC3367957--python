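"""Meta-analysis of published selectivity experiments.

Each published multiple-choice experiment contributes one binary score per
offered prey taxon (1 = most preferred in that experiment, ties allowed, 0 =
anything else; an unselective experiment scores 0 everywhere).  Experiments
whose offered prey all belong to one taxon are excluded, since they cannot
rank taxa against each other.  Differences between taxa are tested with a
quasi-binomial GLM on the binary scores and multcomp-style post-hoc pairwise
contrasts; the association between predator microhabitat and the
microhabitat of the preferred prey is tested with a one-tailed Fisher exact
test on a 2x2 contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .experiment import LiteratureRecord
from .selectivity import holm_adjust
from .vulnerability import GlmResult, quasibinomial_glm_factor

__all__ = [
    "score_preferences", "PreferenceScoreTable", "score_table_from_counts",
    "preference_glm",
    "PreferenceGlmResult", "rank_matrix_occupancy", "microhabitat_table",
    "microhabitat_fisher",
]


@dataclass(frozen=True)
class PreferenceScoreTable:
    """Binary most-preferred scores in long form plus per-taxon totals."""

    scores: pd.DataFrame        # study_id, taxon, score
    per_taxon: pd.DataFrame     # taxon, n_offered, n_preferred
    n_experiments: int
    n_excluded: int             # single-taxon experiments dropped


def score_preferences(records: list[LiteratureRecord]) -> PreferenceScoreTable:
    """Score 1 for every taxon tied for most preferred, 0 otherwise.

    Experiments offering prey from a single taxon are excluded.  The result
    is independent of record order and idempotent.
    """
    rows = []
    n_excluded = 0
    for rec in sorted(records, key=lambda r: r.study_id):
        if len(set(rec.offered)) < 2:
            n_excluded += 1
            continue
        for taxon in sorted(rec.offered):
            rows.append((rec.study_id, taxon, int(taxon in rec.most_preferred)))
    scores = pd.DataFrame(rows, columns=["study_id", "taxon", "score"])
    if scores.empty:
        raise ValueError("no multi-taxon experiments to score")
    per_taxon = (
        scores.groupby("taxon")["score"]
        .agg(n_offered="count", n_preferred="sum")
        .reset_index()
    )
    return PreferenceScoreTable(
        scores=scores,
        per_taxon=per_taxon,
        n_experiments=scores["study_id"].nunique(),
        n_excluded=n_excluded,
    )


def score_table_from_counts(per_taxon: pd.DataFrame) -> PreferenceScoreTable:
    """Expand per-taxon aggregate counts into an equivalent binary score table.

    ``per_taxon`` needs columns ``taxon``, ``n_offered``, ``n_preferred``.
    A one-factor binomial GLM on binary scores depends only on these
    aggregates, so a table reconstructed this way (synthetic pseudo-experiment
    ids, one row per offering) yields the same fit as the underlying
    experiment-level records would.
    """
    rows = []
    for _, r in per_taxon.iterrows():
        n, s = int(r["n_offered"]), int(r["n_preferred"])
        if not 0 <= s <= n:
            raise ValueError(f"taxon {r['taxon']!r}: n_preferred outside [0, n_offered]")
        for i in range(n):
            rows.append((f"agg_{r['taxon']}_{i}", str(r["taxon"]), int(i < s)))
    scores = pd.DataFrame(rows, columns=["study_id", "taxon", "score"])
    return PreferenceScoreTable(
        scores=scores,
        per_taxon=per_taxon.reset_index(drop=True),
        n_experiments=len(scores),
        n_excluded=0,
    )


@dataclass(frozen=True)
class PreferenceGlmResult:
    overall: GlmResult
    taxon_means: pd.Series          # proportion preferred per taxon
    contrasts: pd.DataFrame         # pair, estimate (logit diff), z, p_raw, p_adj
    letters: dict[str, str]         # compact letter display of the grouping
    boundary_taxa: tuple[str, ...]  # never / always preferred (flagged)
    adjustment: str


def preference_glm(
    table: PreferenceScoreTable,
    adjustment: str = "single-step",
    seed: int = 0,
    mc_draws: int = 50_000,
) -> PreferenceGlmResult:
    """Taxon-factor quasi-binomial GLM on binary scores with post-hoc contrasts.

    The overall F comes from the analysis of deviance against the
    intercept-only model.  Pairwise contrasts compare taxon logits using the
    dispersion-scaled covariance; family-wise adjustment is either the
    multcomp-style single-step max-modulus correction (estimated from seeded
    Monte Carlo draws of the joint contrast distribution) or Holm's step-down
    (``adjustment="holm"``).  Taxa never (or always) preferred sit on the
    boundary of the parameter space; their contrasts use the fitted
    covariance but are flagged.
    """
    scores = table.scores
    taxa = sorted(scores["taxon"].unique())
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    overall = quasibinomial_glm_factor(
        scores["score"].to_numpy(float),
        np.ones(len(scores)),
        scores["taxon"].to_numpy(),
    )
    # cell-means fit: one logit per taxon, covariance scaled by the dispersion
    x = pd.get_dummies(scores["taxon"], dtype=float)[taxa]
    fit = sm.GLM(
        scores["score"].to_numpy(float), x.to_numpy(), family=sm.families.Binomial()
    ).fit(maxiter=200)
    coefs = pd.Series(fit.params, index=taxa)
    cov = np.asarray(fit.cov_params()) * overall.dispersion
    means = scores.groupby("taxon")["score"].mean()[taxa]
    boundary = tuple(t for t in taxa if means[t] in (0.0, 1.0))

    pairs = [(a, b) for i, a in enumerate(taxa) for b in taxa[i + 1 :]]
    c_mat = np.zeros((len(pairs), len(taxa)))
    for r, (a, b) in enumerate(pairs):
        c_mat[r, taxa.index(a)] = 1.0
        c_mat[r, taxa.index(b)] = -1.0
    est = c_mat @ coefs.to_numpy()
    var = np.einsum("ij,jk,ik->i", c_mat, cov, c_mat)
    se = np.sqrt(np.maximum(var, 1e-300))
    z = est / se
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    if adjustment == "holm":
        p_adj = holm_adjust(p_raw)
    elif adjustment == "single-step":
        p_adj = _max_modulus_adjust(z, c_mat, cov, se, seed, mc_draws)
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    contrasts = pd.DataFrame(
        {
            "taxon_a": [a for a, _ in pairs],
            "taxon_b": [b for _, b in pairs],
            "estimate": est,
            "z": z,
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )
    letters = _compact_letters(taxa, means, contrasts)
    return PreferenceGlmResult(
        overall=overall,
        taxon_means=means,
        contrasts=contrasts,
        letters=letters,
        boundary_taxa=boundary,
        adjustment=adjustment,
    )


def _max_modulus_adjust(
    z: np.ndarray,
    c_mat: np.ndarray,
    cov: np.ndarray,
    se: np.ndarray,
    seed: int,
    draws: int,
) -> np.ndarray:
    """Single-step adjusted p: P(max_k |Z_k| >= |z_obs|) under the joint null."""
    rng = np.random.default_rng(seed)
    ccov = c_mat @ cov @ c_mat.T
    scale = np.outer(se, se)
    corr = ccov / scale
    # jitter for numerical positive semi-definiteness of boundary-degenerate fits
    corr = (corr + corr.T) / 2 + 1e-10 * np.eye(len(se))
    l = np.linalg.cholesky(corr)
    sims = np.abs(rng.standard_normal((draws, len(se))) @ l.T).max(axis=1)
    return np.array([(sims >= abs(zk)).mean() for zk in z])


def _compact_letters(
    taxa: list[str], means: pd.Series, contrasts: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Insert-absorb compact letter display from the adjusted contrasts."""
    order = list(means.sort_values(ascending=False).index)
    sig = {
        frozenset((r.taxon_a, r.taxon_b))
        for r in contrasts.itertuples()
        if r.p_adj < alpha
    }
    groups: list[set[str]] = []
    for t in order:
        placed = False
        for g in groups:
            if all(frozenset((t, other)) not in sig for other in g):
                g.add(t)
                placed = True
        if not placed:
            groups.append({t})
    # absorb groups fully contained in another
    groups = [
        g for g in groups
        if not any(g < other for other in groups)
    ]
    letters = {t: "" for t in taxa}
    for i, g in enumerate(groups):
        ch = chr(ord("a") + i)
        for t in g:
            letters[t] += ch
    return {t: "".join(sorted(v)) for t, v in letters.items()}


def rank_matrix_occupancy(records: list[LiteratureRecord]) -> tuple[pd.DataFrame, float]:
    """Experiments x taxa occupancy matrix and its fraction of empty cells.

    A cell is occupied when the experiment offered the taxon (rank
    information would be available there); preference-rank methods for
    incomplete rankings need roughly half the cells filled, so this fraction
    is the screening diagnostic for whether such an analysis is feasible.
    """
    multi = [r for r in records if len(set(r.offered)) >= 2]
    taxa = sorted({t for r in multi for t in r.offered})
    mat = pd.DataFrame(
        False, index=[r.study_id for r in multi], columns=taxa, dtype=bool
    )
    for r in multi:
        for t in r.offered:
            mat.loc[r.study_id, t] = True
    frac_empty = 1.0 - mat.to_numpy().mean() if mat.size else 1.0
    return mat, float(frac_empty)


def microhabitat_table(records: list[LiteratureRecord]) -> np.ndarray:
    """2x2 counts of predator microhabitat x preferred-prey microhabitat.

    An experiment contributes when all its most-preferred prey share one
    microhabitat and at least one non-preferred offered prey occupies the
    other; rows are (benthic, water_column) predators, columns (benthic,
    water_column) preferred prey.
    """
    table = np.zeros((2, 2), dtype=int)
    axis = {"benthic": 0, "water_column": 1}
    for rec in records:
        if not rec.most_preferred:
            continue
        pref_micro = {rec.offered[t] for t in rec.most_preferred}
        if len(pref_micro) != 1:
            continue
        pm = pref_micro.pop()
        other = "water_column" if pm == "benthic" else "benthic"
        has_other = any(
            rec.offered[t] == other
            for t in rec.offered
            if t not in rec.most_preferred
        )
        if not has_other:
            continue
        table[axis[rec.predator_microhabitat], axis[pm]] += 1
    return table


def microhabitat_fisher(table: np.ndarray) -> float:
    """One-tailed Fisher exact p for a positive same-microhabitat association.

    The alternative is that predators prefer prey from their own
    microhabitat, i.e. large diagonal counts for rows and columns ordered
    (benthic, water_column).
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (table < 0).any():
        raise ValueError("cell counts must be non-negative")
    return float(stats.fisher_exact(table, alternative="greater")[1])
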