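"""Manly-Chesson selectivity: alpha, electivity, diet breadth, and tests.

For one predator individual offered ``m`` prey types, with ``n_i0`` items of
prey *i* offered and ``r_i`` consumed, Manly's selectivity index is

    alpha_i = (r_i / n_i0) / sum_j (r_j / n_j0)

which estimates the probability that the next capture is prey *i* when all
prey are equally available.  Two corrections reflect the 24 h no-replacement
design:

* background mortality — the mean number of each prey dying in predator-free
  control trials is subtracted from the prey missing at the end of a trial
  (consumption may therefore be fractional);
* depletion — when an individual consumed *all* items of a prey, that prey's
  initial count is inflated by one (in its own ratio and in the normalising
  sum), assuming the extra item would have survived; the resulting alpha is
  slightly conservative.

Alpha is converted for presentation to Chesson's electivity
``eps_i = (m*alpha_i - 1) / ((m - 2)*alpha_i + 1)``, which is -1 for prey
absent from the diet, 0 for unselective feeding (alpha = 1/m) and +1 for a
pure diet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .experiment import ControlSummary, FeedingTrial

__all__ = [
    "ConsumptionVector", "SelectivityProfile", "SelectivityTestResult",
    "ZeroConsumptionError", "correct_for_control_mortality", "manly_alpha",
    "electivity", "holm_adjust", "build_profile", "test_no_selectivity",
    "compare_stages",
]


class ZeroConsumptionError(ValueError):
    """The individual consumed nothing; alpha is undefined."""


@dataclass(frozen=True)
class ConsumptionVector:
    """Control-corrected consumption of one individual, with effective offers."""

    prey_ids: tuple[str, ...]
    r: np.ndarray          # corrected consumed counts, may be fractional
    n0: np.ndarray         # original initial counts
    n0_eff: np.ndarray     # +1 where the depletion correction applies
    depleted: np.ndarray   # boolean mask of fully consumed prey

    @property
    def total_consumption(self) -> float:
        return float(self.r.sum())


def correct_for_control_mortality(
    trial: FeedingTrial,
    controls: ControlSummary,
    depletion_correction: bool = True,
) -> ConsumptionVector:
    """Corrected consumption ``r_i = clamp(missing_i - mean_dead_i, 0, n_i0)``.

    The depletion flag is raised for prey with zero survivors (the predator
    consumed every item); those prey get ``n0_eff = n0 + 1``.
    """
    prey_ids = trial.prey_ids
    missing_ctrl = set(prey_ids) - set(controls.mean_dead)
    if missing_ctrl:
        raise ValueError(f"controls do not cover prey: {sorted(missing_ctrl)}")
    n0 = np.array([trial.n_offered[p] for p in prey_ids], dtype=float)
    surv = np.array([trial.n_surviving[p] for p in prey_ids], dtype=float)
    dead = np.array([controls.mean_dead[p] for p in prey_ids], dtype=float)
    r = np.clip(n0 - surv - dead, 0.0, n0)
    depleted = surv == 0
    n0_eff = n0 + (depleted if depletion_correction else False)
    return ConsumptionVector(
        prey_ids=tuple(prey_ids), r=r, n0=n0, n0_eff=n0_eff, depleted=depleted
    )


def manly_alpha(consumption: ConsumptionVector) -> np.ndarray:
    """Normalised selectivity vector; sums to one.

    Raises :class:`ZeroConsumptionError` when nothing was consumed — such
    individuals carry no selectivity information and are excluded from
    species-level averaging by :func:`build_profile`.
    """
    ratios = consumption.r / consumption.n0_eff
    total = ratios.sum()
    if total <= 0:
        raise ZeroConsumptionError(
            "all-zero consumption vector: Manly's alpha is undefined"
        )
    return ratios / total


def electivity(alpha: np.ndarray, m: int | None = None) -> np.ndarray:
    """Chesson electivity ``(m*a - 1) / ((m - 2)*a + 1)``, in [-1, 1]."""
    alpha = np.asarray(alpha, dtype=float)
    if m is None:
        m = alpha.shape[-1]
    if m < 3:
        raise ValueError(f"electivity needs at least 3 prey types, got m={m}")
    return (m * alpha - 1.0) / ((m - 2) * alpha + 1.0)


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, never below the raw p)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


@dataclass(frozen=True)
class SelectivityTestResult:
    prey_ids: tuple[str, ...]
    t: np.ndarray
    p_raw: np.ndarray
    p_holm: np.ndarray
    significant: np.ndarray      # p_holm < 0.05
    degenerate: np.ndarray       # zero-variance prey


def test_no_selectivity(alphas: np.ndarray, prey_ids: tuple[str, ...]) -> SelectivityTestResult:
    """Per-prey one-sample t-tests of individual alphas against 1/m.

    ``alphas`` is (individuals x m).  Zero-variance prey are degenerate: p = 1
    when the common value equals 1/m, else p -> 0 (flagged, not trusted).
    Holm's step-down correction is applied across the m prey of the predator.
    """
    alphas = np.atleast_2d(np.asarray(alphas, dtype=float))
    n, m = alphas.shape
    if n < 2:
        raise ValueError("need at least 2 individuals for the selectivity t-test")
    null = 1.0 / m
    t = np.empty(m)
    p = np.empty(m)
    degenerate = np.zeros(m, dtype=bool)
    for j in range(m):
        col = alphas[:, j]
        if np.allclose(col.std(ddof=1), 0.0):
            degenerate[j] = True
            if np.isclose(col.mean(), null):
                t[j], p[j] = 0.0, 1.0
            else:
                t[j] = np.inf if col.mean() > null else -np.inf
                p[j] = 0.0
        else:
            res = stats.ttest_1samp(col, null)
            t[j], p[j] = float(res.statistic), float(res.pvalue)
    p_holm = holm_adjust(p)
    return SelectivityTestResult(
        prey_ids=tuple(prey_ids), t=t, p_raw=p, p_holm=p_holm,
        significant=p_holm < 0.05, degenerate=degenerate,
    )


@dataclass(frozen=True)
class SelectivityProfile:
    """Species-level selectivity summary for one predator stage."""

    predator_stage_id: str
    prey_ids: tuple[str, ...]
    alphas: np.ndarray            # (n_used x m) per-individual alpha vectors
    n_excluded: int               # individuals with zero total consumption
    total_consumed: np.ndarray    # summed corrected consumption per prey

    @property
    def mean_alpha(self) -> np.ndarray:
        return self.alphas.mean(axis=0)

    @property
    def se_alpha(self) -> np.ndarray:
        return self.alphas.std(axis=0, ddof=1) / np.sqrt(self.alphas.shape[0])

    @property
    def electivities(self) -> np.ndarray:
        return electivity(self.alphas, len(self.prey_ids))

    @property
    def mean_electivity(self) -> np.ndarray:
        return self.electivities.mean(axis=0)

    @property
    def se_electivity(self) -> np.ndarray:
        return self.electivities.std(axis=0, ddof=1) / np.sqrt(self.alphas.shape[0])

    @property
    def diet_breadth(self) -> int:
        """Number of prey consumed at all (mean electivity > -1)."""
        return int((self.total_consumed > 0).sum())

    def test(self) -> SelectivityTestResult:
        return test_no_selectivity(self.alphas, self.prey_ids)


def build_profile(
    predator_stage_id: str,
    trials: list[FeedingTrial],
    controls: ControlSummary,
    depletion_correction: bool = True,
) -> SelectivityProfile:
    """Per-individual alphas for one stage; zero-consumption trials are dropped.

    The species-level alpha is the arithmetic mean over individuals, matching
    a design where each individual is one replicate.
    """
    own = [t for t in trials if t.predator_stage_id == predator_stage_id]
    if not own:
        raise ValueError(f"no trials for predator stage {predator_stage_id!r}")
    prey_ids = own[0].prey_ids
    rows, totals = [], np.zeros(len(prey_ids))
    n_excluded = 0
    for t in own:
        cv = correct_for_control_mortality(t, controls, depletion_correction)
        totals += cv.r
        try:
            rows.append(manly_alpha(cv))
        except ZeroConsumptionError:
            n_excluded += 1
            warnings.warn(
                f"trial {t.predator_stage_id}/{t.replicate_id} consumed nothing; "
                "excluded from alpha averaging",
                stacklevel=2,
            )
    if not rows:
        raise ZeroConsumptionError(
            f"every individual of {predator_stage_id!r} consumed nothing"
        )
    return SelectivityProfile(
        predator_stage_id=predator_stage_id,
        prey_ids=prey_ids,
        alphas=np.vstack(rows),
        n_excluded=n_excluded,
        total_consumed=totals,
    )


@dataclass(frozen=True)
class StageContrast:
    """Per-prey two-sample t-tests between two stages of one species."""

    prey_ids: tuple[str, ...]
    t: np.ndarray        # NaN where neither stage consumed the prey
    p: np.ndarray
    missing: np.ndarray  # True where the contrast is undefined


def compare_stages(
    later: SelectivityProfile,
    earlier: SelectivityProfile,
    welch: bool = True,
) -> StageContrast:
    """Ontogenetic diet-shift contrast, oriented so that a positive t means
    the prey is more preferred by the *later* stage.

    Prey consumed by neither stage yield a missing marker (NaN), not a number.
    Welch's unequal-variance form is the default; ``welch=False`` selects the
    pooled-variance t-test.
    """
    if later.prey_ids != earlier.prey_ids:
        raise ValueError("stage profiles cover different prey rosters")
    m = len(later.prey_ids)
    t = np.full(m, np.nan)
    p = np.full(m, np.nan)
    missing = np.zeros(m, dtype=bool)
    for j in range(m):
        if later.total_consumed[j] == 0 and earlier.total_consumed[j] == 0:
            missing[j] = True
            continue
        a, b = later.alphas[:, j], earlier.alphas[:, j]
        if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
            # degenerate: identical constants give t=0/p=1, distinct constants
            # an infinite separation
            if np.isclose(a.mean(), b.mean()):
                t[j], p[j] = 0.0, 1.0
            else:
                t[j] = np.inf if a.mean() > b.mean() else -np.inf
                p[j] = 0.0
            continue
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t[j], p[j] = float(res.statistic), float(res.pvalue)
    return StageContrast(prey_ids=later.prey_ids, t=t, p=p, missing=missing)
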