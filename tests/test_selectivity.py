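"""Manly's alpha, corrections, electivity, diet breadth and t-tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from preysel.experiment import ControlSummary, FeedingTrial
from preysel.selectivity import (
    ConsumptionVector, ZeroConsumptionError, build_profile, compare_stages,
    correct_for_control_mortality, electivity, holm_adjust, manly_alpha,
)
from preysel.selectivity import test_no_selectivity as no_selectivity_test


def _cv(r, n0, n0_eff=None):
    r = np.asarray(r, float)
    n0 = np.asarray(n0, float)
    return ConsumptionVector(
        prey_ids=tuple(f"p{i}" for i in range(len(r))),
        r=r, n0=n0,
        n0_eff=np.asarray(n0_eff, float) if n0_eff is not None else n0.copy(),
        depleted=np.zeros(len(r), bool),
    )


class TestControlCorrection:
    def test_mean_control_deaths_subtracted(self):
        trial = FeedingTrial("p", "r1", {"Chironomus": 10}, {"Chironomus": 5})
        ctrl = ControlSummary({"Chironomus": 1.17})
        cv = correct_for_control_mortality(trial, ctrl)
        assert cv.r[0] == pytest.approx(10 - 5 - 1.17)

    def test_clamped_at_zero(self):
        trial = FeedingTrial("p", "r1", {"a": 10}, {"a": 10})
        cv = correct_for_control_mortality(trial, ControlSummary({"a": 0.33}))
        assert cv.r[0] == 0.0

    def test_zero_control_mortality_leaves_missing_unchanged(self):
        trial = FeedingTrial("p", "r1", {"Asellus": 10}, {"Asellus": 4})
        cv = correct_for_control_mortality(trial, ControlSummary({"Asellus": 0.0}))
        assert cv.r[0] == 6.0

    def test_controls_must_cover_roster(self):
        trial = FeedingTrial("p", "r1", {"a": 10, "b": 10}, {"a": 5, "b": 5})
        with pytest.raises(ValueError, match="controls do not cover"):
            correct_for_control_mortality(trial, ControlSummary({"a": 0.0}))


class TestManlyAlpha:
    def test_hand_computed_example(self):
        alpha = manly_alpha(_cv([5, 2, 3], [10, 10, 30]))
        assert alpha == pytest.approx([0.625, 0.25, 0.125])

    def test_equal_proportional_consumption_gives_uniform_alpha(self):
        alpha = manly_alpha(_cv([2, 2, 6], [10, 10, 30]))
        assert alpha == pytest.approx([1 / 3] * 3)

    def test_single_prey_consumed(self):
        alpha = manly_alpha(_cv([0, 4, 0], [10, 10, 30]))
        assert alpha == pytest.approx([0, 1, 0])

    def test_zero_consumption_raises(self):
        with pytest.raises(ZeroConsumptionError):
            manly_alpha(_cv([0, 0], [10, 10]))

    @given(
        st.lists(
            st.tuples(st.integers(1, 30), st.floats(0, 1)),
            min_size=2, max_size=8,
        ).filter(lambda l: any(f > 0 for _, f in l))
    )
    @settings(max_examples=100, deadline=None)
    def test_alpha_sums_to_one(self, spec):
        n0 = np.array([n for n, _ in spec], float)
        r = np.array([n * f for n, f in spec])
        alpha = manly_alpha(_cv(r, n0))
        assert alpha.sum() == pytest.approx(1.0, abs=1e-9)
        assert (alpha >= 0).all()


class TestDepletionCorrection:
    def test_plus_one_inflation(self):
        trial = FeedingTrial("p", "r1", {"a": 10, "b": 10}, {"a": 0, "b": 7})
        cv = correct_for_control_mortality(trial, ControlSummary({"a": 0.0, "b": 0.0}))
        assert cv.n0_eff.tolist() == [11, 10]
        alpha = manly_alpha(cv)
        expected = np.array([10 / 11, 3 / 10])
        assert alpha == pytest.approx(expected / expected.sum())

    def test_no_depletion_is_identity(self):
        trial = FeedingTrial("p", "r1", {"a": 10, "b": 10}, {"a": 2, "b": 7})
        cv = correct_for_control_mortality(trial, ControlSummary({"a": 0.0, "b": 0.0}))
        assert (cv.n0_eff == cv.n0).all()

    def test_two_simultaneous_depletions_still_normalised(self):
        trial = FeedingTrial("p", "r1", {"a": 10, "b": 6, "c": 10},
                             {"a": 0, "b": 0, "c": 5})
        cv = correct_for_control_mortality(
            trial, ControlSummary({"a": 0.0, "b": 0.0, "c": 0.0})
        )
        assert cv.n0_eff.tolist() == [11, 7, 10]
        assert manly_alpha(cv).sum() == pytest.approx(1.0)

    def test_correction_is_conservative(self):
        # alpha for the depleted prey is strictly below the uncorrected value
        # whenever another prey was also eaten
        trial = FeedingTrial("p", "r1", {"a": 10, "b": 10}, {"a": 0, "b": 7})
        ctrl = ControlSummary({"a": 0.0, "b": 0.0})
        corrected = manly_alpha(correct_for_control_mortality(trial, ctrl))
        uncorrected = manly_alpha(
            correct_for_control_mortality(trial, ctrl, depletion_correction=False)
        )
        assert corrected[0] < uncorrected[0]


class TestElectivity:
    def test_unselective_anchor(self):
        for m in (3, 5, 7):
            assert electivity(np.full(m, 1 / m)).tolist() == pytest.approx([0.0] * m)

    def test_range_endpoints(self):
        eps = electivity(np.array([0.0, 1.0, 0.5, 0.5]), m=7)
        assert eps[0] == -1.0
        assert eps[1] == 1.0

    def test_direct_formula_value(self):
        assert electivity(np.array([0.5]), m=7)[0] == pytest.approx(2.5 / 3.5)

    def test_rejects_degenerate_m(self):
        with pytest.raises(ValueError):
            electivity(np.array([0.5, 0.5]), m=2)

    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=9))
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_monotonicity(self, vals):
        a = np.sort(np.asarray(vals))
        eps = electivity(a, m=len(a))
        assert ((eps >= -1) & (eps <= 1)).all()
        assert (np.diff(eps) >= -1e-12).all()  # strictly increasing in alpha


class TestHolm:
    def test_hand_computed_adjustment(self):
        raw = np.array([0.001, 0.02, 0.04, 0.2, 0.5, 0.9, 0.95])
        adj = holm_adjust(raw)
        assert adj[0] == pytest.approx(0.007)
        assert adj[1] == pytest.approx(0.12)
        assert adj[2] == pytest.approx(0.20)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_never_below_raw(self, ps):
        raw = np.asarray(ps)
        adj = holm_adjust(raw)
        assert (adj >= raw - 1e-15).all()
        order = np.argsort(raw)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestNoSelectivityTest:
    def test_uniform_alphas_nonsignificant(self):
        alphas = np.full((5, 7), 1 / 7)
        res = no_selectivity_test(alphas, tuple("abcdefg"))
        assert not res.significant.any()
        assert (res.p_holm == 1.0).all()

    def test_strong_preference_detected_reliably(self):
        # planted strong preference, 8 individuals, many simulated predators
        import warnings

        from preysel.experiment import ControlSummary
        from preysel.simulate import default_config, simulate_trial

        config = default_config()
        stage = config.stages[0]  # concentrates on Chironomus
        ctrl = ControlSummary({p.id: 0.0 for p in config.prey})
        rng = np.random.default_rng(42)
        hits = 0
        runs = 40
        target = [p.id for p in config.prey].index("Chironomus")
        for _ in range(runs):
            alphas = []
            for rep in range(8):
                t = simulate_trial(config, stage, rng)
                cv = correct_for_control_mortality(t, ctrl)
                alphas.append(manly_alpha(cv))
            res = no_selectivity_test(np.vstack(alphas), tuple(p.id for p in config.prey))
            if res.significant[target] and res.t[target] > 0:
                hits += 1
        assert hits >= 0.95 * runs


class TestDietBreadthAndProfiles:
    def test_breadth_counts_consumed_prey(self, default_profiles):
        for prof in default_profiles:
            eps = electivity(prof.mean_alpha, len(prof.prey_ids))
            assert prof.diet_breadth == (prof.total_consumed > 0).sum()
            assert prof.diet_breadth <= len(prof.prey_ids)

    def test_profile_alphas_normalised(self, default_profiles):
        for prof in default_profiles:
            assert prof.alphas.sum(axis=1) == pytest.approx(
                np.ones(prof.alphas.shape[0]), abs=1e-9
            )


class TestStageContrasts:
    def _profile(self, alphas, consumed, stage_id="s"):
        from preysel.selectivity import SelectivityProfile

        return SelectivityProfile(
            predator_stage_id=stage_id,
            prey_ids=tuple(f"p{i}" for i in range(alphas.shape[1])),
            alphas=alphas, n_excluded=0,
            total_consumed=np.asarray(consumed, float),
        )

    def test_identical_samples_give_null_result(self):
        rng = np.random.default_rng(0)
        a = rng.dirichlet(np.ones(3), size=4)
        p1 = self._profile(a, [1, 1, 1], "later")
        p2 = self._profile(a.copy(), [1, 1, 1], "earlier")
        res = compare_stages(p1, p2)
        assert res.t == pytest.approx([0, 0, 0], abs=1e-12)
        assert res.p == pytest.approx([1, 1, 1])

    def test_positive_t_means_later_stage_prefers_more(self):
        later = self._profile(np.array([[0.8, 0.2]] * 4) + np.random.default_rng(1).normal(0, 0.01, (4, 2)), [1, 1])
        earlier = self._profile(np.array([[0.2, 0.8]] * 4) + np.random.default_rng(2).normal(0, 0.01, (4, 2)), [1, 1])
        res = compare_stages(later, earlier)
        assert res.t[0] > 0 > res.t[1]

    def test_prey_eaten_by_neither_stage_is_missing(self):
        rng = np.random.default_rng(3)
        a = rng.dirichlet(np.ones(3), size=4)
        p1 = self._profile(a, [1, 1, 0])
        p2 = self._profile(rng.dirichlet(np.ones(3), size=4), [1, 1, 0])
        res = compare_stages(p1, p2)
        assert res.missing[2]
        assert np.isnan(res.t[2])
        assert not res.missing[:2].any()


def test_zero_consumption_individuals_are_excluded(default_study):
    # an individual consuming nothing is dropped from averaging with a warning
    trials = list(default_study.trials[:3])
    t0 = trials[0]
    lazy = FeedingTrial(t0.predator_stage_id, "lazy", dict(t0.n_offered),
                        dict(t0.n_offered))
    with pytest.warns(UserWarning, match="consumed nothing"):
        prof = build_profile(
            t0.predator_stage_id, trials + [lazy], default_study.controls
        )
    assert prof.n_excluded >= 1
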