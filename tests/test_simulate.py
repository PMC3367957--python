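"""Generator contracts: determinism, Manly-Chesson consistency, edge paths."""

import dataclasses
import warnings

import numpy as np
import pytest

from preysel.experiment import ControlSummary, trials_to_frame
from preysel.selectivity import build_profile, correct_for_control_mortality, manly_alpha
from preysel.simulate import (
    GeneratorConfig, StageConfig, default_config, planted_module_config,
    simulate_literature, simulate_study, simulate_trial, write_study,
)


def test_default_config_mirrors_study_structure():
    config = default_config()
    assert len(config.stages) == 13
    assert len(config.prey) == 7
    offers = {p.id: p.n_offered_default for p in config.prey}
    assert offers == {"Rana": 6, "Lymnaea": 6, "Chironomus": 10, "Cloeon": 10,
                      "Culex": 10, "Asellus": 10, "Daphnia": 30}
    assert all(5 <= s.n_replicates <= 9 for s in config.stages)


def test_fixed_seed_gives_identical_fixture(tmp_path):
    s1 = simulate_study(seed=3)
    s2 = simulate_study(seed=3)
    assert s1.trials == s2.trials
    assert s1.controls == s2.controls
    write_study(s1, tmp_path / "a")
    write_study(s2, tmp_path / "b")
    assert (tmp_path / "a" / "trials.csv").read_bytes() == \
        (tmp_path / "b" / "trials.csv").read_bytes()
    assert (tmp_path / "a" / "truth.json").read_bytes() == \
        (tmp_path / "b" / "truth.json").read_bytes()


def test_different_seeds_differ():
    assert simulate_study(seed=1).trials != simulate_study(seed=2).trials


def test_trial_counts_respect_offers():
    config = default_config()
    rng = np.random.default_rng(0)
    for stage in config.stages:
        t = simulate_trial(config, stage, rng)
        for p in config.prey:
            assert 0 <= t.n_surviving[p.id] <= p.n_offered_default


def test_uniform_weights_recover_uniform_alpha():
    """With uniform attack weights and negligible depletion, the mean
    estimated alpha is 1/m for every prey (law of large numbers)."""
    from conftest import low_depletion_config

    config = low_depletion_config()
    uniform = StageConfig(
        "uni", "sp", "adult", "bottom", 5,
        {p.id: 1.0 for p in config.prey}, budget_mean=300,
    )
    ctrl = ControlSummary({p.id: 0.0 for p in config.prey})
    rng = np.random.default_rng(7)
    alphas = []
    for _ in range(200):
        t = simulate_trial(config, uniform, rng)
        cv = correct_for_control_mortality(t, ctrl)
        if cv.total_consumption > 0:
            alphas.append(manly_alpha(cv))
    mean = np.mean(alphas, axis=0)
    se = np.std(alphas, axis=0, ddof=1) / np.sqrt(len(alphas))
    m = len(config.prey)
    assert (np.abs(mean - 1 / m) <= 3 * se).all()


def test_zero_budget_trial_consumes_nothing():
    config = dataclasses.replace(default_config(), budget_distribution="fixed")
    stage = dataclasses.replace(config.stages[0], budget_mean=0)
    t = simulate_trial(config, stage, np.random.default_rng(0))
    assert all(
        t.n_surviving[p.id] <= p.n_offered_default for p in config.prey
    )
    ctrl = ControlSummary({p.id: 0.0 for p in config.prey})
    # nothing eaten (background mortality can still thin survivors)
    consumed = sum(
        p.n_offered_default - t.n_surviving[p.id]
        for p in config.prey if config.control_mortality[p.id] == 0
    )
    assert consumed == 0


def test_concentrated_weights_exercise_depletion_path():
    """A specialist with a budget above its prey's offer depletes it every time."""
    config = dataclasses.replace(default_config(), budget_distribution="fixed")
    specialist = StageConfig("spec", "sp", "adult", "bottom", 5,
                             {"Rana": 1.0}, budget_mean=12)
    rng = np.random.default_rng(1)
    ctrl = ControlSummary({p.id: 0.0 for p in config.prey})
    for _ in range(10):
        t = simulate_trial(config, specialist, rng)
        assert t.n_surviving["Rana"] == 0
        cv = correct_for_control_mortality(t, ctrl)
        assert cv.depleted[[p.id for p in config.prey].index("Rana")]
        assert cv.n0_eff[[p.id for p in config.prey].index("Rana")] == 7


def test_alpha_recovery_exact_in_low_depletion_regime(
    low_depletion_study, low_depletion_profiles
):
    """Mean estimated alpha within 3 SE of the planted normalised weights
    when prey availability stays effectively constant within a trial."""
    truth = low_depletion_study.truth
    for prof in low_depletion_profiles:
        planted = np.array([truth[prof.predator_stage_id][p] for p in prof.prey_ids])
        assert (np.abs(prof.mean_alpha - planted) <= 3 * prof.se_alpha).all(), \
            prof.predator_stage_id


def test_alpha_recovery_qualitative_at_study_scale(default_study, default_profiles):
    """At realistic 24 h consumption levels, depletion pulls alpha toward
    uniformity, so recovery of the planted weights is qualitative: strong
    overall agreement, and prey a predator never attacks stay near zero."""
    truth = default_study.truth
    planted_all, est_all = [], []
    for prof in default_profiles:
        planted = np.array([truth[prof.predator_stage_id][p] for p in prof.prey_ids])
        planted_all += planted.tolist()
        est_all += prof.mean_alpha.tolist()
        never_attacked = prof.mean_alpha[planted == 0]
        if never_attacked.size:
            # only background-mortality noise can register there
            assert never_attacked.max() < 0.1
    assert np.corrcoef(planted_all, est_all)[0, 1] > 0.9


def test_budget_distributions():
    for dist in ("negbinom", "poisson", "fixed"):
        config = dataclasses.replace(default_config(), budget_distribution=dist)
        study = simulate_study(config, seed=5)
        assert len(study.trials) == sum(s.n_replicates for s in config.stages)
    with pytest.raises(ValueError, match="budget distribution"):
        dataclasses.replace(default_config(), budget_distribution="uniform")


def test_invalid_configs_rejected():
    config = default_config()
    with pytest.raises(ValueError, match="attack weights"):
        StageConfig("bad", "sp", "adult", "bottom", 5, {"Rana": 0.0}, 5)
    with pytest.raises(ValueError, match="outside"):
        GeneratorConfig(
            prey=config.prey, stages=config.stages,
            control_mortality={p.id: 1.5 for p in config.prey},
        )


class TestLiteratureGenerator:
    def test_determinism_and_size(self):
        r1 = simulate_literature(25, seed=6)
        r2 = simulate_literature(25, seed=6)
        assert r1 == r2
        assert len(r1) == 25

    def test_empty_collection(self):
        assert simulate_literature(0, seed=0) == []
        with pytest.raises(ValueError):
            simulate_literature(-1)

    def test_zero_effects_keep_type_i_error_near_nominal(self):
        from preysel.literature import preference_glm, score_preferences

        rejections = 0
        runs = 12
        for seed in range(runs):
            records = simulate_literature(150, seed=100 + seed)
            table = score_preferences(records)
            res = preference_glm(table, adjustment="holm")
            if res.overall.p_value < 0.05:
                rejections += 1
        # with no planted signal the 5%-level rejection rate stays near nominal
        assert rejections <= 3

    def test_planted_effect_dominates(self):
        records = simulate_literature(120, taxon_effects={"Cladocera": 3.0}, seed=10)
        from preysel.literature import score_preferences

        per = score_preferences(records).per_taxon.set_index("taxon")
        prop = per["n_preferred"] / per["n_offered"]
        assert prop["Cladocera"] > 0.5
        assert prop["Cladocera"] == prop.max()
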