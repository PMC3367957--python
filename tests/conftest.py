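import dataclasses
import warnings

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from preysel.selectivity import build_profile
from preysel.simulate import default_config, planted_module_config, simulate_study


def low_depletion_config(factor: int = 2000, budget: float = 200):
    """Study-shaped config rescaled so within-trial depletion is negligible.

    Manly's alpha estimates the planted normalised attack weights without
    bias only when prey availability stays effectively constant during a
    trial; inflating the offers while keeping a fixed moderate budget puts
    the generator in that regime.
    """
    config = default_config()
    prey = [
        dataclasses.replace(p, n_offered_default=p.n_offered_default * factor)
        for p in config.prey
    ]
    stages = [dataclasses.replace(s, budget_mean=budget) for s in config.stages]
    return dataclasses.replace(
        config, prey=prey, stages=stages,
        control_mortality={p.id: 0.0 for p in prey},
        budget_distribution="fixed",
    )


@pytest.fixture(scope="session")
def default_study():
    """Study-shaped synthetic fixture: 13 stages x 7 prey, 5-9 replicates."""
    return simulate_study(default_config(), seed=11)


@pytest.fixture(scope="session")
def default_profiles(default_study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [
            build_profile(s.id, default_study.trials, default_study.controls)
            for s in default_study.config.stages
        ]


@pytest.fixture(scope="session")
def low_depletion_study():
    return simulate_study(low_depletion_config(), seed=11)


@pytest.fixture(scope="session")
def low_depletion_profiles(low_depletion_study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [
            build_profile(s.id, low_depletion_study.trials, low_depletion_study.controls)
            for s in low_depletion_study.config.stages
        ]


@pytest.fixture(scope="session")
def planted_study():
    """Fixture with exactly block-diagonal planted attack structure."""
    return simulate_study(planted_module_config(), seed=7)


@pytest.fixture(scope="session")
def planted_profiles(planted_study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [
            build_profile(s.id, planted_study.trials, planted_study.controls)
            for s in planted_study.config.stages
        ]
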