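import numpy as np
import pytest

from regionsizer.config import (
    AccrualPattern,
    BinaryEffects,
    ContinuousEffects,
    DoseResponseModelSpec,
    GlobalDesign,
    JoiningStrategy,
    McpmodSpec,
    RegionalPlan,
    SimulationSettings,
    StudyConfig,
    TteEffects,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240808)


def make_config(
    *,
    design="superiority",
    endpoint="continuous",
    n_total=554,
    ratio=(1, 1),
    alpha=0.05,
    effects=None,
    ni_margin=None,
    direction=None,
    percentages=(10, 15, 20, 25, 30),
    regional_ratio=(1, 1),
    joining=None,
    pi=0.5,
    regional_accrual=None,
    mcpmod=None,
    n_sims=100,
    seed=1,
):
    """Programmatic StudyConfig builder used across the suite."""
    if effects is None:
        effects = {
            "continuous": ContinuousEffects(
                mean_exp=3.5, mean_ctrl=4.5, sd_exp=2.5, sd_ctrl=2.5
            ),
            "binary": BinaryEffects(p_exp=0.45, p_ctrl=0.30),
            "tte": TteEffects(
                control_median=12,
                hazard_ratio=0.7,
                target_events=380,
                accrual=AccrualPattern(mode="uniform", duration_months=24),
            ),
        }[endpoint]
    return StudyConfig(
        global_design=GlobalDesign(
            design=design,
            endpoint=endpoint,
            n_total=n_total,
            ratio=ratio,
            alpha=alpha,
            effects=effects,
            ni_margin=ni_margin,
            direction=direction,
        ),
        regional=RegionalPlan(
            percentages=list(percentages),
            regional_ratio=regional_ratio,
            joining=joining or JoiningStrategy(mode="complete"),
            pi=pi,
            regional_accrual=regional_accrual,
        ),
        mcpmod=mcpmod,
        sim=SimulationSettings(n_sims=n_sims, seed=seed),
    )


def make_mcpmod_spec(
    *,
    doses=(0, 10, 25, 50, 100),
    n_per_dose=(60, 60, 60, 60, 60),
    e0=1.25,
    emax_effect=0.15,
    sd=0.34,
    delta=None,
    signal_type=1,
    alpha_mct=0.025,
    candidate_models=None,
    true_model_index=0,
):
    if candidate_models is None:
        candidate_models = [
            DoseResponseModelSpec(family="emax", ed50=2.6),
            DoseResponseModelSpec(family="emax", ed50=12.5),
            DoseResponseModelSpec(family="sigmoid_emax", ed50=25, hill=3),
            DoseResponseModelSpec(family="quadratic"),
        ]
    return McpmodSpec(
        doses=list(doses),
        n_per_dose=list(n_per_dose),
        e0=e0,
        emax_effect=emax_effect,
        sd=sd,
        delta=delta,
        candidate_models=candidate_models,
        true_model_index=true_model_index,
        signal_type=signal_type,
        alpha_mct=alpha_mct,
    )


@pytest.fixture
def continuous_554_config():
    """The 554-participant continuous superiority worked example."""
    return make_config()
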