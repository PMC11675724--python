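import pytest
from hypothesis import HealthCheck, settings

from cxlsim.parameters import LifeTable, LifeTableRow, ModelParams, TransitionParams, UtilityMap
from cxlsim.synthetic_data import default_params

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def base_params() -> ModelParams:
    return default_params()


def constant_life_table(qx: float, start_age: int = 18, horizon_age: int = 90) -> LifeTable:
    return LifeTable(
        rows=[LifeTableRow(age=a, qx=qx) for a in range(start_age, horizon_age + 1)]
    )


def toy_params(
    progression=(0.15, 0.0),
    transplant=(0.05, 0.25),
    graft_failure=(0.0,),
    utilities=(0.9, 0.6),
    initial=(0.7, 0.3),
    qx: float = 0.01,
    start_age: int = 18,
    horizon_age: int = 40,
    n_patients: int = 2000,
) -> ModelParams:
    """Small two-VA-state model with an analytically tractable state space."""
    params = default_params()
    params.transitions = TransitionParams(
        n_va_states=len(progression),
        progression_prob=list(progression),
        transplant_prob=list(transplant),
        graft_failure_prob=list(graft_failure),
        post_transplant_va=0,
        initial_va_marginal=list(initial),
    )
    params.utilities = UtilityMap(utility_by_better_eye_va=list(utilities))
    params.life_table = constant_life_table(qx, start_age, horizon_age)
    params.econ.start_age = start_age
    params.econ.horizon_age = horizon_age
    params.econ.n_patients = n_patients
    return ModelParams.model_validate(params.model_dump())
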