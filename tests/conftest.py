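import numpy as np
import pytest

from vancopk import (CohortConfig, CovariateRecord, ModelSpec, Regimen,
                     ResidualErrorModel, StructuralParams)


@pytest.fixture
def neonate_cov():
    return CovariateRecord(weight=2.5, postnatal_age=17.0,
                           gestational_age=37.1, serum_creatinine=29.0,
                           height=48.0, sex="female")


@pytest.fixture
def child_cov():
    return CovariateRecord(weight=12.2, postnatal_age=671.0,
                           serum_creatinine=19.0, height=80.0, sex="male")


@pytest.fixture
def regimen_q8():
    return Regimen(maintenance_dose=30.0, tau=8.0, infusion_duration=1.0)


@pytest.fixture
def params_1cmt():
    return StructuralParams(CL=5.0, V1=10.0)


@pytest.fixture
def params_2cmt():
    return StructuralParams(CL=5.0, V1=10.0, Q=3.0, V2=20.0)


def make_simple_model(n_compartments=1, random_effects=("CL", "V1"),
                      omega_diag=(0.09, 0.06), residual=None,
                      theta=None) -> ModelSpec:
    """Covariate-free model for oracle tests."""
    if theta is None:
        theta = {"CL": 0.15, "V1": 1.4}
        if n_compartments == 2:
            theta.update({"Q": 0.3, "V2": 1.0})
    if residual is None:
        residual = ResidualErrorModel(kind="additive", sigma_add=1.0)
    k = len(random_effects)
    omega = (np.diag(omega_diag[:k])).tolist()
    return ModelSpec(name="simple", n_compartments=n_compartments,
                     theta=theta, covariate_terms=[],
                     random_effects=list(random_effects), omega=omega,
                     residual_model=residual)


@pytest.fixture
def simple_model():
    return make_simple_model()


def random_params(rng, two_cmt=False):
    CL = rng.uniform(0.05, 8.0)
    V1 = rng.uniform(0.5, 50.0)
    if not two_cmt:
        return StructuralParams(CL=CL, V1=V1)
    return StructuralParams(CL=CL, V1=V1, Q=rng.uniform(0.1, 10.0),
                            V2=rng.uniform(0.5, 60.0))


def low_noise(model: ModelSpec, factor: float = 0.05) -> ModelSpec:
    """Model copy with residual sigmas scaled down."""
    res = model.residual_model
    return model.model_copy(update={"residual_model": ResidualErrorModel(
        kind=res.kind,
        sigma_add=res.sigma_add * factor if res.sigma_add else 0.0,
        sigma_prop=res.sigma_prop * factor if res.sigma_prop else 0.0)})
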