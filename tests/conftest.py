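import numpy as np
import pytest

from sdnam1 import ModelParameters, PatientSeries
from sdnam1.model import total_concentration

# a three-source parameter set whose transient, persistent and residual
# components act on clearly different time scales (sharp early transient,
# slow logistic approach, decaying baseline)
WELL_SEPARATED = ModelParameters(
    lam=600.0, k=3.0, theta=4.0, mu=0.08, r=0.25, N=25.0, x2_0=3.0, x3_0=15.0
)

# a dozen observation days mimicking weekly-to-sparser clinical sampling
OBS_DAYS = np.array([1.0, 3, 5, 8, 12, 17, 23, 30, 40, 55, 75, 100])


@pytest.fixture
def well_separated_params() -> ModelParameters:
    return WELL_SEPARATED


@pytest.fixture
def obs_days() -> np.ndarray:
    return OBS_DAYS.copy()


def make_series(params: ModelParameters, days=OBS_DAYS, sigma: float = 0.0,
                rng=None, patient_id: str = "PT") -> PatientSeries:
    """Series sampled exactly from the model, with optional lognormal noise."""
    days = np.asarray(days, dtype=float)
    conc = total_concentration(days[days >= 0], params)
    if sigma > 0:
        conc = conc * np.exp(sigma * rng.standard_normal(conc.size))
    pre = days[days < 0]
    if pre.size:
        conc = np.concatenate([np.full(pre.size, params.x3_0), conc])
    return PatientSeries(patient_id=patient_id, days=days, concentrations=conc)
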