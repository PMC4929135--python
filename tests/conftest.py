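import numpy as np
import pytest

from endomapper.cohort import CohortTable, VariableSpec


def make_table(values, *, roles=None, scales=None, names=None, mask=None,
               asthma=None, cohort_id="test", transform_hints=None):
    """Small CohortTable factory for unit tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    names = names or [f"v{j}" for j in range(p)]
    roles = roles or ["physiology"] * p
    scales = scales or ["continuous"] * p
    hints = transform_hints or ["none"] * p
    variables = [
        VariableSpec(name=names[j], role=roles[j], scale=scales[j],
                     transform_hint=hints[j])
        for j in range(p)
    ]
    if mask is None:
        mask = np.isnan(values)
    if asthma is None:
        asthma = np.ones(n, dtype=bool)
    return CohortTable(
        cohort_id=cohort_id,
        subjects=[f"s{i}" for i in range(n)],
        variables=variables,
        values=values,
        missing_mask=np.asarray(mask, dtype=bool),
        asthma_flag=np.asarray(asthma, dtype=bool),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240611)


@pytest.fixture(scope="session")
def study_config():
    """The packaged study calibration (solved once per session)."""
    from endomapper.calibration import default_study_config
    return default_study_config(seed=1)
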