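import numpy as np
import pytest

from toripk.estimation import PKDataset, SubjectData, laplace_fit
from toripk.model_core import (
    CovariateProfile,
    FixedEffects,
    RandomEffectsSpec,
    individual_parameters,
)
from toripk.simulate import DoseEvent, solve_concentration_batch

TRUTH = {
    "cl_tv": 14.9, "v1_tv": 3710.0, "q_tv": 36.5, "v2_tv": 796.0,
    "emax_tv": -0.444, "t50": 1580.0, "gamma": 1.32, "sigma_prop": 0.19,
}

# rich shared sampling design: 5 doses of 240 mg Q3W, observations through
# washout so the CL time course is identifiable
RICH_EVENTS = [DoseEvent(k * 504.0, 240.0, 1.0) for k in range(5)]
RICH_TIMES = np.array(
    [1, 6, 24, 72, 168, 336, 503, 1007, 1511, 2015, 2200, 2600, 3000.0]
)


@pytest.fixture(scope="session")
def theta():
    return FixedEffects()


@pytest.fixture(scope="session")
def re_spec():
    return RandomEffectsSpec.from_cv()


def make_rich_dataset(n, seed, re_spec, constant_cl=False, sigma=0.19):
    """Simulate n reference-covariate subjects on the rich design."""
    rng = np.random.default_rng(seed)
    th = FixedEffects()
    etas = rng.multivariate_normal(np.zeros(3), re_spec.omega, size=n, method="eigh")
    if constant_cl:
        etas[:, 0] = 0.0
    inds = [individual_parameters(th, CovariateProfile(), e) for e in etas]
    emax = np.zeros(n) if constant_cl else np.array([i.emax_i for i in inds])
    conc = solve_concentration_batch(
        np.array([i.cl_base for i in inds]),
        np.array([i.v1 for i in inds]),
        TRUTH["q_tv"], TRUTH["v2_tv"], emax,
        TRUTH["t50"], TRUTH["gamma"], RICH_EVENTS, RICH_TIMES,
    )
    subjects = [
        SubjectData(
            subject_id=i,
            events=RICH_EVENTS,
            obs_times=RICH_TIMES,
            dv=np.maximum(conc[i] * (1 + rng.normal(0, sigma, RICH_TIMES.size)), 1e-3),
        )
        for i in range(n)
    ]
    return PKDataset(subjects)


@pytest.fixture(scope="session")
def recovery_dataset(re_spec):
    """n=200 subjects simulated from the final model on the rich design."""
    return make_rich_dataset(200, seed=7, re_spec=re_spec)


@pytest.fixture(scope="session")
def recovery_fit(recovery_dataset, re_spec):
    """Laplace fit of (cl_tv, v1_tv, emax_tv, t50) from neutral starts."""
    init = dict(TRUTH)
    init.update({"cl_tv": 10.0, "v1_tv": 3000.0, "emax_tv": -0.3, "t50": 1000.0})
    return laplace_fit(
        recovery_dataset, init, re_spec,
        ["cl_tv", "v1_tv", "emax_tv", "t50"], maxiter=300,
    )
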