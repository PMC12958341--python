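import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=20,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

import rcfqnmr as rq
from rcfqnmr.simulate import scenario_mixture, simulate_fid


def true_yields(truth):
    """Scenario ground-truth yields in wt % (scenario prep: conc * 20)."""
    return {k: 20.0 * v for k, v in truth.conc_mg_ml.items() if k != "TTB"}


@pytest.fixture(scope="session")
def panel():
    return rq.default_panel()


@pytest.fixture(scope="session")
def propyl_sigma0():
    """Noise-free propyl-selective oil: (spectrum, ground truth, fit)."""
    mix = scenario_mixture("propyl_selective", seed=7, noise_sigma=0.0)
    fid, truth = simulate_fid(mix)
    spec = rq.process_fid(fid)
    res = rq.quantify(spec)
    return spec, truth, res


@pytest.fixture(scope="session")
def phenol_rich_sigma0():
    mix = scenario_mixture("phenol_rich", seed=11, noise_sigma=0.0)
    fid, truth = simulate_fid(mix)
    spec = rq.process_fid(fid)
    res = rq.quantify(spec)
    return spec, truth, res
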