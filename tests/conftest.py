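import hypothesis
import pytest

from capriseq.simdata import SimConfig
from capriseq.workflow import SimRun, catalogue_closed_loop, run_simulation

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[hypothesis.HealthCheck.too_slow])
hypothesis.settings.load_profile("suite")


CLEAN = dict(read_error_rate=0.0, chimera_rate=0.0, trunc5_rate=0.0,
             trunc3_rate=0.0, short_read_rate=0.0)


@pytest.fixture(scope="session")
def clean_run() -> SimRun:
    """Error-free, full-length, non-chimeric reads: the closed-loop baseline."""
    return run_simulation(SimConfig(seed=5, n_reads=900, **CLEAN))


@pytest.fixture(scope="session")
def clean_catalogue(clean_run):
    from capriseq.isocat import build_catalogue
    from capriseq.workflow import flnc_transcript_models
    return build_catalogue(flnc_transcript_models(clean_run))


@pytest.fixture(scope="session")
def noisy_run() -> SimRun:
    """Defaults-on simulation: errors, truncations, chimeras, short reads."""
    return run_simulation(SimConfig(seed=9, n_reads=400))
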