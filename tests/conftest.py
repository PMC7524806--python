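import numpy as np
import pytest

from camreg import (ClassifierConfig, reference_model, simulate,
                    trace_metrics)
from camreg.config import QUICK


@pytest.fixture(scope="session")
def ref_model():
    return reference_model()


@pytest.fixture(scope="session")
def ref_metrics(ref_model):
    """Quick-tier burst metrics of the reference model (targets everywhere)."""
    res = simulate(ref_model, QUICK.burn_in + QUICK.window,
                   dt=QUICK.dt, burn_in=QUICK.burn_in)
    return trace_metrics(res)


@pytest.fixture(scope="session")
def ca_target(ref_metrics):
    return ref_metrics.mean_Ca


@pytest.fixture(scope="session")
def target_classifier(ref_metrics):
    return ClassifierConfig().with_targets(ref_metrics.burst_period,
                                           ref_metrics.duty_cycle)
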