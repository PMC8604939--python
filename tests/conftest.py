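import numpy as np
import pytest

from sstrkit import editquant, synthgen, traceio


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Trace set with context multipliers but no background noise."""
    spec = synthgen.SynthTraceSpec(
        noise_zero_prob=1.0,
        context_multiplier_sd=0.3,
        true_editing=dict(
            zip(synthgen.DEFAULT_PANEL_POSITIONS, [0.0, 0.1, 0.2, 0.3, 0.5])
        ),
        seed=11,
    )
    return synthgen.gen_trace_set(spec)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Trace set with multipliers and zero-inflated gamma background noise."""
    spec = synthgen.SynthTraceSpec(
        true_editing={p: 0.3 for p in synthgen.DEFAULT_PANEL_POSITIONS}, seed=7
    )
    return synthgen.gen_trace_set(spec)


@pytest.fixture(scope="session")
def target_map(noiseless_bundle):
    return traceio.locate_target(noiseless_bundle.sample, synthgen.FKB12_TARGET)


@pytest.fixture(scope="session")
def controls(noiseless_bundle):
    return editquant.ControlSet(
        noiseless_bundle.negative, noiseless_bundle.positives
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2021)
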