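import numpy as np
import pytest

from stabiloc.simulate import SimDecayConfig, simulate_decay_experiment

PAPER_TIMEPOINTS = (0.0, 3.0, 6.0, 9.0, 12.0, 24.0, 30.0)


@pytest.fixture(scope="session")
def timepoints():
    return np.asarray(PAPER_TIMEPOINTS)


@pytest.fixture(scope="session")
def noiseless_experiment():
    """500 transcripts, no noise, planted 10% stabilized / 5% destabilized."""
    cfg = SimDecayConfig(
        n_transcripts=500,
        noise_cv=0.0,
        frac_stabilized=0.10,
        frac_destabilized=0.05,
        fold_change=2.0,
        seed=0,
    )
    return simulate_decay_experiment(cfg)


@pytest.fixture(scope="session")
def noisy_experiment():
    """2000 transcripts at 10% multiplicative noise CV."""
    cfg = SimDecayConfig(
        n_transcripts=2000,
        noise_cv=0.10,
        frac_stabilized=0.10,
        frac_destabilized=0.05,
        fold_change=2.0,
        seed=1,
    )
    return simulate_decay_experiment(cfg)


@pytest.fixture(scope="session")
def noisy_pipeline(noisy_experiment):
    from stabiloc.stability import stability_pipeline

    control, knockdown, truth = noisy_experiment
    table, counts = stability_pipeline(control, knockdown)
    return table, counts, truth
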