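import numpy as np
import pytest

from pupilbelief import sdt, synthetic, preprocess as pp

# evidence strengths calibrated so the unbiased observer hits the design
# accuracies (70% Hard, 85% Easy) at the group sigma
SIGMA = sdt.DEFAULT_SIGMA
MU_HARD = sdt.coherence_for_accuracy(0.70, SIGMA)
MU_EASY = sdt.coherence_for_accuracy(0.85, SIGMA)


@pytest.fixture(scope="session")
def design_trials():
    """Large simulated trial set at the two design coherences (both signs)."""
    params = sdt.SDTParams(
        sigma=SIGMA,
        mu_grid=(MU_HARD, MU_EASY, -MU_HARD, -MU_EASY),
        n_per_mu=20_000,
        seed=123,
    )
    return sdt.simulate_trials(params)


@pytest.fixture(scope="session")
def small_experiment():
    """Tiny synthetic experiment (2 subjects x 2 blocks, 100 Hz) with recordings."""
    design = synthetic.TaskDesign(
        n_subjects=2, blocks_per_subject=2, sample_rate_hz=100.0, seed=42
    )
    behavior, recordings = synthetic.generate_experiment(design)
    return design, behavior, recordings


@pytest.fixture()
def flat_recording():
    """Constant recording with a couple of blink gaps, for preprocessing tests."""
    import pandas as pd

    rate = 100.0
    n = 6000
    events = pd.DataFrame(
        {
            "onset_s": [10.0, 30.0],
            "duration_s": [0.15, 0.15],
            "type": ["blink", "blink"],
            "trial": [-1, -1],
        }
    )
    return pp.PupilRecording(samples=np.full(n, 500.0), rate=rate, events=events)
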