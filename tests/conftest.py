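import numpy as np
import pytest

import fnirsbci as fb
from fnirsbci import evaluate, featurize, synth

#: scaled-down study conditions shared by the heavier integration tests:
#: 8 participants, 180 s task blocks (the full protocol otherwise)
COHORT_SEED = 1
N_PARTICIPANTS = 8
BLOCK_S = 180.0


@pytest.fixture(scope="session")
def layout():
    return fb.make_default_layout()


@pytest.fixture(scope="session")
def protocol():
    return fb.make_protocol(BLOCK_S)


@pytest.fixture(scope="session")
def session_cfg():
    return fb.SessionConfig(seed=3, task_block_duration_s=BLOCK_S)


@pytest.fixture(scope="session")
def session(session_cfg, layout, protocol):
    return fb.generate_session(session_cfg, layout, protocol)


@pytest.fixture(scope="session")
def cohort():
    base = fb.SessionConfig(task_block_duration_s=BLOCK_S)
    return fb.generate_cohort(N_PARTICIPANTS, COHORT_SEED, base)


N_NULL_DRAWS = 3


@pytest.fixture(scope="session")
def null_cohorts(cohort):
    """Label-permutation null: block task identities shuffled per session.

    With six task blocks per session a single permutation draw has high
    label-overlap variance, so the null is averaged over several draws."""
    return [
        [synth.permute_task_blocks(s, 1000 * (d + 1) + i) for i, s in enumerate(cohort)]
        for d in range(N_NULL_DRAWS)
    ]


@pytest.fixture(scope="session")
def cv_strong(cohort):
    """LOO-CV on the strong-effect cohort, RF and linear SVM, 100-frame windows."""
    return fb.loocv(cohort, families=("RF", "SVM_LINEAR"), window_frames=(100,), seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cv_nulls(null_cohorts):
    return [
        fb.loocv(c, families=("SVM_LINEAR",), window_frames=(100,), seed=COHORT_SEED)
        for c in null_cohorts
    ]


@pytest.fixture(scope="session")
def online_pipeline_cfg():
    return evaluate.PipelineConfig(window=featurize.WindowSpec(100, fs_hz=5.8))
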