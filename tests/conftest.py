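import numpy as np
import pandas as pd
import pytest

from kscore.config import RunConfig

from kscore.landmarks import CANONICAL
from kscore.pipeline import fit_reference, prepare_subject
from kscore.preprocess import Repetition
from kscore.simulate import generate_cohort


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def cohort_small():
    """6 controls + 6 strongly impaired patients, deterministic."""
    return generate_cohort(6, 6, 0.75, seed=7)


@pytest.fixture(scope="session")
def prepared_small(cohort_small, config):
    return {
        e.meta.subject_id: prepare_subject(
            e.meta, cohort_small.trials[e.meta.subject_id].recording, config
        )
        for e in cohort_small.entries
    }


@pytest.fixture(scope="session")
def reference_small(cohort_small, prepared_small, config):
    controls = [
        prepared_small[e.meta.subject_id]
        for e in cohort_small.entries
        if e.meta.group == "CTRL"
    ]
    return fit_reference(controls, config)


def make_trial_frame(n_rows=3, dt=1 / 30, jitter=None):
    """Canonical trial CSV content as a DataFrame with distinguishable values."""
    t = np.arange(n_rows) * dt
    data = {"time_s": t}
    for i, label in enumerate(CANONICAL.column_labels()):
        data[label] = 0.1 * i + 0.01 * np.arange(n_rows)
    df = pd.DataFrame(data)
    if jitter is not None:
        df["time_s"] = df["time_s"] + jitter
    return df


def rep_from_arrays(t, by_name, subject_id="toy", index=2):
    """Build a Repetition from per-landmark T x 3 arrays (missing -> zeros)."""
    t = np.asarray(t, dtype=float)
    cols = []
    for name in CANONICAL.names:
        arr = np.asarray(by_name.get(name, np.zeros((t.size, 3))), dtype=float)
        cols.append(arr)
    positions = np.concatenate(cols, axis=1)
    return Repetition(
        subject_id=subject_id,
        index=index,
        timestamps=t,
        positions=positions,
        column_labels=CANONICAL.column_labels(),
    )


@pytest.fixture
def toy_rep_factory():
    return rep_from_arrays
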