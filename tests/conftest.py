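import numpy as np
import pytest

import utrocular as u


@pytest.fixture(scope="session")
def default_dataset():
    """One default simulated session (12 runs) with ground truth."""
    runs, gt = u.simulate_experiment(seed=11)
    return runs, gt


@pytest.fixture(scope="session")
def default_samples(default_dataset):
    runs, _ = default_dataset
    return u.samples_from_runs(runs)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_boxcar_run(cond_responses, run_index=0, n_fix=2, n_block=3, tr_s=3.2):
    """Noise-free boxcar run: fixation then one block per condition."""
    conds = list(cond_responses)
    n_vox = len(next(iter(cond_responses.values())))
    total = n_fix + len(conds) * (n_block + n_fix)
    data = np.zeros((n_vox, total))
    labels = [u.FIXATION] * total
    for i, c in enumerate(conds):
        onset = n_fix + i * (n_block + n_fix)
        data[:, onset : onset + n_block] = np.asarray(cond_responses[c])[:, None]
        for t in range(onset, onset + n_block):
            labels[t] = c
    return u.RunData(data=data, volume_labels=labels, tr_s=tr_s, run_index=run_index)
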