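import numpy as np
import pytest

from physiopipe.synth import EXPERT_DEFAULT, NOVICE_DEFAULT, generate_cohort
from physiopipe.features import assemble_matrix, process_subject


def match_events(detected, truth, tol):
    """Greedy one-to-one match of detected to true event times.

    Returns (tp, n_detected, n_truth).
    """
    truth = np.asarray(truth, dtype=float)
    used = set()
    tp = 0
    for d in np.asarray(detected, dtype=float):
        if truth.size == 0:
            break
        dist = np.abs(truth - d)
        i = int(np.argmin(dist))
        if dist[i] <= tol and i not in used:
            used.add(i)
            tp += 1
    return tp, len(detected), len(truth)


@pytest.fixture(scope="session")
def separated_cohort():
    """5 experts + 5 novices with the default (separated) class presets."""
    return generate_cohort(5, 5, EXPERT_DEFAULT, NOVICE_DEFAULT, seed=11)


@pytest.fixture(scope="session")
def separated_tables(separated_cohort):
    return [process_subject(rec) for rec in separated_cohort]


@pytest.fixture(scope="session")
def multimodal_matrix(separated_tables):
    return assemble_matrix(separated_tables, "multimodal")
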