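import numpy as np
import pytest

from axovuln.census import segment_somata
from axovuln.morphometry import measure_field
from axovuln.synthetic import FieldSpec, generate_field


@pytest.fixture(scope="session")
def default_field():
    """One default synthetic field with its truth (session-cached)."""
    return generate_field(FieldSpec(seed=7))


@pytest.fixture(scope="session")
def default_analysis(default_field):
    """Soma mask, skeleton graph and morphometry for the default field."""
    field, truth = default_field
    mask = segment_somata(field)
    graph, result = measure_field(field, mask, n_neurons=max(mask.count, 1))
    return field, truth, mask, graph, result


def greedy_match(pred, true, radius):
    """One-to-one greedy nearest-pair matching; returns matched index pairs."""
    pred = np.asarray(pred, float).reshape(-1, 2)
    true = np.asarray(true, float).reshape(-1, 2)
    if len(pred) == 0 or len(true) == 0:
        return []
    d = np.linalg.norm(pred[:, None, :] - true[None, :, :], axis=-1)
    used_p, used_t, pairs = set(), set(), []
    for flat in np.argsort(d, axis=None):
        i, j = divmod(int(flat), d.shape[1])
        if d[i, j] > radius:
            break
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        pairs.append((i, j))
    return pairs
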