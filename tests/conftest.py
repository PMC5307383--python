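import numpy as np
import pandas as pd
import pytest

from exomir import (
    SampleTable,
    SimulationParams,
    StudyDesign,
    default_params,
    simulate_counts,
)


@pytest.fixture(scope="session")
def study_dataset():
    """Default-scale synthetic study: 8 PRE + 10 discordant twin pairs, 241 miRs."""
    design = StudyDesign()
    params = default_params(seed=20170214)
    counts, samples = simulate_counts(design, params)
    return counts, samples, params


@pytest.fixture()
def tiny_samples():
    """Minimal valid design: 3 singletons + 3 twin pairs."""
    rows = [
        {"sample_id": f"P{i}", "group": "PRE", "pair_id": None} for i in range(3)
    ]
    for i in range(3):
        rows.append({"sample_id": f"N{i}", "group": "POST_NOHRT", "pair_id": f"T{i}"})
        rows.append({"sample_id": f"H{i}", "group": "POST_HRT", "pair_id": f"T{i}"})
    return SampleTable(pd.DataFrame(rows))


def bh_oracle(p):
    """Naive O(n^2) Benjamini-Hochberg step-up oracle: sort, take
    q_(i) = min_{j >= i} m * p_(j) / j, cap at 1, map back."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = np.empty(m)
    for i in range(m):
        q[order[i]] = min(1.0, min(m * ranked[j] / (j + 1) for j in range(i, m)))
    return q
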