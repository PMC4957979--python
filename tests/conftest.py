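import numpy as np
import pytest

from atmhotspot import (
    MutationRecord,
    SyntheticConfig,
    deduplicate_unique,
    generate_catalog,
)


def make_record(pos, label="Missense_Mutation", case="C1", change=None, shallow=False):
    return MutationRecord(
        case_id=case,
        protein_position=pos,
        raw_label=label,
        protein_change=change if change is not None else f"p.A{pos}V",
        concurrent_shallow_deletion=shallow,
    )


@pytest.fixture
def small_catalog():
    """Tiny hand-built catalog: 3 missense uniques, 2 truncating, 1 silent."""
    records = [
        make_record(10, change="p.N10K", case="C1"),
        make_record(10, change="p.N10K", case="C2"),  # recurrent, same variant
        make_record(12, change="p.D12G", case="C3"),
        make_record(12, change="p.D12V", case="C4"),  # same site, different alt
        make_record(100, label="Nonsense_Mutation", change="p.R100*", case="C5"),
        make_record(200, label="Frame_Shift_Del", change="p.K200fs", case="C1"),
        make_record(50, label="Silent", change="p.L50L", case="C6"),
    ]
    return deduplicate_unique(records)


@pytest.fixture
def uniform_catalog():
    """Synthetic uniform-background catalog (f = 1), deduplicated."""
    return deduplicate_unique(generate_catalog(SyntheticConfig(seed=11)))


def brute_force_smooth(y, b):
    """Literal O(L^2) double-sum evaluation of the Gaussian kernel smoother."""
    y = np.asarray(y, dtype=float)
    L = len(y)
    x = np.arange(L, dtype=float)
    out = np.empty(L)
    for i in range(L):
        k = np.exp(-((x[i] - x) ** 2) / (2.0 * b * b))
        out[i] = float((k * y).sum() / k.sum())
    return out
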