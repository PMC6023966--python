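import numpy as np
import pytest

from mircircuit import (
    BinarizedDataset,
    ConstraintProfile,
    GateTypeSpec,
    core_profile,
)


def or_not_types(max_inputs: int, max_gates: int):
    """OR gate (positive inputs only) + single-negated-input NOT gate."""
    return (
        GateTypeSpec(1, lb_pos=1, ub_pos=max_inputs, lb_neg=0, ub_neg=0,
                     max_occurrences=max_gates),
        GateTypeSpec(2, lb_pos=0, ub_pos=0, lb_neg=1, ub_neg=1,
                     max_occurrences=max_gates),
    )


@pytest.fixture
def fig3_dataset() -> BinarizedDataset:
    """Three samples (two negative, one positive) perfectly separated by
    (g1 | g3) & !g2."""
    return BinarizedDataset(
        sample_ids=[1, 2, 3],
        annotations=[0, 0, 1],
        mirna_ids=["g1", "g2", "g3"],
        matrix=[[1, 1, 0], [0, 1, 1], [1, 0, 0]],
    )


@pytest.fixture
def reduced_profile() -> ConstraintProfile:
    """Small OR/NOT profile keeping exhaustive verification cheap."""
    return ConstraintProfile(max_gates=3, max_inputs=3,
                             gate_types=or_not_types(3, 3))


@pytest.fixture
def core():
    return core_profile()


def random_instance(seed: int, n_samples: int = 8, n_mirnas: int = 6):
    """Seeded random binary dataset with random annotations."""
    rng = np.random.default_rng(seed)
    return BinarizedDataset(
        sample_ids=list(range(1, n_samples + 1)),
        annotations=rng.integers(0, 2, size=n_samples),
        mirna_ids=[f"g{i}" for i in range(1, n_mirnas + 1)],
        matrix=rng.integers(0, 2, size=(n_samples, n_mirnas)),
    )
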