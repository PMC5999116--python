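import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from impactnet import Alignment
from impactnet.encoding import EncodedMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def small_alignment() -> Alignment:
    """Six sequences, five columns, with gaps and a clean reference row."""
    return Alignment(
        ids=("ref", "s1", "s2", "s3", "s4", "s5"),
        seqs=(
            "ACDEF",
            "ACDEF",
            "AC-EF",
            "GCDEF",
            "ACDKF",
            "A-DEF",
        ),
        reference_id="ref",
        column_labels=(1, 2, 3, 4, 5),
    )


def binary_matrix(codes, labels=None) -> EncodedMatrix:
    """Wrap a raw 0/1 array as a binary EncodedMatrix (labels default 1..L)."""
    codes = np.asarray(codes, dtype=np.int8)
    n, L = codes.shape
    return EncodedMatrix(
        codes=codes,
        scheme="binary",
        states=(("A",),) * L,
        position_labels=tuple(labels) if labels else tuple(range(1, L + 1)),
        sequence_ids=tuple(f"s{k}" for k in range(n)),
    )


def three_state_matrix(codes, n_states) -> EncodedMatrix:
    """Wrap a raw 0/1/2 array as a three-state EncodedMatrix.

    ``n_states[c]`` is the number of qualifying states at column c (0
    marks the column excluded).
    """
    codes = np.asarray(codes, dtype=np.int8)
    n, L = codes.shape
    state_names = {0: (), 1: ("A",), 2: ("A", "G")}
    return EncodedMatrix(
        codes=codes,
        scheme="three_state",
        states=tuple(state_names[k] for k in n_states),
        position_labels=tuple(range(1, L + 1)),
        sequence_ids=tuple(f"s{k}" for k in range(n)),
        excluded=np.array([k == 0 for k in n_states]),
    )
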