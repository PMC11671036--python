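from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from confland.fixtures import (
    TwoStateMsaSpec,
    TwoStateStructureSpec,
    make_two_state_msa,
    make_two_state_structures,
)
from confland.msa import Msa

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("default")

AA = "ACDEFGHIKLMNPQRSTVWY"


@st.composite
def msas(draw, min_rows: int = 0, max_rows: int = 6) -> Msa:
    """Random valid alignments with gaps and occasional A3M insertions."""
    length = draw(st.integers(3, 10))
    query = "".join(draw(st.lists(st.sampled_from(AA), min_size=length, max_size=length)))
    rows = [("q", query)]
    n = draw(st.integers(min_rows, max_rows))
    for i in range(n):
        chars = draw(
            st.lists(st.sampled_from(AA + "-"), min_size=length, max_size=length)
        )
        if all(c == "-" for c in chars):
            chars[0] = draw(st.sampled_from(AA))
        seq = "".join(chars)
        if draw(st.booleans()):
            pos = draw(st.integers(0, length))
            ins = draw(st.sampled_from(AA)).lower()
            seq = seq[:pos] + ins + seq[pos:]
        rows.append((f"s{i}", seq))
    return Msa(tuple(rows))


@pytest.fixture(scope="session")
def planted_spec() -> TwoStateMsaSpec:
    return TwoStateMsaSpec(
        n_families=2,
        rows_per_family=12,
        match_length=60,
        family_signature_columns=5,
        background_mutation_rate=0.0,
        gap_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def planted_msa(planted_spec):
    return make_two_state_msa(planted_spec)


@pytest.fixture(scope="session")
def reference_pair():
    return make_two_state_structures(TwoStateStructureSpec(n_residues=80, seed=0))
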