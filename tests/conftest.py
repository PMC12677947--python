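import numpy as np
import pytest

import kmertax as kt


@pytest.fixture(scope="session")
def toy_records():
    """Five references in two families, distinct enough to tell apart."""
    rng = np.random.default_rng(7)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def seq(n=120):
        return bases[rng.integers(0, 4, size=n)].tobytes().decode()

    return [
        ("ref1", [("f", "FamA"), ("g", "GenA1"), ("s", "SpA1a")], seq()),
        ("ref2", [("f", "FamA"), ("g", "GenA1"), ("s", "SpA1b")], seq()),
        ("ref3", [("f", "FamA"), ("g", "GenA2"), ("s", "SpA2a")], seq()),
        ("ref4", [("f", "FamB"), ("g", "GenB1"), ("s", "SpB1a")], seq()),
        ("ref5", [("f", "FamB"), ("g", "GenB1"), ("s", "SpB1b")], seq()),
    ]


@pytest.fixture(scope="session")
def toy_index(toy_records):
    return kt.build_reference_index(toy_records)


def brute_force_intersections(records, query_seq):
    """Independent per-pair sorted-set intersection oracle."""
    q = set(kt.extract_kmer_set(query_seq).codes.tolist())
    out = {}
    for rid, _, seq in records:
        k = set(kt.extract_kmer_set(seq).codes.tolist())
        n = len(q & k)
        if n:
            out[rid] = n
    return out
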