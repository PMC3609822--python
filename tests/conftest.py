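import numpy as np
import pandas as pd
import pytest

from riverhap.io import Alignment, HaplotypeTable, collapse_haplotypes
from riverhap.distances import DistanceMatrix


BASES = "ACGT"


def random_alignment(rng, n, L, n_mut_range=(0, 10)) -> Alignment:
    root = rng.integers(0, 4, L)
    ids, seqs = [], []
    for k in range(n):
        s = root.copy()
        nm = int(rng.integers(*n_mut_range))
        if nm:
            sites = rng.choice(L, min(nm, L), replace=False)
            s[sites] = (s[sites] + rng.integers(1, 4, len(sites))) % 4
        ids.append(f"t{k:02d}")
        seqs.append("".join(BASES[b] for b in s))
    return Alignment(ids, seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_alignment() -> Alignment:
    """Five 60-bp sequences incl. a gap/N pair; TN93 oracle values pinned in
    tests were computed once with an independent reference implementation."""
    return Alignment(
        ["s1", "s2", "s3", "s4", "s5"],
        [
            "ATGCCTAGAAGTGTGTGATCGCATTGCTGCCAAGTATTCGATGCATCTGTTACCCAGAGG",
            "ATGCCTAGAAGTGTGTGATCGTATAGCTGCCAAGTATTCGATTCATCTGTTTCCCAGGGG",
            "ATGCCTAGATGCGTGTAATCGCACGGCTGACAATTAAGCGATTCATCTCTTTCCCAGAGG",
            "AGGCAAGGAAGCCTGTGATCACGACCATCCCAGTCCTTCGATGCAACAGTTACTCAGAGG",
            "ATGCCTAGAA-NGTGTGATCGCATTGCTGCCAAGTATTCGATGCATCTGTTACCCAGAGG",
        ],
    )


@pytest.fixture
def two_pop_table() -> tuple[HaplotypeTable, DistanceMatrix]:
    """Two populations over three haplotypes with hand-set distances."""
    counts = pd.DataFrame(
        {"popA": [3, 1, 0], "popB": [0, 2, 2]},
        index=["H001", "H002", "H003"],
    )
    table = HaplotypeTable(
        ["H001", "H002", "H003"], ["AAAA", "AATT", "TTTT"], counts
    )
    d = DistanceMatrix(["H001", "H002", "H003"],
                       np.array([[0.0, 2.0, 4.0],
                                 [2.0, 0.0, 2.0],
                                 [4.0, 2.0, 0.0]]), "diff_count")
    return table, d


def table_from_samples(seqs_by_sample: dict[str, str],
                       pop_by_sample: dict[str, str]):
    """Build a HaplotypeTable from explicit per-sample sequences."""
    aln = Alignment(list(seqs_by_sample), list(seqs_by_sample.values()))
    meta = pd.DataFrame({
        "sample_id": list(pop_by_sample),
        "population": list(pop_by_sample.values()),
        "sex": "unknown",
        "latitude": np.nan,
        "longitude": np.nan,
    })
    return collapse_haplotypes(aln, meta)
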