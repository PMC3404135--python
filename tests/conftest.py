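import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import qmotif as qm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_seqs():
    """Three short DNA sequences sharing the (3,1) motif ACG."""
    return qm.SequenceSet.from_strings(["ACGTA", "TACGT", "CCGTT"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


def random_dna(rng, m: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=m))


def random_protein(rng, m: int) -> str:
    return "".join(rng.choice(list(qm.PROTEIN.symbols), size=m))


def oracle_motifs(seqs: qm.SequenceSet, params: qm.SearchParams) -> set[str]:
    """Definition-pure oracle: enumerate the whole l-mer space in Python."""
    out = set()
    for cand in itertools.product(seqs.alphabet.symbols, repeat=params.l):
        m = "".join(cand)
        if qm.quorum_count(m, seqs, params.d) >= params.q:
            out.add(m)
    return out


def oracle_ball(x: str, d: int, alphabet=qm.DNA) -> set[str]:
    """Brute-force Hamming ball by full enumeration."""
    return {
        "".join(c)
        for c in itertools.product(alphabet.symbols, repeat=len(x))
        if sum(a != b for a, b in zip(c, x)) <= d
    }


def random_instances(rng, count, *, protein=False):
    """Small randomized (seqs, params) instances in the oracle-checkable range."""
    for _ in range(count):
        n = int(rng.integers(4, 9))
        m = int(rng.integers(20, 61))
        if protein:
            l = int(rng.integers(4, 7))
            d = 1
            mk = random_protein
            alpha = qm.PROTEIN
        else:
            l = int(rng.integers(5, 10))
            d = int(rng.integers(1, 3))
            mk = random_dna
            alpha = qm.DNA
        q = n - int(rng.integers(0, 3))
        seqs = qm.SequenceSet.from_strings(
            [mk(rng, m) for _ in range(n)], alphabet=alpha
        )
        yield seqs, qm.SearchParams(l=l, d=d, q=q)
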