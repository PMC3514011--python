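import numpy as np
import pytest

from thermoclade import AlignedSeqSet, SeqEntry, load_sample_table

BASES = "ACGT"


def random_alignment(
    n: int, length: int, rng: np.random.Generator, populations=None
) -> AlignedSeqSet:
    """Random unrelated sequences (no shared ancestry) for counting oracles."""
    pops = populations or ["unassigned"] * n
    return AlignedSeqSet(
        [
            SeqEntry(
                f"s{i}",
                pops[i],
                "".join(rng.choice(list(BASES), size=length)),
            )
            for i in range(n)
        ]
    )


def related_alignment(
    n: int,
    length: int,
    rng: np.random.Generator,
    max_mut: int = 5,
    populations=None,
) -> AlignedSeqSet:
    """Shallowly diverged sequences (a few substitutions off one base), so
    model-based distances stay well inside their domain."""
    base = "".join(rng.choice(list(BASES), size=length))
    pops = populations or ["unassigned"] * n
    records = []
    for i in range(n):
        k = int(rng.integers(0, max_mut + 1))
        pos = rng.choice(length, size=k, replace=False)
        records.append(SeqEntry(f"s{i}", pops[i], mutate(base, pos, rng)))
    return AlignedSeqSet(records)


def mutate(seq: str, positions, rng: np.random.Generator) -> str:
    """Substitute each listed position with a different random base."""
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out)


@pytest.fixture(scope="session")
def table1():
    """The packaged occurrence-table fixture."""
    return load_sample_table()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
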