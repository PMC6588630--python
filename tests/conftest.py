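import numpy as np
import dendropy
import pytest

from chemorep.io import SequenceRecord

AAS = "ACDEFGHIKLMNPQRSTVWY"


def newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)


@pytest.fixture
def seed_protein() -> SequenceRecord:
    rng = np.random.default_rng(42)
    return SequenceRecord(
        "q1", "M" + "".join(AAS[i] for i in rng.integers(0, 20, size=299))
    )


@pytest.fixture
def balanced_tree() -> dendropy.Tree:
    return newick("((a:0.3,b:0.3):0.1,(c:0.3,d:0.3):0.1);")


def random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def diverged_copies(rng: np.random.Generator, length: int, n: int,
                    rate: float) -> list[str]:
    """iid star-tree divergence from one ancestor (no recombination)."""
    anc = rng.integers(0, 4, length)
    out = []
    for _ in range(n):
        s = anc.copy()
        mut = rng.random(length) < rate
        s[mut] = (s[mut] + rng.integers(1, 4, mut.sum())) % 4
        out.append("".join("ACGT"[x] for x in s))
    return out
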