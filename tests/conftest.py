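import numpy as np
import pytest

from densid import (
    AA_ALPHABET,
    AtomicModel,
    Chain,
    Residue,
    ResidueProfile,
    build_profile,
    gen_structure,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_profile(rng, L, conf_range=(0.0, 1.0)) -> ResidueProfile:
    probs = rng.dirichlet(np.ones(20), size=L)
    conf = rng.uniform(*conf_range, size=L)
    return ResidueProfile(chain_id="A", probs=probs, conf=conf)


def onehot_profile(seq: str, conf: float = 0.9) -> ResidueProfile:
    probs = np.zeros((len(seq), 20))
    for i, a in enumerate(seq):
        probs[i, AA_ALPHABET.index(a)] = 1.0
    return ResidueProfile(chain_id="A", probs=probs, conf=np.full(len(seq), conf))


def random_seq(rng, n: int) -> str:
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, n))


@pytest.fixture
def helix_model() -> AtomicModel:
    return gen_structure([30], seed=7)


@pytest.fixture
def tiny_model() -> AtomicModel:
    """Three residues on a line, 4 A apart, identities M K V."""
    chain = Chain("A")
    for i, aa in enumerate("MKV"):
        x = 4.0 * i
        chain.residues.append(
            Residue(
                identity=aa,
                atoms={
                    "N": np.array([x - 1.0, 0.5, 0.0]),
                    "CA": np.array([x, 0.0, 0.0]),
                    "C": np.array([x + 1.0, 0.5, 0.0]),
                    "O": np.array([x + 1.5, 1.5, 0.0]),
                },
                score=0.5 + 0.1 * i,
            )
        )
    return AtomicModel([chain])


@pytest.fixture
def small_hmm(rng):
    return build_profile(random_profile(rng, 5))
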