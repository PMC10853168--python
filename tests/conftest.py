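import numpy as np
import pytest

from hapscore import (
    AlleleSequenceStore,
    HLAGenotype,
    build_grantham_matrix,
)


@pytest.fixture(scope="session")
def matrix():
    return build_grantham_matrix()


@pytest.fixture(scope="session")
def rounded_matrix():
    return build_grantham_matrix(rounded=True)


def _toy_sequences():
    """Tiny aligned pool: a consensus plus controlled substitutions.

    A*02:01 differs from A*01:01 at one site by a Leu->Ile exchange
    (Grantham distance 5); B alleles differ at two sites; C*03:03 and
    C*03:04 are identical in the binding domain (divergence 0 even though
    the names differ).
    """
    base = ("ACDEFGHIKLMNPQRSTVWY" * 10)[:181]
    seqs = {}
    seqs["A*01:01"] = base
    seqs["A*02:01"] = base[:9] + "I" + base[10:]  # L -> I at column 10
    seqs["B*07:02"] = base
    seqs["B*08:01"] = "W" + base[1:9] + "I" + base[10:]  # A->W, L->I
    seqs["C*03:03"] = base
    seqs["C*03:04"] = base
    seqs["C*07:01"] = base[:2] + "W" + base[3:]  # D -> W
    return seqs


@pytest.fixture(scope="session")
def toy_store():
    return AlleleSequenceStore(_toy_sequences())


@pytest.fixture
def het_genotype():
    return HLAGenotype(
        patient_id="PT1",
        alleles={
            "A": ("A*01:01", "A*02:01"),
            "B": ("B*07:02", "B*08:01"),
            "C": ("C*03:03", "C*07:01"),
        },
    )


@pytest.fixture
def hom_genotype():
    return HLAGenotype(
        patient_id="PT2",
        alleles={
            "A": ("A*01:01", "A*01:01"),
            "B": ("B*07:02", "B*07:02"),
            "C": ("C*03:03", "C*03:03"),
        },
    )


def separable_features(seed: int, n: int = 200, margin: float = 2.0):
    """Binary-labelled 3-feature data with a true separation gap.

    Points are pushed ``margin/2`` SD away from the decision boundary along
    the discriminant direction, so the class supports are ``margin`` SD
    apart and a perfect classifier exists.
    """
    rng = np.random.default_rng(seed)
    w = np.ones(3) / np.sqrt(3)
    x = rng.normal(0.0, 1.0, (n, 3))
    s = x @ w
    y = (s > 0).astype(int)
    x = x + np.sign(s)[:, None] * (margin / 2) * w
    return x, y
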