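import io

import numpy as np
import pytest

from inbredload.pedigree import Pedigree, compute_inbreeding, load_and_sort


def make_pedigree(text: str) -> Pedigree:
    """Build a pedigree from inline CSV text (animal,sire,dam[,...])."""
    ped = load_and_sort(io.StringIO(text))
    compute_inbreeding(ped)
    return ped


def random_pedigree(
    n: int,
    seed: int,
    n_founders: int | None = None,
    p_missing_dam: float = 0.15,
) -> Pedigree:
    """Random sorted pedigree: animal x's parents drawn among 1..x-1."""
    rng = np.random.default_rng(seed)
    n_founders = n_founders or max(4, n // 10)
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    for x in range(n_founders, n):
        sire[x] = rng.integers(1, x + 1)
        dam[x] = rng.integers(1, x + 1)
        if dam[x] == sire[x]:
            dam[x] = 0
        elif rng.random() < p_missing_dam:
            dam[x] = 0
    ped = Pedigree(
        labels=np.array([f"A{k}" for k in range(1, n + 1)], dtype=object),
        sire=sire,
        dam=dam,
        birth_year=np.full(n, np.nan),
        sex=np.full(n, "U", dtype=object),
    )
    compute_inbreeding(ped)
    return ped


@pytest.fixture
def full_sib_ped():
    """G1 x G2 founders -> full sibs P1, P2 -> inbred X with F = 0.25."""
    return make_pedigree("animal,sire,dam\nG1,0,0\nG2,0,0\nP1,G1,G2\nP2,G1,G2\nX,P1,P2\n")


@pytest.fixture
def sire_daughter_ped():
    """Sire S mated to his own daughter D (dam's dam U unrelated): F(X) = 0.25."""
    return make_pedigree("animal,sire,dam\nS,0,0\nU,0,0\nD,S,U\nX,S,D\n")
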