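import numpy as np
import pandas as pd
import pytest

import cagemara as cm


@pytest.fixture(scope="session")
def small_bundle() -> cm.SyntheticBundle:
    """A compact simulated study shared by read-only tests."""
    cfg = cm.SimulationConfig(n_genes=150, n_motifs=10, seed=3)
    return cm.simulate_bundle(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def brute_force_affinity(sequence: str, motif: cm.MotifMatrix) -> float:
    """Independent position-by-position enumerator of the occupancy score."""
    w = motif.width
    P = motif.probabilities

    def one_strand(s: str) -> float:
        total = 0.0
        for i in range(len(s) - w + 1):
            prod = 1.0
            for j, base in enumerate(s[i : i + w]):
                if base not in "ACGT":
                    prod = 0.0
                    break
                prod *= P["ACGT".index(base), j]
            total += prod
        return total

    s = sequence.upper()
    return one_strand(s) + one_strand(cm.reverse_complement(s))


def random_motif(rng: np.random.Generator, width: int) -> cm.MotifMatrix:
    mat = rng.dirichlet(np.ones(4), size=width).T
    return cm.MotifMatrix("Mrand", "TFrand", mat)


def random_sequence(rng: np.random.Generator, length: int, n_frac: float = 0.0) -> str:
    alphabet = np.array(list("ACGT"))
    seq = alphabet[rng.integers(0, 4, size=length)]
    if n_frac > 0:
        mask = rng.random(length) < n_frac
        seq[mask] = "N"
    return "".join(seq)
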