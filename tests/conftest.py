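import numpy as np
import pytest

from rbfs import EnsembleConfig, PairDataset


@pytest.fixture
def light_ensemble():
    """Small tree ensemble for fast unit tests."""
    return EnsembleConfig(n_estimators=20, max_depth=3, learning_rate=0.3)


@pytest.fixture
def tiny_fasta(tmp_path):
    """Write a small nucleotide FASTA and return its path."""

    def _write(entries, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in entries:
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def perfect_feature_data():
    """n=60 balanced labels; the single feature equals the label."""
    rng = np.random.default_rng(0)
    y = np.array([0, 1] * 30)
    X = y[:, None].astype(float)
    return X, y


def make_signal_dataset(n=200, p=30, seed=0, coef=3.0):
    """Small planted-signal dataset: column 0 carries the label signal."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    from scipy.special import expit

    y = (rng.random(n) < expit(coef * X[:, 0])).astype(np.int64)
    return X, y


@pytest.fixture
def small_pair_dataset():
    rng = np.random.default_rng(3)
    n, p = 40, 6
    X = rng.standard_normal((n, p))
    y = np.array([0, 1] * (n // 2), dtype=np.int64)
    return PairDataset(
        X,
        y,
        [f"lnc:f{i}" for i in range(p // 2)] + [f"prot:f{i}" for i in range(p // 2)],
        [(f"l{i}", f"p{i}") for i in range(n)],
    )
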