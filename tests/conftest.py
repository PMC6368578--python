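import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ggsig.seqio import SequenceRecord
from ggsig.signature import GGSVector, canonical_words

settings.register_profile(
    "ci", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def naive_word_counts(runs, n):
    """Brute-force sliding-window oracle: dict word -> count over all runs."""
    counts = {}
    for run in runs:
        for i in range(len(run) - n + 1):
            w = run[i : i + n]
            counts[w] = counts.get(w, 0) + 1
    return counts


def random_record(rng, length, label="r"):
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return SequenceRecord(id=label, runs=(seq,))


def random_ggs(rng, n=2, label="v"):
    k = len(canonical_words(n))
    return GGSVector(label=label, n=n, rho=rng.uniform(0.0, 3.0, size=k))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fasta_file(tmp_path):
    def write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return write
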