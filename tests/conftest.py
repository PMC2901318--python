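import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

from tandemscan import DetectionParams, GeneModel, SequenceRecord


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    codes = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    return rng.choice(codes, size=n).tobytes().decode("ascii")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20101)


@pytest.fixture
def toy_gene() -> GeneModel:
    """Plus-strand two-exon transcript with an internal CDS."""
    return GeneModel(
        gene_id="tx1",
        contig="lg1",
        strand="+",
        tx_beg=1000,
        tx_end=5000,
        cds_beg=1100,
        cds_end=2100,
        exons=((1000, 1200), (2000, 2200)),
    )


@pytest.fixture
def loose_params() -> DetectionParams:
    """Permissive thresholds used by the small-scale property checks."""
    return DetectionParams(min_period=1, max_period=8, min_copies=3, flank_len=10)
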