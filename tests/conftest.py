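import numpy as np
import pytest

from neoprecis._aa import AA_INDEX, CORE_LENGTH
from neoprecis.core_motifs import BindingPrediction, PredictorInterface
from neoprecis.immuno_model import ImmunoModelParams
from neoprecis.synthetic_data import SyntheticConfig, gen_alleles_and_motifs


class FixedRankPredictor(PredictorInterface):
    """Test double returning preset ranks per peptide (default accept-all)."""

    def __init__(self, ranks=None, default_rank=1.0, classes=None, core_start=0):
        self._ranks = dict(ranks or {})
        self._default = default_rank
        self._classes = classes or {}
        self._core_start = core_start

    @property
    def supported_alleles(self):
        return set(self._classes) if self._classes else {"*"}

    def mhc_class(self, allele):
        return self._classes.get(allele, "I")

    def predict(self, peptide, allele):
        rank = self._ranks.get(peptide, self._default)
        start = min(self._core_start, len(peptide) - CORE_LENGTH)
        return BindingPrediction(
            rank_percentile=rank, binding_score=1.0 / rank, core_start=start
        )


@pytest.fixture(scope="session")
def world():
    """Small deterministic synthetic world shared across tests."""
    return gen_alleles_and_motifs(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def params():
    return ImmunoModelParams.initialize(seed=3, init_scale=0.3)


@pytest.fixture()
def accept_all():
    return FixedRankPredictor(default_rank=1.0)


def sharp_pwm(peptide: str, peak: float = 100.0) -> np.ndarray:
    """9x20 weight matrix concentrated on one peptide."""
    pwm = np.ones((CORE_LENGTH, 20))
    for i, aa in enumerate(peptide):
        pwm[i, AA_INDEX[aa]] = peak
    return pwm / pwm.sum(axis=1, keepdims=True)
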