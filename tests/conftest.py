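import numpy as np
import pytest

from bdakit.bgc_io import BDA
from bdakit.hmm_scoring import ScoringMatrix
from bdakit.synthetic_fixtures import HOMOLOGY_GROUPS


@pytest.fixture
def toy_matrix() -> ScoringMatrix:
    """Block homology matrix over the fixture vocabulary: condensation
    subtypes, carrier proteins and KS subtypes are mutually homologous."""
    return ScoringMatrix.from_groups(list(HOMOLOGY_GROUPS.values()))


@pytest.fixture
def worked_example() -> tuple[BDA, BDA]:
    """Candidate/reference NRPS pair: six-domain candidate architecture
    versus a seven-domain characterized reference ending in a
    thioesterase."""
    candidate = BDA(
        "MesVir_RPFO01000156.1_1",
        ("Cond_LCL", "AMP_binding", "PP_bind", "Cond_LCL", "AMP_binding", "PCP"),
    )
    reference = BDA(
        "BGC0001873",
        ("Cond_Starter", "AMP_binding", "PCP", "Cond_DCL", "AMP_binding", "PP_bind", "TE"),
    )
    return candidate, reference


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


def random_bda(rng, length, vocabulary, bgc_id="rand"):
    tokens = tuple(vocabulary[i] for i in rng.integers(len(vocabulary), size=length))
    return BDA(bgc_id, tokens)


@pytest.fixture
def fixture_vocabulary() -> list[str]:
    return [t for members in HOMOLOGY_GROUPS.values() for t in members]
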