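import warnings

import numpy as np
import pytest

from cambronet.io import AbundanceMatrix
from cambronet.synthetic import generate_assemblage

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture
def toy_matrix():
    """3 levels x 2 taxa with known column sums (3, 7)."""
    return AbundanceMatrix(
        level_ids=("0", "10", "20"),
        counts=np.array([[1, 0], [2, 3], [0, 4]]),
        taxon_names=("Ottoia", "Vauxia"),
    )


@pytest.fixture
def small_assemblage():
    """One-facies assemblage with default planted pairs."""
    return generate_assemblage(n_taxa=24, n_levels=120, seed=7)
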