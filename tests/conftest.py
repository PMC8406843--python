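import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes _oracles importable

from scfamet.taxonomy import Taxonomy


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_taxonomy():
    """root -> (genus_A -> sp1, sp2; genus_B -> sp3)."""
    rows = [
        ("root", "root", "root", "root"),
        ("gA", "root", "genus", "genus_A"),
        ("gB", "root", "genus", "genus_B"),
        ("sp1", "gA", "species", "species_1"),
        ("sp2", "gA", "species", "species_2"),
        ("sp3", "gB", "species", "species_3"),
    ]
    return Taxonomy(
        pd.DataFrame(rows, columns=["taxon_id", "parent_id", "rank", "name"])
    )
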