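import numpy as np
import pandas as pd
import pytest

from meliflora.simulate import generate_reference_db, simulate_communities
from meliflora.taxonomy import Taxonomy


@pytest.fixture(scope="session")
def small_db():
    """8 species, 2 per genus, 2 genera per family, 2 families per clade."""
    return generate_reference_db(n_taxa=8, seq_length=500, seed=1)


@pytest.fixture(scope="session")
def small_taxonomy(small_db):
    return small_db.taxonomy


@pytest.fixture(scope="session")
def small_communities(small_db):
    comps, meta = simulate_communities(6, small_db.taxon_ids, seed=2)
    return comps, meta


@pytest.fixture
def flat_taxonomy():
    """Hand-built 4-level taxonomy: 8 species, 4 genera, 2 families, 2 clades."""
    rows = []
    for s in range(8):
        g, f, c = s // 2, s // 4, s // 4
        rows.append(
            {
                "taxon_id": f"x{s}",
                "species": f"G{g} s{s}",
                "genus": f"G{g}",
                "family": f"F{f}",
                "clade": f"C{c}",
            }
        )
    return Taxonomy(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
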