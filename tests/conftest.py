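import numpy as np
import pandas as pd
import pytest

from brewcgh.catalog import build_gene_catalog, catalog_to_frame
from brewcgh.normalize import Log2Matrix
from brewcgh.profiles import make_archetype_profiles


@pytest.fixture(scope="session")
def catalog():
    """Full-size default catalog: 16 nuclear chromosomes + Mt, 50 genes each."""
    return build_gene_catalog(seed=7)


@pytest.fixture(scope="session")
def archetypes(catalog):
    return make_archetype_profiles(catalog, seed=7)


@pytest.fixture()
def small_matrix():
    """Tiny hand-checkable Log2Matrix: 2 chromosomes x 3 genes, 3 strains."""
    genes = pd.DataFrame(
        {
            "chromosome": ["I", "I", "I", "II", "II", "II"],
            "start": [100, 200, 300, 100, 200, 300],
            "end": [150, 250, 350, 150, 250, 350],
            "subtelomeric": [True, False, True, True, False, True],
        },
        index=pd.Index([f"g{i}" for i in range(6)], name="gene_id"),
    )
    data = pd.DataFrame(
        {
            "A": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            "B": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
            "C": [0.0, 0.0, -6.0, 0.0, 0.0, 0.0],
        },
        index=genes.index,
    )
    return Log2Matrix(data=data, genes=genes)
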