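import numpy as np
import pandas as pd
import pytest

from senescreen import (
    CountMatrix,
    ScreenLibrary,
    ShrnaRecord,
    SimConfig,
    make_random_library,
)


@pytest.fixture
def tiny_lib() -> ScreenLibrary:
    """Three hairpins over two genes with well-separated 8-mers."""
    return ScreenLibrary(
        records=[
            ShrnaRecord("sh1", "GENEA", "AAAAAAAA"),
            ShrnaRecord("sh2", "GENEA", "CCCCCCCC"),
            ShrnaRecord("sh3", "GENEB", "GGGGGGGG"),
        ],
        barcode_length=8,
    )


@pytest.fixture(scope="session")
def small_lib() -> ScreenLibrary:
    """50 hairpins over 10 genes, 12-mers at pairwise Hamming >= 3."""
    return make_random_library(n_genes=10, shrnas_per_gene=(5, 5),
                               barcode_length=12, min_hamming=3, seed=3)


def desk_config(lib, seed, **overrides) -> SimConfig:
    """The desk-scale study conditions: 500 genes x 5 hairpins, 1% planted
    escape genes, representation 400, 2 dox reps, depth 5e6, dispersion 1000."""
    return SimConfig(library=lib, seed=seed, **overrides)


def make_count_matrix(counts: dict[str, list[int]], roles: dict[str, str],
                      shrna_ids: list[str]) -> CountMatrix:
    """Assemble a CountMatrix from plain dicts (test convenience)."""
    samples = pd.DataFrame(
        {
            "sample_id": list(counts),
            "role": [roles[s] for s in counts],
            "replicate": list(range(1, len(counts) + 1)),
        }
    )
    df = pd.DataFrame(counts, index=pd.Index(shrna_ids, name="shrna_id"))
    return CountMatrix(counts=df, samples=samples)
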