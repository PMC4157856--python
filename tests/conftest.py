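import numpy as np
import pandas as pd
import pytest

from dgetag import (SimConfig, simulate_study, extract_reference_tags,
                    clean_tags, drop_singletons, map_tags, combine_libraries,
                    ADAPTOR)


SMALL = dict(
    n_genes=400,
    n1=80_000,
    n2=80_000,
    frac_de=0.05,
    de_min_tpm=500.0,
    n_terms=20,
    term_size_range=(5, 50),
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One seeded small synthetic study shared across tests."""
    genes, annotations, truth, lib1, lib2 = simulate_study(small_config)
    return {
        "config": small_config,
        "genes": genes,
        "annotations": annotations,
        "truth": truth,
        "lib1": lib1,
        "lib2": lib2,
    }


@pytest.fixture(scope="session")
def small_pipeline(small_study):
    """The small study taken through cleaning, mapping, and combination."""
    index = extract_reference_tags(small_study["genes"])
    out = {"index": index}
    for key, lib in (("1", small_study["lib1"]), ("2", small_study["lib2"])):
        clean = clean_tags(lib, ADAPTOR)
        analysis = drop_singletons(clean)
        expr, report = map_tags(analysis, index, clean_total=clean.total)
        out[f"clean{key}"] = clean
        out[f"expr{key}"] = expr
        out[f"report{key}"] = report
    out["table"] = combine_libraries(out["expr1"], out["expr2"])
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
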