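import pytest

from homeoconverge.pipeline import DataBundle, run_pipeline
from homeoconverge.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_tetrads=60, seed=42)


@pytest.fixture(scope="session")
def small_ds(small_cfg):
    return simulate(small_cfg)


@pytest.fixture(scope="session")
def small_result(small_ds):
    return run_pipeline(DataBundle.from_simulated(small_ds))


def truth_id_of(ds, tetrad) -> str | None:
    """Map an identified tetrad back to its generator truth id via the Ar
    member's gene id."""
    for tid, genes in ds.tetrad_gene_ids.items():
        if genes["Ar"] == tetrad.genes["Ar"]:
            return tid
    return None


def class_truth_lookup(ds) -> dict:
    """(truth_id, pair, mark) -> class label from the generator."""
    out = {}
    for t in ds.truth:
        for mark, k in t.class_ar_an.items():
            out[(t.tetrad_id, "Ar-An", mark)] = k
        for mark, k in t.class_co_cn.items():
            out[(t.tetrad_id, "Co-Cn", mark)] = k
    return out
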