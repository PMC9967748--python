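import numpy as np
import pandas as pd
import pytest

from mycoarch.io_formats import CountTable


def make_count_table(matrix, sample_ids=None, domains=None) -> CountTable:
    matrix = np.asarray(matrix)
    n_taxa, n_samples = matrix.shape
    taxon_ids = [f"T{i:03d}" for i in range(n_taxa)]
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    if domains is None:
        domains = ["fungal"] * n_taxa
    counts = pd.DataFrame(matrix.astype(np.int64),
                          index=pd.Index(taxon_ids, name="taxon_id"),
                          columns=sample_ids)
    taxa = pd.DataFrame(
        {"name": [f"Taxon {i}" for i in range(n_taxa)], "domain": domains},
        index=counts.index,
    )
    return CountTable(counts, taxa)


def make_metadata(sample_ids, plates=None, dates=None, tissue=None,
                  **extra) -> pd.DataFrame:
    n = len(sample_ids)
    meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    meta["patient_id"] = [f"P{i:03d}" for i in range(n)]
    meta["tissue"] = tissue if tissue is not None else ["tumor"] * n
    meta["subtype"] = "CPTC"
    meta["gender"] = "female"
    meta["seq_date"] = dates if dates is not None else ["2021-01-01"] * n
    meta["seq_plate"] = plates if plates is not None else ["PLATE01"] * n
    meta["braf_v600e"] = "negative"
    for key, value in extra.items():
        meta[key] = value
    return meta


@pytest.fixture
def rng():
    return np.random.default_rng(20230305)
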