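import pandas as pd
import pytest
from hypothesis import settings

from phylofilt import Lineage, OtuTable

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_otus(rows, taxonomy=None, replicates=("rep1", "rep2", "rep3")):
    """Build a small OtuTable from {otu_id: count tuple} and lineage strings."""
    counts = pd.DataFrame.from_dict(
        {k: list(v) for k, v in rows.items()}, orient="index", columns=list(replicates)
    )
    taxmap = {
        otu: Lineage.from_string(text)
        for otu, text in (taxonomy or {}).items()
    }
    return OtuTable(counts, taxmap)


@pytest.fixture
def tiny_table():
    """Three OTUs over three replicates with mixed lineage depths."""
    return make_otus(
        {
            "otu1": (5, 0, 2),
            "otu2": (1, 1, 1),
            "otu3": (12, 11, 10),
        },
        {
            "otu1": "Bacteria;Cyanobacteria;Cyanophyceae;Synechococcales;Synechococcaceae;Synechococcus",
            "otu2": "Eukaryota;Streptophyta;Magnoliopsida;Fabales;Fabaceae;Cicer;Cicer arietinum",
            "otu3": "Bacteria;Cyanobacteria;Cyanophyceae;Synechococcales;Synechococcaceae;Synechococcus",
        },
    )
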