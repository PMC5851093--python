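import pandas as pd
import pytest

from mhcpopgen import summaries
from mhcpopgen.io_model import GenotypeDataset, ObservedAlleleSet


@pytest.fixture(scope="session")
def drb_frequency_table() -> pd.DataFrame:
    """Bundled published per-population DRB allele-frequency table."""
    return summaries.read_frequency_table(
        summaries.bundled_path("rhro_drb_allele_frequencies.csv")
    )


@pytest.fixture(scope="session")
def drb_count_tables(drb_frequency_table):
    return summaries.counts_from_table(drb_frequency_table)


@pytest.fixture()
def tiny_observations():
    """Two individuals at one locus: genotypes a/a and a/b seen as sets."""
    return [
        ObservedAlleleSet("i1", "p", frozenset({"a"})),
        ObservedAlleleSet("i2", "p", frozenset({"a", "b"})),
    ]


def make_genotypes(rows):
    return GenotypeDataset(
        pd.DataFrame(
            rows,
            columns=["individual_id", "population", "locus", "allele_a", "allele_b"],
        )
    )
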