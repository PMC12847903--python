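import numpy as np
import pytest

from sigscore import (SimulationConfig, default_catalog, normalize_taxon_name,
                      simulate_cohort, table_from_arrays)

METAPHLAN_FIXTURE = """\
#mpa_vJan21_CHOCOPhlAnSGB_202103
#clade_name\tsampleA\tsampleB
k__Bacteria|p__Firmicutes|c__Clostridia|o__Eubacteriales|f__Oscillospiraceae|g__Faecalibacterium\t30.0\t5.0
k__Bacteria|p__Firmicutes|c__Clostridia|o__Eubacteriales|f__Oscillospiraceae|g__Faecalibacterium|s__Faecalibacterium_prausnitzii\t25.5\t3.25
k__Bacteria|p__Firmicutes|c__Bacilli|o__Lactobacillales|f__Streptococcaceae|g__Streptococcus|s__Streptococcus_salivarius\t0.0\t12.0
k__Bacteria|p__Verrucomicrobia|c__Verrucomicrobiae|o__Verrucomicrobiales|f__Akkermansiaceae|g__Akkermansia|s__Akkermansia_muciniphila\t2.5\t6.0
"""


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture()
def metaphlan_file(tmp_path):
    path = tmp_path / "merged_abundance.tsv"
    path.write_text(METAPHLAN_FIXTURE)
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """A small paper-structured simulated cohort shared across tests."""
    return simulate_cohort(SimulationConfig(seed=11, n_healthy=150,
                                            n_cancer=150))


def make_table(values, taxon_names, sample_ids=None):
    """Helper: validated AbundanceTable from a samples x taxa array."""
    values = np.asarray(values, dtype=float)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(values.shape[0])]
    taxa = [normalize_taxon_name(n) for n in taxon_names]
    return table_from_arrays(sample_ids, taxa, values)
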