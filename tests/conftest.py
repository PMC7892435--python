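import pytest

from founderage.haplotype_io import (
    ChromosomeRecord,
    HaplotypeSet,
    MarkerInfo,
    MarkerMap,
    paper_marker_map,
    packaged_delta_table,
)
from founderage.ld_stats import AncestralHaplotype, paper_ancestral_haplotype

PAPER_FOUNDER = {
    "D1S212": 20,
    "D1S2659": 11,
    "D1S218": 24,
    "D1S2790": 20,
    "D1S1165": 13,
    "D1S2815": 18,
    "D1S196": 12,
    "D1S460": 7,
}


@pytest.fixture(scope="session")
def paper_map():
    return paper_marker_map()


@pytest.fixture(scope="session")
def paper_anc():
    return paper_ancestral_haplotype()


@pytest.fixture(scope="session")
def table1_deltas():
    return packaged_delta_table()


@pytest.fixture(scope="session")
def paper_founder():
    return dict(PAPER_FOUNDER)


@pytest.fixture
def one_marker_map():
    return MarkerMap((MarkerInfo("M1", "distal", 1.0, 2, 0.0),))


def make_hapset(marker_map, carriers, controls, independent=None):
    """Build a HaplotypeSet from allele dicts (one dict per chromosome)."""
    records = []
    for i, alleles in enumerate(carriers):
        records.append(
            ChromosomeRecord(
                chrom_id=f"car{i}",
                family_id=f"famc{i}",
                group="carrier",
                independent=True if independent is None else independent[i],
                alleles=dict(alleles),
            )
        )
    for i, alleles in enumerate(controls):
        records.append(
            ChromosomeRecord(
                chrom_id=f"ctl{i}",
                family_id=f"famn{i}",
                group="control",
                independent=True,
                alleles=dict(alleles),
            )
        )
    return HaplotypeSet(marker_map, tuple(records))


@pytest.fixture
def make_set():
    return make_hapset
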