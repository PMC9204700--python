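import io

import pytest

from hdxkit import (SyntheticSpec, assign_replicates, build_uptake_table,
                    generate_dataset, parse_cluster_csv)


def table_from_dataset(dataset):
    records = parse_cluster_csv(io.StringIO(dataset.csv_text), "s")
    records = assign_replicates(records)
    return build_uptake_table(records)


@pytest.fixture(scope="session")
def small_dataset():
    """Small noisy two-state dataset with fragments and a reference peptide."""
    spec = SyntheticSpec(
        protein_length=60, n_peptides=12, fragment_fraction=0.4,
        times=(0.1, 1.0, 10.0, 100.0, 1000.0), replicates=3,
        noise_sd=0.02, seed=7,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    return table_from_dataset(small_dataset)


@pytest.fixture(scope="session")
def noiseless_dataset():
    spec = SyntheticSpec(
        protein_length=50, n_peptides=8, fragment_fraction=0.3,
        times=(0.1, 1.0, 10.0, 100.0), replicates=3,
        noise_sd=0.0, seed=11,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def noiseless_table(noiseless_dataset):
    return table_from_dataset(noiseless_dataset)


TINY_CSV = """\
prot1,10,17,KLSAMGTR,,,7,846.4767,apo,50,apo_t01_01,2,12.5,1000,424.245626466
prot1,10,17,KLSAMGTR,,,7,846.4767,apo,50,apo_t01_01,3,12.5,500,283.166176466
prot1,10,17,KLSAMGTR,,c3,2,360.2,apo,50,apo_t01_01,1,12.5,200,361.207276466
"""


@pytest.fixture()
def tiny_csv_buffer():
    return io.StringIO(TINY_CSV)
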