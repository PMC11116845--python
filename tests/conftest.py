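import logging

import pytest

from crypticlade.genotypes import (
    AllozymeDataset,
    Genotype,
    Individual,
)


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    logging.getLogger("crypticlade").setLevel(logging.ERROR)
    yield


def make_dataset(rows, loci):
    """Build a dataset from ``[(id, site, {locus: 'a/b' | None}), ...]``."""
    individuals = []
    genotypes = {}
    for ind_id, site, calls in rows:
        individuals.append(Individual(ind_id, site))
        for locus, token in calls.items():
            if token is None:
                continue
            a, b = token.split("/")
            genotypes[(ind_id, locus)] = Genotype(locus, (a, b))
    return AllozymeDataset(individuals, loci, genotypes)


@pytest.fixture
def two_group_dataset():
    """Two sites fixed for different alleles at locus X, sharing locus Y."""
    rows = []
    for i in range(4):
        rows.append((f"n{i}", "north", {"X": "a/a", "Y": "a/a" if i < 3 else "a/b"}))
    for i in range(4):
        rows.append((f"s{i}", "south", {"X": "b/b", "Y": "a/a"}))
    return make_dataset(rows, ["X", "Y"])
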