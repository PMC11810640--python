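from __future__ import annotations

import pytest

from dupmode.classify import ClassifyParams, classify_pairs
from dupmode.io import build_paranome
from dupmode.model import GeneIndex
from dupmode.simulate import SynthConfig, SynthDataset, generate_dataset
from dupmode.synteny import (SyntenyParams, ancestral_loci,
                             intragenomic_anchor_pairs)


@pytest.fixture(scope="session")
def dataset() -> SynthDataset:
    """The default synthetic fixture: 3 planted events per mode, seed 0."""
    return generate_dataset(SynthConfig())


@pytest.fixture(scope="session")
def paranome(dataset):
    return build_paranome(dataset.intraspecies_hits(), dataset.query)


@pytest.fixture(scope="session")
def anchor_pairs(dataset, paranome):
    return intragenomic_anchor_pairs(paranome, dataset.query, SyntenyParams())


@pytest.fixture(scope="session")
def outgroup_ancestral(dataset):
    return {
        name: ancestral_loci(set(dataset.ortholog_maps[name].items()),
                             dataset.query, dataset.outgroups[name],
                             SyntenyParams())
        for name in dataset.outgroups
    }


@pytest.fixture(scope="session")
def full_pairs(paranome, dataset, anchor_pairs, outgroup_ancestral):
    """Pairs classified under the full scheme on the default fixture."""
    return classify_pairs(paranome, dataset.query, anchor_pairs,
                          ClassifyParams(scheme="full"), outgroup_ancestral)


def make_index(n: int = 20, chrom: str = "chr1", species: str = "sp",
               exon_counts=None) -> GeneIndex:
    """Hand-built single-chromosome annotation: g01..gNN at 1 kb spacing."""
    records = []
    for i in range(n):
        start = 1 + i * 1000
        nexon = exon_counts[i] if exon_counts else 2
        records.append((f"g{i + 1:02d}", chrom, start, start + 500, "+",
                        nexon))
    return GeneIndex.build(species, records)
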