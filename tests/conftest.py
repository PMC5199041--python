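"""Shared fixtures: small synthetic datasets generated once per session."""

from __future__ import annotations

import pytest

from rapphr.mining import GenomeRecord, SearchParams, mine_genome
from rapphr.pipeline import seed_queries_from_truth
from rapphr.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_strains=8, n_species=2)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_genomes(small_truth):
    return {
        strain: GenomeRecord(strain, strain.split("_")[0],
                             {f"{strain}_c1": small_truth.contigs[strain]})
        for strain in small_truth.strains["strain"]
    }


@pytest.fixture(scope="session")
def small_search_params(small_truth) -> SearchParams:
    return SearchParams(seed_queries=seed_queries_from_truth(small_truth))


@pytest.fixture(scope="session")
def small_mined(small_genomes, small_search_params):
    """Mined cassettes per strain on the small dataset."""
    return {strain: mine_genome(g, small_search_params)
            for strain, g in small_genomes.items()}


def match_truth_row(truth, cassette):
    """Truth-table row whose receptor interval matches a mined cassette."""
    tc = truth.cassettes
    hit = tc[(tc["strain"] == cassette.strain)
             & (tc["rap_start"] == cassette.receptor.start)
             & (tc["rap_end"] == cassette.receptor.end)]
    return hit.iloc[0] if len(hit) else None
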