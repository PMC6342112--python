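"""Shared fixtures: toy networks and a session-wide reference pipeline run."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import bioregions as br


def make_block_network(
    n_blocks: int = 4,
    block_size: int = 15,
    w_in: float = 0.9,
    w_out: float = 0.05,
) -> tuple[br.SimilarityNetwork, np.ndarray]:
    """Complete weighted network with planted blocks; returns (network, labels)."""
    n = n_blocks * block_size
    labels = np.repeat(np.arange(n_blocks), block_size)
    iu = np.triu_indices(n, 1)
    w = np.where(labels[iu[0]] == labels[iu[1]], w_in, w_out).astype(float)
    net = br.SimilarityNetwork(
        nodes=np.arange(n), edges=np.column_stack(iu), weights=w
    )
    return net, labels


def make_clique_in_background(seed: int = 0, n: int = 60, clique: int = 6):
    """Unit-weight sparse random background (expected degree 3) plus a clique."""
    rng = np.random.default_rng(seed)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 3 / (n - 1):
                edges.add((i, j))
    for i in range(clique):
        for j in range(i + 1, clique):
            edges.add((i, j))
    e = np.array(sorted(edges))
    return br.SimilarityNetwork(nodes=np.arange(n), edges=e, weights=np.ones(len(e)))


@pytest.fixture
def block_network():
    return make_block_network()


@dataclass
class ReferenceRun:
    """Products of the full pipeline on the reference synthetic scenario."""

    scenario: br.SyntheticScenario
    truth: br.GroundTruth
    incidence: br.BipartiteIncidence
    cell_network: br.SimilarityNetwork
    partition: br.Partition
    tv: br.TestValueMatrix
    species_network: br.SimilarityNetwork
    groups: br.Partition
    cm: br.ContributionMatrix
    lam: br.InteractionMatrix


@pytest.fixture(scope="session")
def reference_run(tmp_path_factory) -> ReferenceRun:
    """Full pipeline on the 20×20-cell, 4-region, 800-species scenario.

    Shared across the suite: every downstream check reuses this single run.
    """
    scenario = br.reference_scenario()
    occ, truth = br.sample_occurrences(scenario)
    occ_path = tmp_path_factory.mktemp("reference") / "occurrences.csv"
    occ.to_csv(occ_path, index=False)
    records = br.filter_records(br.read_occurrences(occ_path))
    grid = br.build_grid(records, side_l=scenario.side_l)
    incidence = br.rasterize_to_bipartite(records, grid)
    cell_network = br.project_bipartite(incidence, index="jaccard")
    partition = br.detect_communities(
        cell_network, method="significance_local_opt", tolerance=0.1, seed=7, n_runs=5
    )
    tv = br.compute_test_values(incidence, partition)
    species_network = br.build_species_network(tv)
    groups = br.detect_species_groups(
        species_network, tolerance=0.1, seed=8, n_runs=5
    )
    cm = br.normalize_per_species(br.threshold_positive(tv, delta=1.96))
    lam = br.interaction_matrix(cm)
    return ReferenceRun(
        scenario=scenario,
        truth=truth,
        incidence=incidence,
        cell_network=cell_network,
        partition=partition,
        tv=tv,
        species_network=species_network,
        groups=groups,
        cm=cm,
        lam=lam,
    )
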