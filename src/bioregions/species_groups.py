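"""Species-species similarity from test-value profiles and species groups.

Two species are similar when they over- and under-represent the same
bioregions: s_ii' = 1 / (1 + Σ_j (ρ_ij − ρ_i'j)²), a kernel in (0, 1] that
decreases monotonically with the Euclidean distance between the species'
test-value profiles (a variant with the unsquared distance is available).
Groups of species sharing the same spatial behavior are then communities of
this similarity network, detected with the same significance-aware detector
used for bioregions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .cellnet import SimilarityNetwork, _keep_mask
from .communities import Partition, detect_communities
from .errors import ParameterError
from .testvalues import DEFAULT_DELTA, TestValueMatrix

__all__ = [
    "SpeciesGroupPartition",
    "species_similarity",
    "build_species_network",
    "detect_species_groups",
    "group_profiles",
]

SpeciesGroupPartition = Partition


def _to_similarity(d2: np.ndarray, squared: bool) -> np.ndarray:
    return 1.0 / (1.0 + (d2 if squared else np.sqrt(d2)))


def species_similarity(
    tv: TestValueMatrix, pair: tuple[str, str], squared: bool = True
) -> float:
    """Similarity between two species' test-value profiles."""
    try:
        i = tv.species.index(pair[0])
        j = tv.species.index(pair[1])
    except ValueError as exc:
        raise ParameterError(f"species not in test-value matrix: {exc}") from exc
    d2 = float(np.sum((tv.rho[i] - tv.rho[j]) ** 2))
    return float(_to_similarity(np.array(d2), squared))


def build_species_network(
    tv: TestValueMatrix,
    min_weight: float = 0.0,
    squared: bool = True,
) -> SimilarityNetwork:
    """All-pairs species similarity network from the ρ matrix.

    By default the complete weighted graph is kept (s is strictly positive);
    ``min_weight`` prunes weak edges, and at ``min_weight = 1`` only pairs
    with exactly identical profiles remain connected.
    """
    if tv.K < 2:
        raise ParameterError("species network requires at least two bioregions")
    d2 = pdist(tv.rho, metric="sqeuclidean")
    s = _to_similarity(d2, squared)
    iu = np.triu_indices(len(tv.species), k=1)
    keep = _keep_mask(s, min_weight)
    return SimilarityNetwork(
        nodes=np.array(tv.species, dtype=object),
        edges=np.column_stack([iu[0][keep], iu[1][keep]]),
        weights=s[keep],
        index_name="profile_similarity" + ("" if squared else "_sqrt"),
    )


def detect_species_groups(
    network: SimilarityNetwork,
    method: str = "significance_local_opt",
    tolerance: float = 0.1,
    seed: int = 0,
    n_runs: int = 10,
    n_clusters: int | None = None,
) -> SpeciesGroupPartition:
    """Detect groups of species with shared spatial behavior.

    Delegates to :func:`bioregions.communities.detect_communities` with an
    identical contract; species the detector leaves homeless are attached by
    the maximum-similarity rule inside it.
    """
    return detect_communities(
        network,
        method=method,
        tolerance=tolerance,
        seed=seed,
        n_runs=n_runs,
        n_clusters=n_clusters,
    )


def group_profiles(
    groups: SpeciesGroupPartition,
    tv: TestValueMatrix,
    delta: float = DEFAULT_DELTA,
) -> pd.DataFrame:
    """Five-number summary of ρ per (group, bioregion).

    Quartiles use linear interpolation (type 7).  ``median_significant``
    flags summaries whose median exceeds δ — the group characterizes that
    bioregion.
    """
    sp_index = {s: i for i, s in enumerate(tv.species)}
    rows = []
    for k in sorted(groups.sizes()):
        members = [groups.nodes[i] for i in groups.members(k)]
        try:
            ridx = [sp_index[m] for m in members]
        except KeyError as exc:
            raise ParameterError(
                f"group member {exc.args[0]!r} missing from test-value matrix"
            ) from exc
        block = tv.rho[ridx]
        for j, region in enumerate(tv.regions.tolist()):
            col = block[:, j]
            q1, med, q3 = np.quantile(col, [0.25, 0.5, 0.75])
            rows.append(
                {
                    "group": k,
                    "bioregion": region,
                    "n_species": len(members),
                    "min": float(col.min()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "max": float(col.max()),
                    "median_significant": bool(med > delta),
                }
            )
    return pd.DataFrame(rows)
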