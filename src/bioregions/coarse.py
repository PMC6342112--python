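"""Coarse-grained bioregion interaction network.

Only positive, significant contributions are retained (ρ⁺ = ρ·1{ρ > δ});
each species' significant contributions are then normalized to sum to one
across bioregions (ρ̂⁺), and the interaction matrix averages them over each
region's contributing species A_j = {i : ρ_ij > δ}:

    λ_jj' = (1/|A_j|) Σ_{i ∈ A_j} ρ̂⁺_ij'.

Each defined row of λ sums to one; the diagonal λ_jj is the region's
*specificity* (how exclusively its characteristic species contribute to it)
and the off-diagonal entries quantify directed relationships between
regions — λ is in general asymmetric and is never symmetrized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .communities import Partition
from .errors import ParameterError
from .species_groups import group_profiles
from .testvalues import DEFAULT_DELTA, TestValueMatrix

__all__ = [
    "ContributionMatrix",
    "InteractionMatrix",
    "threshold_positive",
    "normalize_per_species",
    "interaction_matrix",
    "merge_regions",
    "build_coarse_network",
]


@dataclass
class ContributionMatrix:
    """Thresholded (ρ⁺) and per-species normalized (ρ̂⁺) contributions."""

    rho_plus: np.ndarray  # (S, K), >= 0
    species: list[str]
    regions: np.ndarray  # (K,)
    delta: float
    rho_hat: np.ndarray | None = None  # (S, K), rows sum to 1 or are all-zero

    @property
    def K(self) -> int:
        return len(self.regions)

    def significant_sets(self) -> dict[int, list[str]]:
        """A_j: species contributing significantly to each region."""
        return {
            int(region): [
                self.species[i] for i in np.flatnonzero(self.rho_plus[:, j] > 0)
            ]
            for j, region in enumerate(self.regions.tolist())
        }


@dataclass
class InteractionMatrix:
    """K × K matrix λ; diagonal = specificity, off-diagonal = relationships."""

    lam: np.ndarray
    regions: np.ndarray
    defined: np.ndarray  # bool per row: |A_j| >= 1
    n_contributing: np.ndarray  # |A_j|

    def to_frame(self, percentage: bool = False) -> pd.DataFrame:
        values = self.lam * 100.0 if percentage else self.lam
        return pd.DataFrame(values, index=self.regions, columns=self.regions)

    @property
    def specificity(self) -> np.ndarray:
        return np.diag(self.lam)

    def mean_specificity(self) -> float:
        """Average diagonal over defined regions."""
        return float(np.diag(self.lam)[self.defined].mean())


def threshold_positive(
    tv: TestValueMatrix, delta: float = DEFAULT_DELTA
) -> ContributionMatrix:
    """Zero every test value not strictly above δ (ρ⁺_ij = ρ_ij·1{ρ_ij > δ})."""
    if not np.isfinite(tv.rho).all():
        raise ParameterError("test-value matrix contains non-finite entries")
    rho_plus = np.where(tv.rho > delta, tv.rho, 0.0)
    return ContributionMatrix(
        rho_plus=rho_plus,
        species=list(tv.species),
        regions=tv.regions.copy(),
        delta=delta,
    )


def normalize_per_species(cm: ContributionMatrix) -> ContributionMatrix:
    """Distribute each species' significant contributions among regions.

    Rows with at least one significant contribution are scaled to sum to 1;
    species with none keep an all-zero row (and belong to no A_j).
    """
    totals = cm.rho_plus.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_hat = np.where(totals > 0, cm.rho_plus / np.where(totals > 0, totals, 1.0), 0.0)
    return ContributionMatrix(
        rho_plus=cm.rho_plus,
        species=cm.species,
        regions=cm.regions,
        delta=cm.delta,
        rho_hat=rho_hat,
    )


def interaction_matrix(cm: ContributionMatrix) -> InteractionMatrix:
    """Average normalized contributions over each region's species set.

    Rows of regions with an empty A_j are undefined (NaN) and flagged rather
    than silently dropped; if every A_j is empty the threshold δ was too
    strict and an error is raised.
    """
    if cm.rho_hat is None:
        cm = normalize_per_species(cm)
    K = cm.K
    lam = np.full((K, K), np.nan)
    n_contrib = np.zeros(K, dtype=np.int64)
    for j in range(K):
        members = np.flatnonzero(cm.rho_plus[:, j] > 0)
        n_contrib[j] = len(members)
        if len(members):
            lam[j] = cm.rho_hat[members].mean(axis=0)
    defined = n_contrib >= 1
    if not defined.any():
        raise ParameterError(
            "no region has a significant contributor; lower delta"
        )
    return InteractionMatrix(
        lam=lam, regions=cm.regions.copy(), defined=defined, n_contributing=n_contrib
    )


def merge_regions(cm: ContributionMatrix, region_a: int, region_b: int) -> ContributionMatrix:
    """Merge two regions at the contribution level (columns summed, A sets unioned).

    The merged column keeps the lower region id.  Used for coarse sanity
    checks: merging can only concentrate a species' contribution, so the
    merged region's specificity never drops below the smaller of the two
    original diagonals.
    """
    regions = cm.regions.tolist()
    if region_a not in regions or region_b not in regions:
        raise ParameterError("both regions must exist")
    if region_a == region_b:
        raise ParameterError("cannot merge a region with itself")
    ja, jb = regions.index(region_a), regions.index(region_b)
    keep = [j for j in range(cm.K) if j != max(ja, jb)]
    target = min(ja, jb)
    rho_plus = cm.rho_plus.copy()
    rho_plus[:, target] = rho_plus[:, ja] + rho_plus[:, jb]
    merged = ContributionMatrix(
        rho_plus=rho_plus[:, keep],
        species=cm.species,
        regions=cm.regions[keep],
        delta=cm.delta,
    )
    return normalize_per_species(merged)


def build_coarse_network(
    lam: InteractionMatrix,
    groups: Partition | None = None,
    tv: TestValueMatrix | None = None,
    delta: float = DEFAULT_DELTA,
    display_threshold: float = 0.10,
) -> nx.DiGraph:
    """Directed coarse-grained graph over bioregions (and species groups).

    Bioregion nodes carry their specificity (the λ self-loop, stored as an
    attribute) and contributing-species count; a directed edge j→j' is kept
    when λ_jj' ≥ ``display_threshold``.  When ``groups`` and ``tv`` are
    given, species-group nodes are linked to every bioregion their median ρ
    characterizes (median > δ), weighted by that median.  The full λ matrix
    is unaffected by the display threshold — this graph is a report.
    """
    g = nx.DiGraph()
    regions = lam.regions.tolist()
    for j, region in enumerate(regions):
        g.add_node(
            f"bioregion:{region}",
            kind="bioregion",
            specificity=float(lam.lam[j, j]) if lam.defined[j] else float("nan"),
            n_contributing=int(lam.n_contributing[j]),
            defined=bool(lam.defined[j]),
        )
    for j, src in enumerate(regions):
        if not lam.defined[j]:
            continue
        for jp, dst in enumerate(regions):
            if j != jp and lam.lam[j, jp] >= display_threshold:
                g.add_edge(
                    f"bioregion:{src}", f"bioregion:{dst}", weight=float(lam.lam[j, jp])
                )
    if groups is not None and tv is not None:
        profiles = group_profiles(groups, tv, delta=delta)
        for k, size in sorted(groups.sizes().items()):
            g.add_node(f"group:{k}", kind="group", n_species=int(size))
        for _, row in profiles.iterrows():
            if row["median_significant"]:
                g.add_edge(
                    f"group:{int(row['group'])}",
                    f"bioregion:{int(row['bioregion'])}",
                    weight=float(row["median"]),
                )
    return g
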