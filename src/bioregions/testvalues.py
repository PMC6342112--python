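"""Species × bioregion test values and the contribution spectrum.

The test value (valeur-test) ρ_ij compares the number of cells n_ij where
species i occurs inside bioregion j with the n_i·n_j/n expected if the
species' n_i cells were placed uniformly over the n cells of the study area,
normalized by the hypergeometric standard deviation

    σ_ij = sqrt( n_i n_j (n − n_i)(n − n_j) / (n² (n − 1)) ).

ρ_ij is negative when the species is under-represented in the region, zero
when present in proportion to the whole area, positive when over-represented;
a species *contributes* to a region when ρ_ij exceeds a threshold δ
(default 1.96, the 2.5% upper tail of a standard Gaussian).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .communities import Partition
from .errors import ParameterError
from .gridding import BipartiteIncidence

__all__ = [
    "TestValueMatrix",
    "compute_test_values",
    "contribution_spectrum",
    "top_species",
    "empirical_moments",
]

DEFAULT_DELTA = 1.96


@dataclass
class TestValueMatrix:
    """ρ matrix with the counts it was derived from."""

    rho: np.ndarray  # (S, K)
    species: list[str]
    regions: np.ndarray  # (K,) bioregion ids
    n: int
    n_i: np.ndarray  # (S,)
    n_j: np.ndarray  # (K,)
    n_ij: np.ndarray  # (S, K)

    @property
    def K(self) -> int:
        return len(self.regions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.species, columns=self.regions)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TestValueMatrix":
        """Rebuild from a ρ table (counts unavailable, filled with zeros)."""
        S, K = df.shape
        return cls(
            rho=df.to_numpy(dtype=float),
            species=[str(s) for s in df.index],
            regions=np.asarray(df.columns, dtype=np.int64)
            if np.issubdtype(np.asarray(df.columns).dtype, np.number)
            else np.arange(1, K + 1),
            n=0,
            n_i=np.zeros(S, dtype=np.int64),
            n_j=np.zeros(K, dtype=np.int64),
            n_ij=np.zeros((S, K), dtype=np.int64),
        )


def hypergeometric_sd(n: int, n_i, n_j) -> np.ndarray:
    """Standard deviation of n_ij under uniform placement; symmetric in i↔j."""
    n_i = np.asarray(n_i, dtype=float)
    n_j = np.asarray(n_j, dtype=float)
    if n < 2:
        return np.zeros(np.broadcast(n_i, n_j).shape)
    var = n_i * n_j * (n - n_i) * (n - n_j) / (n**2 * (n - 1))
    return np.sqrt(np.maximum(var, 0.0))


def compute_test_values(
    incidence: BipartiteIncidence, partition: Partition
) -> TestValueMatrix:
    """Evaluate ρ_ij for every species and bioregion.

    The partition must cover exactly the incidence cells with K ≥ 2 regions.
    Degenerate entries with σ_ij = 0 (a species present everywhere, or a
    region spanning the whole area) are defined as ρ = 0: such a species is
    present in exact proportion wherever it is.
    """
    part_map = partition.label_of()
    try:
        labels = np.array([part_map[int(c)] for c in incidence.cell_ids], dtype=np.int64)
    except KeyError as exc:
        raise ParameterError(
            f"partition does not cover incidence cell {exc.args[0]}"
        ) from exc
    if len(part_map) != incidence.n:
        raise ParameterError("partition and incidence cover different cell sets")
    if (labels <= 0).any():
        raise ParameterError("partition leaves cells unassigned; run assign_homeless")

    regions = np.unique(labels)
    if len(regions) < 2:
        raise ParameterError("test values require at least two bioregions")
    n = incidence.n
    n_i = incidence.occupancy
    if (n_i == 0).any():
        raise ParameterError("species with zero occupancy must be excluded upstream")
    onehot = (labels[:, None] == regions[None, :]).astype(np.int64)
    n_j = onehot.sum(axis=0)
    n_ij = np.asarray(incidence.presence.T @ onehot)

    expected = np.outer(n_i, n_j) / n
    sd = hypergeometric_sd(n, n_i[:, None], n_j[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(sd > 0, (n_ij - expected) / np.where(sd > 0, sd, 1.0), 0.0)
    return TestValueMatrix(
        rho=rho,
        species=list(incidence.species),
        regions=regions,
        n=n,
        n_i=n_i,
        n_j=n_j,
        n_ij=n_ij,
    )


def empirical_moments(
    n: int, n_i: int, n_j: int, n_samples: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Mean and sd of n_ij over uniform random placements (simulation oracle).

    Each replicate places the species' n_i cells uniformly at random among
    the n cells and counts how many land inside an arbitrary fixed region of
    n_j cells.  Independent of the closed form used by
    :func:`compute_test_values`; intended for validating it.
    """
    if not (0 < n_i <= n and 0 < n_j <= n):
        raise ParameterError("need 0 < n_i, n_j <= n")
    rng = np.random.default_rng(seed)
    u = rng.random((n_samples, n))
    chosen = np.argpartition(u, n_i - 1, axis=1)[:, :n_i]
    counts = (chosen < n_j).sum(axis=1)
    return float(counts.mean()), float(counts.std(ddof=1))


def contribution_spectrum(
    tv: TestValueMatrix, delta_grid
) -> pd.DataFrame:
    """Fraction of species contributing to exactly k regions, per threshold.

    For each δ in ``delta_grid``, species i contributes to region j iff
    ρ_ij > δ; the long-format result has columns (delta, k, fraction) with
    k = 0..K and fractions summing to 1 at every δ.
    """
    delta_grid = np.asarray(list(delta_grid), dtype=float)
    if delta_grid.size == 0:
        raise ParameterError("delta_grid must be nonempty")
    S, K = tv.rho.shape
    rows = []
    for delta in delta_grid:
        k_counts = (tv.rho > delta).sum(axis=1)
        frac = np.bincount(k_counts, minlength=K + 1) / S
        for k in range(K + 1):
            rows.append({"delta": float(delta), "k": k, "fraction": float(frac[k])})
    return pd.DataFrame(rows)


def top_species(
    tv: TestValueMatrix, region: int, delta: float = DEFAULT_DELTA
) -> pd.DataFrame:
    """Species contributing to a region, ranked by descending ρ (ties by label)."""
    regions = tv.regions.tolist()
    if region not in regions:
        raise ParameterError(f"region {region} not in test-value matrix")
    j = regions.index(region)
    col = tv.rho[:, j]
    keep = np.flatnonzero(col > delta)
    df = pd.DataFrame({"species": [tv.species[i] for i in keep], "rho": col[keep]})
    return df.sort_values(["rho", "species"], ascending=[False, True], ignore_index=True)
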