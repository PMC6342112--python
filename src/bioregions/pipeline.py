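"""End-to-end orchestration of the five analysis steps with a run manifest.

Order of stages: gridding → similarity projection → bioregion detection →
test values → species groups → coarse graining.  Every stage persists its
output as plain text (delimited tables, matrix market, GeoJSON, GraphML) in
the run directory, so any stage can be resumed from intermediates, and the
manifest records config, input digest, seeds, versions, counts and timings —
enough to re-run deterministic stages bit-identically.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .cellnet import SimilarityNetwork, project_bipartite, sparsify
from .coarse import (
    build_coarse_network,
    interaction_matrix,
    normalize_per_species,
    threshold_positive,
)
from .communities import Partition, cluster_report, detect_communities
from .errors import ConfigurationError
from .gridding import (
    BipartiteIncidence,
    build_grid,
    filter_records,
    rasterize_to_bipartite,
    read_exclusion_list,
    read_occurrences,
)
from .species_groups import build_species_network, detect_species_groups, group_profiles
from .testvalues import compute_test_values, contribution_spectrum

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunables of the five-step analysis, with survey-style defaults:
    5 km cells, precision strictly below 10 m, Jaccard similarity, tolerance
    0.1, δ = 1.96 and a 10% display threshold."""

    # gridding
    side_l: float = 5000.0
    max_precision_m: float = 10.0
    drop_missing_precision: bool = False
    aggregate_subtaxa: bool = True
    exclude_file: str | None = None
    # projection
    similarity_index: str = "jaccard"
    min_weight: float = 0.0
    top_k: int | None = None
    # community detection (bioregions)
    method: str = "significance_local_opt"
    tolerance: float = 0.1
    n_runs: int = 10
    n_clusters: int | None = None
    # test values / coarse graining
    delta: float = 1.96
    display_threshold: float = 0.10
    # species groups
    groups_method: str = "significance_local_opt"
    groups_min_weight: float = 0.0
    groups_squared: bool = True
    # randomness
    seed: int = 0

    _SECTIONS = {
        "grid": ("side_l", "max_precision_m", "drop_missing_precision",
                 "aggregate_subtaxa", "exclude_file"),
        "project": ("similarity_index", "min_weight", "top_k"),
        "bioregions": ("method", "tolerance", "n_runs", "n_clusters"),
        "testvalues": ("delta",),
        "groups": ("groups_method", "groups_min_weight", "groups_squared"),
        "coarse": ("display_threshold",),
        "run": ("seed",),
    }

    def derived_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(2) % (2**31 - 1)
        return {"bioregions": int(state[0]), "groups": int(state[1])}

    def to_file(self, path: str | Path) -> None:
        cp = configparser.ConfigParser()
        for section, keys in self._SECTIONS.items():
            cp[section] = {
                k: str(getattr(self, k)) for k in keys if getattr(self, k) is not None
            }
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise ConfigurationError(f"cannot read config file {path}")
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        for section, keys in cls._SECTIONS.items():
            if section not in cp:
                continue
            for k in keys:
                if k not in cp[section]:
                    continue
                raw = cp[section][k]
                t = types[k]
                if raw == "None":
                    kwargs[k] = None
                elif "bool" in t:
                    kwargs[k] = raw.lower() in ("1", "true", "yes", "on")
                elif "int" in t:
                    kwargs[k] = int(raw)
                elif "float" in t:
                    kwargs[k] = float(raw)
                else:
                    kwargs[k] = raw
        return cls(**kwargs)


@dataclass
class RunManifest:
    config: dict
    input_path: str
    input_sha256: str
    seeds: dict
    versions: dict
    stages: list = field(default_factory=list)

    def record(self, stage: str, elapsed: float, resumed: bool = False, **counts) -> None:
        self.stages.append(
            {"stage": stage, "seconds": round(elapsed, 3), "resumed": resumed, **counts}
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _versions() -> dict:
    import scipy
    import sklearn

    return {
        "bioregions": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": nx.__version__,
        "scikit-learn": sklearn.__version__,
    }


def run_pipeline(
    occurrences_path: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
    resume: bool = False,
) -> RunManifest:
    """Execute all five steps and write every stage output under ``outdir``.

    With ``resume=True``, stages whose outputs already exist are loaded from
    disk instead of recomputed; identical config + inputs + seeds yield
    identical outputs either way.
    """
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = cfg.derived_seeds()
    manifest = RunManifest(
        config=asdict(cfg),
        input_path=str(occurrences_path),
        input_sha256=_sha256(occurrences_path),
        seeds=seeds,
        versions=_versions(),
    )
    cfg.to_file(outdir / "config.cfg")

    # -- stage 1: gridding ---------------------------------------------------
    t0 = time.perf_counter()
    inc_prefix = outdir / "incidence"
    resumed = resume and Path(str(inc_prefix) + ".mtx").exists()
    if resumed:
        incidence = BipartiteIncidence.from_files(inc_prefix)
        n_records = None
    else:
        records = read_occurrences(occurrences_path)
        exclusion = (
            read_exclusion_list(cfg.exclude_file) if cfg.exclude_file else None
        )
        records = filter_records(
            records,
            max_precision_m=cfg.max_precision_m,
            exclusion_list=exclusion,
            aggregate_subtaxa=cfg.aggregate_subtaxa,
            drop_missing_precision=cfg.drop_missing_precision,
        )
        n_records = len(records)
        grid = build_grid(records, side_l=cfg.side_l)
        incidence = rasterize_to_bipartite(records, grid)
        incidence.to_files(inc_prefix)
        incidence.to_geojson(outdir / "grid.geojson")
    manifest.record(
        "grid",
        time.perf_counter() - t0,
        resumed=resumed,
        n_records=n_records,
        n_cells=incidence.n,
        n_species=incidence.n_species,
        n_links=incidence.n_links,
    )

    # -- stage 2: spatial projection ----------------------------------------
    t0 = time.perf_counter()
    edges_path = outdir / "cells.edges"
    resumed = resume and edges_path.exists()
    if resumed:
        cellnet = SimilarityNetwork.read_edgelist(edges_path, cfg.similarity_index)
    else:
        cellnet = project_bipartite(
            incidence, index=cfg.similarity_index, min_weight=cfg.min_weight
        )
        if cfg.top_k is not None:
            cellnet = sparsify(cellnet, cfg.top_k)
        cellnet.write_edgelist(edges_path)
    manifest.record(
        "project", time.perf_counter() - t0, resumed=resumed, n_edges=cellnet.n_edges
    )

    # -- stage 3: bioregions -------------------------------------------------
    t0 = time.perf_counter()
    part_path = outdir / "partition.csv"
    resumed = resume and part_path.exists()
    if resumed:
        df = pd.read_csv(part_path)
        rep = pd.read_csv(outdir / "cluster_report.csv")
        partition = Partition(
            nodes=df["cell_id"].to_numpy(),
            labels=df["bioregion"].to_numpy(),
            method=cfg.method,
            seed=seeds["bioregions"],
            significance=dict(
                zip(rep["cluster"].astype(int), rep["significance"])
            ),
        )
    else:
        partition = detect_communities(
            cellnet,
            method=cfg.method,
            tolerance=cfg.tolerance,
            seed=seeds["bioregions"],
            n_runs=cfg.n_runs,
            n_clusters=cfg.n_clusters,
        )
        partition.to_frame().to_csv(part_path, index=False)
        cluster_report(partition, cellnet, incidence.grid).to_csv(
            outdir / "cluster_report.csv", index=False
        )
        incidence.to_geojson(outdir / "partition.geojson", labels=partition.label_of())
    manifest.record(
        "bioregions", time.perf_counter() - t0, resumed=resumed, n_bioregions=partition.K
    )

    # -- stage 4: test values ------------------------------------------------
    t0 = time.perf_counter()
    tv = compute_test_values(incidence, partition)
    tv.to_frame().to_csv(outdir / "rho.csv", index_label="species")
    spectrum = contribution_spectrum(tv, np.linspace(-1.0, 6.0, 71))
    spectrum.to_csv(outdir / "spectrum.csv", index=False)
    manifest.record("testvalues", time.perf_counter() - t0, n_species=len(tv.species))

    # -- stage 5a: species groups -------------------------------------------
    t0 = time.perf_counter()
    spnet = build_species_network(
        tv, min_weight=cfg.groups_min_weight, squared=cfg.groups_squared
    )
    groups = detect_species_groups(
        spnet,
        method=cfg.groups_method,
        tolerance=cfg.tolerance,
        seed=seeds["groups"],
        n_runs=cfg.n_runs,
    )
    groups.to_frame("species", "group").to_csv(outdir / "species_groups.csv", index=False)
    profiles = group_profiles(groups, tv, delta=cfg.delta)
    profiles.to_csv(outdir / "group_profiles.csv", index=False)
    manifest.record("groups", time.perf_counter() - t0, n_groups=groups.K)

    # -- stage 5b: coarse graining ------------------------------------------
    t0 = time.perf_counter()
    cm = normalize_per_species(threshold_positive(tv, delta=cfg.delta))
    lam = interaction_matrix(cm)
    lam.to_frame().to_csv(outdir / "lambda.csv", index_label="bioregion")
    lam.to_frame(percentage=True).to_csv(
        outdir / "lambda_pct.csv", index_label="bioregion"
    )
    coarse_net = build_coarse_network(
        lam, groups=groups, tv=tv, delta=cfg.delta,
        display_threshold=cfg.display_threshold,
    )
    nx.write_graphml(coarse_net, outdir / "coarse.graphml")
    edge_rows = [
        {"source": u, "target": v, "weight": d["weight"]}
        for u, v, d in coarse_net.edges(data=True)
    ]
    pd.DataFrame(edge_rows, columns=["source", "target", "weight"]).to_csv(
        outdir / "coarse_edges.csv", index=False
    )
    manifest.record(
        "coarse",
        time.perf_counter() - t0,
        mean_specificity=lam.mean_specificity(),
    )

    manifest.to_json(outdir / "manifest.json")
    return manifest
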