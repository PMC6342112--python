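"""Occurrence ingestion, square gridding and the cell-species incidence structure.

This module covers the first step of the biogeographical network analysis:
georeferenced occurrence records (projected coordinates in meters) are
cleaned, snapped onto a square analysis grid of lateral size ``l``, and
collapsed into a binary bipartite incidence structure linking occupied grid
cells to the species observed in them.  All downstream stages (similarity
projection, bioregion detection, test values) consume the
:class:`BipartiteIncidence` produced here.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .errors import ConfigurationError, ParameterError

logger = logging.getLogger("bioregions")

#: Default mapping from logical field names to column names in input tables.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "species": "species",
    "x": "x",
    "y": "y",
    "precision": "precision",
    "subtaxon": "subtaxon",
}

#: Tokens marking the start of an infraspecific epithet in a taxon name.
INFRASPECIFIC_MARKERS = frozenset(
    {"subsp.", "ssp.", "var.", "subvar.", "f.", "forma", "cv."}
)


@dataclass(frozen=True, slots=True)
class OccurrenceRecord:
    """One georeferenced observation of a taxon.

    Coordinates are eastings/northings in meters of an already-projected CRS
    (the analysis grid is metric); ``precision_m`` is the georeferencing
    precision in meters when known.
    """

    species: str
    x: float
    y: float
    precision_m: float | None = None
    subtaxon: str | None = None


@dataclass(frozen=True, slots=True)
class GridSpec:
    """A square analysis grid with half-open cells and a lower-left origin.

    Cell ``(row, col)`` covers ``[origin_x + col*l, origin_x + (col+1)*l) ×
    [origin_y + row*l, origin_y + (row+1)*l)``, so every point maps to exactly
    one cell and boundary records are deterministic.
    """

    origin_x: float
    origin_y: float
    side_l: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.side_l <= 0:
            raise ParameterError(f"side_l must be positive, got {self.side_l}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ParameterError("grid must have at least one row and one column")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Return the (row, col) of the half-open cell containing (x, y)."""
        col = math.floor((x - self.origin_x) / self.side_l)
        row = math.floor((y - self.origin_y) / self.side_l)
        return row, col

    def cell_id(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def rowcol_of(self, cell_id: int) -> tuple[int, int]:
        return divmod(int(cell_id), self.n_cols)

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def cell_polygon(self, row: int, col: int) -> list[list[float]]:
        """Closed GeoJSON-style ring of the cell's square outline."""
        x0 = self.origin_x + col * self.side_l
        y0 = self.origin_y + row * self.side_l
        x1, y1 = x0 + self.side_l, y0 + self.side_l
        return [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]

    def to_dict(self) -> dict:
        return {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "side_l": self.side_l,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GridSpec":
        return cls(
            origin_x=float(d["origin_x"]),
            origin_y=float(d["origin_y"]),
            side_l=float(d["side_l"]),
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
        )


@dataclass
class BipartiteIncidence:
    """Binary cell × species presence structure.

    ``presence[i, j] == 1`` iff species ``species[j]`` was recorded at least
    once in the occupied grid cell ``cell_ids[i]``.  Every retained cell hosts
    at least one species and every retained species occupies at least one
    cell.  Region sizes and joint counts against a partition are computed
    downstream (see :mod:`bioregions.testvalues`).
    """

    presence: sparse.csr_matrix
    cell_ids: np.ndarray
    species: list[str]
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        self.presence = sparse.csr_matrix(self.presence, dtype=np.int8)
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        if self.presence.shape != (len(self.cell_ids), len(self.species)):
            raise ValueError("presence shape does not match cell/species indices")

    @property
    def n(self) -> int:
        """Number of occupied grid cells."""
        return len(self.cell_ids)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def occupancy(self) -> np.ndarray:
        """n_i: number of cells occupied by each species (column sums)."""
        return np.asarray(self.presence.sum(axis=0)).ravel().astype(np.int64)

    @property
    def richness(self) -> np.ndarray:
        """Number of species per cell (row sums)."""
        return np.asarray(self.presence.sum(axis=1)).ravel().astype(np.int64)

    @property
    def n_links(self) -> int:
        """Total number of (cell, species) presence links."""
        return int(self.presence.nnz)

    def species_sets(self) -> list[set[int]]:
        """Species-column indices present in each cell."""
        csr = self.presence.tocsr()
        return [
            set(csr.indices[csr.indptr[i] : csr.indptr[i + 1]].tolist())
            for i in range(self.n)
        ]

    # -- persistence ---------------------------------------------------------

    def to_files(self, prefix: str | Path) -> None:
        """Write the incidence as matrix-market plus cell/species index tables."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        mmwrite(str(prefix) + ".mtx", self.presence.tocoo())
        cells = pd.DataFrame({"cell_id": self.cell_ids})
        if self.grid is not None:
            rc = np.array([self.grid.rowcol_of(c) for c in self.cell_ids])
            cells["row"], cells["col"] = rc[:, 0], rc[:, 1]
        cells.to_csv(str(prefix) + ".cells.csv", index=False)
        pd.DataFrame({"species": self.species}).to_csv(
            str(prefix) + ".species.csv", index=False
        )
        if self.grid is not None:
            Path(str(prefix) + ".grid.json").write_text(
                json.dumps(self.grid.to_dict())
            )

    @classmethod
    def from_files(cls, prefix: str | Path) -> "BipartiteIncidence":
        prefix = str(prefix)
        presence = sparse.csr_matrix(mmread(prefix + ".mtx"))
        cells = pd.read_csv(prefix + ".cells.csv")
        species = pd.read_csv(prefix + ".species.csv")["species"].astype(str).tolist()
        grid = None
        grid_path = Path(prefix + ".grid.json")
        if grid_path.exists():
            grid = GridSpec.from_dict(json.loads(grid_path.read_text()))
        return cls(
            presence=presence,
            cell_ids=cells["cell_id"].to_numpy(),
            species=species,
            grid=grid,
        )

    def to_geojson(self, path: str | Path, labels: Mapping[int, int] | None = None) -> None:
        """Write occupied cells as GeoJSON square polygons.

        Properties carry row, col, cell_id and richness; ``labels`` optionally
        adds a ``bioregion`` property keyed by cell id.
        """
        if self.grid is None:
            raise ValueError("incidence has no grid attached")
        richness = self.richness
        features = []
        for i, cid in enumerate(self.cell_ids):
            row, col = self.grid.rowcol_of(cid)
            props = {
                "cell_id": int(cid),
                "row": int(row),
                "col": int(col),
                "richness": int(richness[i]),
            }
            if labels is not None and int(cid) in labels:
                props["bioregion"] = int(labels[int(cid)])
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [self.grid.cell_polygon(row, col)],
                    },
                    "properties": props,
                }
            )
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )


# ---------------------------------------------------------------------------
# reading and filtering records
# ---------------------------------------------------------------------------


def read_occurrences(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[OccurrenceRecord]:
    """Read a delimited occurrence table into records.

    The delimiter is sniffed (comma or tab) unless given.  Rows whose
    coordinates cannot be parsed are logged and dropped; a header-only file
    yields an empty list.  A missing required column raises
    :class:`ConfigurationError`.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    try:
        if delimiter is None:
            df = pd.read_csv(path, sep=None, engine="python", dtype=str)
        else:
            df = pd.read_csv(path, sep=delimiter, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ConfigurationError(f"{path}: file has no header row") from exc

    for key in ("species", "x", "y"):
        if cmap[key] not in df.columns:
            raise ConfigurationError(
                f"{path}: required column {cmap[key]!r} (for {key!r}) not found"
            )
    if df.empty:
        return []

    species = df[cmap["species"]].astype(str).str.strip()
    x = pd.to_numeric(df[cmap["x"]], errors="coerce")
    y = pd.to_numeric(df[cmap["y"]], errors="coerce")
    bad = x.isna() | y.isna() | ~np.isfinite(x.fillna(np.inf)) | ~np.isfinite(
        y.fillna(np.inf)
    ) | (species == "") | species.isna()
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: dropped %d rows with unparseable fields", path, n_bad)

    if cmap["precision"] in df.columns:
        prec = pd.to_numeric(df[cmap["precision"]], errors="coerce")
        neg = prec < 0
        if neg.any():
            logger.warning(
                "%s: %d negative precision values treated as missing",
                path,
                int(neg.sum()),
            )
            prec = prec.mask(neg)
    else:
        prec = pd.Series(np.nan, index=df.index)

    if cmap["subtaxon"] in df.columns:
        sub = df[cmap["subtaxon"]].astype("string").str.strip()
    else:
        sub = pd.Series(pd.NA, index=df.index, dtype="string")

    records: list[OccurrenceRecord] = []
    keep = ~bad
    for i in df.index[keep]:
        p = prec.at[i]
        s = sub.at[i]
        records.append(
            OccurrenceRecord(
                species=species.at[i],
                x=float(x.at[i]),
                y=float(y.at[i]),
                precision_m=None if pd.isna(p) else float(p),
                subtaxon=None if pd.isna(s) or s == "" else str(s),
            )
        )
    return records


def aggregate_name(name: str, synonym_map: Mapping[str, str] | None = None) -> str:
    """Truncate a taxon label to its parent species (genus + epithet).

    Explicit entries in ``synonym_map`` take precedence; otherwise the label
    is cut at the first infraspecific marker (``subsp.``, ``var.``, ...) and,
    failing that, at two tokens.
    """
    if synonym_map and name in synonym_map:
        return synonym_map[name]
    tokens = name.split()
    for k, tok in enumerate(tokens):
        if tok.lower() in INFRASPECIFIC_MARKERS:
            tokens = tokens[:k]
            break
    if len(tokens) > 2:
        tokens = tokens[:2]
    return " ".join(tokens) if tokens else name


def filter_records(
    records: Iterable[OccurrenceRecord],
    max_precision_m: float = 10.0,
    exclusion_list: Iterable[str] | None = None,
    aggregate_subtaxa: bool = True,
    drop_missing_precision: bool = False,
    synonym_map: Mapping[str, str] | None = None,
) -> list[OccurrenceRecord]:
    """Apply record-level quality filters.

    Records are retained only when their georeferencing precision is strictly
    below ``max_precision_m`` (records with unknown precision are kept unless
    ``drop_missing_precision``).  Species on the exclusion list are removed —
    matched against both the raw label and the aggregated species label.
    With ``aggregate_subtaxa`` the label is truncated to the parent binomial
    and the original label kept in the ``subtaxon`` field.
    """
    if max_precision_m <= 0:
        raise ParameterError("max_precision_m must be positive")
    excluded = {e.strip() for e in (exclusion_list or ())}
    out: list[OccurrenceRecord] = []
    for rec in records:
        if rec.precision_m is None:
            if drop_missing_precision:
                continue
        elif rec.precision_m >= max_precision_m:
            continue
        name = rec.species
        if aggregate_subtaxa:
            parent = aggregate_name(name, synonym_map)
        else:
            parent = name
        if name in excluded or parent in excluded:
            continue
        if parent != name:
            rec = replace(rec, species=parent, subtaxon=rec.subtaxon or name)
        out.append(rec)
    if not out:
        logger.warning("filter_records: all %s records filtered out", "input")
    return out


def read_exclusion_list(path: str | Path) -> set[str]:
    """One species name per line; blank lines and '#' comments ignored."""
    names = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.add(line)
    return names


# ---------------------------------------------------------------------------
# gridding
# ---------------------------------------------------------------------------


def build_grid(
    records: Sequence[OccurrenceRecord],
    side_l: float,
    origin: tuple[float, float] | None = None,
) -> GridSpec:
    """Build the square analysis grid covering the records' bounding box.

    The default origin is the floor of the minimum coordinates to a multiple
    of ``side_l``, so grids built from different record subsets of the same
    survey align.
    """
    if side_l <= 0:
        raise ParameterError(f"side_l must be positive, got {side_l}")
    if not records:
        raise ParameterError("at least one record is required to build a grid")
    xs = np.array([r.x for r in records])
    ys = np.array([r.y for r in records])
    if origin is None:
        ox = math.floor(xs.min() / side_l) * side_l
        oy = math.floor(ys.min() / side_l) * side_l
    else:
        ox, oy = float(origin[0]), float(origin[1])
    n_cols = math.floor((xs.max() - ox) / side_l) + 1
    n_rows = math.floor((ys.max() - oy) / side_l) + 1
    return GridSpec(origin_x=ox, origin_y=oy, side_l=side_l, n_rows=n_rows, n_cols=n_cols)


def rasterize_to_bipartite(
    records: Sequence[OccurrenceRecord],
    grid: GridSpec,
    min_cells_per_species: int = 1,
    min_species_per_cell: int = 1,
) -> BipartiteIncidence:
    """Collapse records into the binary cell × species incidence.

    Duplicate records in a cell collapse to a single presence.  Cells without
    species and species without cells are dropped.  A record falling outside
    the grid extent is an error — the grid must cover all records.  The
    optional minimum-count filters (off by default) are applied jointly until
    stable.
    """
    pairs: set[tuple[int, str]] = set()
    for rec in records:
        row, col = grid.cell_of(rec.x, rec.y)
        if not grid.contains(row, col):
            raise ValueError(
                f"record at ({rec.x}, {rec.y}) falls outside the grid extent"
            )
        pairs.add((grid.cell_id(row, col), rec.species))
    if not pairs:
        raise ValueError("no records to rasterize")

    cell_ids = np.array(sorted({c for c, _ in pairs}), dtype=np.int64)
    species = sorted({s for _, s in pairs})
    cell_index = {c: i for i, c in enumerate(cell_ids)}
    sp_index = {s: j for j, s in enumerate(species)}
    rows = np.fromiter((cell_index[c] for c, s in pairs), dtype=np.int64, count=len(pairs))
    cols = np.fromiter((sp_index[s] for c, s in pairs), dtype=np.int64, count=len(pairs))
    presence = sparse.csr_matrix(
        (np.ones(len(pairs), dtype=np.int8), (rows, cols)),
        shape=(len(cell_ids), len(species)),
    )

    # optional prevalence filters, iterated to a joint fixed point
    while True:
        occ = np.asarray(presence.sum(axis=0)).ravel()
        rich = np.asarray(presence.sum(axis=1)).ravel()
        keep_sp = occ >= max(min_cells_per_species, 1)
        keep_cell = rich >= max(min_species_per_cell, 1)
        if keep_sp.all() and keep_cell.all():
            break
        presence = presence[keep_cell][:, keep_sp]
        cell_ids = cell_ids[keep_cell]
        species = [s for s, k in zip(species, keep_sp) if k]
    if presence.nnz == 0:
        raise ValueError("prevalence filters removed every cell and species")

    return BipartiteIncidence(
        presence=presence, cell_ids=cell_ids, species=list(species), grid=grid
    )


@dataclass
class DegreeDistributions:
    """Marginal degree sequences of the bipartite incidence."""

    species_per_cell: np.ndarray
    cells_per_species: np.ndarray

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in (
            ("species_per_cell", self.species_per_cell),
            ("cells_per_species", self.cells_per_species),
        ):
            q = np.quantile(arr, [0.25, 0.5, 0.75])
            rows.append(
                {
                    "distribution": name,
                    "mean": float(arr.mean()),
                    "min": int(arr.min()),
                    "q25": float(q[0]),
                    "median": float(q[1]),
                    "q75": float(q[2]),
                    "max": int(arr.max()),
                }
            )
        return pd.DataFrame(rows)


def degree_distributions(incidence: BipartiteIncidence) -> DegreeDistributions:
    """Both marginal degree sequences: richness per cell and range size per species."""
    if incidence.n == 0 or incidence.n_species == 0:
        raise ValueError("incidence is empty")
    return DegreeDistributions(
        species_per_cell=incidence.richness,
        cells_per_species=incidence.occupancy,
    )
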