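"""Stem census handling and quadrat-based community matrices.

A rectangular forest plot is tiled into square quadrats at one or more
spatial scales (quadrat side lengths).  Every stem is assigned to exactly
one quadrat via half-open intervals [i*scale, (i+1)*scale), so the tiling
is a partition of the plot.  Quadrat x species stem-count matrices are the
community objects every downstream analysis (functional dispersion, null
models, correlations) operates on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CENSUS_COLUMNS = ("stem_id", "x", "y", "species", "dbh")

#: census rule: only stems with DBH of at least this many cm are included
DEFAULT_DBH_MIN = 1.0


class CensusError(ValueError):
    """Raised for malformed or out-of-contract census input."""


@dataclass(frozen=True)
class QuadratGrid:
    """A regular tiling of the plot into square quadrats of side ``scale``.

    Quadrats are indexed in row-major order: ``index = row * n_x + col``
    where ``col`` counts along x and ``row`` along y.
    """

    scale: float
    n_x: int
    n_y: int

    @property
    def n_quadrats(self) -> int:
        return self.n_x * self.n_y

    @property
    def quadrat_area(self) -> float:
        """Quadrat area in m^2."""
        return self.scale * self.scale

    def index_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        col = np.floor(np.asarray(x) / self.scale).astype(int)
        row = np.floor(np.asarray(y) / self.scale).astype(int)
        if np.any((col < 0) | (col >= self.n_x) | (row < 0) | (row >= self.n_y)):
            raise CensusError("coordinates outside the plot")
        return row * self.n_x + col

    def centers(self) -> np.ndarray:
        """(n_quadrats, 2) array of quadrat-center coordinates in metres."""
        cols = np.arange(self.n_x)
        rows = np.arange(self.n_y)
        cx = (cols + 0.5) * self.scale
        cy = (rows + 0.5) * self.scale
        xx, yy = np.meshgrid(cx, cy)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def as_matrix(self, values: np.ndarray) -> np.ndarray:
        """Reshape a flat per-quadrat vector to an (n_y, n_x) map."""
        values = np.asarray(values)
        if values.shape[0] != self.n_quadrats:
            raise ValueError("value vector does not match grid size")
        return values.reshape(self.n_y, self.n_x)


@dataclass
class CensusTable:
    """Validated stem records inside a rectangular plot."""

    data: pd.DataFrame  # columns: stem_id, x, y, species, dbh
    plot_width: float
    plot_height: float
    dbh_min: float = DEFAULT_DBH_MIN
    n_excluded_dbh: int = 0
    n_excluded_untraited: int = 0

    def __post_init__(self) -> None:
        d = self.data
        missing = [c for c in CENSUS_COLUMNS if c not in d.columns]
        if missing:
            raise CensusError(f"census table missing columns: {missing}")
        x, y = d["x"].to_numpy(float), d["y"].to_numpy(float)
        if np.any((x < 0) | (x >= self.plot_width) | (y < 0) | (y >= self.plot_height)):
            bad = d.index[(x < 0) | (x >= self.plot_width) | (y < 0) | (y >= self.plot_height)][0]
            raise CensusError(
                f"stem {d.loc[bad, 'stem_id']} lies outside the half-open plot "
                f"[0, {self.plot_width}) x [0, {self.plot_height})"
            )
        if np.any(d["dbh"].to_numpy(float) < self.dbh_min):
            raise CensusError("census contains stems below the DBH threshold")

    @property
    def n_stems(self) -> int:
        return len(self.data)

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    def restrict_to_species(self, keep: list[str]) -> "CensusTable":
        """Drop stems of species not in ``keep`` (e.g. untraited species).

        The dropped-stem count is recorded on the returned table.
        """
        mask = self.data["species"].isin(set(keep))
        out = CensusTable(
            self.data.loc[mask].reset_index(drop=True),
            self.plot_width,
            self.plot_height,
            dbh_min=self.dbh_min,
            n_excluded_dbh=self.n_excluded_dbh,
            n_excluded_untraited=int((~mask).sum()),
        )
        return out


@dataclass
class QuadratCommunity:
    """Quadrat x species stem-count matrix on one grid."""

    grid: QuadratGrid
    species: list[str]
    abundance: np.ndarray  # (n_quadrats, n_species) int

    def __post_init__(self) -> None:
        if self.abundance.shape != (self.grid.n_quadrats, len(self.species)):
            raise ValueError("abundance matrix shape does not match grid/species")
        if np.any(self.abundance < 0):
            raise ValueError("negative abundance")

    @property
    def quadrat_counts(self) -> np.ndarray:
        return self.abundance.sum(axis=1)

    @property
    def quadrat_richness(self) -> np.ndarray:
        return (self.abundance > 0).sum(axis=1)

    @property
    def total_stems(self) -> int:
        return int(self.abundance.sum())


def read_census(
    path,
    plot_dims: tuple[float, float],
    dbh_min: float = DEFAULT_DBH_MIN,
) -> CensusTable:
    """Read and validate a stem census CSV.

    Parameters
    ----------
    path : str or file-like
        CSV with header ``stem_id,x,y,species,dbh``.
    plot_dims : (width, height) in metres
    dbh_min : minimum diameter at breast height (cm); smaller stems are
        excluded and counted in ``n_excluded_dbh``.
    """
    width, height = plot_dims
    df = pd.read_csv(path, dtype={"species": str})
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise CensusError(f"census CSV missing columns: {missing}")
    for col in ("x", "y", "dbh"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            # +2: header line plus 1-based numbering
            line = int(vals.index[vals.isna()][0]) + 2
            raise CensusError(f"malformed numeric value in column '{col}' at line {line}")
        df[col] = vals
    keep = df["dbh"] >= dbh_min
    n_excluded = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)
    return CensusTable(df, width, height, dbh_min=dbh_min, n_excluded_dbh=n_excluded)


def make_grid(census: CensusTable, scale: float) -> QuadratCommunity:
    """Tile the plot at one scale and count stems per quadrat per species.

    ``scale`` must divide both plot dimensions exactly (no partial
    quadrats).  Stems are assigned by the half-open convention.
    """
    n_x = census.plot_width / scale
    n_y = census.plot_height / scale
    if abs(n_x - round(n_x)) > 1e-9 or abs(n_y - round(n_y)) > 1e-9:
        raise CensusError(
            f"scale {scale} m does not divide plot "
            f"{census.plot_width} x {census.plot_height} m exactly"
        )
    grid = QuadratGrid(scale=float(scale), n_x=int(round(n_x)), n_y=int(round(n_y)))
    species = census.species
    sp_index = {s: j for j, s in enumerate(species)}
    q = grid.index_of(census.data["x"].to_numpy(), census.data["y"].to_numpy())
    s = census.data["species"].map(sp_index).to_numpy()
    abundance = np.zeros((grid.n_quadrats, len(species)), dtype=int)
    np.add.at(abundance, (q, s), 1)
    return QuadratCommunity(grid=grid, species=species, abundance=abundance)


def community_summary(comm: QuadratCommunity) -> pd.DataFrame:
    """Per-quadrat abundance and richness summary: mean, SE, min, max.

    SE is the sample SD over quadrats divided by sqrt(number of quadrats).
    """
    if comm.grid.n_quadrats == 0:
        raise ValueError("empty community")
    rows = {}
    for name, vals in (
        ("abundance", comm.quadrat_counts),
        ("richness", comm.quadrat_richness),
    ):
        n = len(vals)
        sd = vals.std(ddof=1) if n > 1 else 0.0
        rows[name] = {
            "mean": float(vals.mean()),
            "se": float(sd / np.sqrt(n)),
            "min": int(vals.min()),
            "max": int(vals.max()),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "quantity"
    return out
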