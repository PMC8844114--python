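"""Trait space construction and abundance-weighted functional dispersion.

Species-level traits are standardized (zero mean, unit sample SD), turned
into a species-species Euclidean distance matrix, and embedded by principal
coordinates analysis (PCoA).  If the distance matrix is not Euclidean the
negative eigenvalues are removed by a constant-shift correction (Cailliez
by default, Lingoes as an option) before re-embedding.  Functional
dispersion (FDis) of a community is the abundance-weighted mean distance of
its species to their abundance-weighted centroid in that space:

    c = sum_j a_j x_j / sum_j a_j
    FDis = sum_j a_j ||x_j - c|| / sum_j a_j

which makes FDis depend only on relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .grid import QuadratCommunity, QuadratGrid

#: eigenvalues below this fraction of the leading eigenvalue are treated as
#: numerical noise and their axes discarded
EIGEN_FLOOR = 1e-10


@dataclass
class TraitMatrix:
    """Species x trait table of continuous trait values."""

    data: pd.DataFrame  # index: species codes; columns: trait names
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing trait values in columns {bad}")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)


@dataclass
class TraitSpace:
    """Species coordinates from a (corrected) PCoA embedding."""

    species: list[str]
    coordinates: np.ndarray  # (n_species, n_axes), axes by decreasing eigenvalue
    eigenvalues: np.ndarray
    correction: str = "none"
    correction_constant: float = 0.0

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class DispersionMap:
    """Per-quadrat FDis (and, once filled, ZFDis) for one trait set."""

    grid: QuadratGrid
    trait_set: str
    fdis: np.ndarray  # (n_quadrats,), NaN where quadrat is empty
    zfdis: np.ndarray | None = None  # filled by the null model stage

    @property
    def valid(self) -> np.ndarray:
        """Quadrats with a defined ZFDis (or FDis if ZFDis not yet filled)."""
        if self.zfdis is not None:
            return np.isfinite(self.zfdis)
        return np.isfinite(self.fdis)


def read_traits(path) -> TraitMatrix:
    """Read a species x trait CSV (first column: species code)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return TraitMatrix(df)


def standardize(traits: TraitMatrix) -> TraitMatrix:
    """Center each trait on zero and rescale to unit sample SD.

    Removes the effect of trait magnitudes on distance computations.
    Raises if any trait column is constant.
    """
    vals = traits.values
    sd = vals.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant trait column: {traits.traits[constant[0]]}")
    out = (vals - vals.mean(axis=0)) / sd
    return TraitMatrix(
        pd.DataFrame(out, index=traits.data.index, columns=traits.data.columns),
        standardized=True,
    )


def trait_distance(traits: TraitMatrix) -> np.ndarray:
    """Species-species Euclidean distance matrix from standardized traits."""
    if not traits.standardized:
        raise ValueError("trait_distance expects standardized traits")
    return squareform(pdist(traits.values, metric="euclidean"))


def _gower_center(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest additive constant c such that d + c (off-diagonal) is Euclidean.

    Computed as the largest real eigenvalue of the standard 2n x 2n companion
    matrix built from the Gower-centered forms of -d^2/2 and -d/2.
    """
    n = d.shape[0]
    delta1 = _gower_center(-0.5 * d**2)
    delta2 = _gower_center(-0.5 * d)
    top = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    bottom = np.hstack([-np.eye(n), -4.0 * delta2])
    ev = np.linalg.eigvals(np.vstack([top, bottom]))
    return float(np.max(ev.real))


def pcoa_embed(dist: np.ndarray, correction: str = "cailliez") -> TraitSpace:
    """Embed a distance matrix by PCoA, correcting negative eigenvalues.

    For a genuinely Euclidean input the raw embedding reproduces the input
    distances and no correction is applied.  Otherwise the distances are
    made Euclidean by a constant shift: Cailliez adds c to every off-diagonal
    distance; Lingoes adds c to every squared off-diagonal distance.  The
    applied constant is recorded on the result.

    Axes with eigenvalue below ``EIGEN_FLOOR`` times the leading eigenvalue
    are dropped as numerical noise.
    """
    dist = np.asarray(dist, float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if correction not in ("cailliez", "lingoes", "none"):
        raise ValueError(f"unknown correction {correction!r}")

    def _decompose(d: np.ndarray):
        b = _gower_center(-0.5 * d**2)
        evals, evecs = np.linalg.eigh(b)
        order = np.argsort(evals)[::-1]
        return evals[order], evecs[:, order]

    evals, evecs = _decompose(dist)
    tol = EIGEN_FLOOR * max(evals.max(), 1.0)
    applied = "none"
    constant = 0.0
    if evals.min() < -tol and correction != "none":
        off = ~np.eye(dist.shape[0], dtype=bool)
        d2 = dist.copy()
        if correction == "cailliez":
            constant = _cailliez_constant(dist)
            d2[off] = dist[off] + constant
        else:  # lingoes: shift squared distances by twice |smallest eigenvalue|
            constant = float(-evals.min())
            d2[off] = np.sqrt(dist[off] ** 2 + 2.0 * constant)
        applied = correction
        evals, evecs = _decompose(d2)

    keep = evals > EIGEN_FLOOR * max(evals.max(), 1.0)
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    return TraitSpace(
        species=list(range(dist.shape[0])),
        coordinates=coords,
        eigenvalues=evals[keep],
        correction=applied,
        correction_constant=constant,
    )


def trait_space_from_traits(traits: TraitMatrix, correction: str = "cailliez") -> TraitSpace:
    """Standardize -> Euclidean distances -> corrected PCoA, keeping species codes."""
    st = traits if traits.standardized else standardize(traits)
    space = pcoa_embed(trait_distance(st), correction=correction)
    space.species = st.species
    return space


def single_trait_space(traits: TraitMatrix, trait: str) -> TraitSpace:
    """A 1-D trait space holding one standardized trait."""
    st = traits if traits.standardized else standardize(traits)
    col = st.data[trait].to_numpy(float)[:, None]
    return TraitSpace(
        species=st.species,
        coordinates=col,
        eigenvalues=np.array([float(col.var(ddof=1))]),
        correction="none",
    )


def fdis(coordinates: np.ndarray, abundance: np.ndarray) -> float:
    """Abundance-weighted functional dispersion of one community.

    Parameters
    ----------
    coordinates : (n_species, n_axes) trait-space positions
    abundance : (n_species,) non-negative weights (stem counts)

    Returns NaN for an empty community (zero total abundance); a
    single-species community has dispersion 0 by definition.
    """
    a = np.asarray(abundance, float)
    x = np.atleast_2d(np.asarray(coordinates, float))
    if x.shape[0] != a.shape[0]:
        raise ValueError("coordinates and abundance lengths differ")
    total = a.sum()
    if total <= 0:
        return float("nan")
    centroid = a @ x / total
    dist = np.linalg.norm(x - centroid, axis=1)
    return float(a @ dist / total)


def fdis_map(abundance: np.ndarray, coordinates: np.ndarray) -> np.ndarray:
    """Vectorized FDis for every row of a quadrat x species abundance matrix."""
    a = np.asarray(abundance, float)
    x = np.asarray(coordinates, float)
    totals = a.sum(axis=1)
    safe = np.where(totals > 0, totals, 1.0)
    centroids = (a @ x) / safe[:, None]  # (Q, k)
    # (Q, S) distances of each species to each quadrat centroid
    diff = x[None, :, :] - centroids[:, None, :]
    dists = np.sqrt(np.einsum("qsk,qsk->qs", diff, diff))
    out = np.einsum("qs,qs->q", a, dists) / safe
    out[totals == 0] = np.nan
    return out


def dispersion_map(
    comm: QuadratCommunity, space: TraitSpace, trait_set: str = "multivariate"
) -> DispersionMap:
    """Per-quadrat FDis of a community in a trait space.

    Community species must be a subset of the trait-space species.  Empty
    quadrats get NaN; single-species quadrats get 0.
    """
    pos = {s: i for i, s in enumerate(space.species)}
    missing = [s for s in comm.species if s not in pos]
    if missing:
        raise ValueError(f"species missing from trait space: {missing[:5]}")
    idx = np.array([pos[s] for s in comm.species])
    coords = space.coordinates[idx]
    return DispersionMap(
        grid=comm.grid, trait_set=trait_set, fdis=fdis_map(comm.abundance, coords)
    )
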