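"""Taxa-label-shuffle null model and the standardized effect size ZFDis.

The null model keeps every quadrat's abundance vector and every species'
plot-level total abundance and occurrence frequency fixed, and only permutes
which species carries which trait values ("shuffling taxon names").  One
label permutation is drawn per randomization and applied plot-wide, to every
quadrat at every scale, which is what keeps the plot-level quantities exact.

ZFDis = (FDis_observed - mean(FDis_null)) / SD(FDis_null), with the sample
SD (n-1) of the null draws.  Positive values indicate trait overdispersion,
negative values trait clustering relative to random assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import QuadratCommunity
from .traits import DispersionMap, TraitSpace, fdis_map

DEFAULT_N_RANDOMIZATIONS = 999


@dataclass
class NullEnsemble:
    """Null FDis values per quadrat from label-shuffle randomizations."""

    n_randomizations: int
    null_fdis: np.ndarray  # (n_randomizations, n_quadrats)
    seed: int | None = None

    @property
    def mean(self) -> np.ndarray:
        return self.null_fdis.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.null_fdis.std(axis=0, ddof=1)


def draw_permutations(
    n_species: int, n_randomizations: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_randomizations, n_species) array of uniform label permutations."""
    return np.array(
        [rng.permutation(n_species) for _ in range(n_randomizations)], dtype=int
    )


def shuffle_labels(space: TraitSpace, permutation: np.ndarray) -> TraitSpace:
    """Reassign trait coordinates to species by a label permutation.

    Species ``s`` receives the coordinates of species ``permutation[s]``;
    the multiset of coordinates is unchanged.
    """
    perm = np.asarray(permutation)
    return TraitSpace(
        species=space.species,
        coordinates=space.coordinates[perm],
        eigenvalues=space.eigenvalues,
        correction=space.correction,
        correction_constant=space.correction_constant,
    )


def null_ensemble(
    comm: QuadratCommunity,
    space: TraitSpace,
    permutations: np.ndarray,
    seed: int | None = None,
) -> NullEnsemble:
    """FDis of every quadrat under each label-shuffle randomization.

    ``permutations`` should be shared across scales and trait sets within a
    run so that each randomization is one plot-wide taxa shuffle.
    """
    if permutations.shape[1] != len(space.species):
        raise ValueError("permutations must cover every trait-space species")
    pos = {s: i for i, s in enumerate(space.species)}
    idx = np.array([pos[s] for s in comm.species])
    n_rand = permutations.shape[0]
    out = np.empty((n_rand, comm.grid.n_quadrats))
    for r in range(n_rand):
        # species s takes the coordinates of species permutations[r][s]
        out[r] = fdis_map(comm.abundance, space.coordinates[permutations[r][idx]])
    return NullEnsemble(n_randomizations=n_rand, null_fdis=out, seed=seed)


def zfdis(obs: DispersionMap, ensemble: NullEnsemble) -> DispersionMap:
    """Fill the standardized effect size of FDis per quadrat.

    Quadrats whose null SD is zero (e.g. empty or monospecific quadrats,
    where every shuffle gives the same FDis) get a missing ZFDis.
    """
    if ensemble.null_fdis.shape[1] != obs.grid.n_quadrats:
        raise ValueError("ensemble grid size does not match observed map")
    mu = ensemble.mean
    sd = ensemble.sd
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs.fdis - mu) / sd
    z[~np.isfinite(z)] = np.nan
    z[sd == 0] = np.nan
    return DispersionMap(grid=obs.grid, trait_set=obs.trait_set, fdis=obs.fdis, zfdis=z)


def interquartile_table(maps: dict[tuple[float, str], DispersionMap]) -> pd.DataFrame:
    """IQR (Q3 - Q1, linear-interpolation quantiles) of ZFDis per scale and trait set.

    ``maps`` is keyed by (scale, trait_set).  Missing quadrats are ignored.
    """
    rows = []
    for (scale, trait_set), dmap in sorted(maps.items()):
        if dmap.zfdis is None:
            raise ValueError("interquartile_table requires zfdis-filled maps")
        vals = dmap.zfdis[np.isfinite(dmap.zfdis)]
        q1, q3 = np.percentile(vals, [25, 75]) if vals.size else (np.nan, np.nan)
        rows.append(
            {
                "scale": scale,
                "trait_set": trait_set,
                "iqr": float(q3 - q1),
                "n_quadrats": int(vals.size),
                "quantile_rule": "linear",
            }
        )
    return pd.DataFrame(rows)
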