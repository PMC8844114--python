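"""End-to-end pipeline: census -> dispersion maps -> gradients -> tests.

This is the orchestration layer the analysis drivers, the test suite and
the acceptance script all call.  Given a census, a trait table and soil
samples it (1) grids the plot at each scale, (2) builds the corrected-PCoA
trait space and per-quadrat FDis/ZFDis maps with a plot-wide taxa-shuffle
null, (3) kriges the soil variables and extracts PCA gradient axes per
scale, and (4) runs torus-translation tests of the dispersion-environment
correlations and the correlation-versus-area trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import CensusTable, QuadratCommunity, make_grid
from .gradients import PcaResult, axis_fields, retain_axes, soil_pca
from .nulls import draw_permutations, null_ensemble, zfdis
from .soil import GridField, SoilSamples, krige_all
from .spatial import ScaleTrend, TorusTestResult, pearson_r, scale_trend, torus_test, test_table
from .traits import (
    DispersionMap,
    TraitMatrix,
    dispersion_map,
    single_trait_space,
    standardize,
    trait_space_from_traits,
)

DEFAULT_SCALES = (5.0, 10.0, 20.0, 50.0)
DEFAULT_ENV_VARS = ("AP", "AK", "AN", "PC1", "PC2")


@dataclass
class PipelineResult:
    communities: dict[float, QuadratCommunity]
    fields: dict[tuple[str, float], GridField]
    pca: dict[float, PcaResult]
    dispersion: dict[tuple[float, str], DispersionMap]  # zfdis filled
    tests: dict[tuple[float, str, str], TorusTestResult]
    trends: dict[tuple[str, str], ScaleTrend]
    n_dropped_untraited: int = 0

    @property
    def results_table(self) -> pd.DataFrame:
        return test_table(self.tests)


def run_pipeline(
    census: CensusTable,
    traits: TraitMatrix,
    soil_samples: SoilSamples,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    trait_sets: tuple[str, ...] = ("multivariate",),
    env_vars: tuple[str, ...] = DEFAULT_ENV_VARS,
    n_randomizations: int = 999,
    seed: int = 0,
    torus_scales: tuple[float, ...] | None = None,
    variogram_model: str = "spherical",
    alpha: float = 0.05,
    horn_iter: int = 200,
) -> PipelineResult:
    """Run the full multi-scale analysis.

    ``trait_sets`` may contain "multivariate" and/or individual trait names.
    Torus tests are run at ``torus_scales`` (default: all scales); plain
    Pearson r feeds the scale trend at every scale regardless.
    """
    rng = np.random.default_rng(seed)
    if torus_scales is None:
        torus_scales = scales

    # stems of species without trait data are dropped (with a logged count)
    census = census.restrict_to_species(traits.species)
    communities = {s: make_grid(census, s) for s in scales}

    st = standardize(traits)
    spaces = {}
    for ts in trait_sets:
        if ts == "multivariate":
            spaces[ts] = trait_space_from_traits(st)
        else:
            spaces[ts] = single_trait_space(st, ts)

    # one permutation per randomization, shared across scales and trait sets
    perms = draw_permutations(len(st.species), n_randomizations, rng)
    dispersion: dict[tuple[float, str], DispersionMap] = {}
    for s, comm in communities.items():
        for ts, space in spaces.items():
            obs = dispersion_map(comm, space, trait_set=ts)
            ens = null_ensemble(comm, space, perms, seed=seed)
            dispersion[(s, ts)] = zfdis(obs, ens)

    grids = {s: communities[s].grid for s in scales}
    fields, _variograms = krige_all(soil_samples, grids, model=variogram_model)
    pca: dict[float, PcaResult] = {}
    for s in scales:
        per_scale = {v: f for (v, sc), f in fields.items() if sc == s}
        data = np.column_stack([per_scale[v].values for v in per_scale])
        res = soil_pca(per_scale)
        retain_axes(res, data, n_iter=horn_iter, rng=rng)
        pca[s] = res
        for name, fld in axis_fields(res, grids[s]).items():
            fields[(name, s)] = fld

    tests: dict[tuple[float, str, str], TorusTestResult] = {}
    r_by: dict[tuple[str, str], dict[float, float]] = {}
    for ts in trait_sets:
        for env in env_vars:
            rs: dict[float, float] = {}
            for s in scales:
                dmap = dispersion[(s, ts)]
                fld = fields[(env, s)]
                if s in torus_scales:
                    res = torus_test(dmap, fld, alpha=alpha)
                    tests[(s, env, ts)] = res
                    rs[s] = res.observed_r
                else:
                    rs[s] = pearson_r(dmap.zfdis, fld.values)
            r_by[(env, ts)] = rs

    trends = {
        key: scale_trend(rs)
        for key, rs in r_by.items()
        if sum(np.isfinite(list(rs.values()))) >= 3
    }
    return PipelineResult(
        communities=communities,
        fields=fields,
        pca=pca,
        dispersion=dispersion,
        tests=tests,
        trends=trends,
        n_dropped_untraited=census.n_excluded_untraited,
    )
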