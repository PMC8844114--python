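"""Dispersion-environment correlations with torus-translation significance.

Both the ZFDis maps and the environmental fields are spatially
autocorrelated, so naive parametric tests of their Pearson correlation are
anticonservative.  The torus-translation test builds the null distribution
by cyclically shifting the environmental map across the quadrat grid with
wraparound in the four cardinal directions, for the original map and its
three symmetry variants (mirror image, 180-degree rotation, rotated
mirror): 4 * n_x * n_y translated maps in total, including the identity
translation, each preserving the map's internal spatial structure.  The
observed r is significant-positive (negative) at level alpha if it is
higher (lower) than a fraction 1 - alpha of the translated-map r values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .soil import GridField
from .traits import DispersionMap

MIN_PAIRS = 3


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with pairwise deletion of non-finite entries.

    Returns NaN when fewer than MIN_PAIRS valid pairs remain or either
    series has zero variance.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < MIN_PAIRS:
        return float("nan")
    aa, bb = a[ok], b[ok]
    if aa.std() == 0 or bb.std() == 0:
        return float("nan")
    return float(np.corrcoef(aa, bb)[0, 1])


def _variants(values2d: np.ndarray) -> list[np.ndarray]:
    """The four orientation variants: original, mirror, 180 rotation, both."""
    return [
        values2d,
        np.fliplr(values2d),
        np.flip(values2d),  # 180-degree rotation
        np.flipud(values2d),  # 180 rotation of the mirror image
    ]


def n_torus_maps(grid) -> int:
    """Total number of torus-translated maps: 4 variants x all cyclic shifts."""
    return 4 * grid.n_x * grid.n_y


def torus_maps(field: GridField) -> Iterator[np.ndarray]:
    """Yield every torus-translated map as a flat per-quadrat vector.

    Order: identity translation of the original orientation first, then the
    remaining shifts, then the three symmetry variants.  Every map is a
    permutation of the original quadrat values.
    """
    v2d = field.grid.as_matrix(field.values)
    for var in _variants(v2d):
        for dy in range(field.grid.n_y):
            for dx in range(field.grid.n_x):
                yield np.roll(var, (dy, dx), axis=(0, 1)).ravel()


def _all_maps_matrix(field: GridField) -> np.ndarray:
    """(4*N, N) matrix of all translated maps, built without python loops
    over quadrats (index arithmetic on the torus)."""
    g = field.grid
    ny, nx = g.n_y, g.n_x
    rows = (np.arange(ny)[None, :] - np.arange(ny)[:, None]) % ny  # dy x iy
    cols = (np.arange(nx)[None, :] - np.arange(nx)[:, None]) % nx  # dx x ix
    blocks = []
    for var in _variants(g.as_matrix(field.values)):
        # shifted[dy, dx, iy, ix] = var[(iy-dy)%ny, (ix-dx)%nx], matching np.roll
        shifted = var[rows[:, None, :, None], cols[None, :, None, :]]
        blocks.append(shifted.reshape(ny * nx, ny * nx))
    return np.vstack(blocks)


@dataclass
class TorusTestResult:
    """Observed correlation and its torus-translation null distribution."""

    observed_r: float
    null_r: np.ndarray
    n_maps: int
    p_low: float
    p_high: float
    verdict: str  # significant-negative | significant-positive | nonsignificant
    alpha: float = 0.05
    rule: str = "two one-sided 5% tails (torus translation, identity included)"


def torus_test(
    zfdis_map: DispersionMap, env: GridField, alpha: float = 0.05
) -> TorusTestResult:
    """Torus-translation test of the dispersion-environment correlation.

    The dispersion map stays fixed (quadrats with missing ZFDis dropped
    pairwise); the environmental map is translated.  The null set includes
    the identity translation, so p >= 1/n_maps and the test is exact.
    """
    if zfdis_map.grid != env.grid:
        raise ValueError("dispersion map and field must share one grid")
    z = zfdis_map.zfdis if zfdis_map.zfdis is not None else zfdis_map.fdis
    ok = np.isfinite(z)
    maps = _all_maps_matrix(env)
    n_maps = maps.shape[0]
    zz = z[ok]
    if zz.size < MIN_PAIRS or zz.std() == 0:
        return TorusTestResult(float("nan"), np.full(n_maps, np.nan), n_maps,
                               float("nan"), float("nan"), "missing", alpha)
    mm = maps[:, ok]
    # vectorized Pearson r of zz against every row of mm
    zc = zz - zz.mean()
    mc = mm - mm.mean(axis=1, keepdims=True)
    denom = np.sqrt((zc @ zc) * np.einsum("ij,ij->i", mc, mc))
    with np.errstate(invalid="ignore", divide="ignore"):
        null_r = (mc @ zc) / denom
    observed = float(null_r[0])  # identity translation is the first map
    finite = null_r[np.isfinite(null_r)]
    p_low = float(np.mean(finite <= observed))
    p_high = float(np.mean(finite >= observed))
    if p_high <= alpha:
        verdict = "significant-positive"
    elif p_low <= alpha:
        verdict = "significant-negative"
    else:
        verdict = "nonsignificant"
    return TorusTestResult(observed, null_r, n_maps, p_low, p_high, verdict, alpha)


@dataclass
class ScaleTrend:
    """Linear trend of the dispersion-environment correlation with quadrat area."""

    scales: np.ndarray  # quadrat side lengths (m)
    r_values: np.ndarray
    slope: float
    intercept: float
    conf_int: tuple[float, float]  # 95% CI of the slope

    @property
    def areas(self) -> np.ndarray:
        return self.scales**2


def scale_trend(r_by_scale: dict[float, float]) -> ScaleTrend:
    """OLS regression of observed r on quadrat area (m^2) across scales."""
    if len(r_by_scale) < 3:
        raise ValueError("need at least three scales for a trend")
    scales = np.array(sorted(r_by_scale))
    rs = np.array([r_by_scale[s] for s in scales])
    areas = scales**2
    model = sm.OLS(rs, sm.add_constant(areas)).fit()
    ci = model.conf_int(alpha=0.05)
    return ScaleTrend(
        scales=scales,
        r_values=rs,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        conf_int=(float(ci[1][0]), float(ci[1][1])),
    )


def test_table(
    results: dict[tuple[float, str, str], TorusTestResult]
) -> pd.DataFrame:
    """Flat results table keyed by (scale, environment variable, trait set)."""
    rows = []
    for (scale, env, trait_set), res in sorted(results.items()):
        rows.append(
            {
                "scale": scale,
                "environment": env,
                "trait_set": trait_set,
                "observed_r": res.observed_r,
                "p_low": res.p_low,
                "p_high": res.p_high,
                "verdict": res.verdict,
                "n_maps": res.n_maps,
            }
        )
    return pd.DataFrame(rows)
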