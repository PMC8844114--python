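"""Soil sampling design, semivariogram fitting and ordinary kriging.

The sampling design mirrors the standard forest-dynamics-plot protocol:
topsoil samples on a regular 30 m grid, each grid node paired with two
extra points at 2, 5 or 15 m in a random compass direction, which gives the
short lag distances a variogram needs.  Point values are interpolated to
quadrat centers by ordinary kriging with a global neighborhood: weights
come from a weighted-least-squares fit of a parametric semivariogram
(spherical by default) to the binned empirical semivariogram, and sum to
one at every prediction point, making the predictor exact at sample
locations when the nugget is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .grid import QuadratGrid

SOIL_VARIABLES = ("pH", "SM", "OM", "AN", "AP", "AK", "TN", "TP", "TK")

DEFAULT_GRID_SPACING = 30.0
DEFAULT_OFFSETS = (2.0, 5.0, 15.0)

#: duplicate sample coordinates are displaced by this much to keep the
#: kriging system nonsingular
JITTER = 1e-6


@dataclass
class SoilSamples:
    """Point soil samples: coordinates plus one column per variable."""

    data: pd.DataFrame  # columns: x, y, then variables
    plot_width: float
    plot_height: float

    def __post_init__(self) -> None:
        d = self.data
        if "x" not in d.columns or "y" not in d.columns:
            raise ValueError("soil samples need x and y columns")
        x, y = d["x"].to_numpy(float), d["y"].to_numpy(float)
        if np.any((x < 0) | (x > self.plot_width) | (y < 0) | (y > self.plot_height)):
            raise ValueError("soil sample outside the plot")
        if not np.isfinite(d.drop(columns=["x", "y"]).to_numpy(float)).all():
            raise ValueError("non-finite soil value")

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("x", "y")]

    @property
    def coords(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(float)


@dataclass
class GridField:
    """One environmental value per quadrat (kriged soil variable or PCA axis)."""

    grid: QuadratGrid
    variable: str
    values: np.ndarray  # (n_quadrats,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (self.grid.n_quadrats,):
            raise ValueError("field length does not match grid")


@dataclass
class VariogramModel:
    """Fitted parametric semivariogram gamma(h) = nugget + psill * f(h/range)."""

    model: str  # spherical | exponential | gaussian
    nugget: float
    psill: float  # partial sill; total sill = nugget + psill
    range_: float
    rmse: float = float("nan")
    n_pairs: int = 0

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, float)
        r = max(self.range_, 1e-12)
        if self.model == "spherical":
            u = np.minimum(h / r, 1.0)
            struct = 1.5 * u - 0.5 * u**3
        elif self.model == "exponential":
            struct = 1.0 - np.exp(-3.0 * h / r)  # effective range convention
        elif self.model == "gaussian":
            struct = 1.0 - np.exp(-3.0 * (h / r) ** 2)
        else:
            raise ValueError(f"unknown variogram model {self.model!r}")
        gamma = self.nugget + self.psill * struct
        # gamma(0) = 0 by definition; the nugget is the limit from above
        return np.where(h == 0, 0.0, gamma)


def design_soil_grid(
    plot_dims: tuple[float, float],
    grid_spacing: float = DEFAULT_GRID_SPACING,
    offsets: tuple[float, ...] = DEFAULT_OFFSETS,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Plan sample locations: regular grid nodes plus two paired offset points.

    Grid nodes sit at multiples of ``grid_spacing`` within the half-open
    plot.  Each node gets two companions at a distance drawn from
    ``offsets`` in a uniform random compass direction, clipped to the plot
    boundary.  Returns a frame with columns x, y, kind (grid/offset) and
    parent (node index).
    """
    if rng is None:
        rng = np.random.default_rng()
    width, height = plot_dims
    if grid_spacing >= min(width, height):
        raise ValueError("grid spacing must be smaller than the plot")
    gx = np.arange(0.0, width, grid_spacing)
    gy = np.arange(0.0, height, grid_spacing)
    rows = []
    node = 0
    for y in gy:
        for x in gx:
            rows.append({"x": x, "y": y, "kind": "grid", "parent": node})
            for _ in range(2):
                d = rng.choice(offsets)
                theta = rng.uniform(0.0, 2.0 * np.pi)
                px = np.clip(x + d * np.cos(theta), 0.0, width)
                py = np.clip(y + d * np.sin(theta), 0.0, height)
                rows.append({"x": px, "y": py, "kind": "offset", "parent": node})
            node += 1
    return pd.DataFrame(rows)


def empirical_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    n_lags: int = 15,
    max_dist: float | None = None,
) -> pd.DataFrame:
    """Binned empirical semivariogram: mean 0.5*(v_i - v_j)^2 per lag bin."""
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    d = cdist(coords, coords)
    iu = np.triu_indices_from(d, k=1)
    h = d[iu]
    g = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    if max_dist is None:
        max_dist = h.max() / 2.0
    keep = h <= max_dist
    h, g = h[keep], g[keep]
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    which = np.clip(np.digitize(h, edges) - 1, 0, n_lags - 1)
    rows = []
    for b in range(n_lags):
        m = which == b
        if m.sum() == 0:
            continue
        rows.append(
            {"lag": float(h[m].mean()), "gamma": float(g[m].mean()), "n_pairs": int(m.sum())}
        )
    return pd.DataFrame(rows)


def fit_variogram(
    samples: SoilSamples,
    variable: str,
    model: str = "spherical",
    n_lags: int = 15,
    max_dist: float | None = None,
) -> VariogramModel:
    """Weighted-least-squares fit of a parametric semivariogram.

    Bins are weighted by pair count over squared model value (Cressie
    weights), which emphasizes the short lags that dominate kriging weights.
    """
    values = samples.data[variable].to_numpy(float)
    if len(values) < 30:
        raise ValueError("need at least 30 samples to fit a variogram")
    var = values.var(ddof=1)
    if var == 0:
        raise ValueError(f"variable {variable!r} has zero variance")
    emp = empirical_variogram(samples.coords, values, n_lags=n_lags, max_dist=max_dist)
    lags = emp["lag"].to_numpy()
    gammas = emp["gamma"].to_numpy()
    npairs = emp["n_pairs"].to_numpy(float)

    def residuals(params):
        nugget, psill, rng_ = params
        vm = VariogramModel(model, nugget, psill, rng_)
        pred = vm(lags)
        w = np.sqrt(npairs) / np.maximum(pred, 1e-12)
        return w * (pred - gammas)

    x0 = np.array([0.1 * var, 0.9 * var, lags.max() / 2.0])
    bounds = ([0.0, 1e-12, lags.min() / 2.0], [2.0 * var, 5.0 * var, 4.0 * lags.max()])
    sol = least_squares(residuals, x0, bounds=bounds)
    nugget, psill, rng_ = sol.x
    fitted = VariogramModel(model, float(nugget), float(psill), float(rng_))
    fitted.rmse = float(np.sqrt(np.mean((fitted(lags) - gammas) ** 2)))
    fitted.n_pairs = int(npairs.sum())
    return fitted


def _dedup_jitter(coords: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
    """Displace exact-duplicate coordinates by JITTER metres."""
    out = coords.copy()
    seen: dict[tuple[float, float], int] = {}
    for i, (x, y) in enumerate(out):
        key = (float(x), float(y))
        if key in seen:
            out[i, 0] += JITTER * (seen[key])
            out[i, 1] += JITTER * (seen[key])
            seen[key] += 1
        else:
            seen[key] = 1
    return out


def krige(
    samples: SoilSamples,
    variable: str,
    grid: QuadratGrid,
    variogram: VariogramModel,
) -> GridField:
    """Ordinary kriging of one soil variable to quadrat centers.

    Solves the standard OK system [[Gamma, 1], [1', 0]] w = [gamma0; 1] with
    a global neighborhood (one LU factorization, all prediction points as a
    single right-hand-side block).  Weights sum to one per point, so a
    constant sample field is reproduced exactly, and with a zero nugget the
    prediction at a sample location equals the sample value.
    """
    coords = _dedup_jitter(samples.coords)
    values = samples.data[variable].to_numpy(float)
    n = len(values)
    gamma = variogram(cdist(coords, coords))
    np.fill_diagonal(gamma, 0.0)
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = gamma
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    lu = lu_factor(a)
    targets = grid.centers()
    rhs = np.ones((n + 1, len(targets)))
    rhs[:n, :] = variogram(cdist(coords, targets))
    w = lu_solve(lu, rhs)
    pred = values @ w[:n, :]
    return GridField(grid=grid, variable=variable, values=pred)


def krige_all(
    samples: SoilSamples,
    grids: dict[float, QuadratGrid],
    model: str = "spherical",
) -> tuple[dict[tuple[str, float], GridField], dict[str, VariogramModel]]:
    """Fit one variogram per variable and krige to every scale's grid."""
    fields: dict[tuple[str, float], GridField] = {}
    variograms: dict[str, VariogramModel] = {}
    for var in samples.variables:
        vm = fit_variogram(samples, var, model=model)
        variograms[var] = vm
        for scale, grid in grids.items():
            fields[(var, scale)] = krige(samples, var, grid, vm)
    return fields, variograms


def soil_summary(fields: dict[tuple[str, float], GridField]) -> pd.DataFrame:
    """Mean and SD of each kriged variable at each scale."""
    rows = []
    for (var, scale), fld in sorted(fields.items()):
        rows.append(
            {
                "variable": var,
                "scale": scale,
                "mean": float(fld.values.mean()),
                "sd": float(fld.values.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)
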