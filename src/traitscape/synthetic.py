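"""Synthetic forest-plot study generator.

Real stem-mapped census plots with paired trait and soil data are access
controlled, so the pipeline is exercised end to end on a virtual plot that
emulates the study system: a rectangular plot, a species pool with
log-series-like regional abundances and six correlated continuous traits,
nine spatially autocorrelated soil fields sampled on a 30 m grid with
paired near points, and local community assembly whose trait dispersion
responds to designated resource fields.

The assembly mechanism is environmental filtering with a resource-modulated
filter width.  Each assembly quadrat q has a locally favored trait optimum
theta_q (drifting smoothly across the plot) and samples species with
weights

    w_s(q)  ~  regional_s * exp(-||t_s - theta_q||^2 / (2 sigma_q^2))
    sigma_q = sigma0 * exp(b_lim z_lim + b_non z_non + b_sat z_sat)

where z are the standardized local values of the limited / non-limited /
saturated resource fields.  A *limited* resource (b_lim < 0) narrows the
filter where it is abundant, lowering local trait dispersion; a
*non-limited* resource (b_non > 0) widens it; a *saturated* resource
(b_sat = 0) has no effect.  Ground truth (true fields, per-quadrat filter
widths) is stored for recovery tests only and is never an input to any
pipeline stage.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.interpolate import RegularGridInterpolator

from .grid import CensusTable, QuadratGrid
from .soil import SOIL_VARIABLES, SoilSamples, design_soil_grid
from .traits import TraitMatrix

TRAIT_NAMES = ("Hmax", "LA", "SLA", "LDMC", "LT", "WD")

#: plot-scale means and SDs the soil fields are scaled to, per variable
SOIL_MOMENTS = {
    "pH": (3.75, 0.09),
    "SM": (18.8, 2.7),
    "OM": (61.0, 11.0),
    "AN": (201.7, 35.5),
    "AP": (1.81, 1.05),
    "AK": (55.0, 19.2),
    "TN": (1.18, 0.50),
    "TP": (0.28, 0.05),
    "TK": (18.2, 3.4),
}

#: how each soil variable loads on the latent spatial factors.  The three
#: focal resources (AP, AK, AN) each get their own latent so their fields
#: are mutually independent and the assembly signal of one does not leak
#: into another; the remaining variables share a fertility factor (LF) and
#: a moisture factor (LW), giving the soil PCA a planted factor structure.
LATENTS = ("LF", "LW", "LP", "LK", "LN")
SOIL_LOADINGS = {
    "pH": {"LF": -0.6, "LP": 0.4},
    "SM": {"LF": 0.3, "LW": 0.7},
    "OM": {"LF": 0.85},
    "AN": {"LN": 0.9},
    "AP": {"LP": 0.9},
    "AK": {"LK": 0.9},
    "TN": {"LF": 0.85},
    "TP": {"LF": 0.8},
    "TK": {"LW": 0.8},
}


@dataclass
class GeneratorConfig:
    """Study conditions for the virtual plot.

    Defaults mirror the reference setting: a 500 x 400 m plot, 134 species,
    nine soil variables sampled on a 30 m grid, resource roles AP=limited,
    AK=non-limited, AN=saturated with effect sizes (-0.8, +0.8, 0).
    """

    plot_width: float = 500.0
    plot_height: float = 400.0
    n_species: int = 134
    n_stems: int = 20_000
    n_traits: int = 6
    trait_corr: float = 0.3
    soil_range: float = 60.0  # GRF correlation length, metres
    nugget_frac: float = 0.2  # measurement-noise share of sample variance
    grid_spacing: float = 30.0
    offsets: tuple[float, ...] = (2.0, 5.0, 15.0)
    roles: dict = field(
        default_factory=lambda: {"AP": "limited", "AK": "non_limited", "AN": "saturated"}
    )
    beta_limited: float = -0.8
    beta_non_limited: float = 0.8
    beta_saturated: float = 0.0
    sigma0: float = 1.2  # baseline filter width, standardized-trait units
    optimum_range: float = 150.0  # correlation length of the optimum drift
    optimum_amplitude: float = 0.5  # SD of the optimum field, trait units
    assembly_scale: float = 10.0  # quadrat side used for assembly, metres
    logseries_p: float = 0.95  # log-series shape for regional abundances
    resolution: float = 2.0  # GRF lattice resolution, metres
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least two species")
        if not 0.0 <= self.nugget_frac <= 1.0:
            raise ValueError("nugget_frac must be in [0, 1]")
        if self.beta_limited > 0 or self.beta_non_limited < 0 or self.beta_saturated != 0:
            raise ValueError("effect-size signs must match resource roles")


def desk_preset(seed: int = 0, **overrides) -> GeneratorConfig:
    """Small-plot preset: the full pipeline runs in minutes on one CPU.

    300 x 200 m plot (all four analysis scales 5/10/20/50 m divide both
    dimensions), 60 species, 12,000 stems; the soil and optimum-drift
    correlation lengths shrink with the plot so the number of independent
    environmental patches per plot stays comparable.
    """
    base = dict(
        plot_width=300.0,
        plot_height=200.0,
        n_species=60,
        n_stems=12_000,
        soil_range=40.0,
        optimum_range=100.0,
        seed=seed,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


class SmoothField:
    """A standardized Gaussian random field on a lattice, with interpolation."""

    def __init__(self, lattice: np.ndarray, resolution: float):
        self.lattice = lattice
        self.resolution = resolution
        ny, nx = lattice.shape
        self._interp = RegularGridInterpolator(
            (np.arange(ny) * resolution, np.arange(nx) * resolution),
            lattice,
            bounds_error=False,
            fill_value=None,
        )

    def at(self, points: np.ndarray) -> np.ndarray:
        """Bilinear interpolation at (x, y) points in metres."""
        pts = np.asarray(points, float)
        return self._interp(np.column_stack([pts[:, 1], pts[:, 0]]))


def gaussian_random_field(
    plot_dims: tuple[float, float],
    range_m: float,
    rng: np.random.Generator,
    resolution: float = 2.0,
) -> SmoothField:
    """Zero-mean, unit-SD random field with Gaussian-kernel autocorrelation.

    White noise on a lattice is smoothed with a Gaussian kernel of SD
    range_m/2 (periodic boundaries keep the field stationary) and then
    re-standardized, giving correlation ~exp(-(h/range_m)^2).
    """
    width, height = plot_dims
    nx = int(np.ceil(width / resolution)) + 1
    ny = int(np.ceil(height / resolution)) + 1
    white = rng.standard_normal((ny, nx))
    sigma_px = max(range_m / (2.0 * resolution), 1e-6)
    smooth = gaussian_filter(white, sigma=sigma_px, mode="wrap")
    smooth = (smooth - smooth.mean()) / smooth.std()
    return SmoothField(smooth, resolution)


def _orthogonal_fields(
    n: int,
    dims: tuple[float, float],
    range_m: float,
    rng: np.random.Generator,
    resolution: float,
) -> list[SmoothField]:
    """n mutually uncorrelated unit-SD random fields.

    Independent GRFs on a small plot can show large chance correlations
    (few effective patches), which would blur the planted soil correlation
    structure and leak one resource's assembly signal into another.  A QR
    orthogonalization of the lattices (linear mixing of same-range GRFs, so
    smoothness is preserved) makes the planted structure exact.
    """
    lattices = [
        gaussian_random_field(dims, range_m, rng, resolution).lattice for _ in range(n)
    ]
    shape = lattices[0].shape
    m = np.column_stack([lat.ravel() for lat in lattices])
    m -= m.mean(axis=0)
    q, r = np.linalg.qr(m)
    sign = np.sign(np.diag(r))
    sign[sign == 0] = 1.0
    q = q * sign
    q = q / q.std(axis=0)
    return [SmoothField(q[:, j].reshape(shape), resolution) for j in range(n)]


@dataclass
class SyntheticStudy:
    """A full virtual study: pipeline inputs plus held-out ground truth."""

    census: CensusTable
    traits: TraitMatrix
    soil_samples: SoilSamples
    truth: dict  # recovery-test material; never a pipeline input
    config: GeneratorConfig


def gen_soil_fields(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[dict[str, SmoothField], SoilSamples]:
    """Nine correlated soil surfaces plus point samples at the designed layout.

    Each variable is a unit-variance mixture of latent factor fields and a
    variable-specific field, rescaled to its plot-scale mean/SD; samples add
    white measurement noise so that it contributes ``nugget_frac`` of the
    sample variance.
    """
    dims = (config.plot_width, config.plot_height)
    pool = _orthogonal_fields(
        len(LATENTS) + len(SOIL_VARIABLES), dims, config.soil_range, rng, config.resolution
    )
    latents = dict(zip(LATENTS, pool[: len(LATENTS)]))
    uniques = dict(zip(SOIL_VARIABLES, pool[len(LATENTS) :]))
    fields: dict[str, SmoothField] = {}
    for var in SOIL_VARIABLES:
        loads = SOIL_LOADINGS[var]
        unique_w = np.sqrt(max(1.0 - sum(w**2 for w in loads.values()), 0.0))
        lat = sum(w * latents[k].lattice for k, w in loads.items())
        combo = lat + unique_w * uniques[var].lattice
        combo = (combo - combo.mean()) / combo.std()
        mean, sd = SOIL_MOMENTS[var]
        fields[var] = SmoothField(mean + sd * combo, config.resolution)

    layout = design_soil_grid(dims, config.grid_spacing, config.offsets, rng)
    pts = layout[["x", "y"]].to_numpy()
    data = {"x": pts[:, 0], "y": pts[:, 1]}
    # sample = mean + sqrt(1-f)*(structural part) + sqrt(f)*noise keeps the
    # sample variance at sd^2 with a nugget fraction f; f=1 is pure noise
    f = config.nugget_frac
    for var in SOIL_VARIABLES:
        mean, sd = SOIL_MOMENTS[var]
        vals = mean + np.sqrt(1.0 - f) * (fields[var].at(pts) - mean)
        vals = vals + rng.standard_normal(len(pts)) * sd * np.sqrt(f)
        data[var] = vals
    samples = SoilSamples(
        pd.DataFrame(data), plot_width=config.plot_width, plot_height=config.plot_height
    )
    return fields, samples


def gen_species_pool(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[TraitMatrix, np.ndarray]:
    """Species pool: correlated traits and log-series-like regional abundances."""
    p = config.n_traits
    cov = np.full((p, p), config.trait_corr)
    np.fill_diagonal(cov, 1.0)
    vals = rng.multivariate_normal(np.zeros(p), cov, size=config.n_species)
    names = list(TRAIT_NAMES[:p]) + [f"T{k}" for k in range(len(TRAIT_NAMES), p)]
    species = [f"sp{j:03d}" for j in range(config.n_species)]
    traits = TraitMatrix(pd.DataFrame(vals, index=species, columns=names))
    from scipy.stats import logser

    counts = logser.rvs(config.logseries_p, size=config.n_species, random_state=rng)
    weights = counts.astype(float)
    return traits, weights / weights.sum()


def gen_census(
    config: GeneratorConfig,
    fields: dict[str, SmoothField],
    pool: tuple[TraitMatrix, np.ndarray],
    rng: np.random.Generator,
) -> tuple[CensusTable, dict]:
    """Place stems quadrat by quadrat under resource-modulated trait filtering."""
    traits, regional = pool
    t = traits.values
    t = (t - t.mean(axis=0)) / t.std(axis=0, ddof=1)  # filter acts on z-scores
    n_sp, n_tr = t.shape

    scale = config.assembly_scale
    n_x = int(round(config.plot_width / scale))
    n_y = int(round(config.plot_height / scale))
    grid = QuadratGrid(scale=scale, n_x=n_x, n_y=n_y)
    centers = grid.centers()

    role_of = {role: var for var, role in config.roles.items()}
    z = {}
    for role in ("limited", "non_limited", "saturated"):
        raw = fields[role_of[role]].at(centers)
        z[role] = (raw - raw.mean()) / raw.std()
    log_sigma = (
        np.log(config.sigma0)
        + config.beta_limited * z["limited"]
        + config.beta_non_limited * z["non_limited"]
        + config.beta_saturated * z["saturated"]
    )
    sigma = np.exp(log_sigma)

    dims = (config.plot_width, config.plot_height)
    theta = np.column_stack(
        [
            config.optimum_amplitude
            * gaussian_random_field(dims, config.optimum_range, rng, config.resolution).at(
                centers
            )
            for _ in range(n_tr)
        ]
    )

    per_quadrat = rng.multinomial(config.n_stems, np.full(grid.n_quadrats, 1.0 / grid.n_quadrats))
    records = []
    stem = 0
    species = traits.species
    for q in range(grid.n_quadrats):
        nq = per_quadrat[q]
        if nq == 0:
            continue
        d2 = ((t - theta[q]) ** 2).sum(axis=1)
        logw = np.log(regional) - d2 / (2.0 * sigma[q] ** 2)
        w = np.exp(logw - logw.max())
        w /= w.sum()
        counts = rng.multinomial(nq, w)
        row, col = divmod(q, grid.n_x)
        x0, y0 = col * scale, row * scale
        for sp_idx in np.flatnonzero(counts):
            k = counts[sp_idx]
            xs = x0 + rng.uniform(0.0, scale, k)
            ys = y0 + rng.uniform(0.0, scale, k)
            dbhs = 1.0 + rng.lognormal(mean=0.5, sigma=0.8, size=k)
            for x, y, dbh in zip(xs, ys, dbhs):
                records.append((f"s{stem:06d}", x, y, species[sp_idx], dbh))
                stem += 1
    df = pd.DataFrame(records, columns=["stem_id", "x", "y", "species", "dbh"])
    census = CensusTable(df, config.plot_width, config.plot_height)
    truth = {
        "assembly_grid": grid,
        "sigma": sigma,
        "z": z,
        "theta": theta,
        "fields": fields,
    }
    return census, truth


def generate_study(config: GeneratorConfig) -> SyntheticStudy:
    """Run the whole generator from the config's seed."""
    rng = np.random.default_rng(config.seed)
    fields, samples = gen_soil_fields(config, rng)
    pool = gen_species_pool(config, rng)
    census, truth = gen_census(config, fields, pool, rng)
    return SyntheticStudy(
        census=census, traits=pool[0], soil_samples=samples, truth=truth, config=config
    )


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write census.csv, traits.csv, soil_samples.csv and the config echo."""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.census.data.to_csv(out / "census.csv", index=False)
    study.traits.data.to_csv(out / "traits.csv")
    study.soil_samples.data.to_csv(out / "soil_samples.csv", index=False)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    np.savetxt(truth_dir / "sigma_per_quadrat.txt", study.truth["sigma"])
    cfg = asdict(study.config)
    cfg["offsets"] = list(cfg["offsets"])
    (out / "config.json").write_text(json.dumps(cfg, indent=2))
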