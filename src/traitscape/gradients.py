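"""Composite environmental gradients: PCA of soil variables per scale.

The nine kriged soil variables at one quadrat scale are standardized and
decomposed by correlation-matrix PCA.  Horn's parallel analysis decides how
many axes carry more structure than chance: observed eigenvalues are bias-
corrected by the mean eigenvalues of equally sized standard-normal data,
and axes with adjusted eigenvalue > 1 are retained.  Regardless of the
retention verdict the first two axis scores are exported as quadrat fields
(PC1, PC2) so analyses stay comparable across scales; the verdict is kept
alongside.  Axis signs are fixed by an anchor variable (organic matter by
default loads positively), because PCA signs are otherwise arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import QuadratGrid
from .soil import GridField

DEFAULT_ANCHOR = "OM"


@dataclass
class PcaResult:
    """Correlation-matrix PCA of quadrat x variable soil data."""

    loadings: pd.DataFrame  # variable x axis, orthonormal columns
    scores: np.ndarray  # quadrat x axis
    eigenvalues: np.ndarray
    cumulative_proportion: np.ndarray
    retained: int | None = None  # filled by horn_parallel via retain_axes

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant variable column")
    return (x - x.mean(axis=0)) / sd


def soil_pca(fields: dict[str, GridField], anchor: str = DEFAULT_ANCHOR) -> PcaResult:
    """PCA (on the correlation matrix) of soil variables sharing one grid."""
    names = list(fields)
    grids = {f.grid.scale for f in fields.values()}
    if len(grids) != 1:
        raise ValueError("all fields must share one grid")
    x = np.column_stack([fields[v].values for v in names])
    z = _standardize_columns(x)
    n = z.shape[0]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = s**2 / (n - 1)
    loadings = vt.T  # orthonormal columns
    scores = z @ loadings
    # anchor-variable sign rule
    if anchor in names:
        arow = names.index(anchor)
        flip = np.sign(loadings[arow, :])
        flip[flip == 0] = 1.0
        loadings = loadings * flip
        scores = scores * flip
    cum = np.cumsum(eig) / eig.sum()
    return PcaResult(
        loadings=pd.DataFrame(
            loadings, index=names, columns=[f"PC{k+1}" for k in range(len(eig))]
        ),
        scores=scores,
        eigenvalues=eig,
        cumulative_proportion=cum,
    )


def horn_parallel(
    data: np.ndarray,
    n_iter: int = 1000,
    rng: np.random.Generator | None = None,
    centile: float = 95.0,
) -> tuple[int, np.ndarray]:
    """Horn's parallel analysis on a quadrat x variable matrix.

    adjusted_k = observed_k - (benchmark random eigenvalue_k - 1), with
    random data standard-normal matrices of the same shape; retain axes
    with adjusted eigenvalue > 1.  The benchmark is the ``centile``-th
    percentile of the random eigenvalues (default 95, which calibrates the
    chance of retaining an axis from pure noise at ~5%; ``centile=0`` uses
    the mean, Horn's original bias-correction, which flags a noise axis
    about half the time).  Returns (retained count, adjusted eigenvalues).
    """
    if n_iter < 100:
        raise ValueError("parallel analysis needs n_iter >= 100")
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(data, float)
    n, p = x.shape
    z = _standardize_columns(x)
    obs = np.linalg.eigvalsh(np.corrcoef(z, rowvar=False))[::-1]
    draws = np.empty((n_iter, p))
    for i in range(n_iter):
        r = rng.standard_normal((n, p))
        draws[i] = np.linalg.eigvalsh(np.corrcoef(r, rowvar=False))[::-1]
    rand = draws.mean(axis=0) if centile == 0 else np.percentile(draws, centile, axis=0)
    adjusted = obs - (rand - 1.0)
    # retention must be contiguous from the first axis
    retained = 0
    for val in adjusted:
        if val > 1.0:
            retained += 1
        else:
            break
    return retained, adjusted


def retain_axes(
    pca: PcaResult, data: np.ndarray, n_iter: int = 1000, rng=None
) -> PcaResult:
    """Attach the parallel-analysis retention verdict to a PCA result."""
    pca.retained, _ = horn_parallel(data, n_iter=n_iter, rng=rng)
    return pca


def axis_fields(pca: PcaResult, grid: QuadratGrid) -> dict[str, GridField]:
    """Export PC1 and PC2 scores as quadrat fields on the PCA's grid."""
    if pca.n_axes < 2:
        raise ValueError("need at least two PCA axes")
    return {
        "PC1": GridField(grid=grid, variable="PC1", values=pca.scores[:, 0]),
        "PC2": GridField(grid=grid, variable="PC2", values=pca.scores[:, 1]),
    }
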