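"""Probability-of-occurrence surfaces from fitted models.

A :class:`ProbabilitySurface` is a per-cell occurrence probability raster on
the same lattice conventions as :class:`~jsdmkit.grids.PredictorGrid`.  For
the probit JSDM the per-cell probability is ``Phi(alpha + B . x)`` — the
standard-normal CDF of the environmental linear predictor — computed either
per retained draw and averaged (the default "draws" mode, a posterior-mean
surface) or once at the posterior means ("plugin" mode).  The two differ by a
Jensen gap because the CDF is nonlinear.

Thresholding uses ``probability >= threshold`` (ties count as predicted
presence), which must be fixed for reproducible sensitivity accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .grids import NODATA, PredictorGrid, read_ascii_grid, write_ascii_grid
from .jsdm import JSDMPosterior
from .sdm import SDMEnsemble, SDMModel


class PredictionError(ValueError):
    """Raised for grid/model mismatches."""


@dataclass
class ProbabilitySurface:
    """Per-cell probability lattice with the predictor grid's mask."""

    values: np.ndarray  # (nrows, ncols); NaN on masked cells
    mask: np.ndarray
    west: float
    south: float
    cell_size: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ok = self.values[self.mask]
        if len(ok) and (np.nanmin(ok) < 0 or np.nanmax(ok) > 1):
            raise PredictionError("unmasked probabilities must lie in [0, 1]")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def north(self) -> float:
        return self.south + self.nrows * self.cell_size

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        lons = self.west + (np.arange(self.ncols) + 0.5) * self.cell_size
        lats = self.north - (np.arange(self.nrows) + 0.5) * self.cell_size
        return lons, lats

    def to_frame(self) -> pd.DataFrame:
        """Tidy (lon, lat, probability) rows for unmasked cells."""
        rows, cols = np.nonzero(self.mask)
        lons, lats = self.cell_centers()
        return pd.DataFrame({"lon": lons[cols], "lat": lats[rows],
                             "probability": self.values[rows, cols]})

    def write(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid; NODATA encodes the mask."""
        arr = np.where(self.mask, self.values, NODATA)
        write_ascii_grid(path, arr, self.west, self.south, self.cell_size)

    @classmethod
    def read(cls, path: str | Path) -> "ProbabilitySurface":
        arr, west, south, cs = read_ascii_grid(path)
        mask = arr != NODATA
        vals = np.where(mask, arr, np.nan)
        return cls(values=vals, mask=mask, west=west, south=south,
                   cell_size=cs)


def _standardized_cells(grid: PredictorGrid, predictors: list[str],
                        standardization: dict | None) -> tuple[np.ndarray,
                                                               np.ndarray]:
    missing = set(predictors) - set(grid.names)
    if missing:
        raise PredictionError(
            f"grid lacks predictor layer(s) {sorted(missing)}")
    rows, cols = np.nonzero(grid.mask)
    X = np.column_stack([grid.data[p][rows, cols] for p in predictors])
    if standardization is not None:
        mis = set(predictors) - set(standardization)
        if mis:
            raise PredictionError(
                f"model was fitted on standardized predictors but constants "
                f"for {sorted(mis)} are missing; cannot standardize the grid")
        mu = np.array([standardization[p][0] for p in predictors])
        sd = np.array([standardization[p][1] for p in predictors])
        X = (X - mu) / sd
    return X, np.stack([rows, cols])


def predict_jsdm_map(post: JSDMPosterior, grid: PredictorGrid,
                     species: str | None = None,
                     mode: str = "draws") -> ProbabilitySurface:
    """Posterior probability-of-occurrence surface for one species.

    Per cell, ``Mu = Phi(intercept + sum_p Beta_p * P_p)``; in "draws" mode
    this is evaluated per retained draw and averaged, in "plugin" mode at the
    posterior means.  Raw grid layers are standardized with the constants the
    model was fitted with.
    """
    species = species or post.species[0]
    if species not in post.species:
        raise PredictionError(f"species {species!r} not in the posterior")
    j = post.species.index(species)
    X, rc = _standardized_cells(grid, post.predictors,
                                post.sites.standardization)
    if mode == "plugin":
        eta = post.alpha[:, j].mean() + X @ post.beta[:, j, :].mean(axis=0)
        probs = norm.cdf(eta)
    elif mode == "draws":
        probs = np.zeros(X.shape[0])
        step = 200  # draws per chunk; bounds peak memory on large grids
        for s in range(0, post.n_draws, step):
            a = post.alpha[s:s + step, j]
            b = post.beta[s:s + step, j, :]
            probs += norm.cdf(a[None, :] + X @ b.T).sum(axis=1)
        probs /= post.n_draws
    else:
        raise PredictionError(f"unknown mode {mode!r}")
    values = np.full(grid.mask.shape, np.nan)
    values[rc[0], rc[1]] = probs
    return ProbabilitySurface(
        values=values, mask=grid.mask.copy(), west=grid.west,
        south=grid.south, cell_size=grid.cell_size,
        provenance={"model": "jsdm", "species": species, "mode": mode})


def predict_sdm_map(model: SDMModel | SDMEnsemble,
                    grid: PredictorGrid) -> ProbabilitySurface:
    """Replicate-averaged SDM probability surface."""
    std = model.standardization
    if isinstance(model, SDMEnsemble):
        predictors = model.members[0].features.predictors
    else:
        predictors = model.features.predictors
    X, rc = _standardized_cells(grid, predictors, std)
    Xdf = pd.DataFrame(X, columns=predictors)
    probs = model.predict(Xdf)
    values = np.full(grid.mask.shape, np.nan)
    values[rc[0], rc[1]] = probs
    return ProbabilitySurface(
        values=values, mask=grid.mask.copy(), west=grid.west,
        south=grid.south, cell_size=grid.cell_size,
        provenance={"model": "sdm"})


def binarize(surface: ProbabilitySurface, threshold: float) -> np.ndarray:
    """Binary range map: cell = 1 iff probability >= threshold.

    Masked cells are -1 in the returned int array.
    """
    if not (0.0 <= threshold <= 1.0):
        raise PredictionError("threshold must lie in [0, 1]")
    out = np.full(surface.values.shape, -1, dtype=int)
    out[surface.mask] = (surface.values[surface.mask] >= threshold).astype(int)
    return out
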