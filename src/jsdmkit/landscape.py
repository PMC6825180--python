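"""Synthetic landscapes and communities with known ground truth.

Downstream stages (occurrence preparation, SDM, JSDM, evaluation) are tested
against data whose generating process is known exactly.  This module produces

* spatially autocorrelated predictor rasters, climate-like (smooth Gaussian
  fields) or urbanization-like (patchy, right-skewed fields),
* binary multi-species occurrences from a multivariate probit: at site *i*
  with predictor vector ``x_i`` the latent vector is
  ``z_i = alpha + B x_i + e_i`` with ``e_i ~ N(0, R)`` for a residual
  correlation matrix R, and species *j* is present iff ``z_ij > 0``,
* presence-only records as a Bernoulli thinning of true presences, emulating
  opportunistic citizen-science detection.

Spatial autocorrelation is implemented as Gaussian-kernel smoothing of white
noise with kernel sd ``corr_length / 2`` cells, which gives an approximately
Gaussian correlogram ``rho(d) = exp(-(d / corr_length)**2)``: correlation
falls to about 0.37 at one correlation length.  This emulates smooth
climate-like gradients; it is not an exact variogram model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .grids import GridError, PredictorGrid
from .tables import ROLE_SIMULATED, OccurrenceSet, SiteTable


class ConfigurationError(ValueError):
    """Raised when a landscape/community configuration is invalid."""


@dataclass
class PredictorSpecification:
    """One synthetic predictor layer.

    ``corr_length`` is the spatial correlation length in cells; ``mean`` and
    ``sd`` are the marginal moments of the layer.  ``urban=True`` produces a
    patchy right-skewed field (soft-thresholded at +1 sd before rescaling),
    mimicking impervious-surface data, whose hotspots can also serve as an
    observation-effort surface.
    """

    name: str
    corr_length: float = 10.0
    mean: float = 0.0
    sd: float = 1.0
    urban: bool = False


@dataclass
class LandscapeConfig:
    """Extent, resolution and predictor roster of a synthetic landscape."""

    extent: tuple[float, float, float, float]  # west, south, east, north
    predictors: list[PredictorSpecification]
    cell_size: float = 0.0004
    seed: int = 0

    def __post_init__(self) -> None:
        west, south, east, north = self.extent
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if self.ncols < 2 or self.nrows < 2:
            raise ConfigurationError(
                "extent must span at least 2x2 cells at the given cell size")
        for spec in self.predictors:
            if spec.corr_length <= 0:
                raise ConfigurationError(
                    f"predictor {spec.name!r}: correlation length must be > 0")
            if spec.sd < 0:
                raise ConfigurationError(
                    f"predictor {spec.name!r}: sd must be >= 0")

    @property
    def ncols(self) -> int:
        return int(np.floor((self.extent[2] - self.extent[0]) / self.cell_size))

    @property
    def nrows(self) -> int:
        return int(np.floor((self.extent[3] - self.extent[1]) / self.cell_size))


@dataclass
class CommunityTruth:
    """Ground-truth community parameters for the probit simulator.

    ``species`` lists the focal species first.  ``alpha`` (J,) holds
    per-species intercepts, ``beta`` (J, P) the coefficient matrix over
    ``predictors``, and ``residual_corr`` (J, J) the residual correlation
    matrix of the latent normals.  ``detection_rate`` is the probability that
    a true presence yields a recorded occurrence.
    """

    species: list[str]
    predictors: list[str]
    alpha: np.ndarray
    beta: np.ndarray
    residual_corr: np.ndarray
    foraging_km: dict[str, float] = field(default_factory=dict)
    home_range_km: dict[str, float] = field(default_factory=dict)
    detection_rate: float = 1.0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.residual_corr = np.asarray(self.residual_corr, dtype=float)
        J, P = len(self.species), len(self.predictors)
        if self.alpha.shape != (J,):
            raise ConfigurationError(f"alpha must have shape ({J},)")
        if self.beta.shape != (J, P):
            raise ConfigurationError(f"beta must have shape ({J}, {P})")
        if self.residual_corr.shape != (J, J):
            raise ConfigurationError(f"residual_corr must be ({J}, {J})")
        if not np.allclose(self.residual_corr, self.residual_corr.T):
            raise ConfigurationError("residual correlation must be symmetric")
        if not np.allclose(np.diag(self.residual_corr), 1.0):
            raise ConfigurationError("residual correlation needs unit diagonal")
        try:
            np.linalg.cholesky(self.residual_corr)
        except np.linalg.LinAlgError:
            raise ConfigurationError(
                "residual correlation matrix is not positive definite") from None
        if not (0.0 < self.detection_rate <= 1.0):
            raise ConfigurationError("detection_rate must be in (0, 1]")

    @property
    def focal(self) -> str:
        return self.species[0]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "species": self.species,
            "predictors": self.predictors,
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "residual_corr": self.residual_corr.tolist(),
            "foraging_km": self.foraging_km,
            "home_range_km": self.home_range_km,
            "detection_rate": self.detection_rate,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CommunityTruth":
        d = json.loads(Path(path).read_text())
        return cls(species=d["species"], predictors=d["predictors"],
                   alpha=np.array(d["alpha"]), beta=np.array(d["beta"]),
                   residual_corr=np.array(d["residual_corr"]),
                   foraging_km=d.get("foraging_km", {}),
                   home_range_km=d.get("home_range_km", {}),
                   detection_rate=d.get("detection_rate", 1.0))


def _correlated_field(rng: np.random.Generator, shape: tuple[int, int],
                      corr_length: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated field (smoothed white noise)."""
    noise = rng.standard_normal(shape)
    fld = gaussian_filter(noise, sigma=corr_length / 2.0, mode="reflect")
    sd = fld.std()
    if sd > 0:
        fld = (fld - fld.mean()) / sd
    return fld


def generate_predictor_grid(config: LandscapeConfig) -> PredictorGrid:
    """Generate one raster per predictor spec on the common lattice.

    Reproducible under the config seed: layers consume the seed stream in the
    order they are listed.  A spec with ``sd == 0`` yields a constant raster.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.nrows, config.ncols)
    data: dict[str, np.ndarray] = {}
    for spec in config.predictors:
        if spec.sd == 0:
            data[spec.name] = np.full(shape, spec.mean, dtype=float)
            # keep the stream position independent of sd so seeds line up
            rng.standard_normal(shape)
            continue
        fld = _correlated_field(rng, shape, spec.corr_length)
        if spec.urban:
            fld = np.maximum(0.0, fld - 1.0)  # hotspots above +1 sd
            sd = fld.std()
            if sd > 0:
                fld = (fld - fld.mean()) / sd
        data[spec.name] = spec.mean + spec.sd * fld
    names = [s.name for s in config.predictors]
    return PredictorGrid(names=names, data=data, west=config.extent[0],
                         south=config.extent[1], cell_size=config.cell_size)


def sample_sites(grid: PredictorGrid, n_sites: int, seed: int,
                 effort_layer: str | None = None,
                 replace: bool = False) -> pd.DataFrame:
    """Sample site locations among valid cells.

    Uniform over valid cells by default; with ``effort_layer`` the sampling
    density is proportional to that (shifted non-negative) layer, emulating
    observation effort concentrated in, e.g., urbanized areas.
    """
    cells = grid.valid_cell_table()
    if len(cells) == 0:
        raise GridError("grid has no valid cells")
    rng = np.random.default_rng(seed)
    p = None
    if effort_layer is not None:
        vals = grid.data[effort_layer][cells["row"], cells["col"]]
        vals = vals - vals.min() + 1e-9
        p = vals / vals.sum()
    if not replace and n_sites > len(cells):
        raise ConfigurationError(
            f"cannot draw {n_sites} distinct sites from {len(cells)} valid cells")
    idx = rng.choice(len(cells), size=n_sites, replace=replace, p=p)
    return cells.iloc[idx].reset_index(drop=True)


def simulate_community(grid: PredictorGrid, truth: CommunityTruth,
                       n_sites: int, seed: int,
                       effort_layer: str | None = None) -> SiteTable:
    """Simulate a multivariate-probit community at ``n_sites`` locations.

    The seed stream is consumed in documented order: (1) site locations,
    (2) latent residual draws.  True marginal occurrence probabilities
    ``Phi(alpha_j + B_j . x_i)`` are retained in ``true_prob`` for testing.
    """
    if n_sites < 1:
        raise ConfigurationError("n_sites must be >= 1")
    missing = set(truth.predictors) - set(grid.names)
    if missing:
        raise ConfigurationError(f"grid lacks predictor layers {sorted(missing)}")
    # truth validation (incl. positive definiteness) ran in __post_init__;
    # revalidate here so mutated arrays fail before any sampling
    try:
        chol = np.linalg.cholesky(truth.residual_corr)
    except np.linalg.LinAlgError:
        raise ConfigurationError(
            "residual correlation matrix is not positive definite") from None

    sites = sample_sites(grid, n_sites, seed, effort_layer=effort_layer)
    latent_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    X = grid.values_at(sites["lon"], sites["lat"])[truth.predictors]
    mu = truth.alpha[None, :] + X.to_numpy() @ truth.beta.T  # (n, J)
    e = latent_rng.standard_normal((n_sites, len(truth.species))) @ chol.T
    z = mu + e
    Y = pd.DataFrame((z > 0).astype(np.int8), columns=truth.species)
    prob = pd.DataFrame(norm.cdf(mu), columns=truth.species)
    return SiteTable(
        coords=sites[["lon", "lat"]].copy(),
        X=X,
        Y=Y,
        role=np.full(n_sites, ROLE_SIMULATED),
        true_prob=prob,
        meta={"seed": seed, "n_sites": n_sites},
    )


def sample_presence_only(sites: SiteTable, truth: CommunityTruth, seed: int,
                         date_range: tuple[str, str] = ("1997-01-01",
                                                        "2018-12-31"),
                         ) -> dict[str, OccurrenceSet]:
    """Thin true presences into presence-only records per species.

    Each presence site is recorded independently with probability
    ``truth.detection_rate``; absences are never emitted.  Records get dates
    drawn uniformly (by day) over ``date_range`` and source tag "synthetic".
    """
    if not (0.0 < truth.detection_rate <= 1.0):
        raise ConfigurationError("detection_rate must be in (0, 1]")
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(date_range[0])
    ndays = (pd.Timestamp(date_range[1]) - start).days + 1
    out: dict[str, OccurrenceSet] = {}
    for sp in truth.species:
        present = np.nonzero(sites.Y[sp].to_numpy() == 1)[0]
        detected = present[rng.random(len(present)) < truth.detection_rate]
        dates = start + pd.to_timedelta(rng.integers(0, ndays, len(detected)),
                                        unit="D")
        out[sp] = OccurrenceSet(species=sp, records=pd.DataFrame({
            "lon": sites.coords["lon"].to_numpy()[detected],
            "lat": sites.coords["lat"].to_numpy()[detected],
            "date": dates.strftime("%Y-%m-%d"),
            "source": "synthetic",
        }))
    return out
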