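"""Occurrence cleaning and site-table construction for presence-background SDMs.

The preparation flow, in order:

1. :func:`deduplicate` — collapse exact duplicate records.
2. :func:`filter_by_date` — optional inclusive date window (e.g. restricting
   interactor records to a recent period).
3. :func:`thin_foraging_distance` / :func:`thin_min_distance` — greedy spatial
   thinning to a minimum pairwise great-circle distance, correcting clustered
   sampling effort (species-specific foraging radius, then a fixed 3-km
   spatial-autocorrelation filter by default).
4. :func:`build_range` — union of circular home-range buffers around retained
   records; range membership defines interactor presence/absence at sites.
5. :func:`sample_background` — pseudo-absence cells drawn uniformly outside
   the focal species' range.
6. :func:`extract_design` / :func:`build_site_table` — predictor extraction
   and assembly of the sites x predictors / sites x species matrices.

Distances are great-circle (haversine) on WGS84 coordinates throughout; no
projection is applied.  Thinning is greedy in input order: a record is kept
iff it is at least the radius away from every previously kept record, which
is deterministic and idempotent.  A seeded random-order mode is available.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._distance import haversine_km
from .grids import PredictorGrid
from .tables import (ROLE_BACKGROUND, ROLE_FOCAL, OccurrenceSet, SiteTable,
                     SpeciesRange)

log = logging.getLogger(__name__)

DEFAULT_MIN_KM = 3.0           # spatial-autocorrelation filter radius
DEFAULT_BACKGROUND_N = 10_000  # pseudo-absence sample size


class PrepError(ValueError):
    """Raised for invalid preparation inputs or infeasible requests."""


def deduplicate(occ: OccurrenceSet) -> OccurrenceSet:
    """Collapse exact duplicate (lon, lat, date) rows, keeping first seen."""
    rec = occ.records.drop_duplicates(subset=["lon", "lat", "date"],
                                      keep="first")
    return OccurrenceSet(occ.species, rec.reset_index(drop=True))


def filter_by_date(occ: OccurrenceSet, start, end) -> OccurrenceSet:
    """Keep records with date in [start, end] inclusive.

    Unparseable dates are dropped with a logged warning rather than raising.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start > end:
        raise PrepError("date window start must not exceed end")
    parsed = pd.to_datetime(occ.records["date"], errors="coerce",
                            format="mixed")
    bad = parsed.isna() & occ.records["date"].notna()
    if bad.any():
        log.warning("%s: dropped %d records with unparseable dates",
                    occ.species, int(bad.sum()))
    keep = (parsed >= start) & (parsed <= end)
    return OccurrenceSet(occ.species,
                         occ.records[keep.fillna(False)].reset_index(drop=True))


def _greedy_thin(lon: np.ndarray, lat: np.ndarray, radius_km: float,
                 order: np.ndarray) -> np.ndarray:
    """Indices kept by greedy thinning visited in ``order``."""
    kept: list[int] = []
    for i in order:
        if not kept:
            kept.append(i)
            continue
        d = haversine_km(lon[i], lat[i], lon[kept], lat[kept])
        if np.all(d >= radius_km):
            kept.append(i)
    return np.sort(np.asarray(kept, dtype=int))


def thin_min_distance(occ: OccurrenceSet, min_km: float = DEFAULT_MIN_KM,
                      order: str = "input",
                      seed: int | None = None) -> OccurrenceSet:
    """Greedy spatial thinning to a minimum pairwise distance of ``min_km``.

    ``order="input"`` (default) visits records in input order;
    ``order="random"`` uses a seeded permutation.  The result is always a
    subset of the input, returned in original row order.
    """
    if min_km < 0:
        raise PrepError("min_km must be non-negative")
    n = len(occ)
    if n <= 1 or min_km == 0:
        return OccurrenceSet(occ.species, occ.records.copy())
    if order == "input":
        visit = np.arange(n)
    elif order == "random":
        visit = np.random.default_rng(seed).permutation(n)
    else:
        raise PrepError(f"unknown thinning order {order!r}")
    kept = _greedy_thin(occ.lon, occ.lat, min_km, visit)
    return OccurrenceSet(occ.species,
                         occ.records.iloc[kept].reset_index(drop=True))


def thin_foraging_distance(occ: OccurrenceSet,
                           foraging_km: float | None) -> OccurrenceSet:
    """Thin to the species-specific average foraging flight distance."""
    if foraging_km is None or (isinstance(foraging_km, float)
                               and np.isnan(foraging_km)):
        raise PrepError(
            f"no foraging distance configured for species {occ.species!r}")
    if foraging_km <= 0:
        raise PrepError("foraging_km must be positive")
    return thin_min_distance(occ, min_km=foraging_km)


def build_range(occ: OccurrenceSet, home_range_km: float) -> SpeciesRange:
    """Union of circular buffers of ``home_range_km`` around each record."""
    if home_range_km <= 0:
        raise PrepError("home_range_km must be positive")
    centers = np.column_stack([occ.lon, occ.lat]) if len(occ) else \
        np.empty((0, 2))
    return SpeciesRange(species=occ.species, centers=centers,
                        radius_km=home_range_km)


def sample_background(grid: PredictorGrid, focal_range: SpeciesRange,
                      n: int = DEFAULT_BACKGROUND_N,
                      seed: int = 0) -> pd.DataFrame:
    """Draw ``n`` distinct valid cell centers outside the focal range.

    Sampling is uniform without replacement among eligible cells; masked
    (no-data) cells are excluded.  Raises if fewer than ``n`` cells are
    eligible, reporting the achievable maximum.
    """
    if n < 0:
        raise PrepError("n must be non-negative")
    cells = grid.valid_cell_table()
    outside = ~focal_range.contains(cells["lon"].to_numpy(),
                                    cells["lat"].to_numpy())
    eligible = cells[outside].reset_index(drop=True)
    if n > len(eligible):
        raise PrepError(
            f"requested {n} background sites but only {len(eligible)} valid "
            f"cells lie outside the focal range")
    idx = np.random.default_rng(seed).choice(len(eligible), size=n,
                                             replace=False)
    return eligible.iloc[idx].reset_index(drop=True)


def label_interactors(sites: pd.DataFrame,
                      ranges: dict[str, SpeciesRange]) -> pd.DataFrame:
    """Binary sites x interactors matrix: 1 iff site falls in the range."""
    lon = sites["lon"].to_numpy(dtype=float)
    lat = sites["lat"].to_numpy(dtype=float)
    return pd.DataFrame(
        {sp: rng.contains(lon, lat).astype(np.int8)
         for sp, rng in ranges.items()})


def extract_design(grid: PredictorGrid, sites: pd.DataFrame,
                   standardize: bool = True
                   ) -> tuple[pd.DataFrame, pd.DataFrame,
                              dict[str, tuple[float, float]] | None]:
    """Nearest-cell predictor values at each site.

    Returns ``(kept_sites, X, standardization)``.  Sites landing on masked
    cells are dropped and logged.  With ``standardize=True`` each column is
    scaled to mean 0, sd 1 over the kept sites and the (mean, sd) constants
    are returned for later map prediction.
    """
    lon = sites["lon"].to_numpy(dtype=float)
    lat = sites["lat"].to_numpy(dtype=float)
    valid = grid.is_valid(lon, lat)
    if not valid.any():
        raise PrepError("all sites fall on masked cells")
    if not valid.all():
        log.warning("dropped %d sites on masked cells", int((~valid).sum()))
    kept = sites[valid].reset_index(drop=True)
    X = grid.values_at(kept["lon"], kept["lat"])
    constants = None
    if standardize:
        constants = {}
        for col in X.columns:
            mu = float(X[col].mean())
            sd = float(X[col].std(ddof=0))
            constants[col] = (mu, sd if sd > 0 else 1.0)
            X[col] = (X[col] - mu) / constants[col][1]
    return kept, X, constants


def build_site_table(grid: PredictorGrid, focal_occ: OccurrenceSet,
                     background: pd.DataFrame,
                     interactor_ranges: dict[str, SpeciesRange],
                     standardize: bool = True,
                     stage_counts: dict | None = None) -> SiteTable:
    """Assemble the SiteTable: focal presences + background pseudo-absences.

    The focal response is 1 on presence sites and 0 on background sites;
    interactor responses are range-membership labels at every site.
    """
    pres = pd.DataFrame({"lon": focal_occ.lon, "lat": focal_occ.lat})
    sites = pd.concat([pres, background[["lon", "lat"]]], ignore_index=True)
    role = np.array([ROLE_FOCAL] * len(pres)
                    + [ROLE_BACKGROUND] * len(background))
    keep_mask = grid.is_valid(sites["lon"].to_numpy(),
                              sites["lat"].to_numpy())
    kept, X, constants = extract_design(grid, sites, standardize=standardize)
    role = role[keep_mask]
    y_focal = (role == ROLE_FOCAL).astype(np.int8)
    Y = pd.DataFrame({focal_occ.species: y_focal})
    if interactor_ranges:
        Y = pd.concat([Y, label_interactors(kept, interactor_ranges)], axis=1)
    meta = {"stage_counts": stage_counts or {},
            "n_presence": int(y_focal.sum()),
            "n_background": int((1 - y_focal).sum())}
    return SiteTable(coords=kept[["lon", "lat"]].copy(), X=X, Y=Y, role=role,
                     standardization=constants, meta=meta)


def prepare_sites(grid: PredictorGrid,
                  occurrences: dict[str, OccurrenceSet],
                  focal: str,
                  foraging_km: dict[str, float],
                  home_range_km: dict[str, float],
                  min_km: float = DEFAULT_MIN_KM,
                  background_n: int = DEFAULT_BACKGROUND_N,
                  seed: int = 0,
                  date_window: tuple[str, str] | None = None,
                  standardize: bool = True) -> SiteTable:
    """Full preparation pipeline from raw occurrences to a SiteTable.

    Applies dedup, the optional interactor date window, foraging-distance
    thinning, the fixed minimum-distance filter, home-range construction,
    background sampling outside the focal range, and design extraction.
    Per-stage record counts are kept in ``SiteTable.meta['stage_counts']``.
    """
    if focal not in occurrences:
        raise PrepError(f"no occurrences for focal species {focal!r}")
    stage_counts: dict[str, dict[str, int]] = {}
    cleaned: dict[str, OccurrenceSet] = {}
    ranges: dict[str, SpeciesRange] = {}
    for sp, occ in occurrences.items():
        counts = {"raw": len(occ)}
        occ = deduplicate(occ)
        counts["dedup"] = len(occ)
        if sp != focal and date_window is not None:
            occ = filter_by_date(occ, *date_window)
            counts["date_window"] = len(occ)
        if sp not in foraging_km:
            raise PrepError(f"no foraging distance configured for species {sp!r}")
        occ = thin_foraging_distance(occ, foraging_km[sp])
        counts["foraging_thin"] = len(occ)
        occ = thin_min_distance(occ, min_km=min_km)
        counts["min_distance_thin"] = len(occ)
        cleaned[sp] = occ
        if sp not in home_range_km:
            raise PrepError(f"no home range configured for species {sp!r}")
        ranges[sp] = build_range(occ, home_range_km[sp])
        stage_counts[sp] = counts
    background = sample_background(grid, ranges[focal], n=background_n,
                                   seed=seed)
    interactor_ranges = {sp: r for sp, r in ranges.items() if sp != focal}
    return build_site_table(grid, cleaned[focal], background,
                            interactor_ranges, standardize=standardize,
                            stage_counts=stage_counts)
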