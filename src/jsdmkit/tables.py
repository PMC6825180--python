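"""Core tabular containers: occurrence records, species ranges, site tables."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._distance import haversine_km

log = logging.getLogger(__name__)

OCC_COLUMNS = ["species", "lon", "lat", "date", "source"]

ROLE_FOCAL = "focal-presence"
ROLE_BACKGROUND = "background"
ROLE_SIMULATED = "simulated"


@dataclass
class OccurrenceSet:
    """Presence-only records for a single species.

    ``records`` is a DataFrame with columns lon, lat (decimal degrees),
    date and source; absences are never represented.
    """

    species: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"lon", "lat"} - set(self.records.columns)
        if missing:
            raise ValueError(f"occurrence records lack columns {missing}")
        for col in ("date", "source"):
            if col not in self.records.columns:
                self.records[col] = pd.NA
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lon(self) -> np.ndarray:
        return self.records["lon"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.records["lat"].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        out = self.records.copy()
        out.insert(0, "species", self.species)
        return out[OCC_COLUMNS]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, species: str) -> "OccurrenceSet":
        sub = df[df["species"] == species].drop(columns=["species"])
        return cls(species=species, records=sub.reset_index(drop=True))


def read_occurrences_csv(path: str | Path) -> dict[str, OccurrenceSet]:
    """Read a multi-species occurrence CSV into per-species sets."""
    df = pd.read_csv(path)
    return {sp: OccurrenceSet.from_frame(df, sp)
            for sp in df["species"].unique()}


def write_occurrences_csv(path: str | Path,
                          sets: dict[str, OccurrenceSet]) -> None:
    frames = [s.to_frame() for s in sets.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


@dataclass
class SpeciesRange:
    """Union of great-circle buffers (radius ``radius_km``) around records."""

    species: str
    centers: np.ndarray  # (n, 2) lon/lat
    radius_km: float

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        if self.radius_km <= 0:
            raise ValueError("home-range radius must be positive")
        if len(self.centers) == 0:
            log.warning("species %s has an empty range", self.species)

    def contains(self, lon, lat) -> np.ndarray:
        """Vectorized point-in-range membership query."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        if len(self.centers) == 0:
            return np.zeros(lon.shape, dtype=bool)
        d = haversine_km(lon[:, None], lat[:, None],
                         self.centers[None, :, 0], self.centers[None, :, 1])
        return (d <= self.radius_km).any(axis=1)


@dataclass
class SiteTable:
    """Sites-by-predictors design matrix and sites-by-species responses.

    The focal species is the first column of ``Y``.  ``role`` flags each site
    as a focal presence, a background pseudo-absence, or a simulated site.
    When ``standardization`` is set, ``X`` holds standardized values and the
    per-predictor (mean, sd) pairs allow mapping back to raw units.
    """

    coords: pd.DataFrame  # columns lon, lat
    X: pd.DataFrame
    Y: pd.DataFrame
    role: np.ndarray
    true_prob: pd.DataFrame | None = None
    standardization: dict[str, tuple[float, float]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.coords)
        if len(self.X) != n or len(self.Y) != n or len(self.role) != n:
            raise ValueError("coords, X, Y and role must have equal length")
        if self.X.isna().any().any():
            raise ValueError("design matrix X contains missing values")
        yvals = self.Y.to_numpy()
        if not np.isin(yvals, (0, 1)).all():
            raise ValueError("Y must be binary")
        self.role = np.asarray(self.role)

    @property
    def n_sites(self) -> int:
        return len(self.coords)

    @property
    def species(self) -> list[str]:
        return list(self.Y.columns)

    @property
    def focal(self) -> str:
        return self.Y.columns[0]

    @property
    def predictors(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, idx) -> "SiteTable":
        idx = np.asarray(idx)
        return SiteTable(
            coords=self.coords.iloc[idx].reset_index(drop=True),
            X=self.X.iloc[idx].reset_index(drop=True),
            Y=self.Y.iloc[idx].reset_index(drop=True),
            role=self.role[idx],
            true_prob=(None if self.true_prob is None
                       else self.true_prob.iloc[idx].reset_index(drop=True)),
            standardization=self.standardization,
            meta=dict(self.meta),
        )

    def destandardized_X(self) -> pd.DataFrame:
        """Map X back to raw predictor units (inverse standardization)."""
        if self.standardization is None:
            return self.X.copy()
        out = self.X.copy()
        for name, (mu, sd) in self.standardization.items():
            out[name] = out[name] * sd + mu
        return out

    def fingerprint(self) -> str:
        """Stable digest of the evaluation data (coords + responses)."""
        import hashlib

        h = hashlib.sha1()
        h.update(np.ascontiguousarray(
            self.coords.to_numpy(dtype=float)).tobytes())
        h.update(np.ascontiguousarray(
            self.Y.to_numpy(dtype=np.int8)).tobytes())
        return h.hexdigest()

    # -- I/O ----------------------------------------------------------------
    def write(self, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
        csv_path = Path(csv_path)
        df = pd.concat(
            [self.coords,
             pd.DataFrame({"role": self.role}),
             self.X.add_prefix("x:"),
             self.Y.add_prefix("y:")], axis=1)
        if self.true_prob is not None:
            df = pd.concat([df, self.true_prob.add_prefix("p:")], axis=1)
        df.to_csv(csv_path, index=False)
        meta = dict(self.meta)
        meta["standardization"] = (
            None if self.standardization is None
            else {k: list(v) for k, v in self.standardization.items()})
        meta["species"] = self.species
        meta["predictors"] = self.predictors
        meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
        meta_path.write_text(json.dumps(meta, indent=2))

    @classmethod
    def read(cls, csv_path: str | Path,
             meta_path: str | Path | None = None) -> "SiteTable":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
        meta = json.loads(meta_path.read_text())
        xcols = [c for c in df.columns if c.startswith("x:")]
        ycols = [c for c in df.columns if c.startswith("y:")]
        pcols = [c for c in df.columns if c.startswith("p:")]
        std = meta.pop("standardization", None)
        return cls(
            coords=df[["lon", "lat"]].copy(),
            X=df[xcols].rename(columns=lambda c: c[2:]),
            Y=df[ycols].rename(columns=lambda c: c[2:]).astype(np.int8),
            role=df["role"].to_numpy(),
            true_prob=(df[pcols].rename(columns=lambda c: c[2:])
                       if pcols else None),
            standardization=(None if std is None
                             else {k: (v[0], v[1]) for k, v in std.items()}),
            meta=meta,
        )
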