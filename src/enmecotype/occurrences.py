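"""Sampling tables and occurrence-point expansion.

Field surveys record one GPS point per village.  To represent a village's
habitat rather than a single pixel, each centre is expanded into the centre
plus ``n_extra`` points drawn uniformly inside a square of fixed area
(default 1.2 km², i.e. ten points per village).  Districts, the modelling
unit, then carry 10 x (number of villages) occurrence points.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: metres per degree of latitude (mean-Earth-radius arc length)
M_PER_DEG_LAT = 111_194.9

SCHEMA = ("district", "village", "latitude", "longitude", "altitude", "agroecology")
ZONES = ("Lowland", "Midland", "Highland")


class SamplingTableError(ValueError):
    """Invalid sampling table contents."""


@dataclass
class SamplingTable:
    """Validated village sampling table (district, village, lat, lon, altitude, zone)."""

    rows: pd.DataFrame

    @property
    def districts(self) -> list[str]:
        return list(dict.fromkeys(self.rows["district"]))

    @property
    def n_villages(self) -> int:
        return len(self.rows)

    def villages_of(self, district: str) -> pd.DataFrame:
        sub = self.rows[self.rows["district"] == district]
        if sub.empty:
            raise SamplingTableError(f"unknown district {district!r}")
        return sub


@dataclass
class OccurrenceSet:
    """Expanded occurrence points with district/village labels."""

    points: pd.DataFrame  # lon, lat, district, village, is_center
    seed: int

    def __len__(self) -> int:
        return len(self.points)

    def lonlat(self) -> np.ndarray:
        return self.points[["lon", "lat"]].to_numpy()


def parse_sampling_table(path: str | Path | pd.DataFrame) -> SamplingTable:
    """Parse and validate a sampling-table CSV (schema case-insensitive)."""
    if isinstance(path, pd.DataFrame):
        df = path.copy()
    else:
        df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        raise SamplingTableError(f"sampling table missing columns: {missing}")
    df = df[list(SCHEMA)]
    for col in ("latitude", "longitude", "altitude"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SamplingTableError(f"non-numeric values in column {col!r}") from exc
    dupes = df.duplicated(subset=["district", "village"])
    if dupes.any():
        bad = df.loc[dupes, ["district", "village"]].to_records(index=False).tolist()
        raise SamplingTableError(f"duplicate (district, village) rows: {bad}")
    if ((df["latitude"] < -90) | (df["latitude"] > 90)).any():
        raise SamplingTableError("latitude out of [-90, 90]")
    if ((df["longitude"] < -180) | (df["longitude"] > 180)).any():
        raise SamplingTableError("longitude out of [-180, 180]")
    if (df["altitude"] < 0).any():
        raise SamplingTableError("negative altitude")
    return SamplingTable(rows=df.reset_index(drop=True))


def load_packaged_table() -> SamplingTable:
    """The packaged transcription of the study's village sampling table.

    Printed agro-ecology labels are preserved verbatim, including rows whose
    label contradicts the stated altitude thresholds.
    """
    with resources.files("enmecotype.data").joinpath("sampling_table.csv").open() as fh:
        return parse_sampling_table(pd.read_csv(fh))


def load_variable_registry() -> pd.DataFrame:
    """The packaged registry of the 34 environmental variables (name, group, kind, units)."""
    with resources.files("enmecotype.data").joinpath("variable_registry.csv").open() as fh:
        return pd.read_csv(fh)


def classify_altitude(altitude: float) -> str:
    """Altitude zone: lowland < 1,500 m; midland 1,500-2,300 m; highland > 2,300 m.

    Informational only — printed survey labels take precedence when echoing
    a published table.
    """
    if altitude < 0:
        raise ValueError(f"negative altitude: {altitude}")
    if altitude < 1500:
        return "Lowland"
    if altitude <= 2300:
        return "Midland"
    return "Highland"


def district_seed(global_seed: int, district: str) -> int:
    """Stable per-district seed so adding a district never perturbs others."""
    digest = hashlib.blake2b(
        f"{global_seed}:{district}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


def expand_village(
    center: tuple[float, float],
    n_extra: int = 9,
    area_km2: float = 1.2,
    seed: int = 0,
) -> np.ndarray:
    """Centre plus ``n_extra`` uniform points in a square of ``area_km2``.

    The square is centred on the village; kilometres are converted to
    degrees with the local metres-per-degree at the village latitude
    (planar approximation — fine at km scale).
    """
    if n_extra < 0:
        raise ValueError("n_extra must be >= 0")
    if area_km2 <= 0:
        raise ValueError("area_km2 must be > 0")
    lon0, lat0 = center
    side_m = float(np.sqrt(area_km2)) * 1000.0
    half_lat = side_m / 2 / M_PER_DEG_LAT
    m_per_deg_lon = M_PER_DEG_LAT * np.cos(np.radians(lat0))
    half_lon = side_m / 2 / m_per_deg_lon
    rng = np.random.default_rng(seed)
    extra = np.column_stack(
        [
            rng.uniform(lon0 - half_lon, lon0 + half_lon, n_extra),
            rng.uniform(lat0 - half_lat, lat0 + half_lat, n_extra),
        ]
    )
    return np.vstack([[lon0, lat0], extra])


def expand_district(
    table: SamplingTable,
    district: str,
    n_extra: int = 9,
    area_km2: float = 1.2,
    seed: int = 0,
) -> OccurrenceSet:
    """Expand every village of a district into its occurrence points."""
    villages = table.villages_of(district)
    dseed = district_seed(seed, district)
    frames = []
    for k, rec in enumerate(villages.itertuples(index=False)):
        pts = expand_village(
            (rec.longitude, rec.latitude), n_extra=n_extra, area_km2=area_km2,
            seed=dseed + k,
        )
        frames.append(
            pd.DataFrame(
                {
                    "lon": pts[:, 0],
                    "lat": pts[:, 1],
                    "district": district,
                    "village": rec.village,
                    "is_center": [True] + [False] * n_extra,
                }
            )
        )
    return OccurrenceSet(points=pd.concat(frames, ignore_index=True), seed=seed)


def expand_all(
    table: SamplingTable,
    n_extra: int = 9,
    area_km2: float = 1.2,
    seed: int = 0,
) -> OccurrenceSet:
    """Pooled occurrence set over every district in the table."""
    frames = [
        expand_district(table, d, n_extra=n_extra, area_km2=area_km2, seed=seed).points
        for d in table.districts
    ]
    return OccurrenceSet(points=pd.concat(frames, ignore_index=True), seed=seed)
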