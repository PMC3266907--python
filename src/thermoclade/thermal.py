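"""Occurrence-record x SST-raster intersection and per-species summaries.

Each species' thermal biology is summarized from the sea-surface
temperature (minimum / mean / maximum climatological layers, deg C) at its
occurrence records.  The headline statistic is the *maximum thermal
tolerance range*: the largest per-record maximum SST minus the smallest
per-record minimum SST — an extreme-based range, deliberately different
from (and never smaller than) the difference of the per-record means.

Rasters are ESRI ASCII grids sharing one header; row 1 is the
northernmost row and values are registered to cell centers.  Coastal
occurrences routinely fall on land (nodata) cells of marine layers, so
extraction falls back to the nearest valid cell center within a small
search radius.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from io import StringIO
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceRecord",
    "GridSpec",
    "SstRaster",
    "SpeciesThermalSummary",
    "read_occurrences",
    "read_ascii_grid",
    "write_ascii_grid",
    "extract_sst",
    "summarize_species",
    "summaries_to_frame",
]

PROVENANCES = ("dna", "literature", "herbarium")


@dataclass
class OccurrenceRecord:
    species: str
    lat: float
    lon: float
    provenance: str = "literature"

    def __post_init__(self):
        if not self.species:
            raise ValueError("empty species id")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} out of range")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} out of range")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class GridSpec:
    """ESRI ASCII grid header (lower-left corner registration)."""

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    def cell_lats(self) -> np.ndarray:
        """Cell-center latitudes per row, row 0 = northernmost."""
        top = self.yllcorner + self.nrows * self.cellsize
        return top - (np.arange(self.nrows) + 0.5) * self.cellsize

    def cell_lons(self) -> np.ndarray:
        return self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize

    def locate(self, lat: float, lon: float) -> Tuple[int, int]:
        """(row, col) of the containing cell; raises if outside bounds."""
        top = self.yllcorner + self.nrows * self.cellsize
        right = self.xllcorner + self.ncols * self.cellsize
        if not (self.yllcorner <= lat <= top) or not (self.xllcorner <= lon <= right):
            raise ValueError(f"point ({lat}, {lon}) outside grid bounds")
        row = min(int((top - lat) / self.cellsize), self.nrows - 1)
        col = min(int((lon - self.xllcorner) / self.cellsize), self.ncols - 1)
        return row, col


@dataclass
class SstRaster:
    """min/mean/max SST layers on a shared grid with nodata (land) cells."""

    spec: GridSpec
    tmin: np.ndarray
    tmean: np.ndarray
    tmax: np.ndarray

    def __post_init__(self):
        shape = (self.spec.nrows, self.spec.ncols)
        for layer in (self.tmin, self.tmean, self.tmax):
            if layer.shape != shape:
                raise ValueError("layer shape does not match grid spec")
        v = self.valid_mask()
        if np.any(self.tmin[v] > self.tmax[v]) or np.any(
            (self.tmin[v] > self.tmean[v]) | (self.tmean[v] > self.tmax[v])
        ):
            raise ValueError("min <= mean <= max violated at a valid cell")

    def valid_mask(self) -> np.ndarray:
        nod = self.spec.nodata
        return (self.tmin != nod) & (self.tmean != nod) & (self.tmax != nod)


@dataclass
class SpeciesThermalSummary:
    """One per-species row of the thermal summary table.

    ``max_c``/``mean_c``/``min_c`` are means over records of the
    per-record max/mean/min SST; ``max_range_c`` is the largest per-record
    max minus the smallest per-record min, hence always >= max_c - min_c.
    """

    species: str
    n: int
    lat_range: float
    lon_range: float
    max_c: float
    mean_c: float
    min_c: float
    max_range_c: float


def read_occurrences(
    source: Union[str, StringIO], strict: bool = True
) -> List[OccurrenceRecord]:
    """Read occurrence records from CSV with header species,lat,lon[,provenance].

    Rows with out-of-range coordinates or unparseable numbers are rejected;
    with ``strict`` (default) any bad row raises an error listing the
    offending line numbers, otherwise bad rows are dropped with a warning.
    A missing provenance column defaults to ``literature`` with a warning.
    """
    df = pd.read_csv(source, dtype={"species": str})
    needed = {"species", "lat", "lon"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    if "provenance" not in df.columns:
        warnings.warn("no provenance column; defaulting to 'literature'")
        df["provenance"] = "literature"
    df["provenance"] = df["provenance"].fillna("literature")
    records, bad = [], []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            records.append(
                OccurrenceRecord(
                    species=str(row["species"]),
                    lat=float(row["lat"]),
                    lon=float(row["lon"]),
                    provenance=str(row["provenance"]),
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append((line, str(exc)))
    if bad:
        msg = "; ".join(f"line {l}: {m}" for l, m in bad)
        if strict:
            raise ValueError(f"rejected rows — {msg}")
        warnings.warn(f"dropped rows — {msg}")
    return records


def _read_one_grid(path: Union[str, StringIO]) -> Tuple[GridSpec, np.ndarray]:
    if isinstance(path, str) and "\n" in path:
        handle = StringIO(path)
    elif isinstance(path, str):
        handle = open(path)
    else:
        handle = path
    header: Dict[str, float] = {}
    pos = handle.tell()
    for _ in range(6):
        parts = handle.readline().split()
        if len(parts) != 2 or parts[0].lower() not in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            raise ValueError("malformed ESRI ASCII grid header")
        header[parts[0].lower()] = float(parts[1])
    spec = GridSpec(
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )
    data = np.loadtxt(handle, dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (spec.nrows, spec.ncols):
        raise ValueError(
            f"grid body {data.shape} does not match header "
            f"({spec.nrows}, {spec.ncols})"
        )
    return spec, data


def read_ascii_grid(
    min_source: Union[str, StringIO],
    mean_source: Union[str, StringIO],
    max_source: Union[str, StringIO],
) -> SstRaster:
    """Read three ESRI ASCII grids (min, mean, max SST) with identical
    headers into a validated :class:`SstRaster`."""
    spec_min, tmin = _read_one_grid(min_source)
    spec_mean, tmean = _read_one_grid(mean_source)
    spec_max, tmax = _read_one_grid(max_source)
    if spec_min != spec_mean or spec_min != spec_max:
        raise ValueError("layer headers do not match")
    return SstRaster(spec=spec_min, tmin=tmin, tmean=tmean, tmax=tmax)


def write_ascii_grid(path: str, spec: GridSpec, data: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"ncols {spec.ncols}\nnrows {spec.nrows}\n"
            f"xllcorner {spec.xllcorner:.10g}\nyllcorner {spec.yllcorner:.10g}\n"
            f"cellsize {spec.cellsize:.10g}\nNODATA_value {spec.nodata:.10g}\n"
        )
        np.savetxt(fh, data, fmt="%.6g")


def extract_sst(
    raster: SstRaster,
    lat: float,
    lon: float,
    search_radius: int = 2,
) -> Tuple[float, float, float]:
    """(min, mean, max) SST at a point.

    The containing cell's values are used if valid; otherwise the nearest
    valid cell by center distance within ``search_radius`` cells
    (Chebyshev), ties broken in row-major order.  Raises if the point is
    outside the grid or no valid cell lies within the radius.
    """
    row, col = raster.spec.locate(lat, lon)
    valid = raster.valid_mask()
    if valid[row, col]:
        r, c = row, col
    else:
        best = None
        for dr in range(-search_radius, search_radius + 1):
            for dc in range(-search_radius, search_radius + 1):
                rr, cc = row + dr, col + dc
                if 0 <= rr < raster.spec.nrows and 0 <= cc < raster.spec.ncols:
                    if valid[rr, cc]:
                        dist = math.hypot(dr, dc)
                        key = (dist, rr, cc)
                        if best is None or key < best:
                            best = key
        if best is None:
            raise ValueError(
                f"no valid cell within {search_radius} cells of ({lat}, {lon})"
            )
        _, r, c = best
    return (
        float(raster.tmin[r, c]),
        float(raster.tmean[r, c]),
        float(raster.tmax[r, c]),
    )


def _lon_range(lons: np.ndarray, circular: bool) -> float:
    if not circular or len(lons) < 2:
        return float(np.max(lons) - np.min(lons))
    # minimal covering arc on the circle
    s = np.sort(np.mod(lons, 360.0))
    gaps = np.diff(np.concatenate([s, [s[0] + 360.0]]))
    return float(360.0 - np.max(gaps))


def summarize_species(
    records: Sequence[OccurrenceRecord],
    raster: SstRaster,
    search_radius: int = 2,
    circular_lon: bool = False,
) -> List[SpeciesThermalSummary]:
    """Per-species geographic range and SST summaries.

    Records whose extraction fails (outside the grid, or no valid cell in
    radius) are dropped with a warning; a species with no surviving record
    is omitted with a warning.  Latitudinal range is max - min latitude;
    longitudinal range is the raw max - min span on [-180, 180] unless
    ``circular_lon`` asks for the minimal covering arc.
    """
    by_species: Dict[str, list] = {}
    for rec in records:
        by_species.setdefault(rec.species, []).append(rec)
    out = []
    for sp in sorted(by_species):
        rows = []
        for rec in by_species[sp]:
            try:
                tmin, tmean, tmax = extract_sst(
                    raster, rec.lat, rec.lon, search_radius=search_radius
                )
            except ValueError as exc:
                warnings.warn(f"{sp}: dropped record ({rec.lat}, {rec.lon}): {exc}")
                continue
            rows.append((rec.lat, rec.lon, tmin, tmean, tmax))
        if not rows:
            warnings.warn(f"{sp}: all records failed extraction; species omitted")
            continue
        arr = np.asarray(rows)
        lats, lons = arr[:, 0], arr[:, 1]
        tmin, tmean, tmax = arr[:, 2], arr[:, 3], arr[:, 4]
        out.append(
            SpeciesThermalSummary(
                species=sp,
                n=len(rows),
                lat_range=float(np.max(lats) - np.min(lats)),
                lon_range=_lon_range(lons, circular_lon),
                max_c=float(np.mean(tmax)),
                mean_c=float(np.mean(tmean)),
                min_c=float(np.mean(tmin)),
                max_range_c=float(np.max(tmax) - np.min(tmin)),
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[SpeciesThermalSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                s.species, s.n, s.lat_range, s.lon_range,
                s.max_c, s.mean_c, s.min_c, s.max_range_c,
            )
            for s in summaries
        ],
        columns=[
            "species", "n", "lat_range", "lon_range",
            "max_c", "mean_c", "min_c", "max_range_c",
        ],
    )
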