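"""Gridded environmental layers on a common geographic grid.

Layers are single-band rasters in geographic coordinates (WGS84 degrees).
A cell's value applies to the whole cell; cells are half-open rectangles
with the grid origin at the upper-left corner, so a point maps to the cell
whose fractional index floors to it.  An :class:`EnvStack` holds several
layers on one grid together with a shared validity mask (the conjunction of
the per-layer masks).

Supported on-disk formats are single-band GeoTIFF (georeferencing via the
ModelPixelScale/ModelTiepoint tags, nodata via the GDAL_NODATA tag) and the
ESRI ASCII grid dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

WGS84 = "EPSG:4326"

GROUPS = ("climatic", "soil", "vegetation_landcover")


class RasterError(ValueError):
    """Malformed raster input."""


class GeoreferenceError(RasterError):
    """A raster file without usable georeferencing."""


@dataclass(frozen=True)
class Affine:
    """Axis-aligned affine transform between cell indices and coordinates.

    ``xy(col, row)`` maps fractional cell indices to geographic coordinates;
    index (0, 0) is the upper-left *corner* of the upper-left cell, so the
    centre of cell (row=i, col=j) sits at ``xy(j + 0.5, i + 0.5)``.
    """

    a: float  # x cell size
    c: float  # x of upper-left corner
    e: float  # y cell size (negative: rows run north -> south)
    f: float  # y of upper-left corner

    def xy(self, col, row):
        return self.c + self.a * np.asarray(col), self.f + self.e * np.asarray(row)

    def colrow(self, x, y):
        """Inverse map: geographic coordinates -> fractional cell indices."""
        return (np.asarray(x) - self.c) / self.a, (np.asarray(y) - self.f) / self.e

    def almost_equals(self, other: "Affine", tol: float = 1e-9) -> bool:
        return all(
            abs(getattr(self, k) - getattr(other, k)) <= tol for k in "acef"
        )


@dataclass
class RasterGrid:
    """A single-band raster: values + georeferencing."""

    values: np.ndarray
    transform: Affine
    nodata: float | None = None
    crs_id: str = WGS84

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RasterError("raster values must be a 2-D array")
        if self.transform.a == 0 or self.transform.e == 0:
            raise GeoreferenceError("degenerate transform (zero cell size)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid of valid cells."""
        m = np.isfinite(self.values)
        if self.nodata is not None:
            m &= self.values != self.nodata
        return m

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        nr, nc = self.shape
        xs, ys = self.transform.xy([0, nc], [0, nr])
        return min(xs), min(ys), max(xs), max(ys)

    def cell_of(self, lon, lat):
        """Map points to (row, col) integer indices (may fall outside)."""
        col, row = self.transform.colrow(lon, lat)
        return np.floor(row).astype(int), np.floor(col).astype(int)

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("geotiff", "ascii_grid"):
            raise RasterError(f"unknown raster format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    if suffix in (".asc", ".grd", ".txt"):
        return "ascii_grid"
    raise RasterError(f"cannot infer raster format from {path!r}")


def read_grid(path: str | Path, fmt: str | None = None) -> RasterGrid:
    """Read a single-band raster from GeoTIFF or ESRI ASCII grid."""
    path = Path(path)
    if not path.exists():
        raise RasterError(f"raster file not found: {path}")
    fmt = _infer_format(path, fmt)
    if fmt == "ascii_grid":
        return _read_ascii(path)
    return _read_geotiff(path)


def write_grid(grid: RasterGrid, path: str | Path, fmt: str | None = None) -> Path:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "ascii_grid":
        _write_ascii(grid, path)
    else:
        _write_geotiff(grid, path)
    return path


def _read_ascii(path: Path) -> RasterGrid:
    header: dict[str, float] = {}
    lines = path.read_text().splitlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    required = {"ncols", "nrows", "cellsize"}
    if not required <= set(header):
        raise GeoreferenceError(
            f"{path.name}: ASCII grid header missing georeferencing "
            f"(need ncols/nrows/cellsize and a lower-left origin)"
        )
    if "xllcorner" in header:
        x0, y0 = header["xllcorner"], header["yllcorner"]
    elif "xllcenter" in header:
        x0 = header["xllcenter"] - header["cellsize"] / 2
        y0 = header["yllcenter"] - header["cellsize"] / 2
    else:
        raise GeoreferenceError(f"{path.name}: no lower-left origin in header")
    values = np.loadtxt(lines[n_header:], dtype=float)
    values = np.atleast_2d(values)
    nr, nc = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nr, nc):
        raise RasterError(
            f"{path.name}: grid body {values.shape} does not match header ({nr}, {nc})"
        )
    cs = header["cellsize"]
    transform = Affine(a=cs, c=x0, e=-cs, f=y0 + nr * cs)
    return RasterGrid(values, transform, nodata=header.get("nodata_value"))


def _write_ascii(grid: RasterGrid, path: Path) -> None:
    t = grid.transform
    if abs(abs(t.a) - abs(t.e)) > 1e-12 * abs(t.a):
        raise RasterError("ASCII grids require square cells")
    nr, nc = grid.shape
    nodata = grid.nodata if grid.nodata is not None else -9999.0
    values = np.where(grid.mask, grid.values, nodata)
    def fmt(v) -> str:
        return format(float(v), ".17g")

    header = (
        f"ncols {nc}\nnrows {nr}\n"
        f"xllcorner {fmt(t.c)}\nyllcorner {fmt(t.f + t.e * nr)}\n"
        f"cellsize {fmt(t.a)}\nNODATA_value {fmt(nodata)}\n"
    )
    body = "\n".join(" ".join(fmt(v) for v in row) for row in values)
    path.write_text(header + body + "\n")


def _read_geotiff(path: Path) -> RasterGrid:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        if values.ndim == 3:
            if values.shape[2] != 1:
                raise RasterError(f"{path.name}: multi-band GeoTIFF not supported")
            values = values[:, :, 0]
        tags = page.tags
        if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
            raise GeoreferenceError(
                f"{path.name}: GeoTIFF lacks ModelPixelScale/ModelTiepoint georeferencing"
            )
        sx, sy = tags[_MODEL_PIXEL_SCALE].value[:2]
        tie = tags[_MODEL_TIEPOINT].value
        # tiepoint: raster (i, j, k) -> model (x, y, z)
        i, j = tie[0], tie[1]
        x, y = tie[3], tie[4]
        transform = Affine(a=sx, c=x - i * sx, e=-sy, f=y + j * sy)
        nodata = None
        if _GDAL_NODATA in tags:
            try:
                nodata = float(str(tags[_GDAL_NODATA].value).strip("\x00 "))
            except ValueError:
                nodata = None
    return RasterGrid(values, transform, nodata=nodata)


def _write_geotiff(grid: RasterGrid, path: Path) -> None:
    import tifffile

    t = grid.transform
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (abs(t.a), abs(t.e), 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.c, t.f, 0.0)),
        # minimal GeoKey directory declaring geographic WGS84
        (_GEO_KEY_DIRECTORY, "H", 16,
         (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)),
    ]
    if grid.nodata is not None:
        extratags.append((_GDAL_NODATA, "s", 0, str(grid.nodata)))
    tifffile.imwrite(str(path), grid.values, extratags=extratags)


# ---------------------------------------------------------------------------
# Stacks
# ---------------------------------------------------------------------------

@dataclass
class EnvStack:
    """Named, grouped environmental layers sharing one grid and mask."""

    layers: dict[str, RasterGrid]
    groups: dict[str, str]
    kind: dict[str, str]  # name -> continuous | categorical
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise RasterError("duplicate layer names")
        ref = next(iter(self.layers.values()))
        for name, g in self.layers.items():
            if g.shape != ref.shape or not g.transform.almost_equals(ref.transform):
                raise RasterError(f"layer {name!r} not aligned with the stack grid")
        for name in names:
            self.groups.setdefault(name, "climatic")
            self.kind.setdefault(name, "continuous")
            if self.groups[name] not in GROUPS:
                raise RasterError(f"unknown group {self.groups[name]!r} for {name!r}")
        if self.mask is None:
            m = np.ones(ref.shape, dtype=bool)
            for g in self.layers.values():
                m &= g.mask
            self.mask = m

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def transform(self) -> Affine:
        return next(iter(self.layers.values())).transform

    def continuous_names(self) -> list[str]:
        return [n for n in self.names if self.kind[n] == "continuous"]

    def background_table(self) -> pd.DataFrame:
        """One row per valid cell, one column per layer."""
        rows, cols = np.nonzero(self.mask)
        data = {n: self.layers[n].values[rows, cols] for n in self.names}
        df = pd.DataFrame(data)
        df.insert(0, "row", rows)
        df.insert(1, "col", cols)
        return df

    def subset(self, names: Sequence[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise RasterError(f"layers not in stack: {missing}")
        return EnvStack(
            layers={n: self.layers[n] for n in names},
            groups={n: self.groups[n] for n in names},
            kind={n: self.kind[n] for n in names},
            mask=self.mask,
        )


def _resample(grid: RasterGrid, template: RasterGrid, order: int) -> np.ndarray:
    nr, nc = template.shape
    cols, rows = np.meshgrid(np.arange(nc) + 0.5, np.arange(nr) + 0.5)
    x, y = template.transform.xy(cols, rows)
    scol, srow = grid.transform.colrow(x, y)
    vals = np.where(grid.mask, grid.values, np.nan)
    snr, snc = grid.shape
    inside = (srow >= 0) & (srow <= snr) & (scol >= 0) & (scol <= snc)
    out = ndimage.map_coordinates(
        vals, [srow - 0.5, scol - 0.5], order=order, mode="nearest"
    )
    out[~inside] = np.nan
    return out


def align_stack(
    grids: Mapping[str, RasterGrid],
    template: RasterGrid,
    method: str = "bilinear",
    groups: Mapping[str, str] | None = None,
    kinds: Mapping[str, str] | None = None,
) -> EnvStack:
    """Resample every grid onto the template grid.

    Continuous layers use the requested method (bilinear by default);
    categorical layers are always resampled nearest-neighbour.
    """
    if method not in ("nearest", "bilinear"):
        raise RasterError(f"unknown resampling method {method!r}")
    groups = dict(groups or {})
    kinds = dict(kinds or {})
    txmin, tymin, txmax, tymax = template.bounds()
    out: dict[str, RasterGrid] = {}
    for name, grid in grids.items():
        if grid.crs_id != template.crs_id:
            raise RasterError(
                f"layer {name!r}: CRS {grid.crs_id} does not match template "
                f"{template.crs_id} and reprojection is not supported"
            )
        gxmin, gymin, gxmax, gymax = grid.bounds()
        if gxmin >= txmax or gxmax <= txmin or gymin >= tymax or gymax <= tymin:
            raise RasterError(f"layer {name!r} lies entirely outside the template extent")
        if grid.shape == template.shape and grid.transform.almost_equals(template.transform):
            values = np.where(grid.mask, grid.values, np.nan)
        else:
            kind = kinds.get(name, "continuous")
            order = 0 if (kind == "categorical" or method == "nearest") else 1
            values = _resample(grid, template, order)
        out[name] = RasterGrid(values, template.transform, nodata=None,
                               crs_id=template.crs_id)
    return EnvStack(layers=out, groups=groups, kind=kinds)


def extract_at(stack: EnvStack, points: Iterable[tuple[float, float]]) -> pd.DataFrame:
    """Extract covariate rows at lon/lat points.

    Returns one row per point with a ``status`` column: ``ok``, ``masked``
    (point hits a nodata cell) or ``out_of_extent``.  Out-of-extent points
    yield an explicit error record rather than being dropped.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.size == 0:
        return pd.DataFrame(columns=["lon", "lat", "status", *stack.names])
    lon, lat = pts[:, 0], pts[:, 1]
    ref = next(iter(stack.layers.values()))
    rows, cols = ref.cell_of(lon, lat)
    nr, nc = stack.shape
    inside = (rows >= 0) & (rows < nr) & (cols >= 0) & (cols < nc)
    status = np.where(inside, "ok", "out_of_extent").astype(object)
    r_safe = np.clip(rows, 0, nr - 1)
    c_safe = np.clip(cols, 0, nc - 1)
    masked = inside & ~stack.mask[r_safe, c_safe]
    status[masked] = "masked"
    data: dict[str, np.ndarray] = {"lon": lon, "lat": lat}
    for name in stack.names:
        vals = stack.layers[name].values[r_safe, c_safe]
        vals = np.where(status == "ok", vals, np.nan)
        data[name] = vals
    data["status"] = status
    df = pd.DataFrame(data)
    return df[["lon", "lat", "status", *stack.names]]


def read_manifest(path: str | Path) -> tuple[dict[str, RasterGrid], dict[str, str], dict[str, str]]:
    """Read a layer manifest CSV (name,group,kind,path) into grids + metadata."""
    path = Path(path)
    df = pd.read_csv(path)
    needed = {"name", "group", "kind", "path"}
    if not needed <= set(c.lower() for c in df.columns):
        raise RasterError(f"manifest {path} must have columns {sorted(needed)}")
    df.columns = [c.lower() for c in df.columns]
    grids, groups, kinds = {}, {}, {}
    for rec in df.itertuples(index=False):
        layer_path = Path(rec.path)
        if not layer_path.is_absolute():
            layer_path = path.parent / layer_path
        if not layer_path.exists():
            raise RasterError(f"manifest layer {rec.name!r}: file not found: {layer_path}")
        grids[rec.name] = read_grid(layer_path)
        groups[rec.name] = rec.group
        kinds[rec.name] = rec.kind
    return grids, groups, kinds
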