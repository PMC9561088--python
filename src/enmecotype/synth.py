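"""Synthetic correlated-raster landscapes with planted ecotype structure.

The generator emulates the statistical shape of a gridded environmental
stack: several mutually correlated continuous layers (smoothed Gaussian
random fields mixed through the Cholesky factor of a target correlation
matrix), one categorical land-cover-style layer, K latent "ecotype"
suitability surfaces with distinct environmental optima on a subset of
driver layers, and a village sampling design (districts of a few villages,
each village expanded to ten occurrence points) whose village centres are
drawn with probability proportional to their ecotype's true suitability.

Every stochastic step takes an explicit seed, so identical specs reproduce
identical landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .occurrences import OccurrenceSet, SamplingTable, classify_altitude, expand_all
from .raster import Affine, EnvStack, RasterGrid


@dataclass
class LandscapeSpec:
    """Recipe for one synthetic environmental stack."""

    shape: tuple[int, int] = (64, 64)
    layer_names: tuple[str, ...] = (
        "temp_max", "temp_wet", "precip_wet",
        "soil_clay", "grass_cover", "soil_noise", "veg_noise",
    )
    groups: dict[str, str] = field(default_factory=lambda: {
        "temp_max": "climatic", "temp_wet": "climatic", "precip_wet": "climatic",
        "soil_clay": "soil", "grass_cover": "vegetation_landcover",
        "soil_noise": "soil", "veg_noise": "vegetation_landcover",
    })
    correlation: np.ndarray | None = None  # defaults to paired driver/distractor blocks
    categorical_name: str | None = "landcover_class"
    categorical_levels: int = 4
    smooth_sigma: float = 3.0
    # per-layer smoothness overrides: the pure-noise decoys emulate
    # fine-grained nuisance layers with negligible spatial structure
    smooth_sigma_overrides: dict[str, float] = field(default_factory=lambda: {
        "soil_noise": 0.5, "veg_noise": 0.5,
    })
    origin: tuple[float, float] = (38.0, 14.0)  # lon, lat of the upper-left corner
    cellsize: float = 0.009  # degrees, ~1 km
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
        else:
            n = len(self.layer_names)
            c = np.eye(n)
            pairs = [("temp_max", "soil_clay", 0.7), ("precip_wet", "grass_cover", 0.7)]
            idx = {name: i for i, name in enumerate(self.layer_names)}
            for a, b, r in pairs:
                if a in idx and b in idx:
                    c[idx[a], idx[b]] = c[idx[b], idx[a]] = r
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        if np.min(np.linalg.eigvalsh(c)) < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")
        return c


@dataclass
class EcotypeTruth:
    """Planted ecotype optima on the driver layers."""

    drivers: tuple[str, ...] = ("temp_max", "temp_wet", "precip_wet")
    optima: dict[str, tuple[float, ...]] = field(default_factory=lambda: {
        "E1": (1.2, 1.2, 0.9),
        "E2": (1.2, -1.2, 0.9),
        "E3": (-1.2, 1.2, -0.9),
        "E4": (-1.2, -1.2, -0.9),
    })
    widths: tuple[float, ...] = (0.3, 0.3, 0.3)

    def __post_init__(self):
        vecs = list(self.optima.values())
        for i, a in enumerate(vecs):
            for b in vecs[i + 1:]:
                if np.allclose(a, b):
                    raise ValueError("ecotype optima must be distinct")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive")

    @property
    def ecotypes(self) -> list[str]:
        return list(self.optima)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return (f - f.mean()) / f.std()


def gen_layers(spec: LandscapeSpec) -> EnvStack:
    """Build the environmental stack described by a landscape spec."""
    rng = np.random.default_rng(spec.seed)
    corr = spec.correlation_matrix()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(corr)))
    base = np.stack([
        _smooth_field(
            rng, spec.shape,
            spec.smooth_sigma_overrides.get(name, spec.smooth_sigma),
        )
        for name in spec.layer_names
    ])
    mixed = np.einsum("ij,jrc->irc", chol, base)
    transform = Affine(a=spec.cellsize, c=spec.origin[0],
                       e=-spec.cellsize, f=spec.origin[1])
    layers: dict[str, RasterGrid] = {}
    groups: dict[str, str] = {}
    kinds: dict[str, str] = {}
    for i, name in enumerate(spec.layer_names):
        layers[name] = RasterGrid(mixed[i], transform)
        groups[name] = spec.groups.get(name, "climatic")
        kinds[name] = "continuous"
    if spec.categorical_name:
        f = _smooth_field(rng, spec.shape, spec.smooth_sigma)
        qs = np.quantile(f, np.linspace(0, 1, spec.categorical_levels + 1)[1:-1])
        cat = np.digitize(f, qs).astype(float)
        layers[spec.categorical_name] = RasterGrid(cat, transform)
        groups[spec.categorical_name] = "vegetation_landcover"
        kinds[spec.categorical_name] = "categorical"
    return EnvStack(layers=layers, groups=groups, kind=kinds)


def plant_suitability(stack: EnvStack, truth: EcotypeTruth) -> dict[str, np.ndarray]:
    """True suitability per ecotype: product of Gaussians on the driver layers,
    normalised to maximum one."""
    missing = [d for d in truth.drivers if d not in stack.layers]
    if missing:
        raise ValueError(f"driver layers not in stack: {missing}")
    out = {}
    for eco, opt in truth.optima.items():
        s = np.ones(stack.shape)
        for d, o, w in zip(truth.drivers, opt, truth.widths):
            v = stack.layers[d].values
            s = s * np.exp(-((v - o) ** 2) / (2 * w**2))
        peak = s.max()
        if peak <= 0:
            raise ValueError(f"degenerate truth surface for {eco}")
        out[eco] = s / peak
    return out


def snap_optima(stack: EnvStack, truth: EcotypeTruth) -> EcotypeTruth:
    """Snap each ecotype optimum to the nearest realised driver vector.

    Smoothed random fields rarely reach an arbitrary corner of driver space
    jointly, which would leave a planted suitability surface without any
    truly suitable cell.  Snapping each optimum to the closest cell's
    driver values guarantees every ecotype a realised habitat while
    preserving the separation between optima.
    """
    vecs = np.stack(
        [stack.layers[d].values[stack.mask] for d in truth.drivers], axis=1
    )
    snapped = {}
    for eco, opt in truth.optima.items():
        i = int(np.argmin(((vecs - np.asarray(opt)) ** 2).sum(axis=1)))
        snapped[eco] = tuple(float(v) for v in vecs[i])
    return EcotypeTruth(drivers=truth.drivers, optima=snapped, widths=truth.widths)


def _elevation_field(spec: LandscapeSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed + 104729)
    f = _smooth_field(rng, spec.shape, spec.smooth_sigma)
    return np.clip(1700.0 + 700.0 * f, 0.0, None)


def sample_study(
    stack: EnvStack,
    truths: dict[str, np.ndarray],
    n_districts_per_ecotype: int = 4,
    villages_per_district: int = 2,
    n_extra: int = 9,
    area_km2: float = 1.2,
    seed: int = 0,
    elevation: np.ndarray | None = None,
) -> tuple[SamplingTable, pd.DataFrame, OccurrenceSet]:
    """Draw a village sampling design from the planted suitability surfaces.

    Returns (sampling table, district -> generating-ecotype truth labels,
    pooled occurrence set).  Village centres are cells drawn without
    replacement with probability proportional to their ecotype's true
    suitability, jittered uniformly within the cell.
    """
    rng = np.random.default_rng(seed)
    transform = stack.transform
    nr, nc = stack.shape
    if elevation is None:
        elevation = np.clip(
            1700.0 + 700.0 * _smooth_field(
                np.random.default_rng(seed + 104729), stack.shape, 3.0
            ),
            0.0, None,
        )
    rows = []
    truth_rows = []
    d_counter = 0
    for eco, surf in truths.items():
        w = np.where(stack.mask, surf, 0.0).ravel()
        if w.sum() <= 0:
            raise ValueError(f"degenerate truth grid for ecotype {eco}")
        p = w / w.sum()
        for _ in range(n_districts_per_ecotype):
            d_counter += 1
            district = f"D{d_counter:02d}"
            cells = rng.choice(nr * nc, size=villages_per_district,
                               replace=False, p=p)
            for v_i, cell in enumerate(cells, start=1):
                r, c = divmod(int(cell), nc)
                jx, jy = rng.uniform(0.05, 0.95, 2)
                lon, lat = transform.xy(c + jx, r + jy)
                alt = float(elevation[r, c])
                rows.append({
                    "district": district,
                    "village": f"{district}_V{v_i}",
                    "latitude": float(lat),
                    "longitude": float(lon),
                    "altitude": alt,
                    "agroecology": classify_altitude(alt),
                })
            truth_rows.append({"district": district, "ecotype": eco})
    table = SamplingTable(rows=pd.DataFrame(rows))
    occ = expand_all(table, n_extra=n_extra, area_km2=area_km2, seed=seed)
    return table, pd.DataFrame(truth_rows), occ


@dataclass
class SyntheticScenario:
    """A fully generated desk-scale study: stack, truth, design, occurrences."""

    stack: EnvStack
    truth: EcotypeTruth
    suitability: dict[str, np.ndarray]
    table: SamplingTable
    truth_labels: pd.DataFrame
    occurrences: OccurrenceSet
    spec: LandscapeSpec


def make_scenario(
    seed: int = 1,
    spec: LandscapeSpec | None = None,
    truth: EcotypeTruth | None = None,
    n_districts_per_ecotype: int = 4,
    villages_per_district: int = 2,
) -> SyntheticScenario:
    """The packaged desk-scale scenario: 64x64 grid, 7 continuous layers
    (3 climatic drivers + 2 correlated distractors + 2 noise decoys),
    1 categorical layer, 4 planted ecotypes, 16 districts, 32 villages."""
    spec = spec if spec is not None else LandscapeSpec(seed=seed)
    if spec.seed != seed:
        spec = LandscapeSpec(**{**spec.__dict__, "seed": seed})
    truth = truth if truth is not None else EcotypeTruth()
    stack = gen_layers(spec)
    truth = snap_optima(stack, truth)
    suit = plant_suitability(stack, truth)
    elev = _elevation_field(spec)
    table, labels, occ = sample_study(
        stack, suit,
        n_districts_per_ecotype=n_districts_per_ecotype,
        villages_per_district=villages_per_district,
        seed=seed, elevation=elev,
    )
    return SyntheticScenario(
        stack=stack, truth=truth, suitability=suit, table=table,
        truth_labels=labels, occurrences=occ, spec=spec,
    )
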