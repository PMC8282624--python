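"""Virtual environments, virtual species and climate scenarios with known ground truth.

This module generates the inputs the rest of the pipeline consumes in tests and
demos: spatially autocorrelated predictor rasters on a geographic grid, species
whose occurrence probability follows known Gaussian niche responses, presence
records sampled from those probabilities (optionally with observer bias), and
additive/multiplicative climate deltas emulating emission-scenario forcing.

Because the niches are analytically known, every downstream stage (ensemble
suitability, stacking, dominance, range shifts) can be checked against truth.

Conventions (used everywhere in the package):
    * geographic degrees, north-up: row 0 is the northernmost row;
    * cell-center registration; half-open cell intervals, so a point on the
      shared edge of two cells belongs to the cell on the south/east side;
    * missing data is carried as NaN plus a boolean mask (True = missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GridSpec",
    "EnvStack",
    "NicheSpec",
    "ClimateDelta",
    "OccurrenceSet",
    "CLIMATE_LAYERS",
    "generate_landscape",
    "true_suitability",
    "sample_occurrences",
    "apply_climate_delta",
]

#: Layers a climate delta is allowed to touch. Elevation, slope and soil
#: properties are static landscape attributes and never altered by a scenario.
CLIMATE_LAYERS = frozenset({"temperature", "precipitation", "precip_seasonality"})


@dataclass(frozen=True)
class GridSpec:
    """Regular geographic grid, cell-center registered, row 0 = north."""

    n_rows: int
    n_cols: int
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not (self.lat_max > self.lat_min):
            raise ValueError("lat_max must exceed lat_min")
        if not (self.lon_max > self.lon_min):
            raise ValueError("lon_max must exceed lon_min")

    @property
    def cell_height(self) -> float:
        return (self.lat_max - self.lat_min) / self.n_rows

    @property
    def cell_width(self) -> float:
        return (self.lon_max - self.lon_min) / self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes per row, north to south."""
        return self.lat_max - (np.arange(self.n_rows) + 0.5) * self.cell_height

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.cell_width

    def cell_of(self, lon, lat):
        """Row/col indices of the cells containing the given points.

        Half-open intervals: a point exactly on an interior cell edge falls in
        the south/east cell; points on the outer max edges are kept inside.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.cell_width).astype(int)
        row = np.floor((self.lat_max - lat) / self.cell_height).astype(int)
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row, col

    def contains(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )


@dataclass
class EnvStack:
    """Named co-registered raster layers on one grid.

    ``mask`` is True where data is missing; it applies to every layer
    identically (e.g. ocean cells).
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"layer {name!r} shape {arr.shape} != grid shape {self.grid.shape}"
                )
        if self.mask is None:
            self.mask = np.zeros(self.grid.shape, dtype=bool)
        elif self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def copy(self) -> "EnvStack":
        return EnvStack(
            grid=self.grid,
            layers={k: v.copy() for k, v in self.layers.items()},
            mask=self.mask.copy(),
        )

    def table(self, variables: list[str] | None = None) -> np.ndarray:
        """(n_valid_cells, n_vars) matrix of layer values at unmasked cells."""
        variables = variables or self.layer_names
        valid = ~self.mask
        return np.column_stack([self.layers[v][valid] for v in variables])


@dataclass(frozen=True)
class NicheSpec:
    """Gaussian niche of a virtual species: independent bell responses per variable."""

    species_id: str
    optima: dict[str, float]
    breadths: dict[str, float]
    max_prob: float = 1.0

    def __post_init__(self) -> None:
        if not self.optima:
            raise ValueError("niche must reference at least one variable")
        if set(self.optima) != set(self.breadths):
            raise ValueError("optima and breadths must name the same variables")
        if any(b <= 0 for b in self.breadths.values()):
            raise ValueError("niche breadths must be strictly positive")
        if not (0 < self.max_prob <= 1):
            raise ValueError("max occurrence probability must be in (0, 1]")


@dataclass(frozen=True)
class ClimateDelta:
    """Scenario forcing: per-layer offsets and/or multiplicative factors.

    Values may be scalars or grids. Only climate layers may be named.
    """

    label: str
    offsets: dict = field(default_factory=dict)
    factors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in list(self.offsets) + list(self.factors):
            if name not in CLIMATE_LAYERS:
                raise ValueError(
                    f"delta names non-climate layer {name!r}; "
                    f"allowed: {sorted(CLIMATE_LAYERS)}"
                )
        for name, f in self.factors.items():
            if np.any(np.asarray(f) <= 0):
                raise ValueError(f"multiplicative factor for {name!r} must be > 0")


@dataclass
class OccurrenceSet:
    """Species presence records in geographic coordinates."""

    species: np.ndarray  # array of species id strings
    lon: np.ndarray
    lat: np.ndarray
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species, dtype=object)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if not (len(self.species) == len(self.lon) == len(self.lat)):
            raise ValueError("species/lon/lat must have equal length")

    def __len__(self) -> int:
        return len(self.species)

    def subset(self, species_id: str) -> "OccurrenceSet":
        keep = self.species == species_id
        return OccurrenceSet(
            self.species[keep], self.lon[keep], self.lat[keep], self.provenance
        )

    def species_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.species:
            seen.setdefault(s)
        return list(seen)


def _smooth_field(rng: np.random.Generator, shape, correlation_length: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated field: Gaussian-filtered white noise."""
    white = rng.standard_normal(shape)
    if correlation_length <= 0:
        return white
    f = ndimage.gaussian_filter(white, sigma=correlation_length, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_landscape(grid: GridSpec, params: dict | None = None, seed: int = 0) -> EnvStack:
    """Generate a synthetic environmental stack with elevation-driven climate.

    Elevation is a non-negative smooth random field, optionally with a
    west-east linear ramp and/or a central mountain ridge. Temperature follows
    a sea-level field minus ``lapse_rate`` x elevation; precipitation has a
    configurable latitudinal gradient plus autocorrelated noise; slope is the
    finite-difference gradient magnitude of elevation. Soil layers are smooth
    random fields in realistic ranges. Deterministic for a given seed.

    Parameters (``params`` keys, with defaults):
        lapse_rate (0.0065 degC/m), autocorrelation_length (5 cells),
        elevation_relief (1500 m), elevation_ramp (0 m, west->east),
        ridge_height (0 m), sea_level_temp (27 degC), temp_noise (1 degC),
        precip_base (2000 mm), precip_lat_gradient (-50 mm/deg northwards),
        precip_noise (400 mm), seasonality_base (60 %), seasonality_noise (15 %).
    """
    p = {
        "lapse_rate": 0.0065,
        "autocorrelation_length": 5.0,
        "elevation_relief": 1500.0,
        "elevation_ramp": 0.0,
        "ridge_height": 0.0,
        "sea_level_temp": 27.0,
        "temp_noise": 1.0,
        "precip_base": 2000.0,
        "precip_lat_gradient": -50.0,
        "precip_noise": 400.0,
        "seasonality_base": 60.0,
        "seasonality_noise": 15.0,
    }
    p.update(params or {})
    if p["lapse_rate"] < 0:
        raise ValueError("lapse rate must be >= 0")

    rng = np.random.default_rng(seed)
    shape = grid.shape
    L = p["autocorrelation_length"]

    relief = _smooth_field(rng, shape, L)
    elev = p["elevation_relief"] * (relief - relief.min()) / max(
        relief.max() - relief.min(), 1e-12
    )
    if p["elevation_ramp"]:
        ramp = np.linspace(0.0, 1.0, grid.n_cols)[None, :]
        elev = elev + p["elevation_ramp"] * ramp
    if p["ridge_height"]:
        # Gaussian ridge running north-south through the grid center.
        x = np.arange(grid.n_cols)
        ridge = np.exp(-0.5 * ((x - grid.n_cols / 2) / (grid.n_cols / 8)) ** 2)
        elev = elev + p["ridge_height"] * ridge[None, :]
    elev = np.maximum(elev, 0.0)

    sea_level_temp = p["sea_level_temp"] + p["temp_noise"] * _smooth_field(rng, shape, L)
    temperature = sea_level_temp - p["lapse_rate"] * elev

    lat_grid = np.repeat(grid.lat_centers()[:, None], grid.n_cols, axis=1)
    precip = (
        p["precip_base"]
        + p["precip_lat_gradient"] * (lat_grid - grid.lat_min)
        + p["precip_noise"] * _smooth_field(rng, shape, L)
    )
    precip = np.maximum(precip, 0.0)

    seasonality = np.clip(
        p["seasonality_base"] + p["seasonality_noise"] * _smooth_field(rng, shape, L),
        0.0,
        100.0,
    )

    # slope in degrees from finite differences; cell size approximated as the
    # latitudinal cell height in meters (adequate for synthetic terrain).
    cell_m = grid.cell_height * 111_320.0
    gy, gx = np.gradient(elev, cell_m)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))

    soil_sand = np.clip(45 + 15 * _smooth_field(rng, shape, L), 0, 100)
    soil_clay = np.clip(30 + 10 * _smooth_field(rng, shape, L), 0, 100)
    soil_ph = np.clip(6.0 + 0.6 * _smooth_field(rng, shape, L), 3.5, 9.0)

    return EnvStack(
        grid=grid,
        layers={
            "temperature": temperature,
            "precipitation": precip,
            "precip_seasonality": seasonality,
            "soil_sand": soil_sand,
            "soil_clay": soil_clay,
            "soil_ph": soil_ph,
            "elevation": elev,
            "slope": slope,
        },
    )


def true_suitability(env: EnvStack, niche: NicheSpec) -> np.ndarray:
    """Ground-truth occurrence probability: product of Gaussian responses.

    ``max_prob * prod_v exp(-(x_v - opt_v)^2 / (2 breadth_v^2))``, NaN on
    masked cells.
    """
    missing = [v for v in niche.optima if v not in env.layers]
    if missing:
        raise KeyError(f"niche references missing variable(s): {missing}")
    suit = np.full(env.grid.shape, niche.max_prob, dtype=float)
    for v, opt in niche.optima.items():
        b = niche.breadths[v]
        suit = suit * np.exp(-0.5 * ((env.layers[v] - opt) / b) ** 2)
    suit[env.mask] = np.nan
    return suit


def sample_occurrences(
    env: EnvStack,
    niche: NicheSpec,
    n: int,
    bias: np.ndarray | None = None,
    seed: int = 0,
) -> OccurrenceSet:
    """Draw presence records with cell probability proportional to suitability x bias.

    Cells are drawn with replacement (several records may land in one cell, so
    grid thinning is exercised downstream); coordinates are jittered uniformly
    within the cell.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    suit = true_suitability(env, niche)
    w = np.where(np.isnan(suit), 0.0, suit)
    if bias is not None:
        if bias.shape != env.grid.shape:
            raise ValueError("bias grid shape mismatch")
        w = w * np.where(np.isnan(bias), 0.0, np.clip(bias, 0, None))
    total = w.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero; species cannot occur")
    rng = np.random.default_rng(seed)
    flat_idx = rng.choice(w.size, size=n, replace=True, p=(w / total).ravel())
    rows, cols = np.unravel_index(flat_idx, w.shape)
    g = env.grid
    jit_lon = rng.uniform(0, 1, n)
    jit_lat = rng.uniform(0, 1, n)
    lon = g.lon_min + (cols + jit_lon) * g.cell_width
    lat = g.lat_max - (rows + jit_lat) * g.cell_height
    return OccurrenceSet(
        species=np.full(n, niche.species_id, dtype=object),
        lon=lon,
        lat=lat,
        provenance="synthetic",
    )


def apply_climate_delta(env: EnvStack, delta: ClimateDelta) -> EnvStack:
    """Return a scenario stack: climate layers transformed as x*factor + offset.

    Non-climate layers (elevation, slope, soils) are copied unchanged; the
    input stack is not modified.
    """
    out = env.copy()
    for name in set(delta.offsets) | set(delta.factors):
        if name not in env.layers:
            raise KeyError(f"delta names layer {name!r} absent from the stack")
    for name, f in delta.factors.items():
        out.layers[name] = out.layers[name] * f
    for name, o in delta.offsets.items():
        out.layers[name] = out.layers[name] + o
    return out
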