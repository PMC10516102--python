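"""Simulated landscapes and virtual species.

Generates inputs with the statistical structure the downstream analysis
assumes: a stack of spatially autocorrelated, inter-correlated climate
fields (standing in for the 19 bioclimatic variables), scenario-shifted
future climates (standing in for AOGCM projections under emission
scenarios), a categorical vegetation-cover raster whose classes respond
to climate, connected protected-area footprints, and virtual species
with known Gaussian niches that provide ground truth for parameter
recovery.

Every operation is deterministic under its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .raster import ClimateStack, RasterGrid

__all__ = [
    "BIOCLIM_NAMES",
    "LANDCOVER_ALLOWED",
    "LANDCOVER_CLASSES",
    "PA_CATEGORIES",
    "SyntheticConfig",
    "VirtualSpecies",
    "ScenarioShift",
    "PAUnit",
    "generate_climate",
    "generate_future",
    "default_scenario_shifts",
    "make_virtual_species",
    "sample_presences",
    "generate_protected_areas",
    "generate_landcover",
]

#: Conventional names for the 19 bioclimatic predictors.
BIOCLIM_NAMES = tuple(f"bio{i:02d}" for i in range(1, 20))

#: Vegetation classes within which modelled ranges are retained.
LANDCOVER_ALLOWED = (
    "Broadleaf evergreen tree, tropical",
    "Broadleaf deciduous tree, tropical",
    "Broadleaf deciduous tree, temperate",
    "Broadleaf deciduous tree, boreal",
    "Broadleaf deciduous shrub, temperate",
)

#: Default simulated class set: the five permitted forest classes plus a
#: non-forest class occupying the warm tail of the climate gradient.
LANDCOVER_CLASSES = LANDCOVER_ALLOWED + ("Grassland, C3",)

#: Protected-area management categories: integral protection,
#: sustainable-use, and indigenous lands.
PA_CATEGORIES = ("IPA", "SUA", "IL")


def default_mixing(
    n_vars: int = 19,
    n_temperature: int = 11,
    rho_within: float = 0.95,
    rho_cross: float = 0.5,
) -> np.ndarray:
    """Block-structured inter-variable correlation matrix.

    Emulates bioclim collinearity: a temperature block and a
    precipitation block, strongly correlated within (``rho_within^|i-j|``)
    and moderately across (``rho_cross``).
    """
    n_temperature = min(n_temperature, n_vars)
    idx = np.arange(n_vars)
    same_block = (idx[:, None] < n_temperature) == (idx[None, :] < n_temperature)
    M = np.where(
        same_block,
        rho_within ** np.abs(idx[:, None] - idx[None, :]),
        rho_cross,
    )
    np.fill_diagonal(M, 1.0)
    return M


@dataclass
class SyntheticConfig:
    """Parameters of the simulated landscape.

    ``mixing`` is the target inter-variable correlation matrix
    (n_climate_vars × n_climate_vars, positive definite). The default
    mimics the strong collinearity of real bioclimatic summaries: a
    temperature block (first 11 variables) and a precipitation block
    (rest) with 0.95^|i-j| correlation within blocks and 0.5 across,
    which leaves roughly six principal axes carrying 95% of variance —
    the dimensionality reduction the PCA step exists for.
    ``spatial_range`` is the Gaussian correlation length in cells;
    ``cell_area`` is km² per cell (uniform on synthetic grids).
    """

    grid_rows: int = 60
    grid_cols: int = 60
    cell_area: float = 100.0
    n_climate_vars: int = 19
    spatial_range: float = 10.0
    mixing: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid must be at least 8x8")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        if self.n_climate_vars < 1:
            raise ValueError("need at least one climate variable")
        if self.mixing is None:
            self.mixing = default_mixing(self.n_climate_vars)
        self.mixing = np.asarray(self.mixing, dtype=float)
        if self.mixing.shape != (self.n_climate_vars, self.n_climate_vars):
            raise ValueError(
                f"mixing matrix must be {self.n_climate_vars}x{self.n_climate_vars}, "
                f"got {self.mixing.shape}"
            )

    @property
    def cell_size(self) -> float:
        """Cell edge length in coordinate units (km)."""
        return float(np.sqrt(self.cell_area))

    def variable_names(self) -> list[str]:
        if self.n_climate_vars <= len(BIOCLIM_NAMES):
            return list(BIOCLIM_NAMES[: self.n_climate_vars])
        return [f"var{i:02d}" for i in range(1, self.n_climate_vars + 1)]


@dataclass
class VirtualSpecies:
    """A simulated species with a known Gaussian niche.

    True suitability is the product of per-variable Gaussian responses
    ``exp(-(x - optimum)^2 / (2 breadth^2))`` rescaled to [0, 1]; the
    "true range" is where suitability reaches ``prevalence_threshold``.
    The default cutoff of 0.05 (5% of peak) makes the true range the
    *occupied area*: with occurrences sampled proportional to
    suitability, it contains ~97% of the occurrence probability mass.
    """

    species_id: str
    niche_vars: tuple[str, ...]
    optima: tuple[float, ...]
    breadths: tuple[float, ...]
    prevalence_threshold: float = 0.05

    def __post_init__(self) -> None:
        if len(self.niche_vars) == 0:
            raise ValueError(f"{self.species_id}: niche_vars must be non-empty")
        if not (len(self.niche_vars) == len(self.optima) == len(self.breadths)):
            raise ValueError(f"{self.species_id}: niche fields must have equal length")
        if any(b <= 0 for b in self.breadths):
            raise ValueError(f"{self.species_id}: breadths must be positive")


@dataclass
class ScenarioShift:
    """A per-variable affine climate change: future = present * mult + add."""

    scenario_id: str
    gcm_id: str
    additive_deltas: dict[str, float] = field(default_factory=dict)
    multiplicative_deltas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.multiplicative_deltas.values()):
            raise ValueError("multiplicative factors must be positive")


@dataclass
class PAUnit:
    """A protected area as a connected set of grid cells."""

    pa_id: int
    category: str
    cells: np.ndarray  # (m, 2) int array of (row, col)
    area: float  # km²

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def generate_climate(config: SyntheticConfig) -> ClimateStack:
    """Simulate co-registered, spatially autocorrelated climate layers.

    Each layer is a Gaussian random field (white noise smoothed with a
    kernel of width ``spatial_range`` cells, then re-standardized), and
    the layers are linearly mixed so their inter-variable correlations
    follow ``config.mixing``.
    """
    try:
        chol = np.linalg.cholesky(config.mixing)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "mixing matrix does not imply a positive-definite covariance; "
            "supply a valid correlation matrix"
        ) from exc

    rng = np.random.default_rng(config.seed)
    k, r, c = config.n_climate_vars, config.grid_rows, config.grid_cols
    fields = rng.standard_normal((k, r, c))
    if config.spatial_range > 0:
        for i in range(k):
            fields[i] = gaussian_filter(fields[i], sigma=config.spatial_range, mode="reflect")
    # re-standardize each field (smoothing shrinks variance), then mix
    flat = fields.reshape(k, -1)
    flat = (flat - flat.mean(axis=1, keepdims=True)) / flat.std(axis=1, keepdims=True)
    mixed = chol @ flat

    cell = config.cell_size
    names = config.variable_names()
    layers = {
        name: RasterGrid(mixed[i].reshape(r, c), x0=0.0, y0=r * cell, cell_size=cell)
        for i, name in enumerate(names)
    }
    return ClimateStack(layers, scenario="present")


def generate_future(present: ClimateStack, shift: ScenarioShift) -> ClimateStack:
    """Apply a scenario shift to a present climate stack."""
    for name in list(shift.additive_deltas) + list(shift.multiplicative_deltas):
        if name not in present:
            raise KeyError(f"shift names unknown variable {name!r}")
    layers = {}
    for name, grid in present.layers.items():
        mult = shift.multiplicative_deltas.get(name, 1.0)
        add = shift.additive_deltas.get(name, 0.0)
        layers[name] = grid.with_values(grid.values * mult + add)
    return ClimateStack(layers, scenario=f"{shift.scenario_id}:{shift.gcm_id}")


def default_scenario_shifts(
    variable_names: list[str] | tuple[str, ...] = BIOCLIM_NAMES,
    n_gcms: int = 5,
) -> list[ScenarioShift]:
    """The default 2-scenario × 5-GCM shift set.

    Emulates a mitigation scenario (moderate warming/drying) and a
    high-emission scenario (twice the shift), with five GCM realizations
    spreading ±20% around each scenario mean. Temperature-like variables
    (first 11) warm; precipitation-like variables (rest) dry; magnitudes
    are in standardized-climate units.
    """
    names = list(variable_names)
    temp = names[: min(11, len(names))]
    precip = names[len(temp):]
    gcm_factors = np.linspace(0.8, 1.2, n_gcms)
    shifts = []
    for scen, strength in (("rcp45", 0.6), ("rcp85", 1.2)):
        for g, f in enumerate(gcm_factors, start=1):
            add = {v: strength * f for v in temp}
            add.update({v: -0.5 * strength * f for v in precip})
            shifts.append(ScenarioShift(scen, f"gcm{g}", additive_deltas=add))
    return shifts


def make_virtual_species(climate: ClimateStack, vs: VirtualSpecies) -> RasterGrid:
    """True suitability of a virtual species on a climate stack.

    Product of per-variable Gaussian responses, rescaled so the best
    cell has suitability 1.
    """
    for name in vs.niche_vars:
        if name not in climate:
            raise KeyError(f"{vs.species_id}: niche variable {name!r} not in climate stack")
    grid = climate.grid
    suit = np.ones(grid.shape, dtype=float)
    for name, opt, breadth in zip(vs.niche_vars, vs.optima, vs.breadths):
        x = climate[name].values
        suit *= np.exp(-((x - opt) ** 2) / (2.0 * breadth**2))
    top = np.nanmax(suit)
    if top > 0:
        suit = suit / top
    return grid.with_values(suit)


def sample_presences(true_suit: RasterGrid, n: int, seed: int, species_id: str = "vsp") -> "LabeledPoints":
    """Draw presence points with probability proportional to suitability.

    Points are placed at cell centers; cells may receive multiple points
    (multinomial sampling with replacement).
    """
    from .occurrences import PRESENCE, LabeledPoints

    if n < 1:
        raise ValueError("n must be >= 1")
    p = np.nan_to_num(true_suit.values.ravel(), nan=0.0).astype(float)
    total = p.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample presences")
    rng = np.random.default_rng(seed)
    idx = rng.choice(p.size, size=n, replace=True, p=p / total)
    rows, cols = np.unravel_index(idx, true_suit.shape)
    x, y = true_suit.xy_of(rows, cols)
    return LabeledPoints(
        species_id=species_id,
        coords=np.column_stack([x, y]),
        labels=np.full(n, PRESENCE, dtype=int),
    )


def _neighbors(cell: tuple[int, int]) -> list[tuple[int, int]]:
    r, c = cell
    return [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]


def generate_protected_areas(
    mask: RasterGrid,
    n_pas: int,
    size_range: tuple[int, int],
    seed: int,
    cell_area: float | None = None,
) -> list[PAUnit]:
    """Grow connected protected-area footprints inside a mask.

    Footprints accrete by random-walk from a seed cell, guaranteeing
    connectedness; sizes (in cells) are uniform over ``size_range`` and
    categories are drawn from the three management classes.
    """
    mask_bool = mask.valid_mask() & (np.nan_to_num(mask.values, nan=0.0) > 0)
    inside = set(zip(*np.nonzero(mask_bool)))
    if not inside:
        raise ValueError("mask is empty")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("size_range must satisfy 1 <= lo <= hi")
    if hi > len(inside):
        raise ValueError(f"size_range upper bound {hi} exceeds mask size {len(inside)}")
    if cell_area is None:
        cell_area = mask.cell_size**2

    rng = np.random.default_rng(seed)
    seeds_rc = sorted(inside)
    pas: list[PAUnit] = []
    for pa_id in range(1, n_pas + 1):
        size = int(rng.integers(lo, hi + 1))
        cells: set[tuple[int, int]] = set()
        for _attempt in range(50):
            start = seeds_rc[rng.integers(len(seeds_rc))]
            cells = {start}
            frontier = [nb for nb in _neighbors(start) if nb in inside]
            while len(cells) < size and frontier:
                pick = frontier.pop(int(rng.integers(len(frontier))))
                if pick in cells:
                    continue
                cells.add(pick)
                frontier.extend(nb for nb in _neighbors(pick) if nb in inside and nb not in cells)
            if len(cells) == size:
                break
        else:
            raise RuntimeError(f"could not grow PA of {size} cells inside the mask")
        category = PA_CATEGORIES[rng.integers(len(PA_CATEGORIES))]
        arr = np.array(sorted(cells), dtype=int)
        pas.append(PAUnit(pa_id=pa_id, category=category, cells=arr, area=size * cell_area))
    return pas


def generate_landcover(
    climate: ClimateStack,
    classes: tuple[str, ...] = LANDCOVER_CLASSES,
    seed: int = 0,
    noise_sd: float = 0.15,
) -> RasterGrid:
    """Categorical vegetation-cover raster driven by the first climate layer.

    Class membership follows fixed thresholds on (first layer + small
    seeded noise), so class probabilities vary smoothly with climate and
    a warm-shifted future moves cells monotonically toward the last
    (warm-end, non-forest) class. Cell values are integer codes indexing
    ``classes``.
    """
    if len(classes) < 2:
        raise ValueError("need at least 2 land-cover classes")
    grid = climate.grid
    rng = np.random.default_rng(seed)
    driver = climate[climate.names[0]].values + noise_sd * rng.standard_normal(grid.shape)

    # fixed standard-normal bin edges: first classes share the cool/mid
    # range; the last class occupies the warm tail (top ~15% at present)
    from scipy.stats import norm

    k = len(classes)
    shares = np.full(k, 0.85 / (k - 1))
    shares[-1] = 0.15
    edges = norm.ppf(np.cumsum(shares)[:-1])
    codes = np.digitize(driver, edges)
    return grid.with_values(codes.astype(int))
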