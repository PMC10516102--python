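"""Range accounting: land-cover masking, areas, change classes, richness.

Binary climate ranges are intersected with the permitted vegetation
classes of each scenario's land-cover model, summed into species-
richness maps, and compared between present and future: a species is
"stable" when its potential distribution area changes by less than 5%,
and otherwise classed as loss or gain. Suitability change tracks the
domain-wide sum of continuous ensemble suitability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import RasterGrid

__all__ = [
    "RangeChangeRecord",
    "STABILITY_PCT",
    "mask_landcover",
    "range_area",
    "range_change",
    "suitability_change",
    "stack_richness",
    "cell_areas_geographic",
]

#: |percent change| below which a range is considered stable.
STABILITY_PCT = 5.0


@dataclass
class RangeChangeRecord:
    species_id: str
    scenario_id: str
    area_present: float
    area_future: float
    pct_change: float
    change_class: str  # loss | gain | stable
    suitability_change_pct: float | None = None


def mask_landcover(
    binary: RasterGrid, landcover: RasterGrid, allowed: set | frozenset | tuple | list
) -> RasterGrid:
    """Retain presence only on cells whose land-cover class is permitted."""
    binary.require_aligned(landcover, "land-cover raster")
    lc = landcover.values
    ok = np.isin(lc, list(allowed))
    v = binary.values
    out = np.where(np.isnan(v), np.nan, ((v > 0) & ok).astype(float))
    return binary.with_values(out)


def range_area(binary: RasterGrid, cell_areas: float | np.ndarray) -> float:
    """Total area (km²) of presence cells; cell_areas scalar or per-cell."""
    areas = np.broadcast_to(np.asarray(cell_areas, dtype=float), binary.shape)
    if np.any(areas <= 0):
        raise ValueError("cell areas must be positive")
    pres = np.nan_to_num(binary.values, nan=0.0) > 0
    return float(np.sum(areas[pres]))


def range_change(
    area_present: float,
    area_future: float,
    species_id: str = "",
    scenario_id: str = "",
    stability_pct: float = STABILITY_PCT,
) -> RangeChangeRecord:
    """Percent area change and its loss/gain/stable class (strict |pct| < 5 rule)."""
    if area_present <= 0:
        raise ValueError("present area must be positive to compute relative change")
    pct = (area_future - area_present) / area_present * 100.0
    if abs(pct) < stability_pct:
        cls = "stable"
    else:
        cls = "loss" if pct < 0 else "gain"
    return RangeChangeRecord(
        species_id=species_id,
        scenario_id=scenario_id,
        area_present=area_present,
        area_future=area_future,
        pct_change=pct,
        change_class=cls,
    )


def suitability_change(
    present_map: RasterGrid, future_map: RasterGrid, mask: np.ndarray | None = None
) -> float:
    """Percent change of summed continuous suitability over the mask."""
    present_map.require_aligned(future_map, "future suitability map")
    sel = np.ones(present_map.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    p = np.nan_to_num(present_map.values, nan=0.0)[sel].sum()
    f = np.nan_to_num(future_map.values, nan=0.0)[sel].sum()
    if p <= 0:
        raise ValueError("present suitability sums to zero over the mask")
    return float((f - p) / p * 100.0)


def stack_richness(binary_maps: list[RasterGrid]) -> RasterGrid:
    """Per-cell species count: the sum of the binary range maps.

    A cell is nodata only where it is nodata in every input map.
    """
    if not binary_maps:
        raise ValueError("need at least one binary map")
    ref = binary_maps[0]
    for g in binary_maps[1:]:
        ref.require_aligned(g, "binary map")
    stack = np.stack([g.values for g in binary_maps])
    rich = np.nansum(np.nan_to_num(stack, nan=0.0) > 0, axis=0).astype(float)
    all_nan = np.all(np.isnan(stack), axis=0)
    rich[all_nan] = np.nan
    return ref.with_values(rich)


def cell_areas_geographic(grid: RasterGrid, cell_size_deg: float | None = None) -> np.ndarray:
    """Per-cell areas (km²) on a geographic grid, cosine-latitude weighted."""
    if cell_size_deg is None:
        cell_size_deg = grid.cell_size
    km_per_deg = 111.32
    rows = np.arange(grid.rows)
    _, lat = grid.xy_of(rows, np.zeros_like(rows))
    row_area = (cell_size_deg * km_per_deg) ** 2 * np.cos(np.deg2rad(lat))
    return np.repeat(row_area[:, None], grid.cols, axis=1)
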