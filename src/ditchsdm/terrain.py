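"""Geomorphological covariates derived from digital terrain/surface models.

This module turns a 2 m DTM/DSM pair into the terrain predictors used by the
distribution models:

* ``burn_streams``      -- hydrological conditioning: lower the DTM along the
  rasterized ditch network so derived flow paths follow the mapped channels.
* ``fill_pits``         -- priority-flood depression filling with an epsilon
  gradient so every cell drains to the boundary.
* ``d8_flow``           -- single-direction (D8) flow routing and drained-area
  accumulation (the ``Drain`` covariate).
* ``ditch_slope``       -- per-ditch slope (elevation drop between terminal
  nodes over polyline length), rasterized onto ditch cells.
* ``mrvbf``             -- multiresolution index of valley-bottom flatness, a
  proxy for sediment deposition zones (``Mrvbf``).
* ``northness``         -- cosine of hillslope aspect at landscape scale
  (``Northness``).
* ``solar_radiation``   -- cumulative potential direct-beam radiation over a
  spring period, with cast shadows and a canopy-cover zero rule (``Solar``).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import Grid

__all__ = [
    "TerrainConfig",
    "SolarConfig",
    "burn_streams",
    "fill_pits",
    "d8_flow",
    "ditch_slope",
    "mrvbf",
    "northness",
    "solar_radiation",
]

# D8 neighbour offsets in fixed clockwise order starting at east.
# Ties for steepest descent resolve to the first entry, which makes
# routing deterministic.
D8_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1),  # E
    (1, 1),  # SE
    (1, 0),  # S
    (1, -1),  # SW
    (0, -1),  # W
    (-1, -1),  # NW
    (-1, 0),  # N
    (-1, 1),  # NE
)
_D8_DIST = np.array([1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2)])

#: direction code for a cell that drains off-grid (boundary sink / outlet)
OFFGRID = -1


@dataclass
class SolarConfig:
    """Parameters of the potential direct solar radiation model.

    ``solar_constant`` is kept configurable and applied as a scale factor on
    the direct beam; the default is the study-area value recorded as printed
    in its source. ``dust_factor`` is recorded metadata: the lumped
    ``transmittance`` already absorbs atmospheric attenuation, and no separate
    dust model is applied.
    """

    solar_constant: float = 1360.7
    transmittance: float = 0.701
    dust_factor: float = 100.0  # ppm, metadata only
    period: tuple[tuple[int, int], tuple[int, int]] = ((3, 1), (6, 30))
    day_step: int = 5
    hour_step: float = 1.0
    veg_height_cutoff: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.transmittance <= 1):
            raise ValueError("transmittance must be in (0, 1]")
        if self.veg_height_cutoff <= 0:
            raise ValueError("veg_height_cutoff must be positive")
        for month, day in self.period:
            if not (1 <= month <= 12 and 1 <= day <= 31):
                raise ValueError(f"period date ({month}, {day}) outside calendar")


@dataclass
class TerrainConfig:
    """Knobs of the terrain-covariate derivation."""

    burn_depth: float = 1.0  # m lowered along the network
    mrvbf_initial_slope_threshold: float = 16.0  # percent slope
    mrvbf_flatness_shape: float = 4.0
    mrvbf_lowness_threshold: float = 0.4
    mrvbf_steps: int = 4
    northness_smooth_window: int = 9  # cells; landscape-scale exposure
    solar: SolarConfig = field(default_factory=SolarConfig)

    def __post_init__(self) -> None:
        if self.burn_depth < 0:
            raise ValueError("burn_depth must be >= 0")
        if self.mrvbf_initial_slope_threshold <= 0 or self.mrvbf_lowness_threshold <= 0:
            raise ValueError("MRVBF thresholds must be positive")
        if self.mrvbf_steps < 1:
            raise ValueError("mrvbf_steps must be >= 1")


def burn_streams(dtm: Grid, network_mask: Grid, config: TerrainConfig | None = None) -> Grid:
    """Lower the DTM by ``burn_depth`` on network cells; leave the rest untouched."""
    config = config or TerrainConfig()
    dtm.require_aligned(network_mask, "network mask")
    mask = network_mask.data > 0
    out = dtm.data.copy()
    out[mask] -= config.burn_depth
    return dtm.like(out)


def fill_pits(dem: Grid, epsilon: float = 1e-6, outlet: tuple[int, int] | None = None) -> Grid:
    """Priority-flood depression filling with an epsilon downhill gradient.

    Seeded from every boundary cell by default: each interior cell of the
    result then has a strictly lower 8-neighbour and D8 routing terminates at
    the grid boundary. With ``outlet`` given, the flood is seeded from that
    cell alone, so *every* cell gains a strictly descending path to the
    single outlet -- the conditioning a one-outlet catchment needs.
    """
    z = dem.data.copy()
    nrows, ncols = z.shape
    filled = np.full_like(z, np.inf)
    visited = np.zeros(z.shape, dtype=bool)
    heap: list[tuple[float, int, int, int]] = []
    order = 0  # tie-break insertion order for determinism
    if outlet is not None:
        heapq.heappush(heap, (z[outlet], order, outlet[0], outlet[1]))
        order += 1
    else:
        for i in range(nrows):
            for j in (0, ncols - 1):
                heapq.heappush(heap, (z[i, j], order, i, j))
                order += 1
        for j in range(1, ncols - 1):
            for i in (0, nrows - 1):
                heapq.heappush(heap, (z[i, j], order, i, j))
                order += 1
    while heap:
        zc, _, i, j = heapq.heappop(heap)
        if visited[i, j]:
            continue
        visited[i, j] = True
        filled[i, j] = zc
        for di, dj in D8_OFFSETS:
            ni, nj = i + di, j + dj
            if 0 <= ni < nrows and 0 <= nj < ncols and not visited[ni, nj]:
                heapq.heappush(heap, (max(z[ni, nj], zc + epsilon), order, ni, nj))
                order += 1
    return dem.like(filled)


def d8_flow(dem: Grid) -> tuple[Grid, Grid]:
    """D8 flow directions and drained surface area.

    Returns ``(directions, drain)``: direction codes index :data:`D8_OFFSETS`
    (``-1`` = drains off-grid), and drain(c) is cell_area times the number of
    cells whose directed path reaches c, including c itself (m2).

    The DEM must be hydrologically conditioned (see :func:`fill_pits`); any
    interior cell without a strictly lower neighbour raises, listing the
    offending cells.
    """
    z = dem.data
    nrows, ncols = z.shape
    # off-grid neighbours are +inf: flow leaves the grid only at a boundary
    # cell with no strictly lower in-grid neighbour (the catchment outlet)
    zp = np.pad(z, 1, mode="constant", constant_values=np.inf)
    best_drop = np.full(z.shape, -np.inf)
    direction = np.full(z.shape, OFFGRID, dtype=np.int64)
    for code, ((di, dj), dist) in enumerate(zip(D8_OFFSETS, _D8_DIST)):
        neigh = zp[1 + di : 1 + di + nrows, 1 + dj : 1 + dj + ncols]
        drop = (z - neigh) / (dist * dem.cell_size)
        take = drop > best_drop + 1e-15
        best_drop[take] = drop[take]
        direction[take] = code
    sinks = best_drop <= 0
    direction[sinks] = OFFGRID

    interior = np.ones(z.shape, dtype=bool)
    interior[0, :] = interior[-1, :] = interior[:, 0] = interior[:, -1] = False
    pits = interior & sinks
    if pits.any():
        cells = list(zip(*np.nonzero(pits)))
        raise ValueError(
            f"DEM not hydrologically conditioned: {len(cells)} unresolved "
            f"flat/pit cells, first few: {cells[:10]}"
        )
    acc = np.ones(z.shape, dtype=np.float64)
    order_idx = np.argsort(z, axis=None, kind="stable")[::-1]
    rows, cols = np.unravel_index(order_idx, z.shape)
    for i, j in zip(rows, cols):
        code = direction[i, j]
        if code == OFFGRID:
            continue
        di, dj = D8_OFFSETS[code]
        acc[i + di, j + dj] += acc[i, j]
    drain = acc * dem.cell_area
    return dem.like(direction.astype(np.float64)), dem.like(drain)


def trace_d8_path(directions: Grid, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Follow D8 directions from ``start`` until the flow leaves the grid."""
    path = [start]
    i, j = start
    seen = {start}
    while True:
        code = int(directions.data[i, j])
        if code == OFFGRID:
            return path
        di, dj = D8_OFFSETS[code]
        i, j = i + di, j + dj
        if (i, j) in seen:
            raise ValueError(f"D8 directions contain a cycle through {(i, j)}")
        seen.add((i, j))
        path.append((i, j))


def ditch_slope(
    polylines: list[np.ndarray], dtm: Grid, network_mask: Grid | None = None
) -> Grid:
    """Per-ditch slope rasterized onto ditch cells.

    Each polyline is an (n, 2) array of projected (x, y) vertices describing
    one ditch. Its slope is |z(first vertex) - z(last vertex)| divided by the
    polyline length (dimensionless rise/run); every raster cell the polyline
    crosses receives that value. Cells not covered by any polyline are nan.
    """
    out = np.full(dtm.shape, np.nan)
    for k, line in enumerate(polylines):
        line = np.asarray(line, dtype=float)
        if line.ndim != 2 or line.shape[0] < 2:
            raise ValueError(f"polyline {k} needs at least two vertices")
        seglen = np.hypot(*np.diff(line, axis=0).T)
        length = float(seglen.sum())
        if length <= 0:
            raise ValueError(f"polyline {k} has zero length")
        z0 = dtm.data[dtm.index_of(*line[0])]
        z1 = dtm.data[dtm.index_of(*line[-1])]
        slope = abs(z0 - z1) / length
        for cell in _cells_along(line, dtm):
            out[cell] = slope
    if network_mask is not None:
        dtm.require_aligned(network_mask, "network mask")
        remaining = (network_mask.data > 0) & ~np.isfinite(out)
        if remaining.any():
            # nearest-ditch fill so every network cell carries a slope
            filled = _nearest_fill(out)
            out[remaining] = filled[remaining]
    return dtm.like(out)


def _cells_along(line: np.ndarray, grid: Grid):
    """Cells traversed by a polyline, by dense sampling at half-cell spacing."""
    cells: list[tuple[int, int]] = []
    step = grid.cell_size / 2.0
    for a, b in zip(line[:-1], line[1:]):
        seg = np.hypot(*(b - a))
        n = max(int(np.ceil(seg / step)), 1)
        for t in np.linspace(0.0, 1.0, n + 1):
            p = a + t * (b - a)
            r, c = grid.index_of(*p)
            if 0 <= r < grid.shape[0] and 0 <= c < grid.shape[1]:
                if not cells or cells[-1] != (r, c):
                    cells.append((r, c))
    return dict.fromkeys(cells)  # ordered, unique


def _nearest_fill(arr: np.ndarray) -> np.ndarray:
    mask = ~np.isfinite(arr)
    if mask.all():
        return arr
    idx = ndimage.distance_transform_edt(mask, return_distances=False, return_indices=True)
    return arr[tuple(idx)]


def slope_percent(dem: Grid) -> np.ndarray:
    """Finite-difference slope magnitude in percent (100 * rise/run)."""
    gy, gx = np.gradient(dem.data, dem.cell_size)
    return 100.0 * np.hypot(gx, gy)


def _pctl(z: np.ndarray, radius: int) -> np.ndarray:
    """Elevation percentile: fraction of cells within ``radius`` lower than centre."""
    zp = np.pad(z, radius, mode="edge")
    lower = np.zeros(z.shape)
    count = np.zeros(z.shape)
    n = z.shape
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            if di == 0 and dj == 0:
                continue
            if di * di + dj * dj > radius * radius:
                continue
            shifted = zp[radius + di : radius + di + n[0], radius + dj : radius + dj + n[1]]
            lower += shifted < z
            count += 1.0
    return lower / count


def _sigmoid_low(x: np.ndarray, threshold: float, shape: float) -> np.ndarray:
    """1 where x << threshold, 0 where x >> threshold."""
    with np.errstate(divide="ignore", over="ignore"):
        return 1.0 / (1.0 + (np.maximum(x, 0.0) / threshold) ** shape)


def mrvbf(dtm: Grid, config: TerrainConfig | None = None) -> Grid:
    """Multiresolution index of valley-bottom flatness.

    Combines per-scale flatness (a sigmoid of slope against a threshold that
    halves each step) with lowness (elevation percentile in a local window),
    coarsening the grid threefold per step from the third step on. Values
    below 0.5 indicate non-valley terrain, 0.5-1.5 steep valley bottoms, and
    above 1.5 progressively larger valley floors.
    """
    config = config or TerrainConfig()
    if config.mrvbf_steps < 1:
        raise ValueError("mrvbf needs at least one step")
    base_shape = dtm.shape
    p = config.mrvbf_flatness_shape
    t_low = config.mrvbf_lowness_threshold

    def step_vf(z: np.ndarray, cell: float, t_slope: float) -> np.ndarray:
        s = 100.0 * np.hypot(*np.gradient(z, cell)[::-1])
        flat = _sigmoid_low(s, t_slope, p)
        low = _sigmoid_low(_pctl(z, 3), t_low, 3.0)
        pvf = flat * low
        return 1.0 - _sigmoid_low(pvf, 0.3, p)  # increasing in pvf

    z = dtm.data.astype(float)
    cell = dtm.cell_size
    t_slope = config.mrvbf_initial_slope_threshold
    result = step_vf(z, cell, t_slope)  # step 1

    for L in range(2, config.mrvbf_steps + 1):
        t_slope /= 2.0
        if L == 2:
            z = ndimage.gaussian_filter(z, sigma=1.0, mode="nearest")
        else:
            z = ndimage.gaussian_filter(z, sigma=1.5, mode="nearest")[::3, ::3]
            cell *= 3.0
            if min(z.shape) < 7:  # too coarse to measure flatness
                break
        vf = step_vf(z, cell, t_slope)
        if vf.shape != base_shape:
            vf = ndimage.zoom(
                vf, (base_shape[0] / vf.shape[0], base_shape[1] / vf.shape[1]), order=1
            )
        p_w = np.log((L - 0.5) / 0.1) / np.log(1.5)
        with np.errstate(divide="ignore", over="ignore"):
            w = 1.0 / (1.0 + np.where(vf > 0, (vf / 0.4) ** (-p_w), np.inf))
        result = w * (L - 1 + vf) + (1.0 - w) * result
    return dtm.like(result)


def northness(dtm: Grid, smooth_window: int = 9) -> Grid:
    """Cosine of aspect (downslope azimuth from north) on a smoothed DTM.

    +1 on north-facing slopes, -1 on south-facing, 0 on flat cells. The
    smoothing window (in cells) makes this a landscape-scale exposure index
    rather than a cell-scale one.
    """
    z = dtm.data
    if smooth_window > 1:
        z = ndimage.uniform_filter(z, size=smooth_window, mode="nearest")
    g_row, g_col = np.gradient(z, dtm.cell_size)
    mag = np.hypot(g_row, g_col)
    with np.errstate(invalid="ignore", divide="ignore"):
        north = np.where(mag > 0, g_row / mag, 0.0)
    return dtm.like(north)


def _solar_declination(doy: np.ndarray | float) -> np.ndarray | float:
    return np.deg2rad(23.45) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)


def _horizon_tangent(z: np.ndarray, cell: float, n_sectors: int, radius_cells: int) -> np.ndarray:
    """Horizon-elevation tangent per azimuth sector, by directional max scans."""
    nrows, ncols = z.shape
    tans = np.zeros((n_sectors, nrows, ncols))
    pad = radius_cells
    zp = np.pad(z, pad, mode="edge")
    for s in range(n_sectors):
        az = 2.0 * np.pi * s / n_sectors  # from north, clockwise
        ue, un = np.sin(az), np.cos(az)  # unit vector east/north
        best = np.full(z.shape, -np.inf)
        for d in range(1, radius_cells + 1):
            di = int(round(-un * d))  # north = decreasing row
            dj = int(round(ue * d))
            if abs(di) > pad or abs(dj) > pad:
                break
            shifted = zp[pad + di : pad + di + nrows, pad + dj : pad + dj + ncols]
            dist = np.hypot(di, dj) * cell
            np.maximum(best, (shifted - z) / dist, out=best)
        tans[s] = np.maximum(best, 0.0)
    return tans


def solar_radiation(
    dsm: Grid,
    dtm: Grid,
    config: SolarConfig | None = None,
    latitude: float = 43.4,
    n_azimuth_sectors: int = 16,
    horizon_radius: float = 200.0,
) -> Grid:
    """Cumulative potential direct-beam radiation over the configured period.

    For each sampled day/hour the solar position is computed from latitude,
    the solar constant is attenuated by ``transmittance ** airmass``, the beam
    is projected on the DSM-derived cell slope/aspect, and cells below the DSM
    horizon toward the sun receive nothing. Cells under tall canopy
    (DSM - DTM >= ``veg_height_cutoff``) are forced to zero because the model
    cannot shade the shading pixel itself.

    Output units follow the configured solar constant (energy per m2 summed
    over the period); only relative spatial contrasts feed the models, which
    rescale every covariate to [0, 1].
    """
    config = config or SolarConfig()
    dsm.require_aligned(dtm, "DTM")
    z = dsm.data
    lat = np.deg2rad(latitude)

    g_row, g_col = np.gradient(z, dsm.cell_size)
    slope_ang = np.arctan(np.hypot(g_row, g_col))
    # downslope vector in (east, north): (-g_col, +g_row)
    aspect = np.arctan2(-g_col, g_row)  # azimuth from north, clockwise positive east

    radius_cells = max(4, int(round(horizon_radius / dsm.cell_size)))
    radius_cells = min(radius_cells, max(z.shape))
    hor = _horizon_tangent(z, dsm.cell_size, n_azimuth_sectors, radius_cells)

    (m0, d0), (m1, d1) = config.period
    cum_days = np.cumsum([0, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30])
    doy0 = int(cum_days[m0 - 1] + d0)
    doy1 = int(cum_days[m1 - 1] + d1)
    if doy1 < doy0:
        raise ValueError("period end precedes period start")

    total = np.zeros(z.shape)
    hours = np.arange(0.0, 24.0, config.hour_step)
    for doy in range(doy0, doy1 + 1, config.day_step):
        dec = _solar_declination(doy)
        for hr in hours:
            h = np.deg2rad(15.0 * (hr - 12.0))
            sin_alt = np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.cos(h)
            if sin_alt <= 0.01:
                continue
            alt = np.arcsin(sin_alt)
            cos_az = (np.sin(dec) - sin_alt * np.sin(lat)) / (np.cos(alt) * np.cos(lat))
            az = np.arccos(np.clip(cos_az, -1.0, 1.0))
            if h > 0:
                az = 2.0 * np.pi - az
            airmass = 1.0 / max(sin_alt, 1.0 / 38.0)
            beam = config.solar_constant * config.transmittance**airmass
            cos_inc = np.cos(slope_ang) * sin_alt + np.sin(slope_ang) * np.cos(alt) * np.cos(
                az - aspect
            )
            sector = int(round(az / (2.0 * np.pi / n_azimuth_sectors))) % n_azimuth_sectors
            lit = np.tan(alt) >= hor[sector]
            total += beam * np.clip(cos_inc, 0.0, None) * lit * config.hour_step * config.day_step

    canopy = (dsm.data - dtm.data) >= config.veg_height_cutoff
    total[canopy] = 0.0
    return dsm.like(total)
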