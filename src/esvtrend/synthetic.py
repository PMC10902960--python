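"""Synthetic mining-landscape and socioeconomic generators.

Everything the pipeline consumes can be simulated here, so the full
analysis runs with no external data:

* an annual land-use raster series on a grassland-dominated mosaic in
  which mining concessions are progressively converted to disturbed bare
  ground (unused land) with a built-up fringe, optionally followed by
  late-period grassland restoration;
* a socioeconomic series (GDP, year-over-year GDP index, Engel
  coefficient, grain yield and price) with compound growth and a
  monotonically falling Engel coefficient;
* piecewise log-linear test series with prescribed per-segment annual
  percent changes, the test harness for the joinpoint stage.

All outputs are fully determined by the seed in the config.

The default scenario is a 100 x 100 grid of 1-ha pixels over 1990-2020:
~76 % grassland (an agro-pastoral steppe mosaic), mining expansion at
30 ha/yr inside two concessions starting in 2002 (the coal-boom onset),
and modest restoration from 2016. The two bundled piecewise scenarios
(CONTROL_SCENARIO, MINING_SCENARIO) reproduce the canonical
flat-then-declining mining trajectory against a steadily rising control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely

from .core import (
    DEFAULT_NODATA,
    GridTransform,
    LandUseClass,
    LandUseSeries,
    Raster,
    SocioEconomicSeries,
)

__all__ = [
    "LandscapeConfig",
    "generate_landscape_series",
    "generate_socioeconomic_series",
    "generate_piecewise_series",
    "CONTROL_SCENARIO",
    "MINING_SCENARIO",
]

#: canonical piecewise scenarios: a steadily rising control area and a
#: flat-then-declining mining area (breaks and per-segment APCs in %/yr)
CONTROL_SCENARIO = {"breaks": (1997, 2005, 2009), "apcs": (1.09, 0.43, 1.01, 0.51)}
MINING_SCENARIO = {"breaks": (1996, 1999, 2007), "apcs": (0.00, 0.78, 0.09, -0.67)}

_DEFAULT_PROPORTIONS = {
    LandUseClass.Grassland: 0.76,
    LandUseClass.Woodland: 0.08,
    LandUseClass.Cropland: 0.08,
    LandUseClass.Wetland: 0.015,
    LandUseClass.Waterbody: 0.015,
    LandUseClass.UnusedLand: 0.03,
    LandUseClass.BuiltUp: 0.02,
}


@dataclass
class LandscapeConfig:
    shape: tuple[int, int] = (100, 100)
    pixel_size: float = 100.0  # metres; 100 m => 1-ha pixels
    years: tuple[int, int] = (1990, 2020)
    proportions: dict = field(default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    n_concessions: int = 2
    concession_size: tuple[int, int] = (25, 25)  # pixels per side
    mining_start_year: int = 2002
    expansion_ha_per_year: float = 30.0
    builtup_fringe_frac: float = 0.12  # share of mined pixels becoming built-up
    restoration_start_year: int | None = 2016
    restoration_ha_per_year: float = 5.0
    noise_rate: float = 0.002  # per-pixel per-year background class flips
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1 (got {total})")
        if self.years[1] < self.years[0]:
            raise ValueError("year range reversed")


def _grow_mosaic(shape, proportions, rng) -> np.ndarray:
    """Seeded multi-source region growing to exact per-class pixel counts."""
    rows, cols = shape
    n = rows * cols
    classes = list(proportions)
    quota = {}
    acc = 0
    for i, k in enumerate(classes):
        c = int(round(proportions[k] * n)) if i < len(classes) - 1 else n - acc
        quota[k] = c
        acc += c
    grid = np.full(n, -1, dtype=np.int16)
    frontiers: dict[LandUseClass, list[int]] = {k: [] for k in classes}

    def neighbors(idx):
        r, c = divmod(idx, cols)
        if r > 0:
            yield idx - cols
        if r < rows - 1:
            yield idx + cols
        if c > 0:
            yield idx - 1
        if c < cols - 1:
            yield idx + 1

    # several nuclei per class, more for larger quotas, for a patchy mosaic
    for k in classes:
        n_nuclei = max(1, quota[k] // 400)
        for _ in range(n_nuclei):
            frontiers[k].append(int(rng.integers(n)))
    assigned = 0
    order = list(classes)
    while assigned < n:
        progressed = False
        rng.shuffle(order)
        for k in order:
            if quota[k] <= 0:
                continue
            fr = frontiers[k]
            while fr:
                pick = fr.pop(int(rng.integers(len(fr))))
                if grid[pick] == -1:
                    grid[pick] = int(k)
                    quota[k] -= 1
                    assigned += 1
                    progressed = True
                    for nb in neighbors(pick):
                        if grid[nb] == -1:
                            fr.append(nb)
                    break
            else:
                # frontier exhausted but quota remains: reseed on a free cell
                free = np.nonzero(grid == -1)[0]
                if len(free):
                    fr.append(int(rng.choice(free)))
                    progressed = True
        if not progressed:  # pragma: no cover - defensive
            break
    return grid.reshape(rows, cols).astype(np.uint8)


def _make_concessions(cfg: LandscapeConfig, rng) -> list[shapely.Polygon]:
    rows, cols = cfg.shape
    px = cfg.pixel_size
    w, h = cfg.concession_size
    polys: list[shapely.Polygon] = []
    attempts = 0
    while len(polys) < cfg.n_concessions and attempts < 200:
        attempts += 1
        c0 = int(rng.integers(2, max(3, cols - w - 2)))
        r0 = int(rng.integers(2, max(3, rows - h - 2)))
        box = shapely.box(c0 * px, (rows - r0 - h) * px, (c0 + w) * px, (rows - r0) * px)
        if all(not box.intersects(p.buffer(3 * px)) for p in polys):
            polys.append(box)
    if len(polys) < cfg.n_concessions:
        raise ValueError("could not place the requested concessions; reduce count or size")
    return polys


def generate_landscape_series(
    cfg: LandscapeConfig | None = None,
) -> tuple[LandUseSeries, list[shapely.Polygon], shapely.Polygon, list[dict]]:
    """Simulate the annual land-use series with concession-driven mining.

    Returns (series, concession polygons, study polygon, transition log).
    The transition log holds, for each year step, a dict
    {(from_class, to_class): pixel count} from which per-year class areas
    are exactly reconstructible.
    """
    cfg = cfg or LandscapeConfig()
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.shape
    tr = GridTransform(0.0, rows * cfg.pixel_size, cfg.pixel_size, cfg.pixel_size)
    base = _grow_mosaic(cfg.shape, cfg.proportions, rng)
    concessions = _make_concessions(cfg, rng)
    study = tr.extent_polygon(cfg.shape)

    ref = Raster(base, tr, nodata=DEFAULT_NODATA)
    conc_mask = ref.mask_for(concessions)
    conc_idx = np.nonzero(conc_mask.ravel())[0]
    pixel_ha = tr.pixel_area_ha
    expand_px = cfg.expansion_ha_per_year / pixel_ha
    restore_px = cfg.restoration_ha_per_year / pixel_ha

    # BFS order of mining growth from each concession's central pixel;
    # pixels already bare/built-up don't consume expansion quota
    flat_base = base.ravel()
    mined_codes = (int(LandUseClass.UnusedLand), int(LandUseClass.BuiltUp))
    mine_order = [
        i for i in _mining_order(conc_mask, concessions, tr, rng)
        if flat_base[i] not in mined_codes
    ]

    years = list(range(cfg.years[0], cfg.years[1] + 1))
    rasters = [Raster(base.copy(), tr, nodata=DEFAULT_NODATA)]
    log: list[dict] = []
    current = base.copy().ravel()
    mined: list[int] = []  # indices in mining order, oldest first
    restored = 0
    mined_quota = 0.0
    restore_quota = 0.0
    class_pool = np.array([int(k) for k in cfg.proportions])
    class_p = np.array([cfg.proportions[k] for k in cfg.proportions])
    warned = False
    for year in years[1:]:
        step: dict[tuple[int, int], int] = {}

        def convert(idx: int, to: int) -> None:
            frm = int(current[idx])
            if frm == to:
                return
            step[(frm, to)] = step.get((frm, to), 0) + 1
            current[idx] = to

        # background class-transition noise outside concessions
        if cfg.noise_rate > 0:
            outside = np.nonzero(~conc_mask.ravel())[0]
            flips = outside[rng.random(len(outside)) < cfg.noise_rate]
            for idx in flips:
                convert(int(idx), int(rng.choice(class_pool, p=class_p)))
        # mining expansion
        if year >= cfg.mining_start_year:
            mined_quota += expand_px
            n_new = int(mined_quota)
            mined_quota -= n_new
            avail = len(mine_order) - len(mined)
            if n_new > avail and not warned:
                warnings.warn("mining expansion demand exceeds concession area; capped")
                warned = True
            for _ in range(min(n_new, avail)):
                idx = mine_order[len(mined)]
                to = (
                    int(LandUseClass.BuiltUp)
                    if rng.random() < cfg.builtup_fringe_frac
                    else int(LandUseClass.UnusedLand)
                )
                convert(idx, to)
                mined.append(idx)
        # restoration of the oldest mined pixels back to grassland
        if cfg.restoration_start_year is not None and year >= cfg.restoration_start_year:
            restore_quota += restore_px
            n_r = min(int(restore_quota), len(mined) - restored)
            restore_quota -= int(restore_quota)
            for _ in range(n_r):
                convert(mined[restored], int(LandUseClass.Grassland))
                restored += 1
        rasters.append(Raster(current.copy().reshape(cfg.shape), tr, nodata=DEFAULT_NODATA))
        log.append({"year": year, "transitions": step})
    return LandUseSeries(years, rasters), concessions, study, log


def _mining_order(conc_mask, concessions, tr, rng) -> list[int]:
    """Contiguous BFS growth order over concession pixels, one seed per concession."""
    rows, cols = conc_mask.shape
    mask = conc_mask.ravel()
    order: list[int] = []
    seen = np.zeros(mask.shape, dtype=bool)
    for poly in concessions:
        cx, cy = poly.centroid.x, poly.centroid.y
        col = int((cx - tr.x0) / tr.dx)
        row = int((tr.y0 - cy) / tr.dy)
        seed = row * cols + col
        if not mask[seed]:  # pragma: no cover - centroid always inside a box
            inside = np.nonzero(mask & ~seen)[0]
            seed = int(inside[0])
        frontier = [seed]
        while frontier:
            pick = frontier.pop(int(rng.integers(len(frontier))))
            if seen[pick] or not mask[pick]:
                continue
            seen[pick] = True
            order.append(pick)
            r, c = divmod(pick, cols)
            for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= nb[0] < rows and 0 <= nb[1] < cols:
                    j = nb[0] * cols + nb[1]
                    if mask[j] and not seen[j]:
                        frontier.append(j)
    return order


def generate_socioeconomic_series(
    years=(1990, 2020),
    gdp0: float = 10_000.0,
    gdp_growth: float = 0.10,
    gdp_noise_sd: float = 0.0,
    engel_start: float = 0.38,
    engel_end: float = 0.33,
    grain_yield: float = 4405.0,
    grain_price: float = 3.05,
    seed: int = 0,
) -> SocioEconomicSeries:
    """Compound-growth GDP with realized year-over-year index and a
    monotonically interpolated Engel coefficient.

    The GDP index is the *realized* ratio gdp(t)/gdp(t-1), so the chained
    product over the series telescopes to gdp(last)/gdp(first) exactly.
    """
    if not (0 < engel_start <= 1 and 0 < engel_end <= 1):
        raise ValueError("Engel coefficients must lie in (0, 1]")
    if gdp0 <= 0 or gdp_growth <= -1:
        raise ValueError("invalid GDP parameters")
    rng = np.random.default_rng(seed)
    yr = np.arange(years[0], years[1] + 1)
    n = len(yr)
    growth = np.full(n - 1, 1.0 + gdp_growth)
    if gdp_noise_sd > 0:
        growth *= np.exp(rng.normal(0.0, gdp_noise_sd, n - 1))
    gdp = np.empty(n)
    gdp[0] = gdp0
    gdp[1:] = gdp0 * np.cumprod(growth)
    index = np.ones(n)
    index[1:] = gdp[1:] / gdp[:-1]
    engel = np.linspace(engel_start, engel_end, n)
    return SocioEconomicSeries(
        years=yr,
        gdp=gdp,
        gdp_index=index,
        engel=engel,
        grain_yield=np.full(n, float(grain_yield)),
        grain_price=np.full(n, float(grain_price)),
    )


def generate_piecewise_series(
    years=(1990, 2020),
    breaks=(),
    apcs=(0.0,),
    start_value: float = 100.0,
    log_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise log-linear series with prescribed per-segment APCs.

    The log-trend is continuous with segment slopes ln(1 + APC/100);
    Gaussian noise of sd ``log_noise_sd`` is added on the log scale.
    """
    yr = np.arange(years[0], years[1] + 1, dtype=float)
    breaks = np.asarray(sorted(breaks), dtype=float)
    if len(breaks) + 1 != len(apcs):
        raise ValueError("need exactly one APC per segment (len(breaks)+1)")
    if len(breaks) and (breaks[0] <= yr[0] or breaks[-1] >= yr[-1]):
        raise ValueError("breakpoints must fall strictly inside the year range")
    a = np.asarray(apcs, dtype=float)
    if np.any(a <= -100):
        raise ValueError("APC <= -100% is not representable on the log scale")
    slopes = np.log1p(a / 100.0)
    logy = np.empty_like(yr)
    logy[0] = np.log(start_value)
    for i in range(1, len(yr)):
        # integrate the piecewise slope over [yr[i-1], yr[i]] (handles a break mid-step)
        t0, t1 = yr[i - 1], yr[i]
        inc = 0.0
        pos = t0
        while pos < t1:
            seg = int(np.searchsorted(breaks, pos, side="right")) if len(breaks) else 0
            nxt = min(t1, breaks[seg]) if seg < len(breaks) else t1
            inc += slopes[seg] * (nxt - pos)
            pos = nxt
        logy[i] = logy[i - 1] + inc
    if log_noise_sd > 0:
        rng = np.random.default_rng(seed)
        logy = logy + rng.normal(0.0, log_noise_sd, len(yr))
    return yr.astype(int), np.exp(logy)
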