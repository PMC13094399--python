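"""Synthetic scenario sets, species ranges, sites and tables with known
ground truth.

The generator emulates the structure of the real study inputs: a baseline
BIO5 grid with a spatial temperature gradient, k future grids equal to
the baseline plus spatially varying warming offsets (labelled as a
GCM × SSP ensemble), nested historical ⊇ current range polygons built
from unions of cell rectangles, and sites placed at chosen temperature
quantiles.  Because polygons are unions of whole cells and warming is
additive, every envelope, overlap percentage, risk tier and refugia
fraction is known exactly at construction time and emitted as a
ground-truth record.

Species construction works backwards from the target overlaps: for each
candidate cell the fraction of scenarios under which its projected value
stays within the current / historical envelope is computed from the
actual future grids, and cells are selected so those fractions average to
the requested overlap percentages (the ensemble-mean overlap over the
current range equals the cell-average of per-cell scenario fractions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import shapely

from .geo_io import Affine, ClimateGrid, ScenarioSet, SiteRecord, SpeciesRange, assemble_scenarios

__all__ = [
    "WarmingSpec",
    "SpeciesSpec",
    "SpeciesTruth",
    "SiteTruth",
    "InfeasibleSpecError",
    "make_baseline",
    "make_scenarios",
    "make_species",
    "make_sites",
    "cell_box",
]

SSPS = ("SSP1-2.6", "SSP3-7.0", "SSP5-8.5")


class InfeasibleSpecError(ValueError):
    """Raised when a species spec cannot be realised on the given grids."""


@dataclass(frozen=True)
class WarmingSpec:
    """Ensemble structure: k scenarios with mean warming spanning delta_range.

    Defaults emulate a 5 GCM × 3 SSP ensemble whose mid-century mean
    warming of the hottest month spans roughly +1 °C (low-emission, cool
    model) to +4 °C (high-emission, hot model).
    """

    k_scenarios: int = 15
    delta_range: tuple[float, float] = (1.0, 4.0)
    spatial_pattern: Literal["uniform", "gradient", "patchy"] = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_scenarios < 1:
            raise ValueError("need at least one scenario")
        if self.delta_range[0] > self.delta_range[1]:
            raise ValueError("delta_range min exceeds max")


@dataclass(frozen=True)
class SpeciesSpec:
    """Target geometry/overlap structure for one synthetic species.

    ``delta_tm`` is the retreat of the current thermal maximum below the
    historical one; ``target_overlap_*`` are ensemble-mean overlap
    percentages the construction must realise within ±2 points.
    """

    target_tier: Literal["low", "moderate", "high"]
    hist_width: float
    delta_tm: float
    target_overlap_current: float
    target_overlap_historical: float
    current_fraction: float = 0.6
    n_cells: int = 120
    species_id: str = "species"

    def __post_init__(self) -> None:
        if self.hist_width < 0 or self.delta_tm < 0:
            raise ValueError("widths and deltas must be non-negative")
        if not 0 < self.current_fraction <= 1:
            raise ValueError("current_fraction must lie in (0, 1]")
        p_c, p_h = self.target_overlap_current, self.target_overlap_historical
        if p_h < p_c:
            raise ValueError("historical overlap cannot be below current")
        tier = ("low" if p_c > 50 and p_h > 50
                else "moderate" if p_h > 50 else "high")
        if tier != self.target_tier:
            raise ValueError(
                f"target overlaps ({p_c}, {p_h}) imply tier {tier!r}, "
                f"not {self.target_tier!r}")


@dataclass
class SpeciesTruth:
    """Ground truth emitted alongside a generated species."""

    species_id: str
    tier: str
    tm_current: float
    tm_historical: float
    delta_tm: float
    hist_width: float
    per_scenario_overlap_current: np.ndarray
    per_scenario_overlap_historical: np.ndarray
    current_cells: np.ndarray
    historical_cells: np.ndarray

    @property
    def mean_overlap_current(self) -> float:
        return float(self.per_scenario_overlap_current.mean())

    @property
    def mean_overlap_historical(self) -> float:
        return float(self.per_scenario_overlap_historical.mean())


@dataclass
class SiteTruth:
    site: SiteRecord
    bio5_baseline: float
    bio5_by_scenario: np.ndarray
    exceeds_current_tm: dict[str, bool]
    exceeds_historical_tm: dict[str, bool]


def make_baseline(
    shape: tuple[int, int] = (400, 160),
    west: float = 120.0,
    south: float = 0.0,
    cellsize: float = 0.05,
    base_temp: float = 22.0,
    gradient: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ClimateGrid:
    """Baseline BIO5 field: base + gradient × latitude + Gaussian noise.

    With the defaults the grid spans 20° of latitude at 0.05° cells, so
    row-to-row temperature steps are 0.05 °C and the field spans 20 °C —
    enough head-room to carve envelopes up to ~19 °C wide.
    """
    nrows, ncols = shape
    if nrows < 1 or ncols < 1:
        raise ValueError("grid dimensions must be positive")
    north = south + nrows * cellsize
    transform = Affine.from_origin(west, north, cellsize, cellsize)
    lat = north - (np.arange(nrows) + 0.5) * cellsize
    values = base_temp + gradient * lat[:, None] * np.ones((1, ncols))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=(nrows, ncols))
    return ClimateGrid(values, transform, label="baseline")


def make_scenarios(baseline: ClimateGrid, spec: WarmingSpec) -> ScenarioSet:
    """k future grids = baseline + per-scenario warming field.

    Per-scenario spatial-mean warming is spaced evenly across
    ``delta_range``; the spatial pattern is uniform, a west–east linear
    gradient, or a smooth random ("patchy") field, each rescaled so its
    spatial mean equals the scenario's mean warming.
    """
    k = spec.k_scenarios
    deltas = (np.full(k, spec.delta_range[0]) if k == 1
              else np.linspace(*spec.delta_range, k))
    nrows, ncols = baseline.shape
    rng = np.random.default_rng(spec.seed)

    futures = []
    for i, d in enumerate(deltas):
        if spec.spatial_pattern == "uniform":
            w = np.full((nrows, ncols), d)
        elif spec.spatial_pattern == "gradient":
            x = (np.arange(ncols) + 0.5) / ncols  # mean exactly 0.5
            w = d * 2.0 * x[None, :] * np.ones((nrows, 1))
        elif spec.spatial_pattern == "patchy":
            coarse = rng.normal(size=(max(nrows // 40, 2), max(ncols // 40, 2)))
            rows = np.linspace(0, coarse.shape[0] - 1, nrows)
            cols = np.linspace(0, coarse.shape[1] - 1, ncols)
            r0 = np.clip(rows.astype(int), 0, coarse.shape[0] - 2)
            c0 = np.clip(cols.astype(int), 0, coarse.shape[1] - 2)
            fr, fc = rows - r0, cols - c0
            w = ((1 - fr)[:, None] * (1 - fc)[None, :] * coarse[r0][:, c0]
                 + fr[:, None] * (1 - fc)[None, :] * coarse[r0 + 1][:, c0]
                 + (1 - fr)[:, None] * fc[None, :] * coarse[r0][:, c0 + 1]
                 + fr[:, None] * fc[None, :] * coarse[r0 + 1][:, c0 + 1])
            w = w - w.min() + 0.1
            w *= d / w[~baseline.nodata_mask].mean()
        else:
            raise ValueError(f"unknown pattern {spec.spatial_pattern!r}")
        gcm, ssp = f"GCM{i // len(SSPS) + 1}", SSPS[i % len(SSPS)]
        futures.append(ClimateGrid(
            baseline.values + w, baseline.transform, crs=baseline.crs,
            nodata_mask=baseline.nodata_mask.copy(), label=f"{gcm}:{ssp}"))
    return assemble_scenarios(baseline, futures)


def cell_box(transform: Affine, row: int, col: int):
    """Shapely rectangle of one grid cell."""
    x0, y0 = transform.xy(row, col, offset="ul")
    x1, y1 = transform.xy(row + 1, col + 1, offset="ul")
    return shapely.box(min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1))


def _cells_to_polygon(transform: Affine, cells: np.ndarray):
    return shapely.unary_union([cell_box(transform, r, c) for r, c in cells])


def make_species(
    scenarios: ScenarioSet,
    spec: SpeciesSpec,
    seed: int = 0,
    block_width: int = 12,
) -> tuple[SpeciesRange, SpeciesTruth]:
    """Construct a species whose envelopes and overlaps hit the spec.

    The historical polygon spans cells whose baseline values realise
    ``hist_width`` below the historical thermal maximum; the current
    polygon is carved from it so the current TM sits ``delta_tm`` lower
    and the ensemble-mean overlaps land within ±2 percentage points of
    the targets.  Raises :class:`InfeasibleSpecError` when the grid span
    or the warming ensemble cannot realise the spec (e.g. a hist_width
    exceeding the grid's temperature span, or a delta_tm so large that
    no cell of the current range can exceed the historical TM under the
    ensemble's warming offsets).
    """
    rng = np.random.default_rng(seed)
    base = scenarios.baseline
    v = base.values
    nrows, ncols = base.shape
    if block_width > ncols:
        raise InfeasibleSpecError("block wider than the grid")
    cb = int(rng.integers(0, ncols - block_width + 1))
    cols = np.arange(cb, cb + block_width)
    c0 = cb
    col_vals = v[:, c0]
    valid_rows = ~base.nodata_mask[:, c0]
    if not valid_rows.any():
        raise InfeasibleSpecError("anchor column is all nodata")
    step = float(np.median(np.abs(np.diff(col_vals[valid_rows])))) or 0.05
    tol = max(2.5 * step, 0.26)

    def nearest_row(target: float) -> int:
        d = np.where(valid_rows, np.abs(col_vals - target), np.inf)
        return int(np.argmin(d))

    # anchor the historical TM near the hot end, leaving jitter room
    hot = float(col_vals[valid_rows].max())
    tm_h_target = hot - 0.25 - 0.5 * float(rng.random())
    r_h = nearest_row(tm_h_target)
    tm_h = float(col_vals[r_h])
    r_c = nearest_row(tm_h - spec.delta_tm)
    tm_c = float(col_vals[r_c])
    if abs((tm_h - tm_c) - spec.delta_tm) > tol:
        raise InfeasibleSpecError(
            f"cannot realise delta_tm={spec.delta_tm} on this grid")
    r_min = nearest_row(tm_h - spec.hist_width)
    hist_min = float(col_vals[r_min])
    if abs((tm_h - hist_min) - spec.hist_width) > tol:
        raise InfeasibleSpecError(
            f"hist_width={spec.hist_width} exceeds the grid's span")

    # candidate current cells and their per-cell scenario survival fractions
    rows_all, cols_all = np.meshgrid(np.arange(nrows), cols, indexing="ij")
    rows_all, cols_all = rows_all.ravel(), cols_all.ravel()
    vals = v[rows_all, cols_all]
    ok = (~base.nodata_mask[rows_all, cols_all] & (vals <= tm_c)
          & (vals >= hist_min) & ~((rows_all == r_c) & (cols_all == c0)))
    rows_cand, cols_cand = rows_all[ok], cols_all[ok]
    fut_vals = np.stack([f.values[rows_cand, cols_cand]
                         for f in scenarios.futures])  # (k, ncand)
    fc = (fut_vals <= tm_c).mean(axis=0)
    fh = (fut_vals <= tm_h).mean(axis=0)

    n = spec.n_cells
    struct_fut = np.array([f.values[r_c, c0] for f in scenarios.futures])
    fc_struct = float((struct_fut <= tm_c).mean())
    fh_struct = float((struct_fut <= tm_h).mean())

    n_a = int(round(spec.target_overlap_current / 100.0 * n - fc_struct))
    a_idx = np.flatnonzero(fc == 1.0)
    if n_a < 0 or a_idx.size < n_a:
        raise InfeasibleSpecError(
            "not enough always-within cells for the current-overlap target")
    a_pick = a_idx[np.argsort(vals[ok][a_idx], kind="stable")[:n_a]]

    n_rem = n - n_a - 1
    if n_rem < 0:
        raise InfeasibleSpecError("n_cells too small for the overlap targets")
    s_rem = spec.target_overlap_historical / 100.0 * n - n_a - fh_struct
    rem_pool = np.flatnonzero(fc == 0.0)
    rem_pool = rem_pool[~np.isin(rem_pool, a_pick)]
    if rem_pool.size < n_rem:
        raise InfeasibleSpecError("not enough never-within-current cells")
    order = np.argsort(fh[rem_pool], kind="stable")
    pool = rem_pool[order]
    pool_fh = fh[pool]
    taken = np.zeros(pool.size, dtype=bool)
    picks = []
    remaining_sum = float(s_rem)
    for i in range(n_rem):
        want = remaining_sum / (n_rem - i)
        avail = np.flatnonzero(~taken)
        j = avail[np.argmin(np.abs(pool_fh[avail] - want))]
        taken[j] = True
        picks.append(j)
        remaining_sum -= float(pool_fh[j])
    rem_pick = pool[picks]

    cur_rows = np.concatenate([[r_c], rows_cand[a_pick], rows_cand[rem_pick]])
    cur_cols = np.concatenate([[c0], cols_cand[a_pick], cols_cand[rem_pick]])
    current_cells = np.column_stack([cur_rows, cur_cols])

    # exact per-scenario overlaps from the actual future grids
    cur_fut = np.stack([f.values[cur_rows, cur_cols] for f in scenarios.futures])
    ov_c = 100.0 * (cur_fut <= tm_c).mean(axis=1)
    ov_h = 100.0 * (cur_fut <= tm_h).mean(axis=1)
    if (abs(ov_c.mean() - spec.target_overlap_current) > 2.0
            or abs(ov_h.mean() - spec.target_overlap_historical) > 2.0):
        raise InfeasibleSpecError(
            f"construction landed at ({ov_c.mean():.2f}, {ov_h.mean():.2f}), "
            f"outside ±2 points of the targets")

    # historical = current + TM/width anchors + filler up to the area ratio
    extra = [(r_h, c0), (r_min, c0)]
    lo, hi = sorted((r_min, r_h))
    for r in range(lo, hi + 1, 4):
        if valid_rows[r] and hist_min <= col_vals[r] <= tm_h:
            extra.append((r, c0))
    n_hist_target = int(round(n / spec.current_fraction))
    chosen = {(int(r), int(c)) for r, c in current_cells} | set(extra)
    # filler: any candidate cells not yet chosen, coolest first
    all_idx = np.flatnonzero(ok)
    filler_order = all_idx[np.argsort(vals[all_idx], kind="stable")]
    for idx in filler_order:
        if len(chosen) >= n_hist_target:
            break
        chosen.add((int(rows_all[idx]), int(cols_all[idx])))
    historical_cells = np.array(sorted(chosen))

    transform = base.transform
    current_poly = _cells_to_polygon(transform, current_cells)
    historical_poly = _cells_to_polygon(transform, historical_cells)
    rng_obj = SpeciesRange(spec.species_id, historical_poly, current_poly)

    # generator's own classification oracle (conservative mean − SE rule)
    def sem(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0

    m_c, m_h = ov_c.mean() - sem(ov_c), ov_h.mean() - sem(ov_h)
    tier = "low" if (m_c > 50 and m_h > 50) else "moderate" if m_h > 50 else "high"

    truth = SpeciesTruth(
        species_id=spec.species_id,
        tier=tier,
        tm_current=tm_c,
        tm_historical=tm_h,
        delta_tm=tm_h - tm_c,
        hist_width=tm_h - hist_min,
        per_scenario_overlap_current=ov_c,
        per_scenario_overlap_historical=ov_h,
        current_cells=current_cells,
        historical_cells=historical_cells,
    )
    if truth.tier != spec.target_tier:
        raise InfeasibleSpecError(
            f"constructed species classifies as {truth.tier!r}, "
            f"target was {spec.target_tier!r}")
    return rng_obj, truth


def make_sites(
    scenarios: ScenarioSet,
    species_range: SpeciesRange,
    tm_current: float,
    tm_historical: float,
    n: int,
    quantiles: tuple[float, ...] = (0.1, 0.5, 0.9),
    seed: int = 0,
    species_id: str | None = None,
) -> tuple[list[SiteRecord], list[SiteTruth]]:
    """Place n sites at baseline-temperature quantiles of the current range.

    Site i sits at the cell whose baseline BIO5 is the
    ``quantiles[i % len]`` quantile of the current range's cells; the
    emitted truth carries the per-site projected values and strict
    exceedance flags against both thermal maxima.
    """
    if n < 1:
        raise ValueError("need at least one site")
    from .envelopes import extract_cell_values  # local import avoids a cycle

    sid = species_id or species_range.species_id
    sample = extract_cell_values(scenarios.baseline, species_range.current,
                                 context=f"{sid}/current")
    order = np.argsort(sample.values, kind="stable")
    rng = np.random.default_rng(seed)

    sites, truths = [], []
    for i in range(n):
        q = quantiles[i % len(quantiles)]
        pos = int(round(q * (order.size - 1)))
        pos = int(np.clip(pos + rng.integers(-1, 2), 0, order.size - 1))
        row, col = sample.cells[order[pos]]
        lon, lat = scenarios.baseline.transform.xy(row, col)
        site = SiteRecord(sid, f"{sid}-site-{i + 1}", lon, lat)
        fut = np.array([f.values[row, col] for f in scenarios.futures])
        stats = {"mild": fut.min(), "mean": fut.mean(), "extreme": fut.max()}
        truths.append(SiteTruth(
            site=site,
            bio5_baseline=float(scenarios.baseline.values[row, col]),
            bio5_by_scenario=fut,
            exceeds_current_tm={s: bool(x > tm_current) for s, x in stats.items()},
            exceeds_historical_tm={s: bool(x > tm_historical)
                                   for s, x in stats.items()},
        ))
        sites.append(site)
    return sites, truths
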