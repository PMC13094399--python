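"""Translocation-site screening against species thermal maxima.

Each successful release site is treated as a point: the containing grid
cell supplies its baseline BIO5 and its projected value under every
future scenario.  The mildest and most extreme scenarios are defined per
site (the minimum and maximum projected value at that point across the
ensemble) and the mean scenario is the arithmetic mean of the k values.
A site "exceeds" a thermal maximum only strictly (equality to the TM
counts as within, since the TM is an attained envelope value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envelopes import HeatEnvelope
from .geo_io import ClimateGrid, ScenarioSet, SiteRecord

__all__ = [
    "PointSampleError",
    "SiteAssessment",
    "SpeciesSiteSummary",
    "sample_point",
    "assess_site",
    "summarise_species_sites",
]

STATS = ("mild", "mean", "extreme")


class PointSampleError(ValueError):
    """Raised when a point falls outside the grid or on a nodata cell."""


@dataclass
class SiteAssessment:
    site: SiteRecord
    bio5_baseline: float
    bio5_by_scenario: np.ndarray
    exceeds_current_tm: dict[str, bool]
    exceeds_historical_tm: dict[str, bool]

    @property
    def bio5_mild(self) -> float:
        return float(self.bio5_by_scenario.min())

    @property
    def bio5_extreme(self) -> float:
        return float(self.bio5_by_scenario.max())

    @property
    def bio5_mean(self) -> float:
        return float(self.bio5_by_scenario.mean())


@dataclass
class SpeciesSiteSummary:
    """Per-species percentages of sites above each TM, by scenario stat."""

    species_id: str
    n_sites: int
    pct_above_current_tm: dict[str, float]
    pct_above_historical_tm: dict[str, float]


def sample_point(grid: ClimateGrid, lon: float, lat: float,
                 name: str = "") -> float:
    """Value of the cell containing (lon, lat); nearest cell, no interpolation."""
    row, col = grid.transform.rowcol(lon, lat)
    nrows, ncols = grid.shape
    label = name or f"({lon}, {lat})"
    if not (0 <= row < nrows and 0 <= col < ncols):
        raise PointSampleError(f"site {label} falls outside the grid extent")
    if grid.nodata_mask[row, col]:
        raise PointSampleError(f"site {label} falls on a nodata cell")
    return float(grid.values[row, col])


def assess_site(
    site: SiteRecord,
    scenarios: ScenarioSet,
    current_env: HeatEnvelope,
    historical_env: HeatEnvelope,
) -> SiteAssessment:
    """Fill baseline/per-scenario values and strict TM exceedance flags."""
    baseline = sample_point(scenarios.baseline, site.lon, site.lat, site.site_name)
    values = np.array([
        sample_point(fut, site.lon, site.lat, site.site_name)
        for fut in scenarios.futures
    ])
    stats = {"mild": values.min(), "mean": values.mean(), "extreme": values.max()}
    return SiteAssessment(
        site=site,
        bio5_baseline=baseline,
        bio5_by_scenario=values,
        exceeds_current_tm={s: bool(v > current_env.env_max)
                            for s, v in stats.items()},
        exceeds_historical_tm={s: bool(v > historical_env.env_max)
                               for s, v in stats.items()},
    )


def summarise_species_sites(assessments: list[SiteAssessment]) -> SpeciesSiteSummary:
    """Percentage of a species' sites above each TM, per {mild, mean, extreme}."""
    if not assessments:
        raise ValueError("need at least one site assessment")
    species = {a.site.species_id for a in assessments}
    if len(species) != 1:
        raise ValueError(f"assessments mix species: {sorted(species)}")
    n = len(assessments)
    pct_curr = {
        s: 100.0 * sum(a.exceeds_current_tm[s] for a in assessments) / n
        for s in STATS
    }
    pct_hist = {
        s: 100.0 * sum(a.exceeds_historical_tm[s] for a in assessments) / n
        for s in STATS
    }
    return SpeciesSiteSummary(species.pop(), n, pct_curr, pct_hist)
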