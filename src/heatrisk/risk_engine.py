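"""Scenario-ensemble overlap statistics, risk classification and refugia.

For each species, every future layer is sampled over the *current* range
polygon and scored against the baseline current-epoch and
historical-epoch envelopes.  The per-scenario overlap is the percentage
of (weighted) cells whose projected BIO5 remains within the envelope; the
ensemble mean and its standard error (k scenarios) feed the three-tier
rules:

* low       — > threshold% overlap with both current and historical envelopes
* moderate  — > threshold% with historical but not current
* high      — neither

To be conservative, a species is moved up a tier when the standard error
of the ensemble mean overlaps the criterion, i.e. the rules are applied
to mean − SE.  Refugia maps classify each historical-range cell by how
many scenarios keep it at or below the historical thermal maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .envelopes import (
    EmptyExtractionError,
    HeatEnvelope,
    ValueSample,
    compute_envelope,
    extract_cell_values,
)
from .geo_io import ClimateGrid, ScenarioSet, SpeciesRange

__all__ = [
    "OverlapSummary",
    "RiskAssessment",
    "RefugiaMap",
    "REFUGIA_CODES",
    "overlap_percent",
    "summarise_overlaps",
    "classify_risk",
    "refugia_map",
]

OverlapMode = Literal["upper", "two_sided"]
Tier = Literal["low", "moderate", "high"]

TIER_ORDER = {"low": 0, "moderate": 1, "high": 2}

# categorical raster codes for refugia maps
REFUGIA_CODES = {"outside": 0, "all": 1, "some": 2, "none": 3}


@dataclass
class OverlapSummary:
    """Per-scenario overlap percentages and their ensemble mean ± SE."""

    species_id: str
    per_scenario_current: np.ndarray
    per_scenario_historical: np.ndarray

    def __post_init__(self) -> None:
        self.per_scenario_current = np.asarray(self.per_scenario_current, float)
        self.per_scenario_historical = np.asarray(self.per_scenario_historical, float)
        for arr in (self.per_scenario_current, self.per_scenario_historical):
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError("need at least one scenario overlap")
            if np.any((arr < 0) | (arr > 100)):
                raise ValueError("overlap percentages must lie in [0, 100]")
        if self.per_scenario_current.size != self.per_scenario_historical.size:
            raise ValueError("scenario lists differ in length")

    @property
    def k(self) -> int:
        return self.per_scenario_current.size

    @property
    def mean_current(self) -> float:
        return float(self.per_scenario_current.mean())

    @property
    def mean_historical(self) -> float:
        return float(self.per_scenario_historical.mean())

    @property
    def se_current(self) -> float:
        return _sem(self.per_scenario_current)

    @property
    def se_historical(self) -> float:
        return _sem(self.per_scenario_historical)


def _sem(values: np.ndarray) -> float:
    """Ensemble SEM: sample SD (k−1 denominator) / sqrt(k); 0 for k=1."""
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(values.size))


@dataclass
class RiskAssessment:
    species_id: str
    overlap: OverlapSummary
    tier: Tier
    upgraded: bool
    threshold: float = 50.0


@dataclass
class RefugiaMap:
    """Categorical grid over the historical range plus area fractions.

    ``categories`` covers the whole grid with codes 0=outside, 1=all
    (below the benchmark TM in every scenario), 2=some, 3=none;
    ``area_fractions`` are the proportions of historical-range cells in
    each of {all, some, none} and sum to 1.
    """

    species_id: str
    categories: np.ndarray
    area_fractions: dict[str, float]
    benchmark_tm: float
    transform: object = None
    crs: str = ""

    def __post_init__(self) -> None:
        total = sum(self.area_fractions[k] for k in ("all", "some", "none"))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"area fractions sum to {total}, not 1")


def overlap_percent(
    future_sample: ValueSample,
    envelope: HeatEnvelope,
    mode: OverlapMode = "upper",
) -> float:
    """Percentage of (weighted) cells remaining within the envelope.

    ``upper`` counts cells whose projected value does not exceed the
    envelope's thermal maximum — the construct is heat exposure, so
    cooling below env_min is not treated as leaving the envelope.
    ``two_sided`` requires env_min ≤ value ≤ env_max.  Ties at the TM
    count as within (the TM is an attained envelope value).
    """
    v = future_sample.values
    if mode == "upper":
        within = v <= envelope.env_max
    elif mode == "two_sided":
        within = (v >= envelope.env_min) & (v <= envelope.env_max)
    else:
        raise ValueError(f"unknown overlap mode {mode!r}")
    w = future_sample.weights
    return float(100.0 * np.sum(w * within) / np.sum(w))


def summarise_overlaps(
    species: SpeciesRange,
    scenarios: ScenarioSet,
    mode: OverlapMode = "upper",
    inclusion_rule: str = "center",
    area_weighting: bool = False,
) -> OverlapSummary:
    """Score every future layer over the current range against both
    baseline envelopes and aggregate across the ensemble."""
    base_curr = extract_cell_values(
        scenarios.baseline, species.current, inclusion_rule, area_weighting,
        context=f"{species.species_id}/current")
    base_hist = extract_cell_values(
        scenarios.baseline, species.historical, inclusion_rule, area_weighting,
        context=f"{species.species_id}/historical")
    env_curr = compute_envelope(base_curr, "current")
    env_hist = compute_envelope(base_hist, "historical")

    # future layers are aligned, so sample them at the same cells
    rr, cc = base_curr.cells[:, 0], base_curr.cells[:, 1]
    pc, ph = [], []
    for fut in scenarios.futures:
        fut_sample = ValueSample(fut.values[rr, cc], base_curr.cells,
                                 base_curr.weights)
        pc.append(overlap_percent(fut_sample, env_curr, mode))
        ph.append(overlap_percent(fut_sample, env_hist, mode))
    return OverlapSummary(species.species_id, np.array(pc), np.array(ph))


def _tier_from(mean_c: float, mean_h: float, threshold: float) -> Tier:
    if mean_c > threshold and mean_h > threshold:
        return "low"
    if mean_h > threshold:
        return "moderate"
    return "high"


def classify_risk(overlap: OverlapSummary, threshold: float = 50.0) -> RiskAssessment:
    """Apply the three-tier rules to the conservative lower bounds.

    The effective overlaps are mean − SE for each envelope; ``upgraded``
    is True when the SE adjustment changes the tier relative to the raw
    means.  The criteria are strict ("> threshold"), so a value exactly
    at the threshold fails it.  The adjustment is one-directional: a
    species is only ever moved to a *higher* risk tier.
    """
    m_c = overlap.mean_current - overlap.se_current
    m_h = overlap.mean_historical - overlap.se_historical
    tier = _tier_from(m_c, m_h, threshold)
    raw = _tier_from(overlap.mean_current, overlap.mean_historical, threshold)
    return RiskAssessment(overlap.species_id, overlap, tier,
                          upgraded=tier != raw, threshold=threshold)


def refugia_map(
    species: SpeciesRange,
    scenarios: ScenarioSet,
    hist_envelope: HeatEnvelope,
    benchmark: Literal["historical", "current"] = "historical",
    benchmark_envelope: HeatEnvelope | None = None,
    inclusion_rule: str = "center",
) -> RefugiaMap:
    """Classify each historical-range cell by scenario exceedance.

    A cell counts toward ``all`` when its projected BIO5 stays at or
    below the benchmark thermal maximum in every scenario, ``some`` when
    it does so in at least one but not all scenarios, and ``none`` when
    every scenario pushes it past the benchmark.  The benchmark defaults
    to the historical TM; benchmarking against the current TM is an
    exploratory option.
    """
    if benchmark == "historical":
        tm = hist_envelope.env_max
    elif benchmark == "current":
        if benchmark_envelope is None:
            raise ValueError("current benchmark needs benchmark_envelope")
        tm = benchmark_envelope.env_max
    else:
        raise ValueError(f"unknown benchmark {benchmark!r}")

    sample = extract_cell_values(
        scenarios.baseline, species.historical, inclusion_rule,
        context=f"{species.species_id}/historical")
    rr, cc = sample.cells[:, 0], sample.cells[:, 1]
    k = scenarios.k
    counts = np.zeros(sample.n_cells, dtype=int)
    for fut in scenarios.futures:
        counts += fut.values[rr, cc] <= tm

    categories = np.full(scenarios.baseline.shape, REFUGIA_CODES["outside"],
                         dtype=np.uint8)
    cell_code = np.where(counts == k, REFUGIA_CODES["all"],
                         np.where(counts == 0, REFUGIA_CODES["none"],
                                  REFUGIA_CODES["some"]))
    categories[rr, cc] = cell_code
    n = sample.n_cells
    fractions = {
        "all": float(np.sum(counts == k)) / n,
        "some": float(np.sum((counts > 0) & (counts < k))) / n,
        "none": float(np.sum(counts == 0)) / n,
    }
    return RefugiaMap(species.species_id, categories, fractions, tm,
                      transform=scenarios.baseline.transform,
                      crs=scenarios.baseline.crs)
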