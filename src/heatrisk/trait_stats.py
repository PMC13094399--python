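"""Association tests linking risk tier to species traits, plus the
literature-tally summaries.

Categorical traits (taxonomic order, IUCN status) against risk tier use
Pearson chi-squared tests of independence without continuity correction;
continuous traits (log10 range size, log10 body size, thermal-maximum
difference Δ, envelope widths, % arid, % remnant) across risk tiers use
tie-corrected Kruskal–Wallis tests with pairwise Dunn post hoc z tests.
Report percentages are rounded half-away-from-zero to whole percent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "GroupedValues",
    "TestResult",
    "PairwiseResult",
    "DegenerateTableError",
    "chi_squared_independence",
    "kruskal_wallis",
    "dunn_posthoc",
    "risk_crosstab",
    "review_tally",
    "load_trait_table",
    "round_half_away",
]

Adjustment = Literal["none", "holm", "bonferroni"]

TIERS = ("high", "moderate", "low")


class DegenerateTableError(ValueError):
    """Raised when a contingency table has a zero expected count."""


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise ValueError("need at least a 2x2 table")
        if np.any(self.counts < 0) or self.counts.sum() < 1:
            raise ValueError("counts must be non-negative with total >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)

    def row_percentages(self) -> pd.DataFrame:
        """Row-normalised percentages rounded to whole percent for report
        parity (half-away-from-zero)."""
        totals = self.counts.sum(axis=1, keepdims=True)
        pct = 100.0 * self.counts / np.where(totals == 0, 1, totals)
        rounded = np.vectorize(round_half_away)(pct)
        return pd.DataFrame(rounded, index=self.row_labels,
                            columns=self.col_labels, dtype=int)


@dataclass
class GroupedValues:
    """Labelled numeric groups (e.g. risk tier → trait values)."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        self.groups = {k: np.asarray(v, dtype=np.float64)
                       for k, v in self.groups.items()}
        for name, vals in self.groups.items():
            if vals.size == 0:
                raise ValueError(f"group {name!r} is empty")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"group {name!r} has non-finite values")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: int | None = None


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    z: float
    p_value: float
    p_adjusted: float


def round_half_away(x: float) -> int:
    """Round half away from zero (3.5 → 4, −3.5 → −4), unlike banker's."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def chi_squared_independence(table: ContingencyTable) -> TestResult:
    """Pearson chi-squared test of independence, no continuity correction."""
    counts = table.counts
    expected = sps.contingency.expected_freq(counts)
    if np.any(expected == 0):
        raise DegenerateTableError("expected count of zero; collapse categories")
    chi2, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return TestResult(float(chi2), float(p), int(df))


def kruskal_wallis(data: GroupedValues) -> TestResult:
    """Tie-corrected Kruskal–Wallis H with chi-squared approximate p.

    All-identical values across groups give H = 0, p = 1 (no evidence of
    difference), not an error.
    """
    samples = list(data.groups.values())
    df = len(samples) - 1
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, df)
    h, p = sps.kruskal(*samples)
    return TestResult(float(h), float(p), df)


def dunn_posthoc(data: GroupedValues,
                 adjustment: Adjustment = "none") -> list[PairwiseResult]:
    """Dunn's pairwise rank-based post hoc comparisons.

    z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − ΣT/(12(N−1))) (1/n_i + 1/n_j)]
    with ΣT = Σ(t³ − t) over tie groups; two-sided normal p-values with
    optional Holm or Bonferroni adjustment across all pairs.
    """
    names = list(data.groups)
    sizes = {k: v.size for k, v in data.groups.items()}
    pooled = np.concatenate([data.groups[k] for k in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    start = 0
    for k in names:
        mean_ranks[k] = float(ranks[start:start + sizes[k]].mean())
        start += sizes[k]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    raw: list[tuple[str, str, float, float]] = []
    for a, b in combinations(names, 2):
        denom = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / denom if denom > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        raw.append((a, b, z, min(p, 1.0)))

    pvals = [r[3] for r in raw]
    if adjustment == "none":
        adj = pvals
    elif adjustment in ("holm", "bonferroni"):
        adj = list(multipletests(pvals, method=adjustment)[1])
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    return [PairwiseResult(a, b, z, p, float(q))
            for (a, b, z, p), q in zip(raw, adj)]


def risk_crosstab(
    tiers: Mapping[str, str],
    trait: Mapping[str, str],
    row_order: Sequence[str] | None = None,
    col_order: Sequence[str] = TIERS,
) -> ContingencyTable:
    """Cross-tabulate a categorical trait (rows) against risk tier (cols).

    ``tiers`` maps species_id → tier, ``trait`` maps species_id → trait
    level.  Species missing a trait value are listed in a warning and
    excluded.
    """
    missing = sorted(set(tiers) - set(trait))
    if missing:
        warnings.warn(f"species missing trait value, excluded: {missing}",
                      stacklevel=2)
    kept = {sid: t for sid, t in tiers.items() if sid in trait}
    rows = list(row_order) if row_order else sorted({trait[s] for s in kept})
    cols = [c for c in col_order if c in set(kept.values())] or list(col_order)
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    ri = {r: i for i, r in enumerate(rows)}
    ci = {c: i for i, c in enumerate(cols)}
    for sid, tier in kept.items():
        if trait[sid] in ri and tier in ci:
            counts[ri[trait[sid]], ci[tier]] += 1
    return ContingencyTable(rows, cols, counts)


def review_tally(
    study_counts: Mapping[str, float],
    tiers: Mapping[str, str],
) -> tuple[pd.DataFrame, TestResult]:
    """Per-tier mean/median study counts plus a Kruskal–Wallis test.

    Tests whether research attention (papers per species) is biased
    across the heat-risk categories.
    """
    grouped: dict[str, list[float]] = {}
    for sid, count in study_counts.items():
        if sid not in tiers:
            raise KeyError(f"species {sid!r} has no risk tier")
        if count < 0:
            raise ValueError(f"negative study count for {sid!r}")
        grouped.setdefault(tiers[sid], []).append(float(count))

    rows = []
    for tier in TIERS:
        if tier in grouped:
            vals = np.array(grouped[tier])
            rows.append({"tier": tier, "n_species": vals.size,
                         "mean_studies": float(vals.mean()),
                         "median_studies": float(np.median(vals))})
    summary = pd.DataFrame(rows).set_index("tier")
    if len(grouped) >= 2:
        kw = kruskal_wallis(GroupedValues({k: np.array(v)
                                           for k, v in grouped.items()}))
    else:
        kw = TestResult(0.0, 1.0, 0)
    return summary, kw


def load_trait_table(
    path,
    log10_columns: Sequence[str] = ("mass_g", "range_area_current_km2",
                                    "range_area_historical_km2"),
) -> pd.DataFrame:
    """Load the species trait table, applying log10 to size/area columns.

    Base-10 logs of body mass and range areas are taken at load so the
    continuous-trait tests operate on the transformed scale.
    """
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise KeyError("trait table needs a species_id column")
    for col in log10_columns:
        if col in df.columns:
            if (df[col] <= 0).any():
                raise ValueError(f"column {col!r} must be positive for log10")
            df[f"log10_{col}"] = np.log10(df[col])
    return df.set_index("species_id")
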