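"""Bundled reference tables for the 36 threatened Australian dryland
mammal species used to exercise the reporting stages: published risk
tiers with taxonomy and conservation status, per-species translocation
site counts, and thermal-ecology study counts for the high-risk group.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

__all__ = ["load_species_risk_table", "load_site_counts", "load_study_counts"]


def _read(name: str) -> pd.DataFrame:
    with files("heatrisk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_species_risk_table() -> pd.DataFrame:
    """Species, taxonomic order, IUCN status, body mass, range decline
    and assigned heat-risk tier for all 36 species."""
    return _read("species_risk_table.csv")


def load_site_counts() -> pd.DataFrame:
    """Number of successful translocation sites per species (0 for
    never-translocated species)."""
    return _read("translocation_site_counts.csv")


def load_study_counts() -> pd.DataFrame:
    """Published thermal-ecology study counts for the eight high-risk
    species."""
    return _read("high_risk_study_counts.csv")
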