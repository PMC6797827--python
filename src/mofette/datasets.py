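"""Bundled data tables from the mofette field study, plus a synthetic
element table standing in for unpublished supplementary data."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .core_io import GasComposition, SoilSample, read_elements_table, read_gas_table, read_soil_table


def _data_path(name: str) -> Path:
    return Path(resources.files("mofette").joinpath("data", name))  # type: ignore[arg-type]


def load_gas_profiles() -> list[GasComposition]:
    """Interstitial soil-gas profiles (sites 3-6, 8) and the bubbling-pool
    sample ``BP``, as printed: majors in mmol/mol, traces in μmol/mol,
    δ13C in ‰ vs V-PDB, below-detection cells kept as limits."""
    return read_gas_table(_data_path("table2_gas.tsv"))


def load_bubbling_pool() -> GasComposition:
    """The deep (bubbling pool) end-member sample."""
    return next(s for s in load_gas_profiles() if s.site == "BP")


def load_soil_profiles() -> list[SoilSample]:
    """Soil pH, HCl effervescence class and C/N content per site/horizon."""
    return read_soil_table(_data_path("table1_soil.tsv"))


def load_simper_printed() -> pd.DataFrame:
    """The published top-10 SIMPER table (percent contributions %Con and
    cumulative %Cum between high- and low-CO2 communities)."""
    return pd.read_csv(_data_path("table3_simper.tsv"), sep="\t")


def load_elements_synthetic() -> pd.DataFrame:
    """Synthetic site × element table (mg/kg).

    Constructed, not measured: the study's element data are unpublished.
    Values reproduce the reported relative-change structure of site 7
    versus the mean of sites 3 and 4 (Ca -93%, P +604%, K +113%).
    """
    return read_elements_table(_data_path("elements_synthetic.tsv"))
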