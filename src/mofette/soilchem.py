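"""Derived soil-chemistry quantities: C:N ratios, toposequence summaries
and relative element changes between sites along the gradient."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core_io import SoilSample


@dataclass
class ToposequenceSummary:
    """Min/max and ordered per-site values of one variable along the
    topographic gradient (sink-rim → back-slope → toe-slope)."""

    variable: str
    minimum: float
    maximum: float
    per_site: "pd.Series"  # site -> list of values, ordered along the gradient


def cn_ratio(c_pct: float, n_pct: float) -> float | None:
    """Mass-based C:N ratio; ``None`` (missing) when N% is zero."""
    if n_pct < 0 or c_pct < 0:
        raise ValueError("C% and N% must be non-negative")
    if n_pct == 0:
        return None
    return c_pct / n_pct


def cn_rounding_tolerance(c_pct: float, n_pct: float, resolution: float = 0.01) -> float:
    """Relative agreement bound for a C:N ratio recomputed from printed
    (rounded) C% and N%.

    With both inputs rounded to ``resolution``, first-order error
    propagation bounds the quotient's relative error by
    0.5·resolution/C + 0.5·resolution/N.  For nitrogen-poor horizons
    (N% ≈ 0.1-0.3 printed to two decimals) this is 1-3%, far looser than
    the quotient's own printing precision.
    """
    if c_pct <= 0 or n_pct <= 0:
        raise ValueError("C% and N% must be positive")
    return 0.5 * resolution / c_pct + 0.5 * resolution / n_pct


def relative_change(target: float, reference: float) -> float:
    """Percent change of ``target`` relative to ``reference``:
    100·(target - reference)/reference."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    return 100.0 * (target - reference) / reference


def element_changes(
    elements: pd.DataFrame,
    target_site: str,
    reference_sites: Sequence[str],
) -> pd.Series:
    """Per-element percent change of a target site versus the unweighted
    mean of the reference sites (e.g. toe-slope site 7 vs sites 3 and 4)."""
    missing = [s for s in [target_site, *reference_sites] if s not in elements.index]
    if missing:
        raise KeyError(f"sites not in element table: {missing}")
    ref = elements.loc[list(reference_sites)].mean(axis=0)
    tgt = elements.loc[target_site]
    return pd.Series(
        {el: relative_change(float(tgt[el]), float(ref[el])) for el in elements.columns},
        name=f"{target_site} vs mean({','.join(reference_sites)})",
    )


def toposequence_summary(
    samples: Sequence[SoilSample],
    variable: str,
    site_order: Sequence[str] | None = None,
) -> ToposequenceSummary:
    """Range and per-site values of a soil variable along the gradient.

    ``variable`` is one of pH, N_pct, C_pct, or CN (recomputed from C% and
    N%, skipping horizons with N% = 0).
    """
    def value(s: SoilSample) -> float | None:
        if variable == "pH":
            return s.pH
        if variable == "N_pct":
            return s.N_pct
        if variable == "C_pct":
            return s.C_pct
        if variable == "CN":
            return cn_ratio(s.C_pct, s.N_pct)
        raise KeyError(f"unknown soil variable {variable!r}")

    values = [(s.site, value(s)) for s in samples]
    values = [(site, v) for site, v in values if v is not None]
    if not values:
        raise ValueError(f"no samples with variable {variable!r}")
    order = list(site_order) if site_order else list(dict.fromkeys(site for site, _ in values))
    per_site = pd.Series(
        {site: [v for s, v in values if s == site] for site in order}, name=variable
    )
    allv = [v for _, v in values]
    return ToposequenceSummary(
        variable=variable, minimum=min(allv), maximum=max(allv), per_site=per_site
    )
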