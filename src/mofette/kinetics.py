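"""Anoxic bottle-incubation analysis for H2-driven acetogenesis.

Covers headspace amount conversion (ideal gas), feeding-cycle segmentation
around H2 re-spikes, windowed maximum production rates normalised per gram
dry soil, and the electron-equivalent balance expressing acetate and
methane yields as percentages of the H2 consumed (8 eq/mol acetate,
8 eq/mol methane, 2 eq/mol H2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np

#: Electron equivalents per mole.
EQ_PER_MOL = {"acetate": 8.0, "methane": 8.0, "hydrogen": 2.0}

#: L·atm/(mol·K)
R_GAS = 0.0820573660809596


@dataclass
class IncubationTimeSeries:
    """Bottle time course: headspace gases and liquid acetate as amounts.

    All analyte arrays are cumulative amounts in μmol at each time point
    (days); tracking amounts rather than concentrations absorbs the
    replacement of liquid sampled for analysis.
    """

    times: np.ndarray  # days, strictly increasing
    h2: np.ndarray | None = None  # μmol in headspace
    co2: np.ndarray | None = None
    ch4: np.ndarray | None = None
    acetate: np.ndarray | None = None  # μmol in liquid
    dry_mass: float = 1.0  # g
    headspace_volume: float = 80.0  # mL
    liquid_volume: float = 40.0  # mL
    temperature: float = 298.15  # K
    pressure: float = 1.0  # atm
    respike_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need at least two time points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.dry_mass <= 0:
            raise ValueError("dry_mass must be > 0")
        if self.headspace_volume <= 0:
            raise ValueError("headspace_volume must be > 0")
        for name in ("h2", "co2", "ch4", "acetate"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.times.shape:
                    raise ValueError(f"{name} length does not match times")
                if (arr < -1e-9).any():
                    raise ValueError(f"negative amounts in {name}")
                setattr(self, name, arr)

    def analyte(self, name: Literal["acetate", "methane", "h2", "co2"]) -> np.ndarray:
        key = {"methane": "ch4", "hydrogen": "h2"}.get(name, name)
        arr = getattr(self, key)
        if arr is None:
            raise ValueError(f"series has no {name} data")
        return arr


@dataclass
class RateEstimate:
    """Maximum windowed production rate, normalised per g dry weight."""

    max_rate: float  # μmol/(g·d)
    window: tuple[float, float]  # (start_day, end_day)
    slope_se: float  # μmol/(g·d)
    negative_clipped: bool = False


@dataclass
class ElectronBalance:
    """Reducing-equivalent bookkeeping of one incubation (meq = μmol·eq)."""

    eq_h2_consumed: float
    eq_acetate: float
    eq_ch4: float
    yield_acetate_pct: float
    yield_ch4_pct: float
    factors: dict[str, float] = field(default_factory=lambda: dict(EQ_PER_MOL))
    imbalance: bool = False

    @property
    def eq_unaccounted(self) -> float:
        return self.eq_h2_consumed - self.eq_acetate - self.eq_ch4


def headspace_moles(
    volume_fraction: float,
    headspace_volume: float,
    temperature: float = 298.15,
    pressure: float = 1.0,
) -> float:
    """Ideal-gas μmol of a species occupying ``volume_fraction`` of the
    headspace (mL) at ``temperature`` (K) and ``pressure`` (atm)."""
    if not 0.0 <= volume_fraction <= 1.0:
        raise ValueError("volume_fraction must be in [0, 1]")
    if headspace_volume <= 0 or temperature <= 0 or pressure <= 0:
        raise ValueError("volume, temperature and pressure must be positive")
    v_l = volume_fraction * headspace_volume / 1000.0
    return pressure * v_l / (R_GAS * temperature) * 1e6


def segment_cycles(series: IncubationTimeSeries) -> list[IncubationTimeSeries]:
    """Split a time course into feeding cycles at the re-spike times.

    A re-spike at time ``r`` ends the running cycle just before ``r``: the
    first observation at or after ``r`` carries the post-spike headspace
    and starts the next cycle (cycle intervals are half-open, [start, r)).
    Concatenating the segments reproduces the full series exactly.
    """
    if not series.respike_times:
        return [series]
    t = series.times
    boundaries: list[int] = []
    for rt in series.respike_times:
        if rt <= t[0] or rt > t[-1]:
            raise ValueError(f"respike time {rt} outside observed range ({t[0]}, {t[-1]}]")
        boundaries.append(int(np.searchsorted(t, rt - 1e-12)))
    boundaries = sorted(set(boundaries))
    segments: list[IncubationTimeSeries] = []
    starts = [0] + boundaries
    ends = boundaries + [len(t)]
    for lo, hi in zip(starts, ends):
        if hi - lo < 2:
            raise ValueError("degenerate feeding cycle with < 2 observations")
        sl = slice(lo, hi)
        segments.append(
            replace(
                series,
                times=t[sl],
                h2=None if series.h2 is None else series.h2[sl],
                co2=None if series.co2 is None else series.co2[sl],
                ch4=None if series.ch4 is None else series.ch4[sl],
                acetate=None if series.acetate is None else series.acetate[sl],
                respike_times=(),
            )
        )
    return segments


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and its standard error (0 SE for a 2-point window)."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    if n <= 2:
        return slope, 0.0
    resid = y - (ym + slope * (x - xm))
    s2 = float((resid**2).sum() / (n - 2))
    return slope, math.sqrt(s2 / sxx)


def max_production_rate(
    series: IncubationTimeSeries,
    analyte: Literal["acetate", "methane"] = "acetate",
    window_points: int = 3,
) -> RateEstimate:
    """Maximum specific production rate in μmol/(g dry weight · day).

    OLS slope of cumulative analyte amount vs time over every run of
    ``window_points`` consecutive observations; the maximum slope is
    normalised by dry mass.  A negative maximum is reported as 0 with
    ``negative_clipped`` set.
    """
    if window_points < 2:
        raise ValueError("window_points must be ≥ 2")
    y = series.analyte(analyte)
    t = series.times
    if len(t) < window_points:
        raise ValueError("fewer observations than window_points")
    best_slope = -math.inf
    best: tuple[float, float, float] | None = None
    for i in range(len(t) - window_points + 1):
        sl = slice(i, i + window_points)
        slope, se = _ols_slope(t[sl], y[sl])
        if slope > best_slope:
            best_slope = slope
            best = (t[sl][0], t[sl][-1], se)
    assert best is not None
    start, end, se = best
    rate = best_slope / series.dry_mass
    se_rate = se / series.dry_mass
    if rate < 0:
        return RateEstimate(max_rate=0.0, window=(start, end), slope_se=se_rate, negative_clipped=True)
    return RateEstimate(max_rate=rate, window=(start, end), slope_se=se_rate)


def h2_consumed(series: IncubationTimeSeries) -> float:
    """Total H2 consumed (μmol) summed over feeding cycles.

    Within each cycle H2 declines from its post-spike value; consumption
    is the start-minus-end difference per cycle.
    """
    total = 0.0
    for seg in segment_cycles(series):
        h2 = seg.analyte("h2")
        total += max(0.0, float(h2[0] - h2[-1]))
    return total


def electron_balance(
    h2_consumed_umol: float,
    acetate_formed_umol: float,
    ch4_formed_umol: float = 0.0,
) -> ElectronBalance:
    """Reducing-equivalent yields of acetate and methane from consumed H2.

    yield_acetate% = 100 · (8 · acetate) / (2 · H2);
    yield_CH4%     = 100 · (8 · CH4) / (2 · H2).
    """
    for name, v in (
        ("h2_consumed", h2_consumed_umol),
        ("acetate_formed", acetate_formed_umol),
        ("ch4_formed", ch4_formed_umol),
    ):
        if v < 0:
            raise ValueError(f"{name} must be ≥ 0")
    eq_h2 = EQ_PER_MOL["hydrogen"] * h2_consumed_umol
    eq_ac = EQ_PER_MOL["acetate"] * acetate_formed_umol
    eq_ch4 = EQ_PER_MOL["methane"] * ch4_formed_umol
    if h2_consumed_umol == 0.0:
        return ElectronBalance(
            eq_h2_consumed=0.0,
            eq_acetate=eq_ac,
            eq_ch4=eq_ch4,
            yield_acetate_pct=float("nan"),
            yield_ch4_pct=float("nan"),
            imbalance=(eq_ac + eq_ch4) > 0,
        )
    return ElectronBalance(
        eq_h2_consumed=eq_h2,
        eq_acetate=eq_ac,
        eq_ch4=eq_ch4,
        yield_acetate_pct=100.0 * eq_ac / eq_h2,
        yield_ch4_pct=100.0 * eq_ch4 / eq_h2,
    )


def balance_from_series(series: IncubationTimeSeries) -> ElectronBalance:
    """Pooled electron balance of a whole incubation time course."""
    ac = series.acetate
    ch4 = series.ch4
    ac_formed = float(ac[-1] - ac[0]) if ac is not None else 0.0
    ch4_formed = float(ch4[-1] - ch4[0]) if ch4 is not None else 0.0
    return electron_balance(h2_consumed(series), max(0.0, ac_formed), max(0.0, ch4_formed))


# ---------------------------------------------------------------------------
# TSV I/O


def read_incubation_table(path: str | Path) -> IncubationTimeSeries:
    """Read an incubation TSV: ``#key: value`` metadata header lines
    (dry_mass_g, headspace_ml, liquid_ml, temperature_k, pressure_atm,
    respike_days as comma-separated list) followed by a ``time_d`` column
    and analyte columns.  ``*_umol`` columns are amounts; ``*_frac``
    columns are headspace volume fractions converted via the ideal gas
    law using the declared headspace volume, temperature and pressure.
    """
    meta: dict[str, str] = {}
    header: list[str] = []
    rows: list[list[str]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        cells = line.split("\t")
        if not header:
            header = [c.strip() for c in cells]
        else:
            rows.append(cells)
    data = {h: np.array([float(r[i]) for r in rows]) for i, h in enumerate(header)}
    if "time_d" not in data:
        raise ValueError("incubation table must have a time_d column")

    hs = float(meta.get("headspace_ml", 80.0))
    temp = float(meta.get("temperature_k", 298.15))
    pres = float(meta.get("pressure_atm", 1.0))
    respikes = tuple(
        float(x) for x in meta.get("respike_days", "").split(",") if x.strip()
    )

    def amounts(gas: str) -> np.ndarray | None:
        if f"{gas}_umol" in data:
            return data[f"{gas}_umol"]
        if f"{gas}_frac" in data:
            return np.array(
                [headspace_moles(v, hs, temp, pres) for v in data[f"{gas}_frac"]]
            )
        return None

    acetate = None
    liquid = float(meta.get("liquid_ml", 40.0))
    if "acetate_umol" in data:
        acetate = data["acetate_umol"]
    elif "acetate_mm" in data:
        acetate = data["acetate_mm"] * liquid  # mM × mL = μmol

    return IncubationTimeSeries(
        times=data["time_d"],
        h2=amounts("h2"),
        co2=amounts("co2"),
        ch4=amounts("ch4"),
        acetate=acetate,
        dry_mass=float(meta.get("dry_mass_g", 1.0)),
        headspace_volume=hs,
        liquid_volume=liquid,
        temperature=temp,
        pressure=pres,
        respike_times=respikes,
    )
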