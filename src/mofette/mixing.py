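"""Two-end-member (air vs deep geogenic gas) mass-balance mixing model.

An observed interstitial soil gas is modelled as a linear mixture of
atmospheric air and the deep end member sampled at the bubbling pool (BP):

    c_mix(s) = f * c_deep(s) + (1 - f) * c_air(s)

with a single deep-gas fraction ``f`` in [0, 1] for all species.  The
fraction is inverted from a conservative tracer (closed form) or a species
set (weighted least squares); per-species residuals against the mixture
prediction then diagnose secondary processes: N2/CO2 excess from O2
consumption in the soil air, CH4 depletion from microbial methane
oxidation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import GasComposition, SubstitutionPolicy
from .isotopes import mix_isotope

#: Standard dry-atmosphere composition used as the air end member
#: (μmol/mol; CO2 at the modern ambient value).  Overridable in config.
AIR_COMPOSITION: dict[str, float] = {
    "N2": 780_900.0,
    "O2": 209_500.0,
    "Ar": 9_340.0,
    "CO2": 410.0,
    "CH4": 1.9,
    "C2H6": 0.0,
    "H2S": 0.0,
}

#: δ13C of ambient atmospheric CO2 (‰ vs V-PDB), overridable.
AIR_D13C_CO2: float = -8.0

#: Default relative-anomaly cutoff for process flags.
DEFAULT_ANOMALY_THRESHOLD: float = 0.05

#: Anchor tracer per diagnostic species, mirroring the binary mixing
#: diagrams: N2 excess is judged at the sample's CO2, while CO2 excess and
#: CH4/O2 depletion are judged at the sample's N2.
DIAGNOSTIC_ANCHORS: dict[str, str] = {"N2": "CO2", "CO2": "N2", "CH4": "N2", "O2": "N2"}


def air_endmember() -> GasComposition:
    """The default atmospheric end member."""
    return GasComposition(
        site="air", depth_cm=None, conc=dict(AIR_COMPOSITION), d13c={"CO2": AIR_D13C_CO2}
    )


@dataclass
class EndMemberPair:
    """The two mixing end members: air and the deep (bubbling pool) gas."""

    air: GasComposition
    deep: GasComposition
    label: str = "air-BP"

    def shared_species(self) -> set[str]:
        return self.air.species() & self.deep.species()

    def __post_init__(self) -> None:
        shared = self.shared_species()
        if not shared:
            raise ValueError("end members share no species")
        # inversion requires at least one contrasting species
        differs = any(
            self.air.get(s, "half") != self.deep.get(s, "half") for s in shared
        )
        if not differs:
            raise ValueError("air and deep end members are identical; inversion undefined")


def default_pair(deep: GasComposition, air: GasComposition | None = None) -> EndMemberPair:
    return EndMemberPair(air=air if air is not None else air_endmember(), deep=deep)


@dataclass
class MixingFit:
    """An inferred deep-gas fraction with per-species residuals."""

    f: float
    tracer: str | tuple[str, ...]
    residuals: dict[str, float] = field(default_factory=dict)  # obs - pred, μmol/mol
    relative_residuals: dict[str, float] = field(default_factory=dict)
    clipped: bool = False

    @property
    def f_percent(self) -> float:
        return 100.0 * self.f


@dataclass
class ProcessFlags:
    """Qualitative process diagnoses from mixing residuals.

    ``None`` marks a flag that could not be evaluated (species missing or
    predicted concentration zero).
    """

    n2_excess: bool | None
    co2_excess: bool | None
    ch4_depletion: bool | None
    o2_depletion: bool | None
    threshold: float

    def any_process(self) -> bool:
        return any(v for v in (self.n2_excess, self.co2_excess, self.ch4_depletion, self.o2_depletion))


def predict_mixture(
    f: float,
    pair: EndMemberPair,
    policy: SubstitutionPolicy = "half",
) -> GasComposition:
    """Forward mixture composition at deep-gas fraction ``f``.

    Isotope values present on both end members are mixed by concentration-
    weighted mass balance (see :func:`mofette.isotopes.mix_isotope`).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"mixing fraction f={f} outside [0, 1]")
    conc: dict[str, float] = {}
    for sp in sorted(pair.shared_species()):
        a = pair.air.get(sp, policy)
        d = pair.deep.get(sp, policy)
        conc[sp] = f * d + (1.0 - f) * a
    d13c: dict[str, float] = {}
    for sp in set(pair.air.d13c) & set(pair.deep.d13c):
        d13c[sp] = mix_isotope(
            f,
            deep=(pair.deep.get(sp, policy), pair.deep.d13c[sp]),
            air=(pair.air.get(sp, policy), pair.air.d13c[sp]),
        )
    return GasComposition(
        site=f"{pair.label} f={f:g}", depth_cm=None, conc=conc, d13c=d13c
    )


def mixing_curve(
    pair: EndMemberPair,
    grid: Sequence[float] | None = None,
    policy: SubstitutionPolicy = "half",
) -> list[tuple[float, GasComposition]]:
    """Predicted compositions along a grid of deep-gas fractions.

    Default grid: 101 evenly spaced fractions spanning [0, 1].
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = list(grid)
    if len(grid) == 0:
        raise ValueError("empty fraction grid")
    return [(float(f), predict_mixture(float(f), pair, policy)) for f in grid]


def _endmember_values(
    species: str, pair: EndMemberPair, policy: SubstitutionPolicy
) -> tuple[float, float]:
    return pair.air.get(species, policy), pair.deep.get(species, policy)


def infer_deep_fraction(
    obs: GasComposition,
    pair: EndMemberPair,
    tracer: str | Sequence[str] = "Ar",
    substitution: SubstitutionPolicy = "half",
    weights: Mapping[str, float] | None = None,
) -> MixingFit:
    """Invert the deep-gas fraction from a tracer or a species set.

    Single tracer: closed form ``f = (obs - air) / (deep - air)``, clipped
    to [0, 1] (``clipped=True`` when outside).  Species set: weighted least
    squares over the set, weights defaulting to ``1/air_s`` (``1/deep_s``
    for species absent from air).  Residuals are evaluated for every
    species shared by the observation and both end members.
    """
    single = isinstance(tracer, str)
    tracers: tuple[str, ...] = (tracer,) if single else tuple(tracer)
    if len(tracers) == 0:
        raise ValueError("empty tracer set")
    for sp in tracers:
        if sp not in obs.species():
            raise ValueError(f"tracer {sp!r} missing from observation {obs.site}")
        if sp not in pair.shared_species():
            raise ValueError(f"tracer {sp!r} missing from an end member")
        if obs.is_censored(sp) and substitution == "zero" and len(tracers) == 1:
            raise ValueError(
                f"tracer {sp!r} is censored and policy 'zero' makes inversion meaningless"
            )

    clipped = False
    if single:
        sp = tracers[0]
        a, d = _endmember_values(sp, pair, substitution)
        if d == a:
            raise ValueError(f"degenerate tracer {sp!r}: end members coincide")
        f = (obs.get(sp, substitution) - a) / (d - a)
    else:
        num = 0.0
        den = 0.0
        for sp in tracers:
            a, d = _endmember_values(sp, pair, substitution)
            if weights is not None:
                w = float(weights.get(sp, 0.0))
            else:
                w = 1.0 / a if a > 0 else (1.0 / d if d > 0 else 0.0)
            delta = d - a
            num += w * (obs.get(sp, substitution) - a) * delta
            den += w * delta * delta
        if den == 0.0:
            raise ValueError("degenerate tracer set: end members coincide on all tracers")
        f = num / den
    if not 0.0 <= f <= 1.0:
        f = min(1.0, max(0.0, f))
        clipped = True

    residuals: dict[str, float] = {}
    rel: dict[str, float] = {}
    for sp in sorted(obs.species() & pair.shared_species()):
        a, d = _endmember_values(sp, pair, substitution)
        pred = f * d + (1.0 - f) * a
        res = obs.get(sp, substitution) - pred
        residuals[sp] = res
        rel[sp] = res / pred if pred != 0 else float("nan")
    return MixingFit(
        f=float(f),
        tracer=tracers[0] if single else tracers,
        residuals=residuals,
        relative_residuals=rel,
        clipped=clipped,
    )


def compute_anomalies(
    obs: GasComposition,
    fit: MixingFit,
    pair: EndMemberPair,
    threshold: float = DEFAULT_ANOMALY_THRESHOLD,
    substitution: SubstitutionPolicy = "half",
) -> ProcessFlags:
    """Process flags from one mixing fit.

    Relative anomaly = (observed - predicted)/predicted at ``fit.f``; a flag
    is raised when the anomaly exceeds ``threshold`` with the diagnostic
    sign: excess for N2 and CO2, depletion for CH4 and O2.
    """

    def anomaly(sp: str) -> float | None:
        if sp not in obs.species() or sp not in pair.shared_species():
            return None
        a, d = _endmember_values(sp, pair, substitution)
        pred = fit.f * d + (1.0 - fit.f) * a
        if pred == 0.0:
            return None
        return (obs.get(sp, substitution) - pred) / pred

    n2 = anomaly("N2")
    co2 = anomaly("CO2")
    ch4 = anomaly("CH4")
    o2 = anomaly("O2")
    return ProcessFlags(
        n2_excess=None if n2 is None else bool(n2 > threshold),
        co2_excess=None if co2 is None else bool(co2 > threshold),
        ch4_depletion=None if ch4 is None else bool(ch4 < -threshold),
        o2_depletion=None if o2 is None else bool(o2 < -threshold),
        threshold=threshold,
    )


def classify_sample(
    obs: GasComposition,
    pair: EndMemberPair,
    threshold: float = DEFAULT_ANOMALY_THRESHOLD,
    substitution: SubstitutionPolicy = "half",
    anchors: Mapping[str, str] = DIAGNOSTIC_ANCHORS,
) -> ProcessFlags:
    """Process flags with the diagram-style anchor tracer per diagnostic.

    Each diagnostic species is compared against the mixing curve at the
    fraction implied by its anchor tracer (N2 judged at the sample's CO2,
    CO2/CH4/O2 judged at the sample's N2), mirroring how deviations from
    the air-BP mixing lines are read off binary diagrams.
    """
    flags: dict[str, bool | None] = {}
    for sp, anchor in anchors.items():
        if sp not in obs.species() or anchor not in obs.species():
            flags[sp] = None
            continue
        fit = infer_deep_fraction(obs, pair, tracer=anchor, substitution=substitution)
        partial = compute_anomalies(obs, fit, pair, threshold, substitution)
        flags[sp] = {
            "N2": partial.n2_excess,
            "CO2": partial.co2_excess,
            "CH4": partial.ch4_depletion,
            "O2": partial.o2_depletion,
        }[sp]
    return ProcessFlags(
        n2_excess=flags.get("N2"),
        co2_excess=flags.get("CO2"),
        ch4_depletion=flags.get("CH4"),
        o2_depletion=flags.get("O2"),
        threshold=threshold,
    )


def ratio_diagram_coords(
    obs: GasComposition,
    policy: SubstitutionPolicy = "half",
    same_units: bool = True,
) -> tuple[float, float]:
    """Coordinates on the Ar/CH4 vs CO2/N2 binary diagram.

    With ``same_units=True`` (default) both ratios are computed after
    converting numerator and denominator to the same unit (dimensionless
    mole ratios).  ``same_units=False`` reproduces the as-printed
    convention (Ar in mmol/mol over CH4 in μmol/mol).
    """
    for sp in ("Ar", "CH4", "CO2", "N2"):
        if sp not in obs.species():
            raise ValueError(f"species {sp!r} missing for ratio diagram")
    ar = obs.get("Ar", policy)
    ch4 = obs.get("CH4", policy)
    co2 = obs.get("CO2", policy)
    n2 = obs.get("N2", policy)
    if ch4 == 0 or n2 == 0:
        raise ZeroDivisionError("zero denominator in ratio diagram")
    ar_over_ch4 = ar / ch4 if same_units else (ar / 1000.0) / ch4
    return ar_over_ch4, co2 / n2


def grid_search_fraction(
    obs: GasComposition,
    pair: EndMemberPair,
    tracer: str,
    substitution: SubstitutionPolicy = "half",
    n_grid: int = 10_001,
) -> float:
    """Brute-force deep-gas fraction minimising |obs - predicted| on the
    tracer over a uniform grid — the independence check for the closed
    form, not a production path."""
    grid = np.linspace(0.0, 1.0, n_grid)
    a, d = _endmember_values(tracer, pair, substitution)
    pred = grid * d + (1.0 - grid) * a
    err = np.abs(obs.get(tracer, substitution) - pred)
    return float(grid[int(np.argmin(err))])


def profile_fractions(
    profiles: Iterable[GasComposition],
    pair: EndMemberPair,
    tracer: str | Sequence[str] = "Ar",
    substitution: SubstitutionPolicy = "half",
) -> list[tuple[GasComposition, MixingFit]]:
    """Infer the deep-gas fraction for every sample in a profile."""
    return [
        (obs, infer_deep_fraction(obs, pair, tracer, substitution)) for obs in profiles
    ]
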