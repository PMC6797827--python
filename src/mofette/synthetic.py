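"""Synthetic-data generators with known ground truth.

Three generators emulate the study's three data classes so every pipeline
stage can be exercised without field or sequence data:

* soil-gas depth profiles as air/deep-gas mixtures with optional
  process perturbations (e.g. CH4 × 0.5 for methane oxidation) and
  multiplicative lognormal measurement noise;
* H2-fed anoxic bottle incubations with feeding cycles, a set electron
  yield into acetate (4 H2 + 2 CO2 → acetate) and additive Gaussian noise;
* Dirichlet-multinomial OTU tables with group-specific support (richness)
  and log-fold composition shifts on a designated OTU subset.

Every generator is deterministic given (parameters, seed) and returns the
generated data together with a serializable :class:`SyntheticTruth`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GasComposition, OtuTable
from .kinetics import IncubationTimeSeries
from .mixing import EndMemberPair, predict_mixture

#: default detection limits (μmol/mol), matching the field table's
#: "<0.5 mmol/mol" (O2), "<0.05 mmol/mol" (H2S) and "<0.1 μmol/mol" traces
DEFAULT_DETECTION_LIMITS: dict[str, float] = {
    "O2": 500.0,
    "H2S": 50.0,
    "CH4": 0.1,
    "C2H6": 0.1,
}


@dataclass
class SyntheticTruth:
    """Ground-truth parameters carried alongside generated data."""

    seed: int
    true_f_by_depth: dict[str, float] | None = None
    process_perturbations: dict[str, float] | None = None
    noise_cv: float | None = None
    true_max_rate: float | None = None  # μmol acetate/(g dry wt · d)
    true_yield_acetate: float | None = None
    true_yield_ch4: float | None = None
    h2_dose_umol: float | None = None
    group_effects: dict[str, float] | None = None
    richness: dict[str, int] | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticTruth":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else str(source))
        return cls(**payload)


# ---------------------------------------------------------------------------
# gas profiles


def gen_gas_profiles(
    pair: EndMemberPair,
    f_by_depth: Mapping[float, float],
    perturbations: Mapping[str, float] | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    site: str = "synthetic",
    detection_limits: Mapping[str, float] | None = None,
) -> tuple[list[GasComposition], SyntheticTruth]:
    """Simulate a soil-gas depth profile as noisy two-end-member mixtures.

    Each depth's composition is the mixing prediction at its true deep-gas
    fraction, multiplied per species by a process perturbation factor
    (default 1) and mean-preserving lognormal noise with coefficient of
    variation ``noise_cv``.  Species falling below their detection limit
    are emitted as censored values.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be ≥ 0")
    perturbations = dict(perturbations or {})
    for sp, factor in perturbations.items():
        if factor <= 0:
            raise ValueError(f"perturbation for {sp} must be > 0, got {factor}")
    limits = dict(DEFAULT_DETECTION_LIMITS if detection_limits is None else detection_limits)
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv**2))) if noise_cv > 0 else 0.0

    profiles: list[GasComposition] = []
    for depth, f in sorted(f_by_depth.items()):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"true fraction {f} at depth {depth} outside [0, 1]")
        mix = predict_mixture(float(f), pair, policy="half")
        conc: dict[str, float] = {}
        censored: dict[str, float] = {}
        for sp, value in mix.conc.items():
            value *= perturbations.get(sp, 1.0)
            if sigma > 0:
                value *= float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
            if sp in limits and value < limits[sp]:
                censored[sp] = limits[sp]
            else:
                conc[sp] = value
        profiles.append(
            GasComposition(
                site=site, depth_cm=float(depth), conc=conc, censored=censored,
                d13c=dict(mix.d13c),
            )
        )
    truth = SyntheticTruth(
        seed=seed,
        true_f_by_depth={str(float(d)): float(f) for d, f in sorted(f_by_depth.items())},
        process_perturbations=perturbations,
        noise_cv=noise_cv,
    )
    return profiles, truth


# ---------------------------------------------------------------------------
# incubations


def gen_incubation(
    true_max_rate: float = 6.7,
    yield_acetate: float = 0.65,
    yield_ch4: float = 0.0,
    dry_mass: float = 8.0,
    h2_dose_umol: float = 1963.0,
    n_cycles: int = 2,
    cycle_length_d: float = 40.0,
    points_per_cycle: int = 10,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[IncubationTimeSeries, SyntheticTruth]:
    """Simulate an H2-fed bottle incubation with feeding cycles.

    Acetate accumulates linearly at ``true_max_rate`` (μmol per g dry
    weight per day) while H2 lasts; H2 is drawn down so that the electron
    yield into acetate is ``yield_acetate`` and into methane ``yield_ch4``
    (acetate = y_ac ΔH2/4, CH4 = y_ch4 ΔH2/4 from the 8:8:2 eq/mol
    factors).  Each cycle restarts from a fresh H2 dose; additive Gaussian
    noise with relative scale ``noise_cv`` emulates measurement error.
    A dose of 0 gives a control bottle (flat baseline).
    """
    if not 0.0 <= yield_acetate <= 1.0 or not 0.0 <= yield_ch4 <= 1.0:
        raise ValueError("yields must be fractions in [0, 1]")
    if yield_acetate + yield_ch4 > 1.0:
        raise ValueError("total electron yield cannot exceed 1")
    if n_cycles < 1 or points_per_cycle < 3:
        raise ValueError("need ≥ 1 cycle and ≥ 3 points per cycle")
    rng = np.random.default_rng(seed)

    ac_rate = true_max_rate * dry_mass  # μmol acetate/day while H2 lasts
    if h2_dose_umol > 0 and yield_acetate > 0:
        h2_rate = 4.0 * ac_rate / yield_acetate  # μmol H2/day
        t_deplete = h2_dose_umol / h2_rate
    else:
        h2_rate = 0.0
        t_deplete = np.inf

    times: list[float] = []
    h2: list[float] = []
    acetate: list[float] = []
    ch4: list[float] = []
    respikes: list[float] = []
    ac_acc = 0.0
    ch4_acc = 0.0
    # sample densely while H2 is being consumed, then once at cycle end
    # (how bottle experiments are actually monitored)
    t_active = min(cycle_length_d, t_deplete) if np.isfinite(t_deplete) else cycle_length_d
    for c in range(n_cycles):
        t0 = c * cycle_length_d
        last = c == n_cycles - 1
        if c > 0:
            respikes.append(t0)
        if t_active < cycle_length_d:
            local = np.linspace(0.0, t_active, points_per_cycle - 1)
            local = np.append(local, cycle_length_d if last else 0.999 * cycle_length_d)
        else:
            local = np.linspace(0.0, cycle_length_d, points_per_cycle, endpoint=last)
        for tl in local:
            consumed = h2_rate * min(tl, t_deplete)
            times.append(t0 + tl)
            h2.append(max(0.0, h2_dose_umol - consumed))
            acetate.append(ac_acc + yield_acetate * consumed / 4.0)
            ch4.append(ch4_acc + yield_ch4 * consumed / 4.0)
        end_consumed = h2_rate * min(cycle_length_d, t_deplete)
        ac_acc += yield_acetate * end_consumed / 4.0
        ch4_acc += yield_ch4 * end_consumed / 4.0

    def noisy(arr: list[float]) -> np.ndarray:
        a = np.asarray(arr)
        if noise_cv > 0:
            a = np.maximum(0.0, a + rng.normal(0.0, 1.0, a.shape) * noise_cv * np.abs(a))
        return a

    series = IncubationTimeSeries(
        times=np.asarray(times),
        h2=noisy(h2),
        ch4=noisy(ch4) if yield_ch4 > 0 else np.asarray(ch4),
        acetate=noisy(acetate),
        dry_mass=dry_mass,
        respike_times=tuple(respikes),
    )
    truth = SyntheticTruth(
        seed=seed,
        true_max_rate=true_max_rate,
        true_yield_acetate=yield_acetate,
        true_yield_ch4=yield_ch4,
        h2_dose_umol=h2_dose_umol,
        noise_cv=noise_cv,
        extra={"n_cycles": n_cycles, "cycle_length_d": cycle_length_d},
    )
    return series, truth


# ---------------------------------------------------------------------------
# OTU tables


def gen_otu_tables(
    n_hc: int = 6,
    n_lc: int = 7,
    richness_hc: int = 1350,
    richness_lc: int = 2400,
    effect_size: float = 2.0,
    n_effect_otus: int = 10,
    depth: int = 20_000,
    overdispersion: float = 200.0,
    pool_size: int | None = None,
    seed: int = 0,
) -> tuple[OtuTable, SyntheticTruth]:
    """Simulate an HC/LC OTU table with Dirichlet-multinomial counts.

    A shared lognormal rank-abundance pool is restricted per group to
    ``richness_hc``/``richness_lc`` OTUs (HC support is a subset of LC
    support where possible).  ``n_effect_otus`` OTUs present in both
    groups are shifted in the HC base composition by ``effect_size``
    natural-log fold.  Per-sample compositions are Dirichlet draws with
    concentration ``overdispersion``; counts are multinomial at ``depth``
    reads per sample.
    """
    if pool_size is None:
        pool_size = max(richness_hc, richness_lc)
    if max(richness_hc, richness_lc) > pool_size:
        raise ValueError("richness cannot exceed the OTU pool size")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)

    base = np.exp(rng.normal(0.0, 1.5, pool_size))  # shared rank-abundance pool
    lc_support = rng.choice(pool_size, size=richness_lc, replace=False)
    if richness_hc <= richness_lc:
        hc_support = rng.choice(lc_support, size=richness_hc, replace=False)
    else:
        hc_support = rng.choice(pool_size, size=richness_hc, replace=False)

    p_lc = np.zeros(pool_size)
    p_lc[lc_support] = base[lc_support]
    p_hc = np.zeros(pool_size)
    p_hc[hc_support] = base[hc_support]

    shared = np.intersect1d(hc_support, lc_support)
    n_eff = min(n_effect_otus, len(shared))
    effect_idx = rng.choice(shared, size=n_eff, replace=False) if n_eff else np.array([], int)
    p_hc[effect_idx] *= np.exp(effect_size)
    p_lc /= p_lc.sum()
    p_hc /= p_hc.sum()

    otu_ids = [f"OTU_{i + 1}" for i in range(pool_size)]
    rows = []
    ids = []
    groups = {}
    for g, (n_g, p_g) in (("HC", (n_hc, p_hc)), ("LC", (n_lc, p_lc))):
        for j in range(n_g):
            alpha = overdispersion * p_g
            # Dirichlet over the support only (zero-probability OTUs stay zero)
            support = alpha > 0
            comp = np.zeros(pool_size)
            comp[support] = rng.dirichlet(alpha[support])
            rows.append(rng.multinomial(depth, comp))
            sid = f"{g}_{j + 1}"
            ids.append(sid)
            groups[sid] = g
    table = OtuTable(
        counts=pd.DataFrame(np.array(rows), index=ids, columns=otu_ids),
        groups=pd.Series(groups),
    )
    truth = SyntheticTruth(
        seed=seed,
        group_effects={otu_ids[i]: float(effect_size) for i in effect_idx},
        richness={"HC": richness_hc, "LC": richness_lc},
        extra={
            "depth": depth,
            "overdispersion": overdispersion,
            "n_hc": n_hc,
            "n_lc": n_lc,
        },
    )
    return table, truth
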