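"""End-to-end orchestration: run every analysis stage on fixture or user
data and emit per-stage TSVs plus a human-readable summary.

Stages are isolated: each can run standalone with the same result, a
failed stage is reported and its dependents skipped, and identical
configuration plus seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import datasets
from .community import bray_curtis, observed_richness, permanova, rarefy, simper
from .core_io import read_gas_table, read_otu_table, read_soil_table
from .isotopes import enrichment_check, rayleigh_fraction_remaining
from .kinetics import balance_from_series, max_production_rate, read_incubation_table
from .mixing import (
    DEFAULT_ANOMALY_THRESHOLD,
    classify_sample,
    default_pair,
    infer_deep_fraction,
    ratio_diagram_coords,
)
from .soilchem import element_changes, toposequence_summary

logger = logging.getLogger("mofette")


@dataclass
class RunConfig:
    """Fully serialized run description; defaults use the bundled tables."""

    gas_table: str | None = None  # None -> bundled field table
    soil_table: str | None = None
    elements_table: str | None = None
    otu_table: str | None = None
    otu_groups: str | None = None
    incubation_table: str | None = None
    tracer: str = "Ar"
    anomaly_threshold: float = DEFAULT_ANOMALY_THRESHOLD
    censoring_policy: str = "half"
    rayleigh_epsilon: float | None = None  # ‰; required for F estimates
    kinetics_window: int = 3
    rarefaction_depth: int | None = None  # None -> min sample total
    n_permutations: int = 999
    seed: int = 0
    out_dir: str = "mofette_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class RunReport:
    outputs: dict[str, Path] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    summary_lines: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_mix_stage(config: RunConfig, out_dir: Path) -> tuple[pd.DataFrame, list[str]]:
    profiles = (
        read_gas_table(config.gas_table)
        if config.gas_table
        else datasets.load_gas_profiles()
    )
    deep = next((s for s in profiles if s.site == "BP"), None)
    if deep is None:
        raise ValueError("no bubbling-pool (site 'BP') end-member row in gas table")
    pair = default_pair(deep)
    soils = [s for s in profiles if s.site != "BP"]
    rows = []
    for obs in soils:
        fit = infer_deep_fraction(obs, pair, config.tracer, config.censoring_policy)
        flags = classify_sample(obs, pair, config.anomaly_threshold, config.censoring_policy)
        try:
            ar_ch4, co2_n2 = ratio_diagram_coords(obs, config.censoring_policy)
        except (ValueError, ZeroDivisionError):
            ar_ch4 = co2_n2 = float("nan")
        rows.append(
            {
                "site": obs.site,
                "depth_cm": obs.depth_cm,
                "deep_fraction": fit.f,
                "deep_fraction_pct": fit.f_percent,
                "clipped": fit.clipped,
                "n2_excess": flags.n2_excess,
                "co2_excess": flags.co2_excess,
                "ch4_depletion": flags.ch4_depletion,
                "o2_depletion": flags.o2_depletion,
                "ar_over_ch4": ar_ch4,
                "co2_over_n2": co2_n2,
            }
        )
    df = pd.DataFrame(rows)
    _write_tsv(df, out_dir / "mixing.tsv")
    flagged = df[df["ch4_depletion"] == True]  # noqa: E712
    lines = [
        f"mixing: {len(df)} samples, tracer {config.tracer}, "
        f"deep-gas fraction {df['deep_fraction'].min():.3f}-{df['deep_fraction'].max():.3f}",
        "mixing: CH4 depletion flagged at "
        + (", ".join(f"{r.site}/{r.depth_cm:g}cm" for r in flagged.itertuples()) or "none"),
    ]
    return df, lines


def run_isotope_stage(config: RunConfig, out_dir: Path) -> tuple[pd.DataFrame, list[str]]:
    profiles = (
        read_gas_table(config.gas_table)
        if config.gas_table
        else datasets.load_gas_profiles()
    )
    deep = next((s for s in profiles if s.site == "BP"), None)
    if deep is None:
        raise ValueError("no bubbling-pool end member")
    pair = default_pair(deep)
    soils = [s for s in profiles if s.site != "BP"]
    checks = enrichment_check(soils, pair)
    rows = []
    for obs in soils:
        enriched = checks[(obs.site, obs.depth_cm)]
        frac = None
        if (
            enriched
            and config.rayleigh_epsilon
            and "CH4" in obs.d13c
            and "CH4" in deep.d13c
        ):
            frac = rayleigh_fraction_remaining(
                obs.d13c["CH4"], deep.d13c["CH4"], config.rayleigh_epsilon
            ).fraction_remaining
        rows.append(
            {
                "site": obs.site,
                "depth_cm": obs.depth_cm,
                "d13c_ch4": obs.d13c.get("CH4"),
                "ch4_13c_enriched": enriched,
                "ch4_fraction_remaining": frac,
            }
        )
    df = pd.DataFrame(rows)
    _write_tsv(df, out_dir / "isotopes.tsv")
    n_enriched = int(df["ch4_13c_enriched"].eq(True).sum())
    lines = [f"isotopes: {n_enriched} sample(s) show 13C-enriched residual CH4"]
    return df, lines


def run_soilchem_stage(config: RunConfig, out_dir: Path) -> tuple[pd.DataFrame, list[str]]:
    soils = (
        read_soil_table(config.soil_table)
        if config.soil_table
        else datasets.load_soil_profiles()
    )
    from .soilchem import cn_ratio

    rows = [
        {
            "site": s.site,
            "layer": s.layer,
            "pH": s.pH,
            "N_pct": s.N_pct,
            "C_pct": s.C_pct,
            "CN": cn_ratio(s.C_pct, s.N_pct),
        }
        for s in soils
    ]
    df = pd.DataFrame(rows)
    _write_tsv(df, out_dir / "soilchem.tsv")
    ph = toposequence_summary(soils, "pH")
    lines = [f"soilchem: pH range {ph.minimum:.2f}-{ph.maximum:.2f} along the toposequence"]
    elements = (
        datasets.load_elements_synthetic()
        if config.elements_table is None
        else datasets.read_elements_table(config.elements_table)
    )
    sites = set(elements.index)
    if {"3", "4", "7"} <= sites:
        changes = element_changes(elements, "7", ["3", "4"])
        changes.rename("pct_change").to_frame().to_csv(
            out_dir / "element_changes.tsv", sep="\t", index_label="element"
        )
        if "Ca" in changes:
            lines.append(f"soilchem: Ca change at toe-slope {changes['Ca']:+.0f}%")
    return df, lines


def run_incubation_stage(config: RunConfig, out_dir: Path) -> tuple[pd.DataFrame, list[str]]:
    if config.incubation_table is None:
        raise FileNotFoundError("no incubation table configured")
    series = read_incubation_table(config.incubation_table)
    rate = max_production_rate(series, "acetate", config.kinetics_window)
    balance = balance_from_series(series)
    df = pd.DataFrame(
        [
            {
                "max_acetate_rate_umol_g_d": rate.max_rate,
                "window_start_d": rate.window[0],
                "window_end_d": rate.window[1],
                "eq_h2_consumed": balance.eq_h2_consumed,
                "yield_acetate_pct": balance.yield_acetate_pct,
                "yield_ch4_pct": balance.yield_ch4_pct,
            }
        ]
    )
    _write_tsv(df, out_dir / "incubation.tsv")
    lines = [
        f"incubation: max acetate rate {rate.max_rate:.2f} umol/(g*d), "
        f"acetate yield {balance.yield_acetate_pct:.0f}% of consumed H2"
    ]
    return df, lines


def run_community_stage(config: RunConfig, out_dir: Path) -> tuple[pd.DataFrame, list[str]]:
    if config.otu_table is None or config.otu_groups is None:
        raise FileNotFoundError("no OTU table/groups configured")
    table = read_otu_table(config.otu_table, config.otu_groups)
    depth = config.rarefaction_depth or int(table.sample_totals().min())
    rare = rarefy(table, depth, seed=config.seed)
    dist = bray_curtis(rare)
    dist.to_frame().to_csv(out_dir / "bray_curtis.tsv", sep="\t")
    result = permanova(dist, rare.groups, config.n_permutations, seed=config.seed)
    sim = simper(rare)
    sim.table.head(25).to_csv(out_dir / "simper.tsv", sep="\t", index_label="otu_id")
    rich = observed_richness(rare)
    df = pd.DataFrame(
        [
            {
                "rarefaction_depth": depth,
                "pseudo_F": result.pseudo_F,
                "R2": result.R2,
                "p_value": result.p_value,
                "mean_between_group_dissimilarity_pct": sim.overall_mean_dissimilarity_pct,
                "richness_min": int(rich.min()),
                "richness_max": int(rich.max()),
            }
        ]
    )
    _write_tsv(df, out_dir / "community.tsv")
    lines = [
        f"community: PERMANOVA p = {result.p_value:.3g}, R2 = {result.R2:.2f} "
        f"({result.method}, {result.n_permutations} permutations)",
        f"community: mean between-group dissimilarity "
        f"{sim.overall_mean_dissimilarity_pct:.0f}%",
    ]
    return df, lines


def run_all(config: RunConfig) -> RunReport:
    """Run every configured stage; see module docstring for the contract."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "run_config.yaml")
    report = RunReport()
    stages = {
        "mix": run_mix_stage,
        "isotope": run_isotope_stage,
        "soilchem": run_soilchem_stage,
        "incubation": run_incubation_stage,
        "community": run_community_stage,
    }
    for name, stage in stages.items():
        try:
            _, lines = stage(config, out_dir)
            report.outputs[name] = out_dir
            report.summary_lines.extend(lines)
        except FileNotFoundError as exc:
            logger.warning("stage %s skipped: %s", name, exc)
            report.skipped.append(name)
            report.summary_lines.append(f"{name}: skipped ({exc})")
        except Exception as exc:  # noqa: BLE001 - per-stage isolation
            logger.error("stage %s failed: %s", name, exc)
            report.errors[name] = str(exc)
            report.summary_lines.append(f"{name}: FAILED ({exc})")
    (out_dir / "summary.txt").write_text("\n".join(report.summary_lines) + "\n")
    return report
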