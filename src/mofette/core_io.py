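"""Domain types, unit handling, censored-value parsing and table readers.

Concentrations are stored in a single canonical unit, μmol/mol (ppmv-like
mole fraction).  Major gas species (CO2, N2, O2, Ar, H2S) are conventionally
*reported* in mmol/mol and trace hydrocarbons (CH4, C2H6) in μmol/mol, so
every reader requires an explicit per-column unit declaration — either a
``#units:`` line in the file or a ``units`` mapping — and converts on read.

Below-detection entries (``<0.5``) are never turned into numbers silently:
they are kept as detection limits and every downstream consumer must pick a
substitution policy (``"half"``, ``"zero"`` or ``"limit"``) explicitly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd

logger = logging.getLogger("mofette")

MAJOR_SPECIES: tuple[str, ...] = ("CO2", "H2S", "N2", "O2", "Ar")
TRACE_SPECIES: tuple[str, ...] = ("CH4", "C2H6")
GAS_SPECIES: tuple[str, ...] = MAJOR_SPECIES + TRACE_SPECIES

#: conventional reporting units, used when writing tables
DEFAULT_UNITS: dict[str, str] = {
    **{s: "mmol/mol" for s in MAJOR_SPECIES},
    **{s: "umol/mol" for s in TRACE_SPECIES},
}

#: scale factor to canonical μmol/mol
_UNIT_SCALE = {"umol/mol": Decimal(1), "mmol/mol": Decimal(1000)}

SOIL_LAYERS = ("Sup", "Sub", "Deep")
HCL_CLASSES = ("None", "Slight", "Strong")

SubstitutionPolicy = Literal["half", "zero", "limit"]


class TableFormatError(ValueError):
    """A tabular input violates the declared layout or value contracts."""


def to_canonical(value: float | str, unit: str) -> float:
    """Convert a concentration to canonical μmol/mol.

    String inputs are scaled exactly (decimal shift), so printed values
    round-trip verbatim through read → write.
    """
    if unit not in _UNIT_SCALE:
        raise TableFormatError(f"unknown concentration unit {unit!r}")
    if isinstance(value, str):
        return float(Decimal(value) * _UNIT_SCALE[unit])
    return float(Decimal(repr(value)) * _UNIT_SCALE[unit])


def from_canonical(value: float, unit: str) -> float:
    """Convert a canonical μmol/mol concentration back to ``unit``."""
    if unit not in _UNIT_SCALE:
        raise TableFormatError(f"unknown concentration unit {unit!r}")
    return float(Decimal(repr(value)) / _UNIT_SCALE[unit])


@dataclass(frozen=True)
class CensoredValue:
    """A below-detection measurement, stored as its detection limit."""

    limit: float  # μmol/mol
    kind: str = "below_detection"

    def __post_init__(self) -> None:
        if not self.limit > 0:
            raise ValueError("detection limit must be > 0")

    def substitute(self, policy: SubstitutionPolicy) -> float:
        if policy == "half":
            return self.limit / 2.0
        if policy == "zero":
            return 0.0
        if policy == "limit":
            return self.limit
        raise ValueError(f"unknown substitution policy {policy!r}")


@dataclass
class GasComposition:
    """One gas sample: species → concentration (μmol/mol) plus censoring.

    A species lives either in ``conc`` or in ``censored``, never both.
    ``d13c`` holds optional δ13C values in ‰ vs V-PDB, keyed by species.
    """

    site: str
    depth_cm: float | None
    conc: dict[str, float] = field(default_factory=dict)
    censored: dict[str, float] = field(default_factory=dict)  # μmol/mol limits
    d13c: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.conc) & set(self.censored)
        if overlap:
            raise ValueError(f"species both measured and censored: {sorted(overlap)}")
        for sp, v in self.conc.items():
            if v < 0:
                raise ValueError(f"negative concentration for {sp}: {v}")
        for sp, v in self.censored.items():
            if not v > 0:
                raise ValueError(f"non-positive detection limit for {sp}: {v}")

    def species(self) -> set[str]:
        return set(self.conc) | set(self.censored)

    def get(self, species: str, policy: SubstitutionPolicy | None = None) -> float:
        """Concentration in μmol/mol; censored species require a policy."""
        if species in self.conc:
            return self.conc[species]
        if species in self.censored:
            if policy is None:
                raise ValueError(
                    f"{species} is below detection for site {self.site}; "
                    "a substitution policy is required"
                )
            return CensoredValue(self.censored[species]).substitute(policy)
        raise KeyError(f"species {species!r} not present in sample {self.site}")

    def is_censored(self, species: str) -> bool:
        return species in self.censored

    def closure_mmol(self, policy: SubstitutionPolicy = "limit") -> float:
        """Sum of major-species concentrations in mmol/mol."""
        total = 0.0
        for sp in MAJOR_SPECIES:
            if sp in self.species():
                total += self.get(sp, policy)
        return total / 1000.0

    def check_closure(self, lo: float = 900.0, hi: float = 1050.0) -> None:
        total = self.closure_mmol("limit")
        if not lo <= total <= hi:
            raise ValueError(
                f"major-species closure {total:.1f} mmol/mol outside "
                f"[{lo}, {hi}] for site {self.site} depth {self.depth_cm}"
            )


@dataclass
class SoilSample:
    """One soil horizon: pH, HCl effervescence class and C/N content."""

    site: str
    layer: str
    pH: float
    hcl_class: str
    N_pct: float
    C_pct: float
    cn_printed: float | None = None
    elements: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.layer not in SOIL_LAYERS:
            raise TableFormatError(
                f"layer {self.layer!r} for site {self.site} not in {SOIL_LAYERS}"
            )
        if self.hcl_class not in HCL_CLASSES:
            raise TableFormatError(
                f"HCl class {self.hcl_class!r} for site {self.site} not in {HCL_CLASSES}"
            )
        if not 0 < self.pH < 14:
            raise ValueError(f"pH {self.pH} out of (0, 14)")
        if self.N_pct < 0 or self.C_pct < 0:
            raise ValueError("N% and C% must be non-negative")


@dataclass
class OtuTable:
    """Samples × OTUs integer count matrix with a two-level group factor."""

    counts: pd.DataFrame  # index = sample ids, columns = OTU ids
    groups: pd.Series  # sample id -> group label

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample or OTU ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.index) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples lacking a group label: {sorted(missing)}")
        self.groups = self.groups.loc[self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_cell(raw: str) -> float | CensoredValue | None:
    s = raw.strip()
    if s in ("", "nd", "ND", "na", "NA", "-"):
        return None
    if s.startswith("<"):
        return CensoredValue(limit=float(Decimal(s[1:])))  # unit applied later
    return float(s)


def _read_tsv_lines(path: str | Path) -> tuple[list[str], dict[str, str], list[list[str]]]:
    """Return header, optional units declaration and data rows of a TSV."""
    path = Path(path)
    header: list[str] = []
    units: dict[str, str] = {}
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#units:"):
                cells = line[len("#units:") :].split("\t")
                # pad/truncate against header
                for name, unit in zip(header, cells):
                    if unit.strip():
                        units[name] = unit.strip()
                continue
            if line.startswith("#"):
                continue
            cells = line.split("\t")
            if not header:
                header = [c.strip() for c in cells]
            else:
                rows.append(cells)
    return header, units, rows


# ---------------------------------------------------------------------------
# gas tables


def read_gas_table(
    path: str | Path,
    units: Mapping[str, str] | None = None,
    check_closure: bool = False,
) -> list[GasComposition]:
    """Read a soil-gas profile table into :class:`GasComposition` records.

    Columns: ``site``, ``depth_cm``, one column per gas species, and optional
    ``d13C_<species>`` columns.  Cells may be numeric, ``<x`` (below the
    detection limit x) or ``nd`` (not determined).  Each species column needs
    a unit, either from the ``units`` mapping or a ``#units:`` line in the
    file; values are converted to canonical μmol/mol.  Row order is kept.
    """
    header, file_units, rows = _read_tsv_lines(path)
    if not header:
        logger.warning("gas table %s is empty", path)
        return []
    declared = dict(file_units)
    if units:
        declared.update(units)

    species_cols: list[str] = []
    d13c_cols: list[str] = []
    for col in header:
        if col in ("site", "depth_cm"):
            continue
        if col.startswith("d13C_"):
            sp = col[len("d13C_") :]
            if sp not in GAS_SPECIES:
                raise TableFormatError(f"unknown δ13C species column {col!r}")
            d13c_cols.append(col)
        elif col in GAS_SPECIES:
            species_cols.append(col)
            if col not in declared:
                raise TableFormatError(f"missing unit declaration for column {col!r}")
        else:
            raise TableFormatError(f"unknown species column {col!r}")

    out: list[GasComposition] = []
    idx = {c: i for i, c in enumerate(header)}
    for cells in rows:
        def cell(col: str) -> str:
            i = idx[col]
            return cells[i] if i < len(cells) else ""

        site = cell("site").strip()
        depth_raw = cell("depth_cm").strip() if "depth_cm" in idx else ""
        depth = float(depth_raw) if depth_raw else None
        conc: dict[str, float] = {}
        censored: dict[str, float] = {}
        d13c: dict[str, float] = {}
        for col in species_cols:
            parsed = _parse_cell(cell(col))
            if parsed is None:
                continue
            unit = declared[col]
            if isinstance(parsed, CensoredValue):
                censored[col] = to_canonical(cell(col).strip()[1:], unit)
            else:
                if parsed < 0:
                    raise TableFormatError(
                        f"negative concentration {parsed} for {col} at site {site}"
                    )
                conc[col] = to_canonical(cell(col).strip(), unit)
        for col in d13c_cols:
            parsed = _parse_cell(cell(col))
            if parsed is None:
                continue
            if isinstance(parsed, CensoredValue):
                raise TableFormatError(f"censored δ13C value in column {col}")
            d13c[col[len("d13C_") :]] = parsed
        sample = GasComposition(site=site, depth_cm=depth, conc=conc, censored=censored, d13c=d13c)
        if check_closure:
            sample.check_closure()
        out.append(sample)
    if not out:
        logger.warning("gas table %s contains no data rows", path)
    return out


def _format_number(x: float) -> str:
    """Format a value the way compact printed tables do (no trailing zeros)."""
    return format(x, "g")


def write_gas_table(
    samples: Iterable[GasComposition],
    path: str | Path,
    units: Mapping[str, str] | None = None,
) -> None:
    """Write gas samples back to TSV in conventional reporting units."""
    samples = list(samples)
    units = dict(units or DEFAULT_UNITS)
    species = [sp for sp in GAS_SPECIES if any(sp in s.species() for s in samples)]
    d13c_species = [sp for sp in GAS_SPECIES if any(sp in s.d13c for s in samples)]
    header = ["site", "depth_cm"] + species + [f"d13C_{sp}" for sp in d13c_species]
    unit_line = ["", ""] + [units[sp] for sp in species] + ["permil"] * len(d13c_species)
    lines = ["\t".join(header), "#units:" + "\t".join(unit_line)]
    for s in samples:
        row = [s.site, _format_number(s.depth_cm) if s.depth_cm is not None else ""]
        for sp in species:
            if sp in s.conc:
                row.append(_format_number(from_canonical(s.conc[sp], units[sp])))
            elif sp in s.censored:
                row.append("<" + _format_number(from_canonical(s.censored[sp], units[sp])))
            else:
                row.append("nd")
        for sp in d13c_species:
            row.append(_format_number(s.d13c[sp]) if sp in s.d13c else "nd")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# soil tables


def read_soil_table(path: str | Path) -> list[SoilSample]:
    """Read a soil-chemistry table (site, layer, pH, HCl, N%, C%[, C/N])."""
    header, _, rows = _read_tsv_lines(path)
    required = {"site", "layer", "pH", "HCl", "N_pct", "C_pct"}
    if not required <= set(header):
        raise TableFormatError(f"soil table must have columns {sorted(required)}")
    idx = {c: i for i, c in enumerate(header)}
    out: list[SoilSample] = []
    for cells in rows:
        def cell(col: str) -> str:
            i = idx.get(col, -1)
            return cells[i].strip() if 0 <= i < len(cells) else ""

        site, layer = cell("site"), cell("layer")
        for col in ("pH", "N_pct", "C_pct"):
            if not cell(col):
                raise TableFormatError(f"missing {col} for site {site} layer {layer}")
        out.append(
            SoilSample(
                site=site,
                layer=layer,
                pH=float(cell("pH")),
                hcl_class=cell("HCl"),
                N_pct=float(cell("N_pct")),
                C_pct=float(cell("C_pct")),
                cn_printed=float(cell("CN")) if cell("CN") else None,
            )
        )
    return out


def read_elements_table(path: str | Path) -> pd.DataFrame:
    """Read a site × element concentration table (mass basis)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"site": str})
    return df.set_index("site")


# ---------------------------------------------------------------------------
# OTU tables


def read_otu_table(
    counts_path: str | Path,
    groups_path: str | Path,
    orientation: Literal["samples_rows", "otus_rows"] = "samples_rows",
) -> OtuTable:
    """Read an OTU count TSV and a two-column sample→group map.

    Samples lacking a group label are dropped with a warning; fractional
    counts are an error.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    if orientation == "otus_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    arr = df.to_numpy()
    if not (arr == arr.astype(int)).all():
        raise TableFormatError("OTU counts must be integers")
    df = df.astype(int)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None

    gmap = pd.read_csv(groups_path, sep="\t", index_col=0, comment="#").iloc[:, 0]
    gmap.index = gmap.index.astype(str)
    unknown = set(gmap.index) - set(df.index)
    if unknown:
        warnings.warn(f"group map has unknown samples: {sorted(unknown)}")
    ungrouped = [s for s in df.index if s not in gmap.index]
    if ungrouped:
        warnings.warn(f"dropping samples without group label: {ungrouped}")
        df = df.drop(index=ungrouped)
    return OtuTable(counts=df, groups=gmap.loc[df.index])


def write_otu_table(table: OtuTable, counts_path: str | Path, groups_path: str | Path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="sample")
    table.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample")
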