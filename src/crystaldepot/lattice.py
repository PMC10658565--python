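"""Crystal-lattice density metrics: cell volume, Matthews coefficient, solvent content.

The Matthews coefficient V_M = V_cell / (Z * n_asu * M) (Å³/Da) measures unit-cell
volume per Dalton of protein; lower values mean denser molecular packing.  The
conventional solvent-content estimate follows from the protein partial specific
volume v̄ (cm³/g):

    f_solvent = 1 - (v̄ / 0.6022) / V_M

where 0.6022 converts cm³/g to Å³/Da (Avogadro's number / 1e24).  With the
standard v̄ = 0.74 cm³/g this is the familiar 1 - 1.23/V_M.
"""

from __future__ import annotations

import io
import math
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# Conversion cm³/g -> Å³/Da: 1e24 Å³/cm³ divided by Avogadro 6.022e23 /mol.
CM3_PER_G_TO_A3_PER_DA = 1.0 / 0.6022

#: Default protein partial specific volume, cm³/g (behind the conventional 1.23/V_M).
DEFAULT_PARTIAL_SPECIFIC_VOLUME = 0.74

#: General-position multiplicities of the common Sohncke (protein-compatible)
#: space groups, keyed by normalized Hermann-Mauguin symbol.
SPACE_GROUP_MULTIPLICITY: dict[str, int] = {
    "P1": 1,
    "P2": 2, "P21": 2, "C2": 4,
    "P222": 4, "P2221": 4, "P21212": 4, "P212121": 4,
    "C222": 8, "C2221": 8, "F222": 16, "I222": 8, "I212121": 8,
    "P4": 4, "P41": 4, "P42": 4, "P43": 4, "I4": 8, "I41": 8,
    "P422": 8, "P4212": 8, "P4122": 8, "P41212": 8, "P4222": 8,
    "P42212": 8, "P4322": 8, "P43212": 8, "I422": 16, "I4122": 16,
    "P3": 3, "P31": 3, "P32": 3, "R3": 9,
    "P312": 6, "P321": 6, "P3112": 6, "P3121": 6, "P3212": 6, "P3221": 6, "R32": 18,
    "P6": 6, "P61": 6, "P62": 6, "P63": 6, "P64": 6, "P65": 6,
    "P622": 12, "P6122": 12, "P6222": 12, "P6322": 12, "P6422": 12, "P6522": 12,
    "P23": 12, "F23": 48, "I23": 24, "P213": 12, "I213": 24,
    "P432": 24, "P4232": 24, "F432": 96, "F4132": 96, "I432": 48,
    "P4332": 24, "P4132": 24, "I4132": 48,
}

_SUBSCRIPT_DIGITS = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")


class CellGeometryError(ValueError):
    """Raised when unit-cell parameters do not describe a realizable cell."""


class UnknownSpaceGroupError(KeyError):
    """Raised when a space-group symbol is not in the multiplicity table."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(
            f"unknown space-group symbol {symbol!r}; known symbols: "
            + ", ".join(sorted(SPACE_GROUP_MULTIPLICITY))
        )


class RecordParseError(ValueError):
    """Raised when a cell record (CRYST1 / mmCIF / CSV) cannot be parsed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Unit-cell edge lengths (Å) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise CellGeometryError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise CellGeometryError(f"cell angle {name} must lie in (0, 180) degrees")


def normalize_space_group_symbol(symbol: str) -> str:
    """Collapse spacing/subscript variants of a Hermann-Mauguin symbol.

    "P 21 21 21", "P2(1)2(1)2(1)", "P2_1_2_1_2_1_" and "P2₁2₁2₁" all map
    to "P212121".
    """
    s = symbol.strip().translate(_SUBSCRIPT_DIGITS)
    s = re.sub(r"[\s_()\-]", "", s)
    if not s:
        raise RecordParseError("empty space-group symbol")
    return s[0].upper() + s[1:]


@dataclass(frozen=True)
class SpaceGroupInfo:
    """Hermann-Mauguin symbol plus its general-position multiplicity."""

    symbol: str
    multiplicity: int

    @classmethod
    def from_symbol(cls, symbol: str) -> "SpaceGroupInfo":
        norm = normalize_space_group_symbol(symbol)
        try:
            mult = SPACE_GROUP_MULTIPLICITY[norm]
        except KeyError:
            raise UnknownSpaceGroupError(norm) from None
        return cls(symbol=norm, multiplicity=mult)


@dataclass(frozen=True)
class CrystalForm:
    """One crystal polymorph: cell, symmetry, copies per asymmetric unit, mass."""

    name: str
    cell: UnitCell
    space_group: SpaceGroupInfo
    copies_per_asu: int
    molar_mass: float  # Da
    partial_specific_volume: float = DEFAULT_PARTIAL_SPECIFIC_VOLUME  # cm³/g

    def __post_init__(self):
        if self.copies_per_asu < 1:
            raise ValueError("copies_per_asu must be >= 1")
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be > 0")


@dataclass(frozen=True)
class LatticeDensityReport:
    """Density metrics for one crystal form.

    ``solvent_fraction + protein_fraction == 1`` by construction; a
    ``protein_overfill`` flag marks the degenerate case where V_M falls at or
    below the protein-only packing limit (solvent clamped to 0).
    """

    cell_volume: float  # Å³
    matthews: float  # Å³/Da
    solvent_fraction: float
    protein_fraction: float
    protein_overfill: bool = False


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def cell_volume(cell: UnitCell) -> float:
    """Triclinic unit-cell volume, Å³.

    V = abc * sqrt(1 - cos²α - cos²β - cos²γ + 2 cosα cosβ cosγ), which is the
    square root of the metric-tensor determinant.  For an orthogonal cell this
    reduces exactly to a·b·c.

    Raises
    ------
    CellGeometryError
        If the radicand is non-positive (angles incompatible with a real cell).
    """
    ca = math.cos(math.radians(cell.alpha))
    cb = math.cos(math.radians(cell.beta))
    cg = math.cos(math.radians(cell.gamma))
    radicand = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if radicand <= 0.0:
        raise CellGeometryError(
            f"cell angles ({cell.alpha}, {cell.beta}, {cell.gamma}) deg do not "
            f"describe a realizable cell (metric determinant {radicand:g} <= 0)"
        )
    return cell.a * cell.b * cell.c * math.sqrt(radicand)


def matthews_coefficient(form: CrystalForm, volume: float | None = None) -> float:
    """Matthews coefficient V_M = V_cell / (Z · n_asu · M), Å³/Da."""
    if volume is None:
        volume = cell_volume(form.cell)
    if volume <= 0:
        raise ValueError("cell volume must be > 0")
    return volume / (form.space_group.multiplicity * form.copies_per_asu * form.molar_mass)


def infer_molar_mass(volume: float, multiplicity: int, copies_per_asu: int,
                     matthews: float) -> float:
    """Algebraic inverse of :func:`matthews_coefficient`: M = V / (Z · n · V_M)."""
    if matthews <= 0:
        raise ValueError("matthews must be > 0")
    if multiplicity < 1 or copies_per_asu < 1:
        raise ValueError("multiplicity and copies_per_asu must be >= 1")
    return volume / (multiplicity * copies_per_asu * matthews)


def solvent_fraction(matthews: float,
                     partial_specific_volume: float = DEFAULT_PARTIAL_SPECIFIC_VOLUME
                     ) -> tuple[float, bool]:
    """Solvent volume fraction from the Matthews coefficient.

    Returns ``(fraction, overfill_flag)``.  When V_M is at or below the
    protein-only limit v̄/0.6022 the fraction is clamped to 0 and the flag set
    (with a warning) rather than going negative.
    """
    if matthews <= 0:
        raise ValueError("matthews must be > 0")
    limit = partial_specific_volume * CM3_PER_G_TO_A3_PER_DA
    frac = 1.0 - limit / matthews
    if frac <= 1e-12:
        if frac < -1e-12:
            warnings.warn(
                f"V_M = {matthews:.4g} Å³/Da is below the protein-only packing limit "
                f"{limit:.4g}; solvent fraction clamped to 0",
                stacklevel=2,
            )
        return 0.0, True
    return frac, False


def density_report(form: CrystalForm) -> LatticeDensityReport:
    """Full density metrics for one crystal form."""
    vol = cell_volume(form.cell)
    vm = matthews_coefficient(form, vol)
    frac, overfill = solvent_fraction(vm, form.partial_specific_volume)
    return LatticeDensityReport(
        cell_volume=vol,
        matthews=vm,
        solvent_fraction=frac,
        protein_fraction=1.0 - frac,
        protein_overfill=overfill,
    )


def rank_density(reports: list[LatticeDensityReport],
                 names: list[str] | None = None) -> list[int]:
    """Indices of *reports* sorted most-compact first.

    Stable ascending sort by solvent fraction, ties broken by V_M and then by
    name (input order if names are absent).
    """
    if len(reports) < 2:
        raise ValueError("rank_density needs at least two reports")
    if names is not None and len(names) != len(reports):
        raise ValueError("names must match reports in length")

    def key(i: int):
        tie = names[i] if names is not None else ""
        return (reports[i].solvent_fraction, reports[i].matthews, tie)

    return sorted(range(len(reports)), key=key)


def density_table(forms: list[CrystalForm], percent_decimals: int = 2) -> pd.DataFrame:
    """Tidy per-form report: name, cell_volume_A3, matthews_A3_per_Da, solvent_pct, rank.

    Rank 1 marks the most compact (lowest-solvent) lattice.  ``solvent_pct`` is
    rounded for display; the unrounded fraction is kept in ``solvent_fraction``.
    """
    if not forms:
        raise ValueError("no crystal forms given")
    reports = [density_report(f) for f in forms]
    names = [f.name for f in forms]
    if len(reports) >= 2:
        order = rank_density(reports, names)
        rank = {idx: pos + 1 for pos, idx in enumerate(order)}
    else:
        rank = {0: 1}
    return pd.DataFrame({
        "name": names,
        "cell_volume_A3": [r.cell_volume for r in reports],
        "matthews_A3_per_Da": [r.matthews for r in reports],
        "solvent_fraction": [r.solvent_fraction for r in reports],
        "solvent_pct": [round(100.0 * r.solvent_fraction, percent_decimals) for r in reports],
        "rank": [rank[i] for i in range(len(reports))],
    })


# ---------------------------------------------------------------------------
# Record readers (CRYST1 / mmCIF / CSV)
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["name", "a", "b", "c", "alpha", "beta", "gamma",
               "space_group", "copies", "molar_mass_da"]


def parse_cryst1(line: str) -> tuple[UnitCell, SpaceGroupInfo]:
    """Parse a PDB ``CRYST1`` fixed-column record."""
    if not line.startswith("CRYST1"):
        raise RecordParseError(f"not a CRYST1 record: {line[:20]!r}")
    try:
        cell = UnitCell(
            a=float(line[6:15]), b=float(line[15:24]), c=float(line[24:33]),
            alpha=float(line[33:40]), beta=float(line[40:47]), gamma=float(line[47:54]),
        )
    except (ValueError, CellGeometryError) as exc:
        if isinstance(exc, CellGeometryError):
            raise
        raise RecordParseError(f"malformed CRYST1 numeric fields in {line!r}") from exc
    symbol = line[55:66].strip()
    if not symbol:
        raise RecordParseError("CRYST1 record has no space-group field (columns 56-66)")
    return cell, SpaceGroupInfo.from_symbol(symbol)


def read_cif_cell(source: str) -> tuple[UnitCell, SpaceGroupInfo]:
    """Read cell and symmetry from an mmCIF file path or mmCIF text."""
    import gemmi

    try:
        if "\n" in source or source.lstrip().startswith("data_"):
            doc = gemmi.cif.read_string(source)
        else:
            doc = gemmi.cif.read_file(source)
        block = doc.sole_block()
    except Exception as exc:  # gemmi raises RuntimeError/ValueError on bad input
        raise RecordParseError(f"cannot parse mmCIF source: {exc}") from exc

    def want(tag: str) -> str:
        val = block.find_value(tag)
        if val is None:
            raise RecordParseError(f"mmCIF source lacks {tag}")
        return val

    cell = UnitCell(
        a=float(want("_cell.length_a")),
        b=float(want("_cell.length_b")),
        c=float(want("_cell.length_c")),
        alpha=float(want("_cell.angle_alpha")),
        beta=float(want("_cell.angle_beta")),
        gamma=float(want("_cell.angle_gamma")),
    )
    sym = (block.find_value("_symmetry.space_group_name_H-M")
           or block.find_value("_space_group.name_H-M_alt"))
    if sym is None:
        raise RecordParseError("mmCIF source lacks _symmetry.space_group_name_H-M")
    return cell, SpaceGroupInfo.from_symbol(gemmi.cif.as_string(sym))


def parse_csv_row(row: dict | pd.Series) -> CrystalForm:
    """Build a :class:`CrystalForm` from one canonical CSV row."""
    try:
        cell = UnitCell(a=float(row["a"]), b=float(row["b"]), c=float(row["c"]),
                        alpha=float(row["alpha"]), beta=float(row["beta"]),
                        gamma=float(row["gamma"]))
        sg = SpaceGroupInfo.from_symbol(str(row["space_group"]))
        return CrystalForm(
            name=str(row["name"]), cell=cell, space_group=sg,
            copies_per_asu=int(row["copies"]), molar_mass=float(row["molar_mass_da"]),
        )
    except KeyError as exc:
        raise RecordParseError(f"CSV row missing field {exc}") from exc


def read_cell_record(source) -> tuple[UnitCell, SpaceGroupInfo]:
    """Dispatch on dialect: CRYST1 line, mmCIF path/text, or CSV-row mapping."""
    if isinstance(source, (dict, pd.Series)):
        form = parse_csv_row(source)
        return form.cell, form.space_group
    if isinstance(source, str):
        if source.lstrip().startswith("CRYST1"):
            return parse_cryst1(source.lstrip("\n"))
        return read_cif_cell(source)
    raise RecordParseError(f"unsupported cell-record source type {type(source).__name__}")


def read_forms_csv(path_or_buf) -> list[CrystalForm]:
    """Read the canonical crystal-form CSV (see :data:`CSV_COLUMNS`)."""
    df = pd.read_csv(path_or_buf)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise RecordParseError(f"crystal-form CSV missing columns: {sorted(missing)}")
    return [parse_csv_row(row) for _, row in df.iterrows()]


def write_forms_csv(forms: list[CrystalForm], path_or_buf) -> None:
    """Write crystal forms in the canonical CSV dialect."""
    pd.DataFrame([{
        "name": f.name,
        "a": f.cell.a, "b": f.cell.b, "c": f.cell.c,
        "alpha": f.cell.alpha, "beta": f.cell.beta, "gamma": f.cell.gamma,
        "space_group": f.space_group.symbol,
        "copies": f.copies_per_asu,
        "molar_mass_da": f.molar_mass,
    } for f in forms]).to_csv(path_or_buf, index=False)
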