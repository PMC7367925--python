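"""Compound registry: identities, physicochemical constants and unit conversions.

The whole toolkit stores concentrations internally in -log10(M) ("neglog"
units), the unified convention used when points of departure from many
assays are tabulated side by side; conversions to M/µM/nM happen only at
the I/O boundary.  A neglog of 6.0 is 1 µM, 5.6 is about 2.5 µM.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import InvalidValueError, SchemaError

STOCK_SOLVENTS = frozenset({"DMSO", "PBS", "water", "medium"})

#: Air-water partition coefficient below which a compound is treated as
#: non-volatile under standard multi-well exposure conditions.
KAW_VOLATILE_THRESHOLD = 0.03
#: Lower edge of the borderline band (half the non-volatile threshold).
KAW_BORDERLINE_LOW = KAW_VOLATILE_THRESHOLD / 2

_UNIT_SCALE = {"M": 1.0, "uM": 1e6, "µM": 1e6, "nM": 1e9}

_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")


def cas_checksum_ok(cas: str) -> bool:
    """Validate a CAS registry number against its check digit."""
    m = _CAS_RE.match(cas.strip())
    if not m:
        return False
    digits = (m.group(1) + m.group(2))[::-1]
    total = sum((i + 1) * int(d) for i, d in enumerate(digits))
    return total % 10 == int(m.group(3))


@dataclass(frozen=True)
class ConcentrationValue:
    """A concentration stored as -log10 of its molar value."""

    neglog_molar: float

    def __post_init__(self):
        if not math.isfinite(self.neglog_molar):
            raise InvalidValueError("neglog concentration must be finite")

    @property
    def molar(self) -> float:
        return 10.0 ** (-self.neglog_molar)

    @property
    def micromolar(self) -> float:
        return self.molar * 1e6

    @property
    def nanomolar(self) -> float:
        return self.molar * 1e9

    @classmethod
    def from_molar(cls, molar: float) -> "ConcentrationValue":
        if not (math.isfinite(molar) and molar > 0):
            raise InvalidValueError(f"molar concentration must be finite and > 0, got {molar!r}")
        return cls(-math.log10(molar))

    def display(self, unit: str = "µM", sig_figs: int = 2) -> str:
        """Human-facing rendering at 2 significant figures by default."""
        value = neglog_to_conc(self.neglog_molar, unit)
        if value == 0:
            return f"0 {unit}"
        rounded = round(value, -int(math.floor(math.log10(abs(value)))) + (sig_figs - 1))
        return f"{rounded:g} {unit}"


def neglog_to_conc(neglog: float, unit: str = "M") -> float:
    """Convert a -log10(M) value to a concentration in M, µM or nM."""
    if not math.isfinite(neglog):
        raise InvalidValueError(f"neglog must be finite, got {neglog!r}")
    try:
        scale = _UNIT_SCALE[unit]
    except KeyError:
        raise InvalidValueError(f"unknown unit {unit!r}; use M, uM/µM or nM") from None
    return 10.0 ** (-neglog) * scale


def conc_to_neglog(conc: float, unit: str = "M") -> float:
    """Inverse of :func:`neglog_to_conc`; round-trips to 1e-12 relative."""
    if not (math.isfinite(conc) and conc > 0):
        raise InvalidValueError(f"concentration must be finite and > 0, got {conc!r}")
    try:
        scale = _UNIT_SCALE[unit]
    except KeyError:
        raise InvalidValueError(f"unknown unit {unit!r}; use M, uM/µM or nM") from None
    return -math.log10(conc / scale)


def mass_conc_to_molar(mass_conc_mg_ml: float, mw_kda: float) -> float:
    """Convert a mass concentration (mg/mL) to µM given a molecular weight in kDa.

    Used to express serum protein as molar albumin: 23 mg/mL at 66.5 kDa
    gives ~346 µM, the reference albumin content of undiluted FCS.
    """
    if not math.isfinite(mw_kda) or mw_kda <= 0:
        raise InvalidValueError(f"molecular weight must be > 0 kDa, got {mw_kda!r}")
    if not math.isfinite(mass_conc_mg_ml) or mass_conc_mg_ml < 0:
        raise InvalidValueError(f"mass concentration must be >= 0, got {mass_conc_mg_ml!r}")
    # mg/mL == g/L; divide by g/mol (kDa * 1000) -> mol/L; * 1e6 -> µM
    return mass_conc_mg_ml / mw_kda * 1000.0


def dilution_series(start_neglog: float, end_neglog: float, step_log: float) -> list[ConcentrationValue]:
    """Inclusive arithmetic series in -log10(M), most concentrated first.

    The standard reporter-battery design is ``dilution_series(4, 10, 0.5)``:
    13 concentrations from 100 µM down to 0.1 nM in half-log steps.
    """
    if not (math.isfinite(step_log) and step_log > 0):
        raise InvalidValueError(f"step must be > 0, got {step_log!r}")
    if not (math.isfinite(start_neglog) and math.isfinite(end_neglog)):
        raise InvalidValueError("series bounds must be finite")
    if end_neglog < start_neglog:
        raise InvalidValueError("end_neglog must be >= start_neglog")
    # floor with tolerance so e.g. (4, 10, 0.5) lands exactly on 13 points
    n = int(math.floor((end_neglog - start_neglog) / step_log + 1e-9)) + 1
    return [ConcentrationValue(start_neglog + i * step_log) for i in range(n)]


@dataclass
class Compound:
    """A registry entry: identity, physicochemical constants, handling notes."""

    compound_id: str
    name: str
    cas: str
    mw: float  # Da
    stock_solvent: str = "DMSO"
    stock_conc: float | None = None  # mol/L
    smiles: str | None = None
    log_kow: float | None = None
    k_aw: float | None = None
    aqueous_solubility: float | None = None  # mol/L at pH 7.4
    ppb_fraction_bound: float | None = None
    handling_notes: str = ""

    def __post_init__(self):
        if not (math.isfinite(self.mw) and self.mw > 0):
            raise InvalidValueError(f"{self.compound_id}: mw must be > 0, got {self.mw!r}")
        if self.stock_solvent not in STOCK_SOLVENTS:
            raise InvalidValueError(
                f"{self.compound_id}: stock_solvent must be one of {sorted(STOCK_SOLVENTS)}"
            )
        if self.ppb_fraction_bound is not None and not (0.0 <= self.ppb_fraction_bound <= 1.0):
            raise InvalidValueError(
                f"{self.compound_id}: ppb_fraction_bound must be in [0, 1]"
            )
        if not cas_checksum_ok(self.cas):
            raise InvalidValueError(f"{self.compound_id}: invalid CAS number {self.cas!r}")


def check_solubility(compound: Compound, test_conc: ConcentrationValue) -> str:
    """Report whether a tested concentration exceeds the aqueous solubility.

    Returns ``"ok"``, ``"warn_exceeds_solubility"`` or ``"unknown"`` (no
    solubility on record).
    """
    if compound.aqueous_solubility is None:
        return "unknown"
    if test_conc.molar > compound.aqueous_solubility:
        return "warn_exceeds_solubility"
    return "ok"


def volatility_flag(compound: Compound) -> str:
    """Classify volatility from the air-water partition coefficient K_AW.

    K_AW < 0.03 counts as non-volatile; values in [0.015, 0.03) are
    borderline (e.g. HgCl2 at K_AW = 0.02); >= 0.03 volatile.
    """
    k = compound.k_aw
    if k is None:
        return "unknown"
    if k >= KAW_VOLATILE_THRESHOLD:
        return "volatile"
    if k >= KAW_BORDERLINE_LOW:
        return "borderline"
    return "non_volatile"


REGISTRY_COLUMNS = [
    "compound_id", "name", "cas", "smiles", "mw_da", "log_kow", "k_aw",
    "solubility_mol_l", "ppb_fraction_bound", "stock_solvent", "stock_conc_m",
    "handling_notes",
]


class CompoundRegistry:
    """In-memory compound registry keyed by compound_id."""

    def __init__(self, compounds: list[Compound] | None = None):
        self._by_id: dict[str, Compound] = {}
        for c in compounds or []:
            self.add(c)

    def add(self, compound: Compound) -> None:
        if compound.compound_id in self._by_id:
            raise InvalidValueError(f"duplicate compound_id {compound.compound_id!r}")
        self._by_id[compound.compound_id] = compound

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._by_id

    def __getitem__(self, compound_id: str) -> Compound:
        return self._by_id[compound_id]

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    @classmethod
    def read_csv(cls, path: str | Path | io.IOBase) -> "CompoundRegistry":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"registry is missing columns: {missing}")
        reg = cls()
        for i, row in df.iterrows():
            def opt_float(key: str) -> float | None:
                v = row[key].strip()
                if v == "":
                    return None
                try:
                    return float(v)
                except ValueError:
                    raise SchemaError(f"non-numeric {key} {v!r}", location=f"row {i + 2}") from None

            reg.add(Compound(
                compound_id=row["compound_id"],
                name=row["name"],
                cas=row["cas"],
                smiles=row["smiles"] or None,
                mw=opt_float("mw_da"),
                log_kow=opt_float("log_kow"),
                k_aw=opt_float("k_aw"),
                aqueous_solubility=opt_float("solubility_mol_l"),
                ppb_fraction_bound=opt_float("ppb_fraction_bound"),
                stock_solvent=row["stock_solvent"],
                stock_conc=opt_float("stock_conc_m"),
                handling_notes=row["handling_notes"],
            ))
        return reg

    def write_csv(self, path: str | Path) -> None:
        rows = []
        for c in sorted(self._by_id.values(), key=lambda c: c.compound_id):
            rows.append({
                "compound_id": c.compound_id, "name": c.name, "cas": c.cas,
                "smiles": c.smiles or "", "mw_da": c.mw,
                "log_kow": "" if c.log_kow is None else c.log_kow,
                "k_aw": "" if c.k_aw is None else c.k_aw,
                "solubility_mol_l": "" if c.aqueous_solubility is None else c.aqueous_solubility,
                "ppb_fraction_bound": "" if c.ppb_fraction_bound is None else c.ppb_fraction_bound,
                "stock_solvent": c.stock_solvent,
                "stock_conc_m": "" if c.stock_conc is None else c.stock_conc,
                "handling_notes": c.handling_notes,
            })
        pd.DataFrame(rows, columns=REGISTRY_COLUMNS).to_csv(path, index=False)


def demo_registry() -> CompoundRegistry:
    """A small illustrative registry of well-known test compounds.

    Physicochemical values here are round-number illustrations for demos and
    tests, not authoritative measurements; real studies should load their own
    curated registry file.
    """
    return CompoundRegistry([
        Compound("tolbutamide", "Tolbutamide", "64-77-7", mw=270.35, log_kow=2.34,
                 aqueous_solubility=5e-4, ppb_fraction_bound=0.95,
                 stock_solvent="DMSO", stock_conc=0.1),
        Compound("paracetamol", "Paracetamol", "103-90-2", mw=151.16, log_kow=0.46,
                 aqueous_solubility=9e-2, ppb_fraction_bound=0.15,
                 stock_solvent="DMSO", stock_conc=0.1),
        Compound("colchicine", "Colchicine", "64-86-8", mw=399.44, log_kow=1.3,
                 ppb_fraction_bound=0.40, stock_solvent="DMSO", stock_conc=0.01),
        Compound("clofibrate", "Clofibrate", "637-07-0", mw=242.7, log_kow=3.6,
                 ppb_fraction_bound=0.95, stock_solvent="DMSO", stock_conc=0.1),
        Compound("sulfisoxazole", "Sulfisoxazole", "127-69-5", mw=267.3, log_kow=1.0,
                 ppb_fraction_bound=0.85, stock_solvent="DMSO", stock_conc=0.1),
        Compound("mercuric_chloride", "Mercury(II) chloride", "7487-94-7", mw=271.5,
                 log_kow=0.5, k_aw=0.02, stock_solvent="water", stock_conc=0.01),
        Compound("paraquat", "Paraquat dichloride", "1910-42-5", mw=257.16, log_kow=-4.5,
                 stock_solvent="medium", stock_conc=0.05,
                 handling_notes="dissolve freshly in culture medium before each use"),
    ])
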