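"""Chemical-formula and adduct arithmetic for mass-based metabolite annotation.

Everything the annotation stage needs to move between the three mass scales of
electrospray LC-MS data:

* molecular formulas and their monoisotopic (most-abundant-isotope) masses;
* observed ``m/z`` values and the neutral masses they imply under a given
  adduct hypothesis (protonation, sodiation, ... with charge up to 2);
* relative mass errors in parts per million (ppm), the matching statistic of
  the identification model.

Also houses the compound-database reader: a delimited table of
``compound_id, name, formula, neutral_mass, class_label, is_standard`` rows,
with the neutral mass computed from the formula when absent.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "FormulaError",
    "UnknownElementError",
    "ChemicalFormula",
    "parse_formula",
    "monoisotopic_mass",
    "AdductSpecies",
    "STANDARD_ADDUCTS",
    "adducts_for_polarity",
    "get_adduct",
    "mz_from_neutral",
    "neutral_mass_from_mz",
    "MassError",
    "ppm_error",
    "CompoundDatabase",
    "load_compound_database",
]

# Monoisotopic masses of the most abundant isotope of each element, in Da.
# Values from the IUPAC/CIAAW 2016 atomic-mass evaluation (AME2016), rounded
# to 1e-7 Da; bundled statically so mass arithmetic needs no runtime lookup.
MONOISOTOPIC_MASSES: Dict[str, float] = {
    "H": 1.0078250,
    "B": 11.0093054,
    "C": 12.0,
    "N": 14.0030740,
    "O": 15.9949146,
    "F": 18.9984032,
    "Na": 22.9897693,
    "Mg": 23.9850417,
    "Si": 27.9769265,
    "P": 30.9737615,
    "S": 31.9720707,
    "Cl": 34.9688527,
    "K": 38.9637065,
    "Ca": 39.9625909,
    "Fe": 55.9349363,
    "Zn": 63.9291420,
    "Se": 79.9165218,
    "Br": 78.9183376,
    "I": 126.9044719,
    "Li": 7.0160034,
}

#: Mass of a proton (H+ ion, electron removed), Da.
PROTON_MASS = 1.00727646688
#: Electron rest mass, Da.
ELECTRON_MASS = 0.00054857991


class FormulaError(ValueError):
    """Malformed chemical-formula string."""


class UnknownElementError(FormulaError):
    """Formula refers to an element symbol absent from the bundled mass table."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass
class ChemicalFormula:
    """A molecular formula as a mapping from element symbol to atom count."""

    element_counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for element, count in self.element_counts.items():
            if element not in MONOISOTOPIC_MASSES:
                raise UnknownElementError(f"unknown element {element!r}")
            if count < 0:
                raise FormulaError(f"negative count for element {element!r}")

    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __str__(self) -> str:
        """Render in Hill order: C, H, then remaining elements alphabetically."""
        counts = {e: c for e, c in self.element_counts.items() if c > 0}
        if "C" in counts:
            order = ["C"] + (["H"] if "H" in counts else [])
            order += sorted(e for e in counts if e not in ("C", "H"))
        else:
            order = sorted(counts)
        return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in order)

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = dict(self.element_counts)
        for e, c in other.element_counts.items():
            merged[e] = merged.get(e, 0) + c
        return ChemicalFormula(merged)


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a Hill-style formula string like ``"C5H8O4"``.

    No isotope labels, charges or grouping; an unknown element symbol raises
    :class:`UnknownElementError` rather than being skipped silently.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    s = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None or not m.group(1):
            raise FormulaError(f"malformed formula {s!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in MONOISOTOPIC_MASSES:
            raise UnknownElementError(
                f"unknown element {element!r} in formula {s!r} at position {pos}"
            )
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ChemicalFormula(counts)


def monoisotopic_mass(formula: Union[ChemicalFormula, str]) -> float:
    """Monoisotopic mass in Da: sum of most-abundant-isotope masses."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return float(
        sum(MONOISOTOPIC_MASSES[e] * c for e, c in formula.element_counts.items())
    )


@dataclass(frozen=True)
class AdductSpecies:
    """An ionization hypothesis: charge carrier(s) attached to a neutral M.

    ``mass_shift`` is the signed, electron-corrected mass added per charge
    carrier, so that ``mz = (M + charge * mass_shift) / charge``.
    """

    name: str
    mass_shift: float
    charge: int
    polarity: str

    def __post_init__(self) -> None:
        if self.charge not in (1, 2):
            raise ValueError(f"charge must be 1 or 2, got {self.charge}")
        if not math.isfinite(self.mass_shift):
            raise ValueError("mass_shift must be finite")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")


# Electron-corrected shifts: cations lose one electron per charge carrier,
# anions gain one.  Deprotonation is modeled as removal of a proton.
STANDARD_ADDUCTS: Dict[str, AdductSpecies] = {
    "[M+H]+": AdductSpecies("[M+H]+", PROTON_MASS, 1, "positive"),
    "[M+2H]2+": AdductSpecies("[M+2H]2+", PROTON_MASS, 2, "positive"),
    "[M+Na]+": AdductSpecies(
        "[M+Na]+", MONOISOTOPIC_MASSES["Na"] - ELECTRON_MASS, 1, "positive"
    ),
    "[M+K]+": AdductSpecies(
        "[M+K]+", MONOISOTOPIC_MASSES["K"] - ELECTRON_MASS, 1, "positive"
    ),
    "[M-H]-": AdductSpecies("[M-H]-", -PROTON_MASS, 1, "negative"),
    "[M-2H]2-": AdductSpecies("[M-2H]2-", -PROTON_MASS, 2, "negative"),
    "[M+Cl]-": AdductSpecies(
        "[M+Cl]-", MONOISOTOPIC_MASSES["Cl"] + ELECTRON_MASS, 1, "negative"
    ),
}

_DEFAULT_POSITIVE = ("[M+H]+", "[M+2H]2+", "[M+Na]+", "[M+K]+")
_DEFAULT_NEGATIVE = ("[M-H]-", "[M-2H]2-")


def get_adduct(name: str) -> AdductSpecies:
    try:
        return STANDARD_ADDUCTS[name]
    except KeyError:
        raise KeyError(
            f"unknown adduct {name!r}; known: {sorted(STANDARD_ADDUCTS)}"
        ) from None


def adducts_for_polarity(
    polarity: str, include_chloride: bool = False
) -> list[AdductSpecies]:
    """Default adduct hypotheses for one ESI polarity.

    Positive mode follows the protonated/sodiated/potassiated species with
    charge up to 2; negative mode defaults to deprotonation, with the chloride
    adduct available on request.
    """
    if polarity == "positive":
        names = list(_DEFAULT_POSITIVE)
    elif polarity == "negative":
        names = list(_DEFAULT_NEGATIVE) + (["[M+Cl]-"] if include_chloride else [])
    else:
        raise ValueError(f"polarity must be positive|negative, got {polarity!r}")
    return [STANDARD_ADDUCTS[n] for n in names]


def mz_from_neutral(neutral_mass, adduct: AdductSpecies):
    """Observed m/z of a neutral mass under an adduct hypothesis."""
    return (neutral_mass + adduct.charge * adduct.mass_shift) / adduct.charge


def neutral_mass_from_mz(mz, adduct: AdductSpecies):
    """Invert the ionization equation: neutral M from observed m/z.

    Accepts scalars or numpy arrays.  Raises for non-positive m/z.
    """
    if np.any(np.asarray(mz) <= 0):
        raise ValueError("m/z must be positive")
    return np.multiply(mz, adduct.charge) - adduct.charge * adduct.mass_shift


@dataclass(frozen=True)
class MassError:
    """A signed relative mass error in parts per million."""

    value: float
    observed_neutral_mass: float
    theoretical_mass: float


def ppm_error(observed: float, theoretical: float) -> MassError:
    """Signed ppm error of an observed neutral mass against a theoretical one."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    value = (observed - theoretical) / theoretical * 1e6
    return MassError(float(value), float(observed), float(theoretical))


_DB_REQUIRED = ("compound_id", "formula")
_CLASS_LABELS = (
    "tryptophan metabolism",
    "acylcarnitines",
    "lipids",
    "bacterial origin",
    "glycine conjugates",
    "others",
)


@dataclass
class CompoundDatabase:
    """Formula-keyed reference masses queried by the matcher.

    ``frame`` columns: compound_id, name, formula, neutral_mass, class_label,
    is_standard (plus any extras, preserved).  Matching operates at the level
    of unique formulas: all compounds sharing a formula share one mass value,
    so mass alone cannot distinguish them (isomer ambiguity).
    """

    frame: pd.DataFrame
    _formula_table: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CompoundDatabase":
        df = frame.copy()
        missing = [c for c in _DB_REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"compound database missing columns: {missing}")
        if df["compound_id"].duplicated().any():
            dupes = df.loc[df["compound_id"].duplicated(), "compound_id"].tolist()
            raise ValueError(f"duplicate compound_id values: {dupes[:5]}")
        if "name" not in df.columns:
            df["name"] = df["compound_id"]
        if "class_label" not in df.columns:
            df["class_label"] = "others"
        if "is_standard" not in df.columns:
            df["is_standard"] = False
        df["is_standard"] = df["is_standard"].astype(bool)
        if "neutral_mass" not in df.columns:
            df["neutral_mass"] = np.nan
        df["neutral_mass"] = pd.to_numeric(df["neutral_mass"], errors="coerce")
        needs_mass = df["neutral_mass"].isna()
        if needs_mass.any():
            df.loc[needs_mass, "neutral_mass"] = [
                monoisotopic_mass(f) for f in df.loc[needs_mass, "formula"]
            ]
        else:
            # validate that formulas at least parse
            for f in df["formula"]:
                parse_formula(f)
        if (df["neutral_mass"] <= 0).any():
            raise ValueError("non-positive neutral mass in compound database")
        return cls(df.reset_index(drop=True))

    def formula_table(self) -> pd.DataFrame:
        """Unique formulas sorted by mass.

        Columns: formula, neutral_mass (of the first compound carrying the
        formula), compound_ids (tuple, database order), standard_ids (tuple of
        compounds flagged is_standard), n_compounds, db_order (position of the
        first carrier, used for deterministic tie-breaking).
        """
        if self._formula_table is None:
            df = self.frame
            rows = []
            seen: Dict[str, int] = {}
            for order, rec in enumerate(df.itertuples(index=False)):
                if rec.formula in seen:
                    rows[seen[rec.formula]]["compound_ids"].append(rec.compound_id)
                    if rec.is_standard:
                        rows[seen[rec.formula]]["standard_ids"].append(rec.compound_id)
                else:
                    seen[rec.formula] = len(rows)
                    rows.append(
                        {
                            "formula": rec.formula,
                            "neutral_mass": rec.neutral_mass,
                            "compound_ids": [rec.compound_id],
                            "standard_ids": [rec.compound_id] if rec.is_standard else [],
                            "db_order": order,
                        }
                    )
            ft = pd.DataFrame(rows)
            ft["compound_ids"] = ft["compound_ids"].map(tuple)
            ft["standard_ids"] = ft["standard_ids"].map(tuple)
            ft["n_compounds"] = ft["compound_ids"].map(len)
            ft = ft.sort_values("neutral_mass", kind="mergesort").reset_index(drop=True)
            self._formula_table = ft
        return self._formula_table

    def to_csv(self, path: Union[str, Path], sep: str = "\t") -> None:
        self.frame.to_csv(path, sep=sep, index=False)


def load_compound_database(path: Union[str, Path]) -> CompoundDatabase:
    """Read a compound database from delimited text (TSV or CSV by extension)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep)
    return CompoundDatabase.from_frame(frame)
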