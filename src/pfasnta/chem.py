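"""Elemental-formula arithmetic for negative-mode PFAS screening.

Provides Hill-style formula parsing, monoisotopic mass and anion m/z
computation (electron mass included), ppm errors, ring-and-double-bond
equivalents, first-isotope (M+1) abundance ratios, and the CF2-normalized
Kendrick mass transform used to reveal perfluoroalkyl homologous series.

All mass arithmetic is pinned to the isotope table in :data:`ELEMENTS`
(monoisotopic masses of the most abundant isotope, 2021 IUPAC values,
>=6 decimal places).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ELEMENTS",
    "ELECTRON_MASS",
    "KENDRICK_CF2_EXACT",
    "KENDRICK_CF2_NOMINAL",
    "Formula",
    "KendrickValues",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "rdb",
    "isotope_m1_ratio",
    "kendrick",
]


@dataclass(frozen=True)
class ElementInfo:
    """One row of the pinned isotope table."""

    symbol: str
    mass: float  #: monoisotopic mass of the most abundant isotope (Da)
    m1_ratio: float  #: abundance ratio heavy(M+1)/light, 0 if no M+1 isotope


#: Supported elements. ``m1_ratio`` is the single-substitution (M+1)/M
#: abundance ratio (e.g. 13C/12C); elements whose next isotope is M+2
#: (Cl, K) or that are monoisotopic (F, Na, P) carry 0.
ELEMENTS: Mapping[str, ElementInfo] = {
    e.symbol: e
    for e in [
        ElementInfo("C", 12.0, 0.010815728),        # 13C/12C = 0.0107/0.9893
        ElementInfo("H", 1.007825032, 0.000115013),  # 2H/1H
        ElementInfo("N", 14.003074005, 0.003653700),  # 15N/14N
        ElementInfo("O", 15.994914620, 0.000380926),  # 17O/16O
        ElementInfo("S", 31.972071174, 0.007895568),  # 33S/32S
        ElementInfo("F", 18.998403163, 0.0),
        ElementInfo("Cl", 34.968852682, 0.0),
        ElementInfo("P", 30.973761998, 0.0),
        ElementInfo("Na", 22.989769282, 0.0),
        ElementInfo("K", 38.963706486, 0.0),
    ]
}

#: Electron rest mass in Da; added once per negative charge.
ELECTRON_MASS = 0.000548580

#: Kendrick rescaling constants for the CF2 base unit, conventional rounding.
KENDRICK_CF2_NOMINAL = 50.0
KENDRICK_CF2_EXACT = 49.996806


class FormulaError(ValueError):
    """Raised for malformed or unsupported formula strings."""


@dataclass(frozen=True)
class Formula:
    """An elemental composition with an integer charge.

    ``counts`` maps element symbols to non-negative atom counts; ``charge``
    is 0 for neutrals and -1 for the anions handled in this package.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in self.counts.items():
            if sym not in ELEMENTS:
                raise FormulaError(f"unsupported element symbol: {sym!r}")
            if n < 0:
                raise FormulaError(f"negative count for {sym}: {n}")
            if n > 0:
                clean[sym] = int(n)
        if not clean:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, sym: str) -> int:
        return self.counts.get(sym, 0)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return Formula(merged, self.charge + other.charge)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def __str__(self) -> str:
        return format_formula(self)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style element-count string, e.g. ``"C9H5F13NO4S-"``.

    A single trailing ``-`` or ``+`` sets the charge to -1/+1. Isotope
    labels and multi-charge suffixes are not supported.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    s = text.strip()
    charge = 0
    if s.endswith(("-", "−")):
        charge, s = -1, s[:-1]
    elif s.endswith("+"):
        charge, s = 1, s[:-1]
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at {s[pos:]!r}")
        sym = m.group(1)
        if sym not in ELEMENTS:
            # two-letter match may shadow a one-letter element + garbage
            if sym[0] in ELEMENTS and len(sym) == 2:
                raise FormulaError(f"unsupported element symbol: {sym!r}")
            raise FormulaError(f"unsupported element symbol: {sym!r}")
        n = int(m.group(2)) if m.group(2) else 1
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return Formula(counts, charge)


_HILL_FIRST = ("C", "H")


def format_formula(f: Formula) -> str:
    """Format in Hill order (C, H, then alphabetical), charge as suffix."""
    parts = []
    rest = sorted(sym for sym in f.counts if sym not in _HILL_FIRST)
    order = [s for s in _HILL_FIRST if s in f.counts] + rest
    if "C" not in f.counts:  # pure Hill: alphabetical when no carbon
        order = sorted(f.counts)
    for sym in order:
        n = f.counts[sym]
        parts.append(sym + (str(n) if n > 1 else ""))
    suffix = {0: "", -1: "-", 1: "+"}.get(f.charge)
    if suffix is None:
        suffix = f"{f.charge:+d}"
    return "".join(parts) + suffix


def monoisotopic_mass(f: Formula) -> float:
    """Sum of most-abundant-isotope atomic masses in Da (charge ignored)."""
    return sum(ELEMENTS[sym].mass * n for sym, n in f.counts.items())


def ion_mz(f: Formula, mode: str = "ion") -> float:
    """m/z of a singly charged negative ion.

    mode ``"ion"``: ``f`` already is the ion composition; one electron mass
    is added. mode ``"deprotonated"``: ``f`` is the neutral; one H is
    removed and one electron mass added ([M-H]-).
    """
    if mode in ("ion", "ion-as-written"):
        return monoisotopic_mass(f) + ELECTRON_MASS
    if mode == "deprotonated":
        if f["H"] < 1:
            raise FormulaError(f"cannot deprotonate {f}: no hydrogen")
        return monoisotopic_mass(f) - ELEMENTS["H"].mass + ELECTRON_MASS
    raise ValueError(f"unknown ion mode: {mode!r}")


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def rdb(f: Formula) -> float:
    """Ring-and-double-bond equivalents: C - (H+F+Cl)/2 + (N+P)/2 + 1.

    Half-integral results are returned as-is; they flag radical or ionic
    compositions, which are used only as a plausibility screen.
    """
    return (
        f["C"]
        - (f["H"] + f["F"] + f["Cl"]) / 2.0
        + (f["N"] + f["P"]) / 2.0
        + 1.0
    )


def isotope_m1_ratio(f: Formula) -> float:
    """Predicted (M+1)/M intensity ratio from single heavy-isotope substitution.

    Exact for the first isotopologue: the probability of exactly one heavy
    substitution relative to the all-light species is sum(n_E * p_E/q_E).
    """
    return sum(ELEMENTS[sym].m1_ratio * n for sym, n in f.counts.items())


@dataclass(frozen=True)
class KendrickValues:
    """CF2-rescaled mass bookkeeping for one feature."""

    mz: float
    kendrick_mass: float
    nominal_kendrick_mass: int
    kmd: float  #: nominal_kendrick_mass - kendrick_mass (signed, Da)


def kendrick(
    mz: float,
    unit_nominal: float = KENDRICK_CF2_NOMINAL,
    unit_exact: float = KENDRICK_CF2_EXACT,
) -> KendrickValues:
    """CF2-normalized Kendrick mass defect.

    KM = m/z * (nominal unit mass / exact unit mass); KMD = round(KM) - KM,
    rounding to the nearest integer (ties-to-even, the Python default).
    Perfluoroalkyl homologues (CF2 spacing) share a KMD near or below zero,
    whereas hydrogen-rich matrix compounds drift to strongly negative KMD.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    km = mz * unit_nominal / unit_exact
    nominal = round(km)
    return KendrickValues(mz=mz, kendrick_mass=km, nominal_kendrick_mass=nominal, kmd=nominal - km)


def formula_mz(f: Formula, ion_mode: str | None = None) -> float:
    """m/z for a formula, inferring the mode from its charge when not given.

    Charged formulas are treated as written ions; neutrals default to
    deprotonation.
    """
    if ion_mode is None:
        ion_mode = "ion" if f.charge != 0 else "deprotonated"
    return ion_mz(f, ion_mode)


def combine(formulas: Iterable[Formula]) -> Formula:
    out: Formula | None = None
    for f in formulas:
        out = f if out is None else out + f
    if out is None:
        raise FormulaError("no formulas to combine")
    return out
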