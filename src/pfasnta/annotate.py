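"""Identification evidence and confidence-level assignment.

Covers the three evidence routes of PFAS non-target screening in negative
mode: (i) spectral-library search with a coverage-style fit score, (ii)
suspect screening by exact mass and first-isotope ratio, and (iii) manual
style diagnostic-fragment / neutral-loss interpretation, followed by
assignment on the 1a-5b PFAS identification confidence scale (1a =
confirmed by reference standard ... 5 = exact mass of interest).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chem import (
    Formula,
    formula_mz,
    ion_mz,
    isotope_m1_ratio,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
)

__all__ = [
    "Spectrum",
    "LibraryEntry",
    "SuspectEntry",
    "FragmentRule",
    "AnnotationEvidence",
    "LibraryHit",
    "SuspectHit",
    "ClassEvidence",
    "NeutralLoss",
    "fit_score",
    "library_search",
    "suspect_screen",
    "neutral_losses",
    "classify_by_fragments",
    "assign_confidence",
    "CONFIDENCE_LEVELS",
    "DEFAULT_LOSS_TABLE",
    "DEFAULT_FRAGMENT_RULES",
]


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum; peaks kept sorted by m/z."""

    precursor_mz: float
    peaks: list[tuple[float, float]]  #: (m/z, relative intensity)
    acquisition: str = "dda"  #: dda or swath
    collision_energy: float | None = None

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("spectrum must contain at least one peak")
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("peak intensities must be non-negative")
        self.peaks = sorted((float(m), float(i)) for m, i in self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])

    def has_peak(self, mz: float, tol: float) -> bool:
        return bool(np.any(np.abs(self.mz - mz) <= tol))


@dataclass(frozen=True)
class LibraryEntry:
    """One reference MS/MS spectrum with its ion composition."""

    name: str
    formula: Formula
    ion_mode: str  #: "ion" (formula is the anion) or "deprotonated"
    spectrum: Spectrum
    class_label: str = ""

    @property
    def theoretical_mz(self) -> float:
        return ion_mz(self.formula, self.ion_mode)


@dataclass(frozen=True)
class SuspectEntry:
    """A suspect-list row: a formula expected as a specific ion species."""

    name: str
    formula: Formula
    ion_mode: str = "deprotonated"
    class_label: str = ""
    source: str = ""

    @property
    def theoretical_mz(self) -> float:
        return ion_mz(self.formula, self.ion_mode)

    @property
    def isotope_ratio(self) -> float:
        return isotope_m1_ratio(self.formula)


@dataclass
class LibraryHit:
    name: str
    score: float
    mass_error_ppm: float
    replicate_count: int
    rt_consistent: bool
    class_label: str = ""


@dataclass
class SuspectHit:
    name: str
    mass_error_ppm: float
    isotope_diff_percent: float | None
    class_label: str = ""


@dataclass
class NeutralLoss:
    from_mz: float  #: precursor or heavier fragment
    to_mz: float
    loss_mass: float
    matches: list[str] = field(default_factory=list)  #: matching loss formula names


@dataclass(frozen=True)
class FragmentRule:
    """Class-diagnostic fragmentation rule.

    ``required_fragments`` are (label, theoretical m/z) anion fragments;
    ``required_losses`` are (label, neutral mass) losses from the precursor
    or between fragments; ``forbidden_fragments`` must be absent (e.g. the
    sulfuramidous-acid class requires the sulfonate SO3- to be missing).
    The rule is satisfied when at least ``min_matches`` requirements match
    and no forbidden fragment is present.
    """

    class_label: str
    required_fragments: tuple[tuple[str, float], ...] = ()
    required_losses: tuple[tuple[str, float], ...] = ()
    forbidden_fragments: tuple[tuple[str, float], ...] = ()
    min_matches: int = 1

    def __post_init__(self) -> None:
        if not (self.required_fragments or self.required_losses):
            raise ValueError("rule needs at least one requirement")


@dataclass
class ClassEvidence:
    class_label: str
    matched_fragments: list[str]
    matched_losses: list[str]
    satisfied: bool


@dataclass
class AnnotationEvidence:
    """Accumulated identification evidence for one feature."""

    feature_id: str
    library_hits: list[LibraryHit] = field(default_factory=list)
    suspect_hits: list[SuspectHit] = field(default_factory=list)
    class_evidence: list[ClassEvidence] = field(default_factory=list)
    has_reference_standard_match: bool = False  #: RT match against an in-house standard
    literature_spectrum_match: bool = False  #: MS/MS matched to a published spectrum
    formula_confirmed: bool = False  #: isotope pattern + RDB support a unique formula
    isomer_ambiguity: bool = False  #: >=2 structural/positional isomer candidates remain
    confidence: str | None = None

    @property
    def diagnostic_class(self) -> bool:
        return any(c.satisfied for c in self.class_evidence)

    def is_empty(self) -> bool:
        return not (
            self.library_hits
            or self.suspect_hits
            or self.class_evidence
            or self.has_reference_standard_match
            or self.literature_spectrum_match
            or self.formula_confirmed
        )


def fit_score(query: Spectrum, library: Spectrum, frag_tol: float = 0.01) -> float:
    """Library-coverage fit score, 0-100.

    100 x (summed intensity of library peaks that have a query peak within
    ``frag_tol``) / (total library peak intensity). 100 means every library
    peak is present in the unknown spectrum — the score measures how
    completely the library spectrum is encompassed by the query, not the
    reverse, so extra query peaks do not penalise.
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    qmz = query.mz
    total = library.intensity.sum()
    if total <= 0:
        raise ValueError("library spectrum has zero total intensity")
    matched = sum(
        inten for mz, inten in library.peaks if np.any(np.abs(qmz - mz) <= frag_tol)
    )
    return 100.0 * matched / total


@dataclass(frozen=True)
class LibraryCriteria:
    ppm_max: float = 5.0  #: strict <
    score_min: float = 80.0  #: inclusive >=
    replicate_count: int = 3  #: matches required in >= this many replicate spectra
    require_rt_consistent: bool = True


def library_search(
    feature_mz: float,
    replicate_spectra: Sequence[Spectrum],
    library: Sequence[LibraryEntry],
    criteria: LibraryCriteria = LibraryCriteria(),
    frag_tol: float = 0.01,
    rt_consistent: bool = True,
) -> list[LibraryHit]:
    """In-house library search against replicate MS/MS spectra.

    A hit requires: |mass error| < 5 ppm to the entry's theoretical ion m/z,
    fit score >= 80 in at least ``replicate_count`` replicate spectra, and a
    homologue-consistent retention time (caller-supplied flag). Returns hits
    sorted by best fit score, descending. No MS/MS -> no hits.
    """
    hits: list[LibraryHit] = []
    if not replicate_spectra:
        return hits
    for entry in library:
        err = ppm_error(feature_mz, entry.theoretical_mz)
        if abs(err) >= criteria.ppm_max:
            continue
        scores = [fit_score(q, entry.spectrum, frag_tol) for q in replicate_spectra]
        n_ok = sum(s >= criteria.score_min for s in scores)
        if n_ok < criteria.replicate_count:
            continue
        if criteria.require_rt_consistent and not rt_consistent:
            continue
        hits.append(
            LibraryHit(
                name=entry.name,
                score=max(scores),
                mass_error_ppm=err,
                replicate_count=n_ok,
                rt_consistent=rt_consistent,
                class_label=entry.class_label,
            )
        )
    hits.sort(key=lambda h: (-h.score, abs(h.mass_error_ppm), h.name))
    return hits


@dataclass(frozen=True)
class SuspectCriteria:
    ppm_max: float = 5.0  #: strict <
    isotope_diff_max: float = 5.0  #: percent, strict <


def suspect_screen(
    feature_mz: float,
    suspects: Sequence[SuspectEntry],
    observed_isotope_ratio: float | None = None,
    criteria: SuspectCriteria = SuspectCriteria(),
) -> list[SuspectHit]:
    """Exact-mass suspect screening.

    A hit requires |mass error| < 5 ppm; when an observed (M+1)/M ratio is
    available the percent difference |obs - theor| / theor x 100 must be
    < 5, otherwise the isotope criterion is skipped (not failed) — SWATH
    features may lack a usable M+1. Sorted by |ppm|.
    """
    hits: list[SuspectHit] = []
    for s in suspects:
        err = ppm_error(feature_mz, s.theoretical_mz)
        if abs(err) >= criteria.ppm_max:
            continue
        iso_diff: float | None = None
        if observed_isotope_ratio is not None:
            theor = s.isotope_ratio
            if theor > 0:
                iso_diff = abs(observed_isotope_ratio - theor) / theor * 100.0
                if iso_diff >= criteria.isotope_diff_max:
                    continue
            elif observed_isotope_ratio > 0:
                continue  # monoisotopic suspect cannot explain an observed M+1
            else:
                iso_diff = 0.0
        hits.append(
            SuspectHit(
                name=s.name,
                mass_error_ppm=err,
                isotope_diff_percent=iso_diff,
                class_label=s.class_label,
            )
        )
    hits.sort(key=lambda h: (abs(h.mass_error_ppm), h.name))
    return hits


def _neutral_mass(text: str) -> float:
    return monoisotopic_mass(parse_formula(text))


#: Neutral losses recognised by default (name -> mass, Da). C6F13/C8F17 are
#: homolytic perfluoroalkyl radical losses characteristic of sulfonamides.
DEFAULT_LOSS_TABLE: Mapping[str, float] = {
    name: _neutral_mass(name)
    for name in ["CF2", "C2F4", "SO2", "C3H4O2", "HF", "CO2", "C6F13", "C8F17"]
}


def neutral_losses(
    spec: Spectrum,
    loss_table: Mapping[str, float] = DEFAULT_LOSS_TABLE,
    tol: float = 0.005,
    include_unmatched: bool = False,
) -> list[NeutralLoss]:
    """Annotate precursor->fragment and fragment->fragment mass differences.

    Every pairwise positive difference is compared against ``loss_table``;
    by default only differences matching at least one loss formula within
    ``tol`` are returned (set ``include_unmatched`` to keep all pairs).
    """
    sources = sorted({spec.precursor_mz, *(m for m, _ in spec.peaks)}, reverse=True)
    out: list[NeutralLoss] = []
    for i, hi in enumerate(sources):
        for lo in sources[i + 1:]:
            if hi <= lo:
                continue
            d = hi - lo
            matches = sorted(
                name for name, mass in loss_table.items() if abs(d - mass) <= tol
            )
            if matches or include_unmatched:
                out.append(NeutralLoss(from_mz=hi, to_mz=lo, loss_mass=d, matches=matches))
    out.sort(key=lambda nl: (-nl.from_mz, -nl.to_mz))
    return out


def _anion_mz(text: str) -> float:
    return formula_mz(parse_formula(text + "-"))


# Diagnostic anion fragments (theoretical m/z). Reported measured values in
# the source spectra deviate for two of them: 77.9655 is sometimes printed
# with an SO3- label although SO3- is 79.9574 and 77.9655 fits NO2S-; the
# CH3NO2S- fragment is printed at 92.9880 vs 92.9890 theoretical (~11 ppm).
# The 0.01 Da MS/MS tolerance absorbs both offsets.
FRAGMENT_MZ: Mapping[str, float] = {
    "SO3-": _anion_mz("SO3"),        # 79.9574
    "FSO3-": _anion_mz("FSO3"),      # 98.9558
    "NO2S-": _anion_mz("NO2S"),      # 77.9655
    "CH3NO2S-": _anion_mz("CH3NO2S"),  # 92.9890 (printed measured 92.9880)
    "CH3NO4S2-": _anion_mz("CH3NO4S2"),  # 156.9509 (printed measured 156.9513)
    "C6F13SO2NH-": _anion_mz("C6H1F13NO2S"),  # 397.9526; printed once as "C6F13SO3NH"
}

#: Built-in class rules for the PFAS classes handled here. PFSA-type classes
#: demand the sulfonate fragment; sulfonamide-head classes demand NO2S- and,
#: for the N-methyl sulfuramidous-acid class, the absence of SO3-.
DEFAULT_FRAGMENT_RULES: tuple[FragmentRule, ...] = (
    FragmentRule(
        class_label="PFSA",
        required_fragments=(("SO3-", FRAGMENT_MZ["SO3-"]), ("FSO3-", FRAGMENT_MZ["FSO3-"])),
        min_matches=1,
    ),
    FragmentRule(
        class_label="Cl-PFSA",
        required_fragments=(("SO3-", FRAGMENT_MZ["SO3-"]), ("FSO3-", FRAGMENT_MZ["FSO3-"])),
        min_matches=1,
    ),
    FragmentRule(
        class_label="FASA",
        required_fragments=(("NO2S-", FRAGMENT_MZ["NO2S-"]),),
        forbidden_fragments=(("SO3-", FRAGMENT_MZ["SO3-"]),),
        min_matches=1,
    ),
    FragmentRule(
        class_label="FASA-PrA",
        required_fragments=(("NO2S-", FRAGMENT_MZ["NO2S-"]),),
        required_losses=(("C3H4O2", DEFAULT_LOSS_TABLE["C3H4O2"]),),
        min_matches=2,
    ),
    FragmentRule(
        class_label="MeFASA-SA",  # N-methyl perfluoroalkane sulfonyl sulfuramidous acids
        required_fragments=(
            ("NO2S-", FRAGMENT_MZ["NO2S-"]),
            ("CH3NO2S-", FRAGMENT_MZ["CH3NO2S-"]),
        ),
        forbidden_fragments=(("SO3-", FRAGMENT_MZ["SO3-"]),),
        min_matches=2,
    ),
    FragmentRule(
        class_label="PFCA",
        required_losses=(("CO2", DEFAULT_LOSS_TABLE["CO2"]),),
        min_matches=1,
    ),
)


def classify_by_fragments(
    spec: Spectrum,
    rules: Sequence[FragmentRule] = DEFAULT_FRAGMENT_RULES,
    frag_tol: float = 0.01,
    loss_tol: float = 0.005,
) -> list[ClassEvidence]:
    """Evaluate class-diagnostic fragment rules against one spectrum."""
    if not rules:
        raise ValueError("rule set must be non-empty")
    losses = neutral_losses(spec, tol=loss_tol)
    observed_losses = {m for nl in losses for m in nl.matches}
    out: list[ClassEvidence] = []
    for rule in rules:
        frags = [name for name, mz in rule.required_fragments if spec.has_peak(mz, frag_tol)]
        loss_hits = [name for name, _ in rule.required_losses if name in observed_losses]
        forbidden = any(spec.has_peak(mz, frag_tol) for _, mz in rule.forbidden_fragments)
        satisfied = (len(frags) + len(loss_hits)) >= rule.min_matches and not forbidden
        out.append(
            ClassEvidence(
                class_label=rule.class_label,
                matched_fragments=frags,
                matched_losses=loss_hits,
                satisfied=satisfied,
            )
        )
    return out


#: Identification confidence scale, strongest first.
CONFIDENCE_LEVELS = ("1a", "1b", "2a", "2b", "3a", "3b", "4", "5a", "5b")


def assign_confidence(evidence: AnnotationEvidence) -> str:
    """Assign the highest attainable confidence level from the evidence.

    Ladder (strongest first):

    * 1a — library MS/MS match plus retention-time agreement with an
      in-house reference standard.
    * 1b — library MS/MS match indistinguishable from a standard's class
      spectrum, no RT-matched standard in hand.
    * 2a — diagnostic fragmentation evidence for a unique known structure
      (suspect/candidate supported), no standard.
    * 2b — diagnostic MS/MS matched to a literature-reported spectrum.
    * 3a — MS/MS consistent with the class but positional isomer candidates
      remain.
    * 3b — tentative structure proposed from fragmentation alone (novel).
    * 4 — unequivocal molecular formula (isotope/RDB confirmed), no
      structural evidence.
    * 5a — suspect exact-mass match only.
    * 5b — non-target exact mass of interest only.

    Deterministic and monotone: removing or weakening any evidence item can
    never raise the assigned level.
    """
    if evidence.is_empty():
        raise ValueError(f"no evidence recorded for {evidence.feature_id}")
    level: str
    if evidence.library_hits and evidence.has_reference_standard_match:
        level = "1a"
    elif evidence.library_hits:
        level = "1b"
    elif evidence.diagnostic_class and evidence.isomer_ambiguity:
        level = "3a"
    elif evidence.diagnostic_class and (evidence.suspect_hits or evidence.literature_spectrum_match):
        level = "2a" if evidence.suspect_hits else "2b"
    elif evidence.diagnostic_class:
        level = "3b"
    elif evidence.formula_confirmed and not evidence.suspect_hits:
        level = "4"
    elif evidence.suspect_hits and evidence.isomer_ambiguity:
        level = "5b"
    elif evidence.suspect_hits:
        level = "5a" if not evidence.formula_confirmed else "4"
    else:
        level = "5b"
    evidence.confidence = level
    return level
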