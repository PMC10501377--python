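"""Library fit scoring, suspect screening, fragment logic and confidence."""

import dataclasses

import pytest

from pfasnta.annotate import (
    AnnotationEvidence,
    CONFIDENCE_LEVELS,
    DEFAULT_FRAGMENT_RULES,
    FRAGMENT_MZ,
    FragmentRule,
    LibraryCriteria,
    LibraryEntry,
    LibraryHit,
    Spectrum,
    SuspectCriteria,
    SuspectEntry,
    SuspectHit,
    assign_confidence,
    classify_by_fragments,
    fit_score,
    library_search,
    neutral_losses,
    suspect_screen,
)
from pfasnta.chem import parse_formula

SO3, FSO3, NO2S = FRAGMENT_MZ["SO3-"], FRAGMENT_MZ["FSO3-"], FRAGMENT_MZ["NO2S-"]


def spec(peaks, precursor=500.0):
    return Spectrum(precursor_mz=precursor, peaks=peaks)


class TestFitScore:
    def test_full_containment_scores_100(self):
        lib = spec([(79.9574, 100), (98.9556, 50)])
        query = spec([(79.9574, 10), (98.9556, 5), (130.99, 80)])
        assert fit_score(query, lib) == 100.0

    def test_partial_containment_is_intensity_weighted(self):
        lib = spec([(79.9574, 100), (98.9556, 50)])
        query = spec([(79.9574, 10)])
        assert fit_score(query, lib) == pytest.approx(66.7, abs=0.05)

    def test_identity_scores_100(self):
        s = spec([(100.0, 5), (200.0, 10), (300.0, 1)])
        assert fit_score(s, s) == 100.0

    def test_monotone_as_query_peaks_added(self):
        lib = spec([(100.0, 30), (200.0, 30), (300.0, 40)])
        peaks = []
        prev = -1.0
        for mz in (100.0, 200.0, 300.0):
            peaks.append((mz, 1.0))
            score = fit_score(spec(peaks), lib)
            assert score >= prev
            prev = score
        assert prev == 100.0

    def test_score_bounded(self):
        lib = spec([(100.0, 30)])
        assert 0.0 <= fit_score(spec([(555.0, 1)]), lib) <= 100.0


def _pfos_like_library():
    entry = LibraryEntry(
        name="PFOS",
        formula=parse_formula("C8F17SO3-"),
        ion_mode="ion",
        spectrum=spec([(SO3, 100), (FSO3, 60)], precursor=498.9302),
        class_label="PFSA",
    )
    return entry, entry.theoretical_mz


class TestLibrarySearch:
    def test_perfect_match_in_triplicate_is_a_hit(self):
        entry, mz = _pfos_like_library()
        replicates = [spec([(SO3, 90), (FSO3, 55)], precursor=mz)] * 3
        hits = library_search(mz, replicates, [entry])
        assert [h.name for h in hits] == ["PFOS"]
        assert hits[0].score == 100.0

    def test_score_below_80_boundary_rejected(self):
        entry, mz = _pfos_like_library()
        # only SO3- matched: score 100*100/160 = 62.5 < 80
        replicates = [spec([(SO3, 90)], precursor=mz)] * 3
        assert library_search(mz, replicates, [entry]) == []

    def test_mass_error_above_5ppm_rejected_despite_good_score(self):
        entry, mz = _pfos_like_library()
        replicates = [spec([(SO3, 90), (FSO3, 55)])] * 3
        assert library_search(mz * (1 + 6e-6), replicates, [entry]) == []

    def test_match_in_fewer_than_three_replicates_rejected(self):
        entry, mz = _pfos_like_library()
        good = spec([(SO3, 90), (FSO3, 55)])
        bad = spec([(412.97, 5)])
        assert library_search(mz, [good, good, bad], [entry]) == []

    def test_no_ms2_gives_empty_result(self):
        entry, mz = _pfos_like_library()
        assert library_search(mz, [], [entry]) == []


class TestSuspectScreen:
    SUSPECT = SuspectEntry(name="O-PFHpS/PFHx-OS", formula=parse_formula("C6HF13SO4"))

    def test_printed_suspect_mass_hits_within_fraction_of_ppm(self):
        hits = suspect_screen(414.9315, [self.SUSPECT])
        assert len(hits) == 1
        assert abs(hits[0].mass_error_ppm) < 0.2

    def test_mass_48ppm_away_rejected(self):
        assert suspect_screen(414.9515, [self.SUSPECT]) == []

    def test_isotope_ratio_within_5_percent_difference_passes(self):
        theor = self.SUSPECT.isotope_ratio
        hits = suspect_screen(414.9315, [self.SUSPECT], observed_isotope_ratio=theor * 1.031)
        assert len(hits) == 1
        assert hits[0].isotope_diff_percent == pytest.approx(3.1, abs=0.05)

    def test_isotope_ratio_off_by_10_percent_rejected(self):
        theor = self.SUSPECT.isotope_ratio
        assert suspect_screen(414.9315, [self.SUSPECT], observed_isotope_ratio=theor * 1.10) == []

    def test_missing_isotope_ratio_skips_criterion(self):
        assert len(suspect_screen(414.9315, [self.SUSPECT], observed_isotope_ratio=None)) == 1

    def test_hit_set_shrinks_as_ppm_tightens(self):
        suspects = [self.SUSPECT,
                    SuspectEntry(name="near", formula=parse_formula("C6HF13SO4"))]
        wide = {h.name for h in suspect_screen(
            414.9315, suspects, criteria=SuspectCriteria(ppm_max=20))}
        narrow = {h.name for h in suspect_screen(
            414.9315, suspects, criteria=SuspectCriteria(ppm_max=0.05))}
        assert narrow <= wide


class TestNeutralLosses:
    def test_propanoate_loss_from_precursor(self):
        s = spec([(397.9527, 100)], precursor=469.9736)
        losses = neutral_losses(s, tol=0.005)
        assert any("C3H4O2" in nl.matches and nl.loss_mass == pytest.approx(72.0209, abs=1e-4)
                   for nl in losses)

    def test_so2_difference_between_fragments(self):
        s = spec([(92.9888, 50), (156.9513, 80)], precursor=475.9310)
        losses = neutral_losses(s, tol=0.005)
        so2 = [nl for nl in losses if "SO2" in nl.matches]
        assert len(so2) == 1
        assert so2[0].loss_mass == pytest.approx(63.9625, abs=1e-4)

    def test_no_table_match_gives_empty_annotations(self):
        s = spec([(123.4567, 10)], precursor=200.0)
        assert neutral_losses(s, tol=0.005) == []


class TestClassifyByFragments:
    def test_sulfonate_fragments_satisfy_pfsa_rule(self):
        s = spec([(SO3, 100), (FSO3, 60)], precursor=498.9302)
        ev = {c.class_label: c for c in classify_by_fragments(s)}
        assert ev["PFSA"].satisfied
        assert "SO3-" in ev["PFSA"].matched_fragments

    def test_no2s_fragment_plus_propanoate_loss_satisfy_fasa_pra_rule(self):
        s = spec([(77.9655, 40), (397.9527, 100)], precursor=469.9736)
        ev = {c.class_label: c for c in classify_by_fragments(s)}
        assert ev["FASA-PrA"].satisfied
        assert ev["FASA-PrA"].matched_losses == ["C3H4O2"]

    def test_sulfuramidous_rule_requires_sulfonate_absence(self):
        with_so3 = spec([(77.9656, 40), (92.9880, 30), (SO3, 10)], precursor=475.9310)
        without = spec([(77.9656, 40), (92.9880, 30)], precursor=475.9310)
        get = lambda s: {c.class_label: c for c in classify_by_fragments(s)}
        assert not get(with_so3)["MeFASA-SA"].satisfied
        assert get(without)["MeFASA-SA"].satisfied

    def test_empty_rule_set_rejected(self):
        with pytest.raises(ValueError):
            classify_by_fragments(spec([(100.0, 1)]), rules=[])


def _evidence(**kw):
    ev = AnnotationEvidence(feature_id="F1")
    for k, v in kw.items():
        setattr(ev, k, v)
    return ev


LIB_HIT = LibraryHit(name="PFOS", score=100, mass_error_ppm=0.1, replicate_count=3,
                     rt_consistent=True)
SUS_HIT = SuspectHit(name="FBSA", mass_error_ppm=0.5, isotope_diff_percent=1.0)


def _class_ok():
    s = spec([(NO2S, 40)], precursor=397.9526)
    return classify_by_fragments(s)


class TestAssignConfidence:
    def test_library_plus_standard_is_1a(self):
        ev = _evidence(library_hits=[LIB_HIT], has_reference_standard_match=True)
        assert assign_confidence(ev) == "1a"

    def test_library_without_standard_is_1b(self):
        assert assign_confidence(_evidence(library_hits=[LIB_HIT])) == "1b"

    def test_diagnostic_fragments_without_standard_is_2a(self):
        ev = _evidence(class_evidence=_class_ok(), suspect_hits=[SUS_HIT])
        assert assign_confidence(ev) == "2a"

    def test_hydrogen_substituted_homologue_with_isomer_ambiguity_is_3a(self):
        ev = _evidence(class_evidence=_class_ok(), suspect_hits=[SUS_HIT],
                       isomer_ambiguity=True)
        assert assign_confidence(ev) == "3a"

    def test_fragmentation_derived_novel_structure_is_3b(self):
        assert assign_confidence(_evidence(class_evidence=_class_ok())) == "3b"

    def test_confirmed_formula_without_structure_is_4(self):
        assert assign_confidence(_evidence(formula_confirmed=True)) == "4"

    def test_suspect_exact_mass_only_is_5a(self):
        assert assign_confidence(_evidence(suspect_hits=[SUS_HIT])) == "5a"

    def test_ambiguous_isomer_pair_with_poor_ms2_is_5b(self):
        ev = _evidence(suspect_hits=[SUS_HIT, dataclasses.replace(SUS_HIT, name="isomer2")],
                       isomer_ambiguity=True)
        assert assign_confidence(ev) == "5b"

    def test_empty_evidence_is_an_error(self):
        with pytest.raises(ValueError):
            assign_confidence(AnnotationEvidence(feature_id="F1"))

    def test_downgrading_evidence_never_raises_level(self):
        """Removing any single evidence item keeps the level equal or lower."""
        rank = {lvl: i for i, lvl in enumerate(CONFIDENCE_LEVELS)}
        full = _evidence(
            library_hits=[LIB_HIT], suspect_hits=[SUS_HIT], class_evidence=_class_ok(),
            has_reference_standard_match=True, formula_confirmed=True,
        )
        weakenings = [
            dict(library_hits=[]),
            dict(suspect_hits=[]),
            dict(class_evidence=[]),
            dict(has_reference_standard_match=False),
            dict(formula_confirmed=False),
        ]
        base = rank[assign_confidence(full)]
        stack = [(full, base)]
        while stack:
            ev, lvl = stack.pop()
            for w in weakenings:
                weaker = dataclasses.replace(ev, **w)
                if weaker.is_empty():
                    continue
                wl = rank[assign_confidence(weaker)]
                # weaker evidence must never yield a stronger level
                assert wl >= lvl
                if wl > lvl:
                    stack.append((weaker, wl))
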