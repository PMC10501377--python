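"""Formula arithmetic, isotope ratios and the CF2 Kendrick transform."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pfasnta.chem import (
    ELEMENTS,
    Formula,
    FormulaError,
    format_formula,
    ion_mz,
    isotope_m1_ratio,
    kendrick,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
    rdb,
)

CF2 = 49.996806


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected,charge",
        [
            ("C9H5F13NO4S", {"C": 9, "H": 5, "F": 13, "N": 1, "O": 4, "S": 1}, 0),
            ("C9H5F13NO4S-", {"C": 9, "H": 5, "F": 13, "N": 1, "O": 4, "S": 1}, -1),
            ("H", {"H": 1}, 0),
            ("C6HF13SO4", {"C": 6, "H": 1, "F": 13, "S": 1, "O": 4}, 0),
            ("C8HClF16O3S", {"C": 8, "H": 1, "Cl": 1, "F": 16, "O": 3, "S": 1}, 0),
        ],
    )
    def test_examples(self, text, expected, charge):
        f = parse_formula(text)
        assert dict(f.counts) == expected
        assert f.charge == charge

    def test_unknown_element_named_in_error(self):
        with pytest.raises(FormulaError, match="Xx"):
            parse_formula("C2Xx3")

    def test_empty_string_rejected(self):
        with pytest.raises(FormulaError):
            parse_formula("   ")

    @given(
        st.dictionaries(
            st.sampled_from(sorted(ELEMENTS)),
            st.integers(min_value=1, max_value=40),
            min_size=1,
            max_size=6,
        ),
        st.sampled_from([0, -1, 1]),
    )
    @settings(max_examples=100, derandomize=True)
    def test_roundtrip_identity(self, counts, charge):
        f = Formula(counts, charge)
        assert parse_formula(format_formula(f)) == f


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "text,mass,tol",
        [
            ("CF2", 49.996806, 1e-6),
            ("C", 12.0, 1e-9),
            ("C3H4O2", 72.0211, 5e-5),  # propanoate-group neutral loss
        ],
    )
    def test_examples(self, text, mass, tol):
        assert monoisotopic_mass(parse_formula(text)) == pytest.approx(mass, abs=tol)

    def test_agrees_with_pyteomics(self):
        """Independent oracle: pyteomics' NIST-based mass calculator."""
        from pyteomics import mass as pmass

        for text in ["C9H5F13NO4S", "C6HF13SO4", "SO3", "C7H3F13NO4S2", "CH4N2O"]:
            ours = monoisotopic_mass(parse_formula(text))
            assert ours == pytest.approx(pmass.calculate_mass(formula=text), abs=2e-5)

    @given(
        st.dictionaries(st.sampled_from(sorted(ELEMENTS)), st.integers(1, 20), min_size=1, max_size=4),
        st.dictionaries(st.sampled_from(sorted(ELEMENTS)), st.integers(1, 20), min_size=1, max_size=4),
    )
    @settings(max_examples=100, derandomize=True)
    def test_additivity(self, c1, c2):
        f1, f2 = Formula(c1), Formula(c2)
        assert monoisotopic_mass(f1 + f2) == pytest.approx(
            monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-9
        )


class TestIonMz:
    def test_ion_as_written_sulfonamido_propanoate(self):
        f = parse_formula("C9H5F13NO4S-")
        assert ion_mz(f, "ion") == pytest.approx(469.9737, abs=5e-4)

    def test_deprotonated_matches_printed_suspect_mass(self):
        assert ion_mz(parse_formula("C6HF13SO4"), "deprotonated") == pytest.approx(
            414.9315, abs=5e-4
        )

    def test_deprotonated_water_is_hydroxide(self):
        assert ion_mz(parse_formula("H2O"), "deprotonated") == pytest.approx(17.0033, abs=5e-4)

    def test_deprotonation_identity(self):
        """[M-H]- m/z = M - m(H) + m(e) for any H-containing neutral."""
        for text in ["C3H4O2", "C9H6F13NO4S", "CH4"]:
            f = parse_formula(text)
            assert ion_mz(f, "deprotonated") == pytest.approx(
                monoisotopic_mass(f) - 1.007825 + 0.000549, abs=1e-6
            )

    def test_deprotonating_hydrogen_free_formula_fails(self):
        with pytest.raises(FormulaError):
            ion_mz(parse_formula("CF2"), "deprotonated")


class TestPpmError:
    def test_examples(self):
        assert ppm_error(469.9736, 469.9737) == pytest.approx(-0.21, abs=0.05)
        assert ppm_error(500.0, 500.0) == 0.0
        assert ppm_error(500.0050, 500.0000) == pytest.approx(10.0, abs=1e-6)

    def test_nonpositive_theoretical_rejected(self):
        with pytest.raises(ValueError):
            ppm_error(500.0, 0.0)


class TestRdb:
    @pytest.mark.parametrize(
        "text,expected",
        [("C9H6F13NO4S", 1.0), ("CH4", 0.0), ("C6H6", 4.0), ("C8HClF16O3S", 0.0),
         ("C4F9SO3", 0.5)],  # half-integral: ionic/radical composition
    )
    def test_examples(self, text, expected):
        assert rdb(parse_formula(text)) == pytest.approx(expected)


def _m1_oracle(f: Formula) -> float:
    """Brute-force isotope-pattern oracle: convolve (q + p x) per atom and
    take the coefficient ratio M+1 / M."""
    poly = np.array([1.0])
    for sym, n in f.counts.items():
        r = ELEMENTS[sym].m1_ratio
        q = 1.0 / (1.0 + r)
        p = 1.0 - q
        for _ in range(n):
            poly = np.convolve(poly, [q, p])
    return poly[1] / poly[0]


class TestIsotopeM1Ratio:
    def test_single_carbon_is_13c_abundance_ratio(self):
        assert isotope_m1_ratio(Formula({"C": 1})) == pytest.approx(0.010816, abs=1e-4)

    def test_fluorine_is_monoisotopic(self):
        assert isotope_m1_ratio(Formula({"F": 13})) == 0.0

    def test_carbon_dominated_formula_scales_with_carbon_count(self):
        f = parse_formula("C9F19")  # fluorine contributes nothing
        assert isotope_m1_ratio(f) == pytest.approx(9 * 0.0108157, rel=1e-4)

    @given(
        st.dictionaries(st.sampled_from(sorted(ELEMENTS)), st.integers(1, 10), min_size=1, max_size=5)
    )
    @settings(max_examples=60, derandomize=True)
    def test_matches_enumeration_oracle(self, counts):
        f = Formula({k: v for k, v in counts.items()})
        if f.n_atoms > 30:
            return
        assert isotope_m1_ratio(f) == pytest.approx(_m1_oracle(f), abs=1e-6)


class TestKendrick:
    def test_pfas_feature_has_small_negative_kmd(self):
        assert kendrick(469.9736).kmd == pytest.approx(-0.0036, abs=5e-4)

    def test_cf2_itself_has_zero_defect(self):
        kv = kendrick(CF2)
        assert kv.kendrick_mass == pytest.approx(50.0, abs=1e-9)
        assert kv.kmd == pytest.approx(0.0, abs=1e-9)

    def test_heavier_homologue(self):
        assert kendrick(575.9227).kmd == pytest.approx(0.0405, abs=5e-4)

    def test_invariant_kmd_equals_nominal_minus_km(self):
        kv = kendrick(414.9315)
        assert kv.kmd == kv.nominal_kendrick_mass - kv.kendrick_mass
        assert abs(kv.kmd) <= 0.5

    @given(st.floats(min_value=50.0, max_value=1000.0), st.integers(1, 10))
    @settings(max_examples=100, derandomize=True)
    def test_cf2_shift_invariance(self, mz, k):
        assert kendrick(mz + k * CF2).kmd == pytest.approx(kendrick(mz).kmd, abs=1e-9)

    def test_nonpositive_mz_rejected(self):
        with pytest.raises(ValueError):
            kendrick(0.0)
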