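"""Formula arithmetic, ion masses, isotope patterns, subformula search."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tpscreen.chem import (
    ELECTRON_MASS,
    M_MINUS_H,
    M_PLUS_H,
    AdductSpec,
    ChlorineEstimate,
    ElementalFormula,
    FormulaError,
    IsotopePattern,
    enumerate_subformulas,
    estimate_chlorine_count,
    ion_mz,
    monoisotopic_mass,
    parse_formula,
    rdbe,
    simulate_isotope_pattern,
)

# independent mass table (NIST monoisotopic values) for oracle sums
ORACLE_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.00307400480,
    "O": 15.99491461956,
    "S": 31.97207100,
    "P": 30.97376163,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Br": 78.91833710,
}
ORACLE_ELECTRON = 0.00054858
ORACLE_PROTON = 1.00727646


def oracle_mass(counts: dict[str, int]) -> float:
    return sum(n * ORACLE_MASS[el] for el, n in counts.items())


formula_strategy = st.fixed_dictionaries(
    {},
    optional={
        el: st.integers(min_value=1, max_value=20) for el in ORACLE_MASS
    },
).filter(bool)


class TestParse:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C8H6O4", {"C": 8, "H": 6, "O": 4}),
            ("C4H4ClN3O", {"C": 4, "H": 4, "Cl": 1, "N": 3, "O": 1}),
            ("H2O", {"H": 2, "O": 1}),
            ("ClBr", {"Cl": 1, "Br": 1}),
        ],
    )
    def test_examples(self, text, expected):
        assert parse_formula(text).element_counts == expected

    @pytest.mark.parametrize("bad", ["", "   ", "C4Xx2", "c8h6", "C-4", "Zz"])
    def test_rejects_bad_input(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    @settings(max_examples=100, deadline=None)
    @given(formula_strategy)
    def test_hill_round_trip(self, counts):
        f = ElementalFormula(counts)
        assert parse_formula(f.hill()) == f


class TestMass:
    def test_water(self):
        assert monoisotopic_mass(parse_formula("H2O")) == pytest.approx(
            18.010565, abs=1e-6
        )

    def test_phthalic_acid(self):
        assert monoisotopic_mass(parse_formula("C8H6O4")) == pytest.approx(
            166.026609, abs=1e-6
        )

    def test_empty_composition_is_zero(self):
        assert monoisotopic_mass(ElementalFormula({})) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(formula_strategy)
    def test_ion_mz_matches_hand_summation(self, counts):
        """Adduct and fragment m/z agree with an independent mass-table
        sum to < 1e-5 Th."""
        f = ElementalFormula(counts)
        assert ion_mz(f, M_PLUS_H) == pytest.approx(
            oracle_mass(counts) + ORACLE_PROTON, abs=1e-5
        )
        assert ion_mz(f, M_MINUS_H) == pytest.approx(
            oracle_mass(counts) - ORACLE_PROTON, abs=1e-5
        )
        assert ion_mz(f, +1) == pytest.approx(
            oracle_mass(counts) - ORACLE_ELECTRON, abs=1e-5
        )
        assert ion_mz(f, -1) == pytest.approx(
            oracle_mass(counts) + ORACLE_ELECTRON, abs=1e-5
        )

    @settings(max_examples=50, deadline=None)
    @given(formula_strategy)
    def test_proton_difference_identity(self, counts):
        f = ElementalFormula(counts)
        assert ion_mz(f, M_PLUS_H) - ion_mz(f, M_MINUS_H) == pytest.approx(
            2 * 1.00727646, abs=1e-6
        )

    def test_adduct_validation(self):
        with pytest.raises(ValueError):
            AdductSpec("[M+2H]2+", "positive", 2, 2)
        with pytest.raises(ValueError):
            AdductSpec("[M+H]+", "negative", 1, 1)
        with pytest.raises(ValueError):
            ion_mz(parse_formula("CH4"), 2)


class TestIsotopePattern:
    def test_one_chlorine_ratio(self):
        pat = simulate_isotope_pattern(parse_formula("C3H2ClN2"))
        assert pat.a2_ratio == pytest.approx(0.32, abs=0.01)

    def test_two_chlorine_ratio(self):
        pat = simulate_isotope_pattern(parse_formula("C8H5Cl2O"))
        assert pat.a2_ratio == pytest.approx(0.64, abs=0.02)

    def test_no_chlorine_tiny_a2(self):
        pat = simulate_isotope_pattern(parse_formula("C5H12"))
        assert pat.a2_ratio < 0.01

    def test_abundances_non_negative_and_monotone_in_cl(self):
        """For a fixed CHNO skeleton, A+2/A rises with chlorine count."""
        ratios = []
        for n_cl in range(4):
            f = ElementalFormula({"C": 10, "H": 12, "N": 2, "O": 2, "Cl": n_cl})
            pat = simulate_isotope_pattern(f)
            assert all(ab >= 0 for _, ab in pat.peaks)
            ratios.append(pat.a2_ratio)
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_invariant_enforcement(self):
        with pytest.raises(ValueError):
            IsotopePattern(((1.0, 1.0),))
        with pytest.raises(ValueError):
            IsotopePattern(((0.0, 1.0), (2.0, -0.1)))


class TestChlorineCount:
    @pytest.mark.parametrize("ratio,expected", [(0.32, 1), (0.64, 2), (0.0, 0)])
    def test_reference_ratios(self, ratio, expected):
        peaks = ((0.0, 1.0), (2.0, ratio)) if ratio else ((0.0, 1.0),)
        assert estimate_chlorine_count(IsotopePattern(peaks)).count == expected

    def test_recovery_on_noiseless_patterns(self):
        """True chlorine count recovered for >= 99% of simulated 0-3 Cl
        patterns over random CHNO skeletons."""
        rng = np.random.default_rng(42)
        total = correct = 0
        for _ in range(100):
            skeleton = {
                "C": int(rng.integers(4, 25)),
                "H": int(rng.integers(4, 30)),
                "N": int(rng.integers(0, 4)),
                "O": int(rng.integers(0, 5)),
            }
            for n_cl in range(4):
                f = ElementalFormula({**skeleton, "Cl": n_cl})
                pat = simulate_isotope_pattern(f)
                est = estimate_chlorine_count(pat)
                total += 1
                correct += est.count == n_cl
        assert correct / total >= 0.99


def brute_force_subformulas(precursor, target_mz, charge, tol_ppm):
    """Independent nested-loop enumeration over the full lattice."""
    els = list(precursor.element_counts)
    out = set()
    for combo in itertools.product(*(range(precursor[el] + 1) for el in els)):
        counts = {el: c for el, c in zip(els, combo) if c}
        if not counts:
            continue
        m = sum(n * ORACLE_MASS[el] for el, n in counts.items())
        mz = m - charge * ORACLE_ELECTRON
        if abs(mz - target_mz) <= target_mz * tol_ppm * 1e-6:
            c = counts.get("C", 0)
            h = counts.get("H", 0) + counts.get("F", 0) + counts.get("Cl", 0) \
                + counts.get("Br", 0)
            n = counts.get("N", 0) + counts.get("P", 0)
            if c - h / 2 + n / 2 + 1 >= -0.5:
                out.add(ElementalFormula(counts))
    return out


class TestSubformulaEnumeration:
    def test_propiconazole_fragment(self):
        subs = enumerate_subformulas(
            parse_formula("C15H18Cl2N3O2"), 87.04406, +1, 5.0
        )
        assert parse_formula("C4H7O2") in subs

    def test_chloridazon_fragment(self):
        subs = enumerate_subformulas(
            parse_formula("C4H5ClN3O"), 100.99010, +1, 5.0
        )
        assert parse_formula("C3H2ClN2") in subs

    def test_target_above_precursor_is_empty(self):
        assert enumerate_subformulas(parse_formula("C4H5ClN3O"), 999.0, +1, 5.0) == []

    @pytest.mark.parametrize(
        "precursor,target",
        [
            ("C15H18Cl2N3O2", 186.97120),
            ("C8H5O4", 121.0295),
            ("C10H14N2O3", 120.0444),
            ("C6H12ClNOS", 100.0),
        ],
    )
    def test_matches_brute_force(self, precursor, target):
        """Pruned lattice search equals exhaustive nested loops."""
        p = parse_formula(precursor)
        charge = -1 if precursor == "C8H5O4" else +1
        ours = set(enumerate_subformulas(p, target, charge, 10.0))
        brute = brute_force_subformulas(p, target, charge, 10.0)
        assert ours == brute

    def test_sorted_by_mass_error(self):
        subs = enumerate_subformulas(parse_formula("C20H30N4O6"), 180.05, +1, 200.0)
        errs = [abs(ion_mz(s, +1) - 180.05) for s in subs]
        assert errs == sorted(errs)
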