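"""Peptide parsing, composition arithmetic, and isotope-pattern engine."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from proteo18.chem import (
    ISOTOPES,
    PROTON_MASS,
    ElementalComposition,
    PeptideParseError,
    RESIDUE_COMPOSITIONS,
    isotope_distribution,
    monoisotopic_mz,
    parse_peptide,
    peptide_composition,
)

SEQUENCES = st.text(
    alphabet=sorted(RESIDUE_COMPOSITIONS), min_size=1, max_size=20
)


def enumerate_isotopologues(counts: dict[str, int]) -> dict[int, tuple[float, float]]:
    """Exhaustive per-atom isotope assignment oracle (small molecules only).

    Returns nominal shift -> (abundance-weighted mean mass, total abundance),
    computed by brute-force enumeration over every atom's isotope choice.
    """
    atoms = [el for el, n in counts.items() for _ in range(n)]
    mono = sum(ISOTOPES[el][0][0] for el in atoms)
    agg: dict[int, tuple[float, float]] = {}
    for combo in itertools.product(*(ISOTOPES[el] for el in atoms)):
        mass = sum(m for m, _ in combo)
        ab = math.prod(a for _, a in combo)
        shift = round(mass - mono)
        mw, a = agg.get(shift, (0.0, 0.0))
        agg[shift] = (mw + ab * mass, a + ab)
    return {s: (mw / a, a) for s, (mw, a) in agg.items() if a > 0}


class TestParsePeptide:
    def test_flanked_form(self):
        pep = parse_peptide("R.YSYLKPR.A")
        assert (pep.prev_aa, pep.sequence, pep.next_aa) == ("R", "YSYLKPR", "A")
        assert str(pep) == "R.YSYLKPR.A"

    def test_bare_sequence_gets_dash_flanks(self):
        pep = parse_peptide("G")
        assert (pep.prev_aa, pep.sequence, pep.next_aa) == ("-", "G", "-")
        assert str(pep) == "G"

    def test_unknown_residue_is_named_with_position(self):
        with pytest.raises(PeptideParseError, match=r"'B' at position 3"):
            parse_peptide("R.YSB LKPR.A")

    def test_lowercase_core_is_uppercased(self):
        assert parse_peptide("r.ysylkpr.a").sequence == "YSYLKPR"

    @given(seq=SEQUENCES)
    def test_serialization_round_trip(self, seq):
        flanked = f"K.{seq}.A"
        assert str(parse_peptide(flanked)) == flanked
        assert str(parse_peptide(seq)) == seq


class TestComposition:
    def test_single_glycine_is_free_glycine(self):
        comp = peptide_composition(parse_peptide("G"), fixed_mods={})
        assert comp.counts == {"C": 2, "H": 5, "N": 1, "O": 2}

    def test_diglycine_shares_one_water(self):
        comp = peptide_composition(parse_peptide("GG"), fixed_mods={})
        assert comp.counts == {"C": 4, "H": 8, "N": 2, "O": 3}

    def test_cysteic_acid_fixed_modification(self):
        comp = peptide_composition(parse_peptide("C"), fixed_mods={"C": {"O": 3}})
        assert comp.counts == {"C": 3, "H": 7, "N": 1, "O": 5, "S": 1}

    def test_addition_commutative_and_elementwise(self):
        a = ElementalComposition({"C": 2, "H": 6})
        b = ElementalComposition({"H": 1, "O": 2, "S": 1})
        assert (a + b).counts == (b + a).counts == {"C": 2, "H": 7, "O": 2, "S": 1}

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ElementalComposition({"C": -1})

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            ElementalComposition({"Xx": 1})


class TestIsotopeDistribution:
    def test_hydrogen_molecule_binomial(self):
        dist = isotope_distribution(ElementalComposition({"H": 2}), 3)
        a_h, a_d = ISOTOPES["H"][0][1], ISOTOPES["H"][1][1]
        expected = (a_h**2, 2 * a_h * a_d, a_d**2)
        assert np.allclose(dist.abundances, expected, rtol=0, atol=1e-12)
        # stated precision of the reference pattern
        assert dist.abundances[0] == pytest.approx(0.9998, abs=5e-5)
        assert dist.abundances[1] == pytest.approx(2.3e-4, abs=1e-6)
        assert dist.abundances[2] == pytest.approx(1.3e-8, abs=5e-10)

    def test_single_carbon_natural_abundances(self):
        dist = isotope_distribution(ElementalComposition({"C": 1}), 2)
        assert dist.abundances == pytest.approx((0.9893, 0.0107), abs=1e-12)

    @pytest.mark.parametrize(
        "counts",
        [
            {"H": 2, "O": 1},
            {"C": 1, "O": 2},
            {"S": 1, "O": 2},
            {"C": 2, "H": 6},
            {"C": 1, "H": 4, "S": 1},
        ],
    )
    def test_matches_exhaustive_enumeration(self, counts):
        oracle = enumerate_isotopologues(counts)
        dist = isotope_distribution(ElementalComposition(counts), 6)
        for i, (mass, ab) in enumerate(zip(dist.masses, dist.abundances)):
            expected_mass, expected_ab = oracle.get(i, (None, 0.0))
            assert ab == pytest.approx(expected_ab, abs=1e-10)
            if expected_mass is not None and expected_ab > 1e-10:
                assert mass == pytest.approx(expected_mass, abs=1e-7)

    def test_first_peak_equals_enumeration_to_machine_precision(self):
        for counts in ({"H": 2}, {"C": 1, "O": 2}, {"S": 2}):
            oracle = enumerate_isotopologues(counts)
            dist = isotope_distribution(ElementalComposition(counts), 1)
            assert dist.abundances[0] == pytest.approx(oracle[0][1], abs=1e-12)

    def test_convolution_associativity(self):
        c1 = ElementalComposition({"C": 3, "H": 5, "N": 1, "O": 1})
        c2 = ElementalComposition({"C": 6, "H": 12, "N": 2, "O": 1, "S": 1})
        d1 = np.array(isotope_distribution(c1, 10).abundances)
        d2 = np.array(isotope_distribution(c2, 10).abundances)
        combined = np.array(isotope_distribution(c1 + c2, 10).abundances)
        assert np.allclose(combined, np.convolve(d1, d2)[:10], atol=1e-9)

    def test_element_insertion_order_irrelevant(self):
        a = isotope_distribution(ElementalComposition({"C": 5, "H": 9, "N": 1, "O": 1}), 6)
        b = isotope_distribution(ElementalComposition({"O": 1, "N": 1, "H": 9, "C": 5}), 6)
        assert a.abundances == b.abundances

    def test_peptide_tail_strictly_decreasing(self):
        comp = peptide_composition(parse_peptide("LGEYGFQNALIVR"), fixed_mods={})
        ab = isotope_distribution(comp, 10).abundances
        peak = int(np.argmax(ab))
        tail = [a for a in ab[peak:] if a > 0]
        assert all(x > y for x, y in zip(tail, tail[1:]))

    def test_masses_strictly_increasing_with_unit_spacing(self):
        comp = peptide_composition(parse_peptide("HLVDEPQNLIK"), fixed_mods={})
        masses = isotope_distribution(comp, 8).masses
        gaps = np.diff(masses)
        assert np.all(gaps >= 1.000) and np.all(gaps <= 1.007)

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError):
            isotope_distribution(ElementalComposition({}), 3)


class TestMonoisotopicMz:
    def test_hydrogen_molecule_singly_protonated(self):
        mz = monoisotopic_mz(ElementalComposition({"H": 2}), 1)
        assert mz == pytest.approx(2 * ISOTOPES["H"][0][0] + PROTON_MASS, abs=1e-9)
        assert mz == pytest.approx(3.0229265, abs=1e-5)

    def test_carbon_doubly_protonated(self):
        mz = monoisotopic_mz(ElementalComposition({"C": 1}), 2)
        assert mz == pytest.approx((12.0 + 2 * PROTON_MASS) / 2, abs=1e-9)

    def test_charge_state_algebra(self):
        comp = peptide_composition(parse_peptide("YLYEIAR"), fixed_mods={})
        mz1 = monoisotopic_mz(comp, 1)
        mz2 = monoisotopic_mz(comp, 2)
        assert mz1 == pytest.approx(2 * mz2 - PROTON_MASS, abs=1e-9)

    def test_zero_charge_rejected(self):
        with pytest.raises(ValueError):
            monoisotopic_mz(ElementalComposition({"C": 1}), 0)
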