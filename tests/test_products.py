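"""Exact masses, stereochemistry counting, footprints, peak matching."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyteomics_mass

from pulserad.products import (
    CH3S,
    Formula,
    PROTON_MASS,
    adduct_mh,
    compound_radicals,
    count_diastereomers,
    dimer_mh,
    enumerate_products,
    match_peaks,
    monoisotopic_mass,
    normalize_footprint,
    parent_formula,
    products_frame,
)


class TestFormula:
    def test_parse_and_str(self):
        f = Formula.parse("C8H16N2O2S")
        assert f.as_dict() == {"C": 8, "H": 16, "N": 2, "O": 2, "S": 1}
        assert str(f) == "C8H16N2O2S"

    def test_addition_and_subtraction(self):
        f = Formula.parse("C2H4O") + Formula.parse("CH2")
        assert f.as_dict() == {"C": 3, "H": 6, "O": 1}
        with pytest.raises(ValueError):
            Formula.parse("CH4") - Formula.parse("C2")

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            Formula.parse("C2Fe")

    def test_empty_formula_mass_zero(self):
        assert monoisotopic_mass(Formula()) == 0.0


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "formula",
        ["C8H16N2O2S", "C7H14N2O2S", "C8H15N2O2S", "C7H13N2O2S", "CH3S", "H2O"],
    )
    def test_agrees_with_independent_oracle(self, formula):
        """Hard-coded isotope table vs the pyteomics mass calculator."""
        ours = monoisotopic_mass(Formula.parse(formula))
        theirs = pyteomics_mass.calculate_mass(formula=formula)
        assert ours == pytest.approx(theirs, abs=1e-4)

    def test_parent_masses(self):
        assert monoisotopic_mass(parent_formula(1)) == pytest.approx(204.0932, abs=5e-4)
        assert monoisotopic_mass(parent_formula(2)) == pytest.approx(190.0776, abs=5e-4)


class TestCouplingMasses:
    def test_isobaric_dimer_mh_compound1(self):
        rads = compound_radicals(1)
        for a, b in itertools.combinations_with_replacement(rads, 2):
            assert dimer_mh(a, b) == pytest.approx(407.1781, abs=5e-4)

    def test_isobaric_dimer_mh_compound2(self):
        rads = compound_radicals(2)
        for a, b in itertools.combinations_with_replacement(rads, 2):
            assert dimer_mh(a, b) == pytest.approx(379.1468, abs=5e-4)

    def test_dimer_mh_symmetric(self):
        a, b = compound_radicals(1)[:2]
        assert dimer_mh(a, b) == dimer_mh(b, a)

    def test_adduct_masses(self):
        assert adduct_mh(compound_radicals(1)[0]) == pytest.approx(251.0883, abs=5e-4)
        assert adduct_mh(compound_radicals(2)[0]) == pytest.approx(237.0726, abs=5e-4)

    def test_cross_parent_coupling_rejected(self):
        with pytest.raises(ValueError):
            dimer_mh(compound_radicals(1)[0], compound_radicals(2)[0])
        with pytest.raises(ValueError):
            dimer_mh(compound_radicals(1)[0], CH3S)

    def test_adduct_minus_dimer_difference_constant(self):
        rads = compound_radicals(1)
        diffs = {round(adduct_mh(r) - dimer_mh(r, r), 6) for r in rads}
        assert len(diffs) == 1


# --- independent brute-force stereochemistry oracle -----------------------
# Enumerates raw configuration strings and merges them by breadth-first
# closure over the allowed identifications (half swap for identical halves,
# global mirror when no fixed centre remains).  Implemented independently
# of the package's canonical-form counter.

def _oracle_count(half_a, half_b, merge_enantiomers):
    def half_cfg(h, new):
        return ("S",) * h.fixed_centers + ((new,) if h.gains_center else ())

    n_new = int(half_a.gains_center) + int(half_b.gains_center)
    raw = []
    for bits in itertools.product("RS", repeat=n_new):
        it = iter(bits)
        a = half_cfg(half_a, next(it) if half_a.gains_center else None)
        b = half_cfg(half_b, next(it) if half_b.gains_center else None)
        raw.append((a, b))

    def neighbours(state):
        a, b = state
        out = []
        if half_a.name == half_b.name:
            out.append((b, a))
        if merge_enantiomers and half_a.fixed_centers + half_b.fixed_centers == 0:
            flip = {"R": "S", "S": "R"}
            out.append(
                (tuple(flip[c] for c in a), tuple(flip[c] for c in b))
            )
        return out

    seen, classes = set(), 0
    for state in raw:
        if state in seen:
            continue
        classes += 1
        frontier = [state]
        while frontier:
            cur = frontier.pop()
            if cur in seen:
                continue
            seen.add(cur)
            frontier.extend(neighbours(cur))
    return classes


class TestDiastereomerCounts:
    @pytest.mark.parametrize(
        "pair,expected",
        [
            (("aS2", "aS2"), 3),  # SSSS, SRSS, SRRS
            (("aS2", "aC1"), 4),
            (("aS2", "aS1"), 2),  # SSS, SRS
            (("aS2", "aC2"), 2),
            (("aS1", "aS1"), 1),
            (("aS1", "aC1"), 2),
            (("aS1", "aC2"), 1),
        ],
    )
    def test_reported_counts(self, pair, expected):
        halves = {h.name: h for h in compound_radicals(1)}
        assert count_diastereomers(halves[pair[0]], halves[pair[1]]) == expected

    def test_as1_containing_products_sum_to_four(self):
        halves = {h.name: h for h in compound_radicals(1)}
        total = sum(
            count_diastereomers(halves["aS1"], halves[o])
            for o in ("aS1", "aC1", "aC2")
        )
        assert total == 4

    def test_raw_configurations_of_as2_homodimer(self):
        """Four raw R/S assignments collapse to three diastereoisomers."""
        halves = {h.name: h for h in compound_radicals(1)}
        a = halves["aS2"]
        assert 2 ** (2 * a.gains_center) == 4
        assert count_diastereomers(a, a) == 3

    def test_ac1_homodimer_enantiomer_merging(self):
        halves = {h.name: h for h in compound_radicals(1)}
        a = halves["aC1"]
        assert count_diastereomers(a, a, merge_enantiomers=True) == 2
        assert count_diastereomers(a, a, merge_enantiomers=False) == 3

    @pytest.mark.parametrize("merge", [True, False])
    @pytest.mark.parametrize("compound", [1, 2])
    def test_matches_brute_force_oracle_for_all_pairs(self, compound, merge):
        rads = compound_radicals(compound, include_thiyl=True)
        for a, b in itertools.combinations_with_replacement(rads, 2):
            assert count_diastereomers(a, b, merge) == _oracle_count(a, b, merge), (
                a.name,
                b.name,
            )

    def test_symmetric_in_arguments(self):
        rads = compound_radicals(1)
        for a, b in itertools.combinations(rads, 2):
            assert count_diastereomers(a, b) == count_diastereomers(b, a)


class TestEnumeration:
    def test_compound1_product_count(self):
        prods = enumerate_products(compound_radicals(1), include_adducts=True)
        assert sum(p.kind == "dimer" for p in prods) == 10  # C(4,2)+4
        assert sum(p.kind == "adduct" for p in prods) == 4

    def test_compound2_product_count(self):
        prods = enumerate_products(compound_radicals(2), include_adducts=True)
        assert sum(p.kind == "dimer" for p in prods) == 6
        assert sum(p.kind == "adduct" for p in prods) == 3

    def test_single_radical_gives_one_homodimer(self):
        prods = enumerate_products(compound_radicals(1)[:1])
        assert len(prods) == 1 and prods[0].homodimer

    def test_all_dimers_share_one_formula(self):
        prods = [p for p in enumerate_products(compound_radicals(1)) if p.kind == "dimer"]
        assert len({str(p.formula) for p in prods}) == 1
        assert max(p.mh for p in prods) - min(p.mh for p in prods) == 0.0

    def test_frame_columns(self):
        frame = products_frame(enumerate_products(compound_radicals(2), True))
        assert list(frame.columns) == [
            "pair", "formula", "mh", "n_diastereomers", "homodimer", "kind",
        ]


class TestFootprint:
    def test_reported_methionine_ratios(self):
        out = normalize_footprint({"aS2": 154.0, "aS1": 94.0, "aC1": 14.0, "aC2": 10.0})
        assert out == pytest.approx({"aS2": 15.4, "aS1": 9.4, "aC1": 1.4, "aC2": 1.0})

    @given(scale=st.floats(1e-3, 1e6))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        base = {"aS2": 72.2, "aS1": 1.0, "aC2": 2.3}
        out = normalize_footprint({k: v * scale for k, v in base.items()})
        for k in base:
            assert out[k] == pytest.approx(base[k], rel=1e-9)

    def test_single_species(self):
        assert normalize_footprint({"aS2": 5.0}) == {"aS2": 1.0}

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            normalize_footprint({"aS2": 0.0})


class TestPeakMatching:
    def test_dimer_peak_matches_all_isobaric_dimers(self):
        prods = enumerate_products(compound_radicals(1), include_adducts=True)
        peaks = pd.DataFrame({"mz": [407.1781], "intensity": [100.0]})
        out = match_peaks(peaks, prods, tol_ppm=5.0)
        assert out.loc[0, "n_matches"] == 10
        assert bool(out.loc[0, "ambiguous"])

    def test_isobaric_adducts_flagged_ambiguous(self):
        """aS1 and aS2 methylthio adducts share one formula."""
        prods = enumerate_products(compound_radicals(2), include_adducts=True)
        mz = adduct_mh(compound_radicals(2)[0])
        out = match_peaks(pd.DataFrame({"mz": [mz], "intensity": [1.0]}), prods, 5.0)
        matched = set(out.loc[0, "matches"])
        assert {"aS2-CH3S", "aS1-CH3S"} <= matched

    def test_far_peak_matches_nothing(self):
        prods = enumerate_products(compound_radicals(1))
        out = match_peaks(pd.DataFrame({"mz": [1000.0], "intensity": [1.0]}), prods, 5.0)
        assert out.loc[0, "n_matches"] == 0

    def test_zero_tolerance_requires_exact_equality(self):
        prods = enumerate_products(compound_radicals(1))
        exact = prods[0].mh
        peaks = pd.DataFrame({"mz": [exact, exact + 1e-9], "intensity": [1.0, 1.0]})
        out = match_peaks(peaks, prods, tol_ppm=0.0)
        assert out.loc[0, "n_matches"] > 0
        assert out.loc[1, "n_matches"] == 0
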