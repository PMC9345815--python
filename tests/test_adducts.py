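"""Formula parsing, monoisotopic masses, adduct m/z and ppm matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiebin.adducts import (
    ADDUCT_RULES,
    IonisationProduct,
    adduct_mz,
    match_products,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
    predict_products,
    rule,
)

# Reference compounds of the standards mix with their printed theoretical
# m/z (4 dp).  p-cresol sulfate is checked with a widened absolute band:
# its printed value reflects a slightly different atomic-mass table.
TABLE_ROWS = [
    ("carnitine", "C7H15NO3", "[M+H]1+", 162.1125),
    ("creatinine", "C4H7N3O", "[M+H]1+", 114.0662),
    ("hydroxyproline betaine", "C7H13NO3", "[M+H]1+", 160.0968),
    ("indoxyl sulfate", "C8H7NO4S", "[M-H]1-", 212.0023),
    ("N-methyl histidine", "C7H11N3O2", "[M+H]1+", 170.0924),
    ("nicotine", "C10H14N2", "[M+H]1+", 163.1230),
    ("proline betaine", "C7H13NO2", "[M+H]1+", 144.1019),
    ("trans-3'-hydroxycotinine", "C10H12N2O2", "[M+H]1+", 193.0972),
    ("trigonelline", "C7H7NO2", "[M+H]1+", 138.0550),
]


class TestParseFormula:
    def test_hill_notation(self):
        assert parse_formula("C7H15NO3") == {"C": 7, "H": 15, "N": 1, "O": 3}

    def test_single_atom(self):
        assert parse_formula("H") == {"H": 1}

    def test_isotope_prefix(self):
        assert parse_formula("[13C]C5H12O6") == {"13C": 1, "C": 5, "H": 12, "O": 6}

    @pytest.mark.parametrize("bad", ["C7H15Xx3", "", "  ", "c7", "C7h15", "C0"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)


class TestMonoisotopicMass:
    def test_carbon_defines_the_scale(self):
        assert monoisotopic_mass("C") == 12.0

    def test_water(self):
        assert monoisotopic_mass("H2O") == pytest.approx(18.010565, abs=5e-7)

    def test_carnitine_neutral(self):
        assert monoisotopic_mass("C7H15NO3") == pytest.approx(161.105193, abs=5e-7)


class TestAdductMz:
    @pytest.mark.parametrize("name, formula, adduct, printed", TABLE_ROWS)
    def test_reference_compounds_to_printed_precision(
        self, name, formula, adduct, printed
    ):
        mz = adduct_mz(monoisotopic_mass(formula), rule(adduct))
        assert round(mz, 4) == pytest.approx(printed, abs=1e-9)

    def test_p_cresol_sulfate_within_one_unit_of_last_place(self):
        mz = adduct_mz(monoisotopic_mass("C7H8O4S"), rule("[M-H]1-"))
        assert mz == pytest.approx(187.0070, abs=1e-4)

    def test_doubly_protonated(self):
        mz = adduct_mz(161.105193, rule("[M+2H]2+"))
        assert round(mz, 5) == pytest.approx(81.55987, abs=1e-9)

    def test_dimer_uses_two_molecules(self):
        M = 100.0
        assert adduct_mz(M, rule("[2M+H]1+")) == pytest.approx(
            2 * M + 1.00727646, abs=1e-6
        )

    def test_chloride_isotope_shift(self):
        M = 200.0
        delta = adduct_mz(M, rule("[M+37Cl]1-")) - adduct_mz(M, rule("[M+Cl]1-"))
        assert delta == pytest.approx(36.9659026 - 34.9688527, abs=1e-6)

    def test_twelve_registered_rules(self):
        assert len(ADDUCT_RULES) == 12
        assert sum(r.polarity == "positive" for r in ADDUCT_RULES) == 6

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            adduct_mz(0.0, rule("[M+H]1+"))


class TestPredictProducts:
    def test_cartesian_product_size(self):
        compounds = [(f"c{i}", "C6H12O6") for i in range(31)]
        assert len(predict_products(compounds)) == 372

    def test_single_rule(self):
        products = predict_products([("glc", "C6H12O6")], rules=[rule("[M+H]1+")])
        assert len(products) == 1
        assert products[0].theoretical_mz == pytest.approx(181.070665, abs=1e-5)

    def test_empty_compounds(self):
        assert predict_products([]) == []

    def test_applicability_predicate_hook(self):
        products = predict_products(
            [("glc", "C6H12O6")],
            applicable=lambda name, comp, r: r.polarity == "negative",
        )
        assert len(products) == 6
        assert all(p.rule.polarity == "negative" for p in products)


class TestPpmError:
    @pytest.mark.parametrize(
        "theoretical, measured, expected",
        [(200.0, 200.0, 0.0), (200.0, 200.0004, 2.0), (100.0, 99.999, -10.0)],
    )
    def test_worked_values(self, theoretical, measured, expected):
        assert ppm_error(theoretical, measured) == pytest.approx(expected, abs=1e-6)

    @given(t=st.floats(50, 1500), d=st.floats(-0.01, 0.01))
    @settings(derandomize=True, max_examples=200)
    def test_antisymmetric_about_reference(self, t, d):
        assert ppm_error(t, t) == 0.0
        assert ppm_error(t, t + d) == pytest.approx(-ppm_error(t, t - d), abs=1e-9)


def bin_table(rows):
    df = pd.DataFrame(
        rows, columns=["bin", "polarity", "accurate_mz", "occupancy", "purity", "centrality"]
    )
    return df.set_index("bin")


def product(mz, polarity="positive", name="x"):
    r = rule("[M+H]1+") if polarity == "positive" else rule("[M-H]1-")
    return IonisationProduct(name, "CH4", r, mz)


class TestMatchProducts:
    table = bin_table(
        [
            ("p162.11", "positive", 162.1121, 1.0, 0.99, 0.5),
            ("p162.12", "positive", 162.1160, 1.0, 0.99, 0.5),
            ("n162.11", "negative", 162.1121, 1.0, 0.99, 0.5),
            ("p133.01", "positive", 133.0141, 0.5, 0.99, 0.5),
        ]
    )

    def test_match_within_tolerance(self):
        out = match_products([product(162.1125)], self.table, tol_ppm=10)
        assert out["bin"].tolist() == ["p162.11"]
        assert out["ppm_error"].iloc[0] == pytest.approx(-2.467, abs=0.01)
        assert bool(out["nearest"].iloc[0])

    def test_beyond_tolerance_not_matched(self):
        # 162.1125 vs 162.1160 is ~21.6 ppm, well past the 10 ppm window
        out = match_products([product(162.1125)], self.table, tol_ppm=10)
        assert "p162.12" not in out["bin"].tolist()

    def test_polarity_gate(self):
        out = match_products([product(162.1121, "negative")], self.table)
        assert out["bin"].tolist() == ["n162.11"]

    def test_occupancy_gate(self):
        out = match_products([product(133.0141)], self.table, occupancy_min=1.0)
        assert out.empty
        out = match_products([product(133.0141)], self.table, occupancy_min=0.5)
        assert out["bin"].tolist() == ["p133.01"]

    def test_zero_tolerance_keeps_exact_coincidences_only(self):
        out = match_products(
            [product(162.1121), product(162.1125)], self.table, tol_ppm=0.0
        )
        assert out["bin"].tolist() == ["p162.11"]
        assert out["theoretical_mz"].tolist() == [162.1121]

    @given(tols=st.tuples(st.floats(0, 30), st.floats(0, 30)))
    @settings(derandomize=True, max_examples=100)
    def test_matches_monotone_in_tolerance(self, tols):
        lo, hi = sorted(tols)
        p = [product(162.1125), product(162.1121, "negative")]
        few = match_products(p, self.table, tol_ppm=lo)
        many = match_products(p, self.table, tol_ppm=hi)
        assert len(many) >= len(few)

    def test_all_qualifying_bins_reported_nearest_flagged(self):
        tbl = bin_table(
            [
                ("p162.11", "positive", 162.1121, 1.0, 0.99, 0.5),
                ("p162.12", "positive", 162.1124, 1.0, 0.99, 0.5),
            ]
        )
        out = match_products([product(162.1125)], tbl, tol_ppm=10)
        assert set(out["bin"]) == {"p162.11", "p162.12"}
        assert out.loc[out["nearest"], "bin"].tolist() == ["p162.12"]
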