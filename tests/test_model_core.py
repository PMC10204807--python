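"""Domain types, structural validation, and model I/O round trips."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from leafcbm.io import (
    ModelFormatError,
    ModelValidationError,
    format_equation,
    load_model,
    parse_equation,
    read_tsv_model,
    save_model,
    write_tsv_model,
)
from leafcbm.model import (
    Metabolite,
    Reaction,
    StoichiometricModel,
    parse_formula,
    validate_model,
)

from conftest import make_model


class TestFormulaParsing:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
            ("CO2", {"C": 1, "O": 2}),
            ("C3.56H5.34N1.1O1.92S0.06",
             {"C": 3.56, "H": 5.34, "N": 1.1, "O": 1.92, "S": 0.06}),
            ("H3N", {"H": 3, "N": 1}),
            ("", {}),
        ],
    )
    def test_parse(self, formula, expected):
        assert parse_formula(formula) == pytest.approx(expected)

    def test_malformed_raises(self):
        with pytest.raises(ValueError):
            parse_formula("6CH12")


class TestEquationStrings:
    @pytest.mark.parametrize(
        "equation, stoich, reversible",
        [
            ("a + 2 b -> c", {"a": -1.0, "b": -2.0, "c": 1.0}, False),
            ("a <-> b", {"a": -1.0, "b": 1.0}, True),
            ("co2_e ->", {"co2_e": -1.0}, False),
            ("0.5 x + y -> 1.5 z", {"x": -0.5, "y": -1.0, "z": 1.5}, False),
        ],
    )
    def test_parse(self, equation, stoich, reversible):
        got, rev = parse_equation(equation)
        assert got == pytest.approx(stoich)
        assert rev is reversible

    def test_no_arrow_raises(self):
        with pytest.raises(ModelFormatError):
            parse_equation("a + b")

    @given(
        coefs=st.lists(
            st.floats(min_value=0.01, max_value=99.0,
                      allow_nan=False, allow_infinity=False),
            min_size=1, max_size=5,
        ),
        reversible=st.booleans(),
    )
    @settings(max_examples=50, deadline=None)
    def test_format_parse_roundtrip(self, coefs, reversible):
        stoich = {f"s{i}": -c for i, c in enumerate(coefs)}
        stoich["prod"] = 1.0
        rxn = Reaction(id="r", stoichiometry=stoich,
                       lower_bound=-10.0 if reversible else 0.0, upper_bound=10.0)
        parsed, rev = parse_equation(format_equation(rxn))
        assert rev is reversible
        assert parsed == pytest.approx(stoich)


class TestValidation:
    def test_clean_toy_model(self, toy_chain):
        assert validate_model(toy_chain) == []

    def test_bound_order_diagnostic(self, toy_chain):
        toy_chain.reactions["R1"].lower_bound = 5.0
        toy_chain.reactions["R1"].upper_bound = 1.0
        diags = validate_model(toy_chain)
        assert [d.rule for d in diags] == ["bound-order"]
        assert diags[0].entity == "R1"

    def test_dangling_metabolite_diagnostic(self, toy_chain):
        toy_chain.reactions["R1"].stoichiometry["ghost"] = 1.0
        diags = validate_model(toy_chain)
        assert any(d.rule == "metabolite-exists" and "ghost" in d.message
                   for d in diags)

    def test_unknown_compartment_diagnostic(self, toy_chain):
        toy_chain.metabolites["A"].compartment = "nowhere"
        assert any(d.rule == "compartment-exists"
                   for d in validate_model(toy_chain))

    def test_exchange_shape_diagnostic(self):
        model = make_model(
            {"EX_bad": ({"a": -1.0, "b": 1.0}, -10, 10),
             "R": ({"a": 1.0, "b": -1.0}, -10, 10)},
        )
        assert any(d.rule == "exchange-shape" for d in validate_model(model))

    def test_carbon_imbalance_reported_with_element(self):
        # glucose -> 1 CO2: five carbons vanish (hand count: 6 vs 1)
        model = make_model(
            {"BAD": ({"glc": -1.0, "co2": 1.0}, 0, 10)},
            formulas={"glc": "C6H12O6", "co2": "CO2"},
        )
        diags = validate_model(model)
        assert any(d.rule == "element-balance" and "C" in d.message
                   for d in diags)
        # imbalance magnitude is the net atom count
        assert any("-5" in d.message for d in diags)

    def test_objective_reference_diagnostic(self, toy_chain):
        toy_chain.objective["missing"] = 1.0
        assert any(d.rule == "objective-reference"
                   for d in validate_model(toy_chain))


class TestTsvIO:
    def test_three_reaction_roundtrip(self, toy_chain, tmp_path):
        path = tmp_path / "toy.tsv"
        write_tsv_model(toy_chain, path)
        loaded = read_tsv_model(path)
        assert set(loaded.reactions) == set(toy_chain.reactions)
        assert validate_model(loaded) == []

    def test_roundtrip_bit_exact(self, leaf_model, tmp_path):
        """TSV write -> read -> write reproduces the file byte for byte."""
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_tsv_model(leaf_model, p1)
        write_tsv_model(read_tsv_model(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_roundtrip_preserves_structure(self, leaf_model, tmp_path):
        path = tmp_path / "leaf.tsv"
        write_tsv_model(leaf_model, path)
        loaded = read_tsv_model(path)
        assert len(loaded.metabolites) == len(leaf_model.metabolites)
        assert len(loaded.reactions) == len(leaf_model.reactions)
        for rid, rxn in leaf_model.reactions.items():
            other = loaded.reactions[rid]
            assert other.stoichiometry == rxn.stoichiometry  # bit-exact floats
            assert other.lower_bound == rxn.lower_bound
            assert other.upper_bound == rxn.upper_bound
            assert other.gpr == rxn.gpr
            assert other.pathway == rxn.pathway
        assert loaded.objective == leaf_model.objective

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "nope.tsv")

    def test_parse_error_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("!reactions\nheader\nr1\tname\tno arrow here\t\t\n")
        with pytest.raises(ModelFormatError, match="line 3"):
            read_tsv_model(path)

    def test_dangling_reference_fails_validation(self, tmp_path):
        path = tmp_path / "dangling.tsv"
        path.write_text(
            "!model\tx\tx\te\n"
            "!compartments\nid\tname\nc\tcytosol\n"
            "!metabolites\nid\tname\tcompartment\tformula\tboundary\tannotations\n"
            "a\t\tc\t\t0\t\n"
            "!reactions\nid\tname\tequation\tlb\tub\tgpr\tpathway\tec\tannotations\n"
            "r1\t\ta -> ghost\t0\t10\t\t\t\t\n"
        )
        with pytest.raises(ModelValidationError) as err:
            load_model(path)
        assert "ghost" in str(err.value)


class TestSbmlIO:
    def test_roundtrip_numeric_tolerance(self, leaf_model, tmp_path):
        path = tmp_path / "leaf.xml"
        save_model(leaf_model, path, format="sbml")
        loaded = load_model(path, format="sbml")
        assert len(loaded.metabolites) == len(leaf_model.metabolites)
        assert len(loaded.reactions) == len(leaf_model.reactions)
        for rid, rxn in leaf_model.reactions.items():
            other = loaded.reactions[rid]
            assert other.lower_bound == pytest.approx(rxn.lower_bound, abs=1e-9)
            assert other.upper_bound == pytest.approx(rxn.upper_bound, abs=1e-9)
            for met, coef in rxn.stoichiometry.items():
                assert other.stoichiometry[met] == pytest.approx(coef, abs=1e-9)
        assert loaded.objective == {"BIOMASS_leaf": 1.0}
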