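"""Unit tests for compounds, formulas, signatures, rules, and reaction strings."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retrostoic.chem_core import (
    BalanceReport,
    Compound,
    FormulaParseError,
    MoietySignature,
    Reaction,
    ReactionParseError,
    CompoundLookupError,
    RuleInapplicableError,
    SignatureUnavailableError,
    StructureError,
    apply_rule,
    check_reaction_balance,
    format_formula,
    format_reaction_string,
    moiety_signature,
    parse_formula,
    parse_reaction_string,
    reaction_rule,
    rule_id_for,
    signature_formula,
)


# ---------------------------------------------------------------------------
# Formulas

@pytest.mark.parametrize(
    "text, expected",
    [
        ("C9H11NO3", {"C": 9, "H": 11, "N": 1, "O": 3}),
        ("H", {"H": 1}),
        ("C21H27N7O14P2", {"C": 21, "H": 27, "N": 7, "O": 14, "P": 2}),
        ("NH4", {"N": 1, "H": 4}),
        ("HO4P", {"H": 1, "O": 4, "P": 1}),
        ("CHCl3", {"C": 1, "H": 1, "Cl": 3}),
    ],
)
def test_parse_formula(text, expected):
    assert parse_formula(text) == expected


@pytest.mark.parametrize("bad", ["", "C9Qq2", "H0", "C-3", "*"])
def test_parse_formula_rejects_malformed(bad):
    with pytest.raises(FormulaParseError):
        parse_formula(bad)


def test_parse_formula_error_names_position():
    with pytest.raises(FormulaParseError) as err:
        parse_formula("C6H12Zz")
    assert err.value.pos == 5


def test_wildcard_formula_needs_flag():
    with pytest.raises(FormulaParseError):
        parse_formula("RC6H5")
    assert parse_formula("RC6H5", allow_wildcards=True) == {"R": 1, "C": 6, "H": 5}


@given(
    st.dictionaries(
        st.sampled_from(["C", "H", "N", "O", "P", "S", "Cl", "Fe", "Mg"]),
        st.integers(min_value=1, max_value=40),
        min_size=1,
        max_size=6,
    )
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_formula_roundtrip(counts):
    assert parse_formula(format_formula(counts)) == counts


# ---------------------------------------------------------------------------
# Compounds and reactions

def test_compound_invariants():
    with pytest.raises(ValueError):
        Compound(id="empty", formula={})
    proton = Compound(id="h", formula={"H": 1}, charge=1)
    assert proton.formula == {"H": 1}
    generic = Compound(id="gen", formula={"R": 1, "O": 1}, is_generic=True)
    assert generic.is_generic
    # wildcard in formula auto-flags generic
    assert Compound(id="gen2", formula={"R": 1, "C": 2}).is_generic


def test_reaction_invariants():
    with pytest.raises(ValueError):
        Reaction(id="onesided", stoich={"a": Fraction(-1)})
    with pytest.raises(ValueError):
        Reaction(id="netzero", stoich={"a": Fraction(0)})
    r = Reaction(id="ok", stoich={"a": Fraction(-1), "b": Fraction(2), "c": 0})
    assert "c" not in r.stoich  # zero coefficients are dropped


def test_balance_eq2_species(demo):
    """The printed overall conversion of the cofactor-free route closes exactly."""
    rxn = Reaction(
        id="eq2",
        stoich={
            "tyr": -1, "h": -1, "h2o2": -1,
            "hxt": 1, "nh4": 1, "co2": 1,
        },
    )
    report = check_reaction_balance(rxn, demo.compounds)
    assert report.balanced and bool(report)


def test_balance_residuals_tyr_to_hxt(demo):
    rxn = Reaction(id="raw", stoich={"tyr": -1, "hxt": 1})
    report = check_reaction_balance(rxn, demo.compounds)
    assert not report.balanced
    assert report.element_residuals == {"C": -1, "H": -1, "N": -1}
    assert report.charge_residual == 0


def test_balance_identity_and_lookup_error(demo):
    twin = dict(demo.compounds)
    twin["tyr2"] = Compound(id="tyr2", formula=demo.compounds["tyr"].formula)
    rxn = Reaction(id="iso", stoich={"tyr": -1, "tyr2": 1})
    assert check_reaction_balance(rxn, twin).balanced
    with pytest.raises(CompoundLookupError):
        check_reaction_balance(
            Reaction(id="bad", stoich={"tyr": -1, "nope": 1}), demo.compounds
        )


# ---------------------------------------------------------------------------
# Moiety signatures

WATER = Compound(id="w", formula={"O": 1, "H": 2}, smiles="O")
METHANE = Compound(id="m", formula={"C": 1, "H": 4}, smiles="C")
ETHANOL = Compound(id="eth", formula=parse_formula("C2H6O"), smiles="CCO")
ETHANAL = Compound(id="etl", formula=parse_formula("C2H4O"), smiles="CC=O")
PROPANOL = Compound(id="pol", formula=parse_formula("C3H8O"), smiles="CCCO")
PROPANAL = Compound(id="pal", formula=parse_formula("C3H6O"), smiles="CCC=O")


@pytest.mark.parametrize(
    "compound, expected",
    [
        (WATER, {"O;H2;()": 1}),
        (METHANE, {"C;H4;()": 1}),
        (ETHANOL, {"C;H3;(C1)": 1, "C;H2;(C1,O1)": 1, "O;H1;(C1)": 1}),
        (ETHANAL, {"C;H3;(C1)": 1, "C;H1;(C1,O2)": 1, "O;(C2)": 1}),
    ],
)
def test_moiety_signature_radius1(compound, expected):
    assert dict(moiety_signature(compound, radius=1).counts) == expected


def test_signature_errors():
    with pytest.raises(SignatureUnavailableError):
        moiety_signature(Compound(id="nostruct", formula={"C": 1, "H": 4}))
    with pytest.raises(StructureError):
        moiety_signature(
            Compound(id="badsmiles", formula={"C": 1}, smiles="c1cc")
        )


@pytest.mark.parametrize("radius", [1, 2])
def test_signature_reconstructs_formula(demo, radius):
    """Center-atom contributions of a signature reproduce the full formula."""
    for cid in ["tyr", "tyramine", "dopamine", "hpaa4", "tyrosol", "hxt"]:
        sig = moiety_signature(demo.compounds[cid], radius=radius)
        assert signature_formula(sig.counts) == dict(demo.compounds[cid].formula)


def test_radius2_distinguishes_positional_isomers():
    """m-/p-cresol share a radius-1 signature but split at radius 2."""
    para = Compound(id="pcresol", formula=parse_formula("C7H8O"), smiles="Cc1ccc(O)cc1")
    meta = Compound(id="mcresol", formula=parse_formula("C7H8O"), smiles="Cc1cccc(O)c1")
    assert moiety_signature(para, 1).counts == moiety_signature(meta, 1).counts
    assert moiety_signature(para, 2).counts != moiety_signature(meta, 2).counts


def test_aromatic_bonds_have_distinct_order_token(demo):
    sig = moiety_signature(demo.compounds["tyr"])
    assert any(";(Ca,Ca)" in key or "Ca" in key for key in sig.counts)


# ---------------------------------------------------------------------------
# Reaction rules

CURRENCY = {"nad", "nadh", "h"}
INDEX = {c.id: c for c in [ETHANOL, ETHANAL, PROPANOL, PROPANAL]}


def _dehydrogenation(sub, prod, rid):
    return Reaction(
        id=rid,
        stoich={sub: Fraction(-1), "nad": Fraction(-1), prod: Fraction(1),
                "nadh": Fraction(1), "h": Fraction(1)},
    )


def test_rule_delta_and_dedup():
    r1 = reaction_rule(_dehydrogenation("eth", "etl", "dh1"), INDEX, CURRENCY)
    assert r1.delta == {
        "C;H2;(C1,O1)": -1, "O;H1;(C1)": -1,
        "C;H1;(C1,O2)": 1, "O;(C2)": 1,
    }
    r2 = reaction_rule(_dehydrogenation("pol", "pal", "dh2"), INDEX, CURRENCY)
    assert r2.delta == r1.delta and r2.id == r1.id
    assert rule_id_for(r1.delta) == r1.id


def test_identity_reaction_gives_empty_rule():
    twin = Compound(id="eth2", formula=ETHANOL.formula, smiles="CCO")
    index = {**INDEX, "eth2": twin}
    rxn = Reaction(id="iso", stoich={"eth": Fraction(-1), "eth2": Fraction(1)})
    rule = reaction_rule(rxn, index, CURRENCY)
    assert rule.delta == {}


def test_rule_extraction_reports_missing_signature():
    from retrostoic.chem_core import RuleExtractionError

    structureless = Compound(id="mystery", formula={"C": 2, "H": 6, "O": 1})
    index = {**INDEX, "mystery": structureless}
    rxn = Reaction(id="bad", stoich={"mystery": Fraction(-1), "etl": Fraction(1)})
    with pytest.raises(RuleExtractionError, match="mystery"):
        reaction_rule(rxn, index, CURRENCY)


def test_apply_rule_roundtrip_and_guards():
    rule = reaction_rule(_dehydrogenation("eth", "etl", "dh1"), INDEX, CURRENCY)
    pool = dict(moiety_signature(ETHANOL).counts)
    assert apply_rule(pool, rule) == dict(moiety_signature(ETHANAL).counts)
    empty_rule = reaction_rule(
        Reaction(id="iso", stoich={"eth": Fraction(-1), "eth2": Fraction(1)}),
        {**INDEX, "eth2": Compound(id="eth2", formula=ETHANOL.formula, smiles="CCO")},
        CURRENCY,
    )
    assert apply_rule(pool, empty_rule) == pool
    with pytest.raises(RuleInapplicableError) as err:
        apply_rule(dict(moiety_signature(METHANE).counts), rule)
    assert err.value.key == "C;H2;(C1,O1)"


# ---------------------------------------------------------------------------
# Reaction strings

def test_parse_reaction_string_basic():
    stoich, direction = parse_reaction_string("1 A + 2 B <=> 1 C")
    assert stoich == {"A": Fraction(-1), "B": Fraction(-2), "C": Fraction(1)}
    assert direction == "bidirectional"


@pytest.mark.parametrize(
    "text",
    ["1 A + 2 B <=> 1 C", "1 glc => 2 etoh + 2 co2", "1 x <= 1 y + 3 h2o"],
)
def test_reaction_string_roundtrip(text):
    stoich, direction = parse_reaction_string(text)
    canonical = format_reaction_string(stoich, direction)
    assert parse_reaction_string(canonical) == (stoich, direction)
    assert format_reaction_string(*parse_reaction_string(canonical)) == canonical


def test_parse_reaction_string_directions():
    assert parse_reaction_string("A => B")[1] == "forward"
    assert parse_reaction_string("A <= B")[1] == "reverse"


@pytest.mark.parametrize(
    "bad",
    ["A <=>", "A + B", "1 A + 1 A <=> 2 B", "A <=> 1 2 B", "x A <=> B"],
)
def test_parse_reaction_string_rejects(bad):
    with pytest.raises(ReactionParseError):
        parse_reaction_string(bad)


def test_fractional_coefficients():
    stoich, _ = parse_reaction_string("1/2 o2 + 1 c => 1 co")
    assert stoich["o2"] == Fraction(-1, 2)  # consumed
    assert stoich["co"] == Fraction(1)
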