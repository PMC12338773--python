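"""Pathway search tests: planted recovery, demo routes, oracles, validation."""

from collections import Counter
from fractions import Fraction

import pytest

from retrostoic.fixtures import ToyNetworkSpec, make_toy_network
from retrostoic.pathway_design import (
    HypotheticalCompound,
    Pathway,
    PathwayStep,
    design_pathways,
    resolve_intermediate,
    validate_pathway,
)

from conftest import dfs_pathway_multisets


def _multisets(pathways):
    return {
        frozenset(Counter((s.ref_id, s.direction) for s in p.steps).items())
        for p in pathways
    }


# ---------------------------------------------------------------------------
# Toy networks

def test_planted_two_step_pathway_recovered():
    net = make_toy_network(
        ToyNetworkSpec(n_compounds=4, n_reactions=2, planted_path_length=2,
                       n_decoys=0, seed=5)
    )
    pws = design_pathways(
        net.planted_overall, net.reactions, {}, net.compounds,
        signatures=net.signatures, currency=net.currency,
        max_steps=2, max_novel=0, n_pathways=5, seed=0,
    )
    assert len(pws) == 1
    assert [s.ref_id for s in pws[0].steps] == ["RP0", "RP1"]
    assert validate_pathway(pws[0], net.compounds, net.currency).ok


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_search_equals_dfs_oracle_on_toys(seed):
    """The MILP's step multisets equal exhaustive DFS enumeration."""
    net = make_toy_network(
        ToyNetworkSpec(n_compounds=8, n_reactions=6, planted_path_length=3,
                       n_decoys=3, seed=seed)
    )
    found = design_pathways(
        net.planted_overall, net.reactions, {}, net.compounds,
        signatures=net.signatures, currency=net.currency,
        max_steps=4, max_novel=0, n_pathways=50, seed=seed,
    )
    oracle = dfs_pathway_multisets(
        net.reactions, net.compounds, net.planted_overall, net.currency,
        max_steps=4,
    )
    assert _multisets(found) == oracle
    assert any(
        [s.ref_id for s in p.steps] == [s.ref_id for s in net.planted_pathway.steps]
        for p in found
    )


@pytest.mark.parametrize("seed", [0, 2])
def test_monotonicity_in_max_steps(seed):
    """Raising the step limit never loses previously feasible pathways."""
    net = make_toy_network(
        ToyNetworkSpec(n_compounds=8, n_reactions=6, planted_path_length=3,
                       n_decoys=3, seed=seed)
    )
    kwargs = dict(
        signatures=net.signatures, currency=net.currency,
        max_novel=0, n_pathways=50, seed=0,
    )
    at_3 = design_pathways(
        net.planted_overall, net.reactions, {}, net.compounds,
        max_steps=3, **kwargs,
    )
    at_4 = design_pathways(
        net.planted_overall, net.reactions, {}, net.compounds,
        max_steps=4, **kwargs,
    )
    assert _multisets(at_3) <= _multisets(at_4)


def test_infeasible_limits_give_empty_list_with_diagnostic():
    net = make_toy_network(
        ToyNetworkSpec(n_compounds=5, n_reactions=3, planted_path_length=3,
                       n_decoys=0, seed=1)
    )
    pws = design_pathways(
        net.planted_overall, net.reactions, {}, net.compounds,
        signatures=net.signatures, currency=net.currency,
        max_steps=2, max_novel=0, n_pathways=5, seed=0,
    )
    assert pws == []


# ---------------------------------------------------------------------------
# Demo network

def test_demo_moiety_conservation(demo):
    """Every returned pathway's signature deltas sum to the overall requirement."""
    pws = design_pathways(
        demo.overall_eq2, demo.reactions, demo.rules, demo.compounds,
        signatures=demo.signatures, currency=demo.currency,
        max_steps=5, max_novel=2, n_pathways=10, seed=0,
    )
    assert pws
    req = Counter()
    for cid, coeff in demo.overall_eq2.coeffs.items():
        if cid in demo.currency:
            continue
        for k, n in demo.signatures[cid].counts.items():
            req[k] += int(coeff) * n
    for p in pws:
        total = Counter()
        for step in p.steps:
            for cid, coeff in step.stoich.items():
                if cid in demo.currency:
                    continue
                sig = demo.signatures.get(cid) or p.hypotheticals[cid].signature
                for k, n in sig.counts.items():
                    total[k] += int(coeff) * n
        assert +total == +req and -total == -req


def test_demo_known_and_bypass_routes(demo):
    """The four-step cataloged route and the one-step bypass both surface."""
    pws = design_pathways(
        demo.overall_eq1, demo.reactions, demo.rules, demo.compounds,
        signatures=demo.signatures, currency=demo.currency,
        max_steps=5, max_novel=2, n_pathways=10, seed=0,
    )
    multis = _multisets(pws)
    known = frozenset(
        Counter(
            [("R_TDC", 1), ("R_TYO", 1), ("R_ALDR", 1), ("R_HPAH", 1)]
        ).items()
    )
    bypass = frozenset(
        Counter(
            [(demo.rule_bypass_id, 1), ("R_ALDR", 1), ("R_HPAH", 1)]
        ).items()
    )
    assert known in multis
    assert bypass in multis
    bypass_pw = next(p for p in pws if _multisets([p]) == {bypass})
    step5 = bypass_pw.steps[0]
    assert step5.kind == "novel" and step5.substrate == "tyr" and step5.product == "hpaa4"
    # the bypass step folds decarboxylation + oxidative deamination into one
    assert step5.stoich["co2"] == 1 and step5.stoich["nh4"] == 1


def test_demo_results_deterministic_across_seeds(demo):
    runs = [
        design_pathways(
            demo.overall_eq2, demo.reactions, demo.rules, demo.compounds,
            signatures=demo.signatures, currency=demo.currency,
            max_steps=5, max_novel=2, n_pathways=10, seed=seed,
        )
        for seed in (0, 7)
    ]
    shapes = [
        [
            (len(p.steps), p.n_novel, tuple(s.ref_id for s in p.steps))
            for p in run
        ]
        for run in runs
    ]
    assert shapes[0] == shapes[1]


def test_max_novel_zero_excludes_rule_steps(demo):
    pws = design_pathways(
        demo.overall_eq1, demo.reactions, demo.rules, demo.compounds,
        signatures=demo.signatures, currency=demo.currency,
        max_steps=5, max_novel=0, n_pathways=10, seed=0,
    )
    assert pws
    assert all(p.n_novel == 0 for p in pws)


# ---------------------------------------------------------------------------
# Validation

def test_validate_reference_pathways(demo):
    assert validate_pathway(demo.known_pathway, demo.compounds, demo.currency).ok
    report = validate_pathway(demo.fig8_pathway, demo.compounds, demo.currency)
    assert report.ok and not report.failures


def test_validate_detects_ordering_failure(demo):
    swapped = Pathway(
        steps=[demo.known_pathway.steps[1], demo.known_pathway.steps[0],
               *demo.known_pathway.steps[2:]],
        overall=demo.known_pathway.overall,
        n_novel=0,
    )
    report = validate_pathway(swapped, demo.compounds, demo.currency)
    assert not report.ok
    assert any("before it is produced" in f for f in report.failures)


def test_validate_detects_sum_mismatch(demo):
    truncated = Pathway(
        steps=demo.known_pathway.steps[:3],
        overall=demo.known_pathway.overall,
        n_novel=0,
    )
    report = validate_pathway(truncated, demo.compounds, demo.currency)
    assert any("step sum" in f for f in report.failures)


def test_validate_rejects_empty_pathway(demo):
    with pytest.raises(ValueError):
        validate_pathway(
            Pathway(steps=[], overall=demo.overall_eq2, n_novel=0),
            demo.compounds, demo.currency,
        )


# ---------------------------------------------------------------------------
# Intermediate resolution

def test_resolve_known_compound(demo):
    out = resolve_intermediate(
        dict(demo.signatures["dopamine"].counts), demo.compounds, demo.signatures
    )
    assert out == ["dopamine"]


def test_resolve_unseen_gives_hypothetical_with_formula(demo):
    counts = dict(demo.signatures["dopamine"].counts)
    counts["C;H3;(C1)"] = counts.get("C;H3;(C1)", 0) + 1  # graft a methyl
    out = resolve_intermediate(counts, demo.compounds, demo.signatures)
    assert isinstance(out, HypotheticalCompound)
    assert out.formula["C"] == 9  # dopamine C8 + 1
    assert out.id.startswith("NOVEL_")


def test_resolve_ambiguous_isomers():
    from retrostoic.chem_core import Compound, moiety_signature, parse_formula

    para = Compound(id="pcresol", formula=parse_formula("C7H8O"), smiles="Cc1ccc(O)cc1")
    meta = Compound(id="mcresol", formula=parse_formula("C7H8O"), smiles="Cc1cccc(O)c1")
    compounds = {"pcresol": para, "mcresol": meta}
    sigs = {cid: moiety_signature(c, 1) for cid, c in compounds.items()}
    out = resolve_intermediate(dict(sigs["pcresol"].counts), compounds, sigs)
    assert out == ["mcresol", "pcresol"]  # radius-1 degenerate pair

    with pytest.raises(ValueError):
        resolve_intermediate({"C;H4;()": -1}, compounds, sigs)
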