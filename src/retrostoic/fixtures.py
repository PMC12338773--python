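"""Packaged synthetic fixtures: the hydroxytyrosol demo network and random toys.

``make_hxt_demo`` builds a small curated database around the biosynthesis
of hydroxytyrosol (HXT) from L-tyrosine: the four-step known route
(tyrosine decarboxylase EC 4.1.1.25; tyramine:oxygen oxidoreductase;
aldehyde dehydrogenase; 4-hydroxyphenylacetate 3-monooxygenase acting on
tyrosol) plus three reaction rules enabling shorter novel routes — a
one-step bypass of decarboxylation+oxidation (rule derived from
MNXR121797, an indolyl-alkane hydroxylase), a peroxide-driven ring
hydroxylation (EC 1.11.2.5 pattern, tyramine → dopamine), and an
amine→hydroxyl replacement (rule shared with MNXR102311,
aminodeoxychorismate synthase; dopamine → HXT).  The demo is a synthetic
reconstruction: intermediate structures are encoded from their standard
formulas/SMILES and rule deltas are computed from the named
transformations on the demo compounds.  Both reference overall conversions
are included:

    Eq-1 route:  Tyr + 2 NADH + 3 H+ + 2 O2 -> HXT + NH4+ + CO2 + H2O2 + 2 NAD+
    Eq-2 route:  Tyr + H+ + H2O2 -> HXT + NH4+ + CO2

``make_toy_network`` plants a linear pathway inside a randomly decorated
balanced reaction network, for oracle tests of the pathway search.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import numpy as np

from .chem_core import (
    Compound,
    MoietySignature,
    Reaction,
    ReactionRule,
    check_reaction_balance,
    moiety_signature,
    parse_formula,
    rule_id_for,
    signature_formula,
)
from .enzyme_select import EnzymeCandidate
from .pathway_design import Pathway, PathwayStep, build_signature_index
from .stoich_opt import CoMetaboliteSpec, OverallStoichiometry

__all__ = [
    "ToyNetworkSpec",
    "ToyNetwork",
    "HxtDemo",
    "GenerationError",
    "make_toy_network",
    "make_hxt_demo",
    "DEMO_CURRENCY",
    "TOY_CURRENCY",
]

#: Currency species of the demo network (proton, water, small inorganics,
#: and the NAD(H) redox couple); excluded from rule extraction and
#: pathway ordering.
DEMO_CURRENCY = frozenset(
    {"h", "h2o", "o2", "h2o2", "nh4", "co2", "nadh", "nad"}
)

#: Toy networks balance formula differences with CO2/H2O/H2 only.
TOY_CURRENCY = frozenset({"co2", "h2o", "h2"})


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Hydroxytyrosol demo

@dataclass
class HxtDemo:
    compounds: dict[str, Compound]
    reactions: dict[str, Reaction]
    rules: dict[str, ReactionRule]
    signatures: dict[str, MoietySignature]
    currency: frozenset[str]
    overall_eq1: OverallStoichiometry
    overall_eq2: OverallStoichiometry
    known_pathway: Pathway
    fig8_pathway: Pathway
    inclusive_cospec: CoMetaboliteSpec
    candidates: list[EnzymeCandidate]
    training: list[tuple[dict[str, int], float]]
    rule_bypass_id: str = ""
    rule_r2_id: str = ""
    rule_r3_id: str = ""


def _cpd(cid, name, formula, charge=0, smiles=None, kegg=None):
    return Compound(
        id=cid,
        name=name,
        formula=parse_formula(formula),
        charge=charge,
        smiles=smiles,
        xrefs={"kegg": kegg} if kegg else {},
    )


def _delta_between(sig_a: MoietySignature, sig_b: MoietySignature) -> dict[str, int]:
    """Signed difference b - a of two signatures."""
    delta = Counter(dict(sig_b.counts))
    delta.subtract(dict(sig_a.counts))
    return {k: v for k, v in delta.items() if v}


def make_hxt_demo() -> HxtDemo:
    """The packaged hydroxytyrosol mini-network (synthetic reconstruction)."""
    compounds = {
        c.id: c
        for c in [
            _cpd("tyr", "L-tyrosine", "C9H11NO3", 0,
                 "NC(Cc1ccc(O)cc1)C(=O)O", kegg="C00082"),
            _cpd("tyramine", "tyramine", "C8H11NO", 0,
                 "NCCc1ccc(O)cc1", kegg="C00483"),
            _cpd("hpaa4", "4-hydroxyphenylacetaldehyde", "C8H8O2", 0,
                 "O=CCc1ccc(O)cc1", kegg="C03765"),
            _cpd("tyrosol", "tyrosol", "C8H10O2", 0,
                 "OCCc1ccc(O)cc1", kegg="C06044"),
            _cpd("dopamine", "dopamine", "C8H11NO2", 0,
                 "NCCc1ccc(O)c(O)c1", kegg="C03758"),
            _cpd("hxt", "hydroxytyrosol", "C8H10O3", 0,
                 "OCCc1ccc(O)c(O)c1", kegg="C50000"),
            # currency species (structureless entries handled by formula)
            _cpd("h", "proton", "H", 1),
            _cpd("h2o", "water", "H2O", 0),
            _cpd("o2", "dioxygen", "O2", 0),
            _cpd("h2o2", "hydrogen peroxide", "H2O2", 0),
            _cpd("nh4", "ammonium", "NH4", 1),
            _cpd("co2", "carbon dioxide", "CO2", 0),
            _cpd("nadh", "NADH", "C21H27N7O14P2", -2),
            _cpd("nad", "NAD+", "C21H26N7O14P2", -1),
        ]
    }

    F = Fraction
    reactions = {
        r.id: r
        for r in [
            # step 1: tyrosine decarboxylase
            Reaction(
                id="R_TDC",
                stoich={"tyr": F(-1), "tyramine": F(1), "co2": F(1)},
                ec_numbers=["4.1.1.25"],
                direction="forward",
            ),
            # step 2: tyramine:oxygen oxidoreductase (oxidative deamination)
            Reaction(
                id="R_TYO",
                stoich={
                    "tyramine": F(-1), "o2": F(-1), "h2o": F(-1), "h": F(-1),
                    "hpaa4": F(1), "nh4": F(1), "h2o2": F(1),
                },
                ec_numbers=["1.4.3.4"],
                direction="forward",
            ),
            # step 3: aldehyde reduction to tyrosol (NADH-dependent)
            Reaction(
                id="R_ALDR",
                stoich={
                    "hpaa4": F(-1), "nadh": F(-1), "h": F(-1),
                    "tyrosol": F(1), "nad": F(1),
                },
                ec_numbers=["1.1.1.90"],
                direction="forward",
            ),
            # step 4: 4-hydroxyphenylacetate 3-monooxygenase on tyrosol
            Reaction(
                id="R_HPAH",
                stoich={
                    "tyrosol": F(-1), "o2": F(-1), "nadh": F(-1), "h": F(-1),
                    "hxt": F(1), "nad": F(1), "h2o": F(1),
                },
                ec_numbers=["1.14.14.9"],
                direction="forward",
            ),
            # cataloged NAD(P)H-dependent tyramine -> dopamine monooxygenase
            # (the peroxide-driven variant of this conversion is only
            # available as rule R2, i.e. as a novel step)
            Reaction(
                id="R_TYRH",
                stoich={
                    "tyramine": F(-1), "o2": F(-1), "nadh": F(-1), "h": F(-1),
                    "dopamine": F(1), "nad": F(1), "h2o": F(1),
                },
                ec_numbers=["1.14.13.-"],
                direction="forward",
            ),
        ]
    }

    signatures = build_signature_index(compounds, currency=DEMO_CURRENCY, radius=1)

    sig = signatures
    rule_bypass_delta = _delta_between(sig["tyr"], sig["hpaa4"])
    rule_r2_delta = _delta_between(sig["tyramine"], sig["dopamine"])
    rule_r3_delta = _delta_between(sig["dopamine"], sig["hxt"])
    rules = {}
    for delta, parent, ec in [
        (rule_bypass_delta, "MNXR121797", "1.13.99.-"),
        (rule_r2_delta, "MNXR_EC1.11.2.5", "1.11.2.5"),
        (rule_r3_delta, "MNXR102311", "2.6.1.85"),
    ]:
        rule = ReactionRule(
            id=rule_id_for(delta),
            delta=delta,
            parent_reactions=(parent,),
            source_ec=(ec,),
            radius=1,
        )
        rules[rule.id] = rule
    rule_bypass_id = rule_id_for(rule_bypass_delta)
    rule_r2_id = rule_id_for(rule_r2_delta)
    rule_r3_id = rule_id_for(rule_r3_delta)

    overall_eq1 = OverallStoichiometry(
        coeffs={
            "tyr": F(-1), "nadh": F(-2), "h": F(-3), "o2": F(-2),
            "hxt": F(1), "nh4": F(1), "co2": F(1), "h2o2": F(1), "nad": F(2),
        },
        yield_=F(1),
        support=9 - 2,
    )
    overall_eq2 = OverallStoichiometry(
        coeffs={
            "tyr": F(-1), "h": F(-1), "h2o2": F(-1),
            "hxt": F(1), "nh4": F(1), "co2": F(1),
        },
        yield_=F(1),
        support=4,
    )

    known_pathway = Pathway(
        steps=[
            PathwayStep("known", "R_TDC", 1, dict(reactions["R_TDC"].stoich)),
            PathwayStep("known", "R_TYO", 1, dict(reactions["R_TYO"].stoich)),
            PathwayStep("known", "R_ALDR", 1, dict(reactions["R_ALDR"].stoich)),
            PathwayStep("known", "R_HPAH", 1, dict(reactions["R_HPAH"].stoich)),
        ],
        overall=overall_eq1,
        n_novel=0,
    )
    fig8_pathway = Pathway(
        steps=[
            PathwayStep("known", "R_TDC", 1, dict(reactions["R_TDC"].stoich)),
            PathwayStep(
                "novel", rule_r2_id, 1,
                {"tyramine": F(-1), "h2o2": F(-1), "dopamine": F(1), "h2o": F(1)},
                substrate="tyramine", product="dopamine",
            ),
            PathwayStep(
                "novel", rule_r3_id, 1,
                {"dopamine": F(-1), "h2o": F(-1), "h": F(-1),
                 "hxt": F(1), "nh4": F(1)},
                substrate="dopamine", product="hxt",
            ),
        ],
        overall=overall_eq2,
        n_novel=2,
    )

    inclusive_cospec = CoMetaboliteSpec(
        allowed={"o2", "h2o", "h2o2", "nh4", "co2", "h"},
        couples=[("nadh", "nad")],
        side_constraint={"co2": "produce", "o2": "consume"},
    )

    # Synthetic enzyme catalog for the amine->hydroxyl rule (R3): sequences
    # and organisms are placeholders; native substrates come from the demo
    # compound set so the default signature-similarity scorer applies.
    candidates = [
        EnzymeCandidate(
            enzyme_id=f"enz{i:02d}",
            organism=f"Synthetica exempli str. {i}",
            sequence=seq,
            native_substrate=native,
            ec="2.6.1.85",
            rule_id=rule_r3_id,
        )
        for i, (native, seq) in enumerate(
            [
                ("dopamine", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
                ("tyramine", "MSDNKQLAHLVEQRAGLTFEQLMSWTGISAAQ"),
                ("tyrosol", "MALWMRLLPLLALLALWGPDPAAAFVNQHLCG"),
                ("hxt", "MGSSHHHHHHSSGLVPRGSHMASMTGGQQMGR"),
                ("tyr", "MVLSPADKTNVKAAWGKVGAHAGEYGAEALER"),
                ("hpaa4", "MNIFEMLRIDEGLRLKIYKDTEGYYTIGIGHL"),
            ],
            start=1,
        )
    ]

    # Synthetic thermodynamic training table: measured values generated from
    # a fixed per-moiety contribution vector (deterministic), so a fitted
    # model reproduces sensible, internally consistent step energies.
    all_keys = sorted({k for s in sig.values() for k in s.counts})
    rng = np.random.default_rng(20240817)
    beta_syn = {k: float(v) for k, v in zip(all_keys, rng.normal(0.0, 25.0, len(all_keys)))}
    training: list[tuple[dict[str, int], float]] = []
    for cid in sorted(sig):
        delta = dict(sig[cid].counts)  # formation-style rows span the key space
        training.append((delta, sum(beta_syn[k] * v for k, v in delta.items())))
    step_deltas = [
        _delta_between(sig["tyr"], sig["tyramine"]),
        _delta_between(sig["tyramine"], sig["hpaa4"]),
        _delta_between(sig["hpaa4"], sig["tyrosol"]),
        _delta_between(sig["tyrosol"], sig["hxt"]),
        rule_bypass_delta,
        rule_r2_delta,
        rule_r3_delta,
    ]
    for delta in step_deltas:
        training.append(
            (dict(delta), sum(beta_syn[k] * v for k, v in delta.items()))
        )

    demo = HxtDemo(
        compounds=compounds,
        reactions=reactions,
        rules=rules,
        signatures=signatures,
        currency=DEMO_CURRENCY,
        overall_eq1=overall_eq1,
        overall_eq2=overall_eq2,
        known_pathway=known_pathway,
        fig8_pathway=fig8_pathway,
        inclusive_cospec=inclusive_cospec,
        candidates=candidates,
        training=training,
        rule_bypass_id=rule_bypass_id,
        rule_r2_id=rule_r2_id,
        rule_r3_id=rule_r3_id,
    )
    _self_check(demo)
    return demo


def _self_check(demo: HxtDemo) -> None:
    for rxn in demo.reactions.values():
        report = check_reaction_balance(rxn, demo.compounds)
        if not report.balanced:
            raise GenerationError(f"demo reaction {rxn.id} unbalanced: {report}")
    for overall in (demo.overall_eq1, demo.overall_eq2):
        report = check_reaction_balance(overall.as_reaction(), demo.compounds)
        if not report.balanced:
            raise GenerationError("demo overall stoichiometry unbalanced")
    for pw in (demo.known_pathway, demo.fig8_pathway):
        total: Counter = Counter()
        for step in pw.steps:
            for cid, v in step.stoich.items():
                total[cid] += v
        expected = Counter(pw.overall.coeffs)
        if +total != +expected or -total != -expected:
            raise GenerationError("demo reference pathway does not sum to overall")


# ---------------------------------------------------------------------------
# Toy networks

@dataclass
class ToyNetworkSpec:
    n_compounds: int = 8
    n_reactions: int = 5
    planted_path_length: int = 3
    n_decoys: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.planted_path_length > self.n_reactions:
            raise ValueError("planted_path_length must be <= n_reactions")
        if self.n_reactions != self.planted_path_length + self.n_decoys:
            raise ValueError("n_reactions must equal planted_path_length + n_decoys")
        if self.n_compounds < self.planted_path_length + 1:
            raise ValueError("need at least planted_path_length + 1 compounds")


@dataclass
class ToyNetwork:
    compounds: dict[str, Compound]
    reactions: dict[str, Reaction]
    signatures: dict[str, MoietySignature]
    currency: frozenset[str]
    planted_pathway: Pathway
    planted_overall: OverallStoichiometry
    source: str
    target: str


_CARBON_CTX = ["(C1)", "(C1,C1)", "(C1,O1)", "(C1,C1,C1)", "(C1,C1,O1)"]
_OXYGEN_CTX = ["(C1)", "(C1,C1)", "(C2)"]
_CTX_DEGREE = {"(C1)": 1, "(C1,C1)": 2, "(C1,O1)": 2, "(C1,C1,C1)": 3,
               "(C1,C1,O1)": 3, "(C2)": 1}


def _toy_signature(rng: np.random.Generator) -> dict[str, int]:
    """Random CHO signature with an even hydrogen total (keeps balances integral)."""
    n_c = int(rng.integers(2, 6))
    n_o = int(rng.integers(0, 3))
    counts: Counter = Counter()
    h_total = 0
    keys: list[tuple[str, int, str]] = []
    for _ in range(n_c):
        ctx = _CARBON_CTX[int(rng.integers(0, len(_CARBON_CTX)))]
        h = int(rng.integers(0, 4 - _CTX_DEGREE[ctx] + 1))
        keys.append(("C", h, ctx))
        h_total += h
    for _ in range(n_o):
        ctx = _OXYGEN_CTX[int(rng.integers(0, len(_OXYGEN_CTX)))]
        h = int(rng.integers(0, 2)) if ctx == "(C1)" else 0
        keys.append(("O", h, ctx))
        h_total += h
    if h_total % 2:  # fix hydrogen parity on the first adjustable center
        for i, (el, h, ctx) in enumerate(keys):
            cap = (4 - _CTX_DEGREE[ctx]) if el == "C" else 1
            if h < cap:
                keys[i] = (el, h + 1, ctx)
                break
            if h > 0:
                keys[i] = (el, h - 1, ctx)
                break
    for el, h, ctx in keys:
        hpart = f"H{h};" if h else ""
        counts[f"{el};{hpart}{ctx}"] += 1
    return dict(counts)


def _currency_closure(diff: Mapping[str, int]) -> dict[str, int]:
    """CO2/H2O/H2 coefficients canceling a CHO formula difference."""
    d_c, d_h, d_o = diff.get("C", 0), diff.get("H", 0), diff.get("O", 0)
    x_co2 = -d_c
    x_h2o = -d_o - 2 * x_co2
    if (d_h + 2 * x_h2o) % 2:
        raise GenerationError("hydrogen parity violated in toy generation")
    x_h2 = -(d_h + 2 * x_h2o) // 2
    return {c: v for c, v in
            [("co2", x_co2), ("h2o", x_h2o), ("h2", x_h2)] if v}


def _toy_currency_compounds() -> dict[str, Compound]:
    return {
        "co2": Compound(id="co2", name="carbon dioxide", formula={"C": 1, "O": 2}),
        "h2o": Compound(id="h2o", name="water", formula={"H": 2, "O": 1}),
        "h2": Compound(id="h2", name="dihydrogen", formula={"H": 2}),
    }


def _shortest_route(reactions: Mapping[str, Reaction], currency, source, target) -> int:
    """BFS over main-compound edges; len of the shortest source->target chain."""
    edges: dict[str, list[str]] = {}
    for rxn in reactions.values():
        mains_in = [c for c in rxn.reactants if c not in currency]
        mains_out = [c for c in rxn.products if c not in currency]
        for a in mains_in:
            for b_ in mains_out:
                edges.setdefault(a, []).append(b_)
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for a in frontier:
            for b_ in edges.get(a, []):
                if b_ not in dist:
                    dist[b_] = dist[a] + 1
                    nxt.append(b_)
        frontier = nxt
    return dist.get(target, -1)


def make_toy_network(spec: ToyNetworkSpec, max_retries: int = 50) -> ToyNetwork:
    """Random balanced toy network with a planted linear pathway.

    Every reaction is element-balanced by construction (CO2/H2O/H2 closure
    over synthetic CHO compounds); the planted pathway validates and sums
    to the planted overall conversion, and decoy reactions never create a
    shorter balanced route (checked by graph search, regenerating decoys on
    violation up to ``max_retries``).  Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.planted_path_length

    sig_counts = []
    seen = set()
    while len(sig_counts) < spec.n_compounds:
        s = _toy_signature(rng)
        key = tuple(sorted(s.items()))
        if key in seen:
            continue
        seen.add(key)
        sig_counts.append(s)

    compounds = _toy_currency_compounds()
    signatures: dict[str, MoietySignature] = {}
    ids = [f"M{i:02d}" for i in range(spec.n_compounds)]
    for cid, counts in zip(ids, sig_counts):
        formula = signature_formula(counts)
        compounds[cid] = Compound(id=cid, name=f"toy {cid}", formula=formula)
        signatures[cid] = MoietySignature(counts=counts, radius=1)

    path_ids = ids[: L + 1]
    source, target = path_ids[0], path_ids[-1]

    def make_reaction(rid: str, a: str, b: str) -> Reaction:
        diff = Counter(compounds[b].formula)
        diff.subtract(compounds[a].formula)
        stoich = {a: Fraction(-1), b: Fraction(1)}
        for c, v in _currency_closure(diff).items():
            stoich[c] = stoich.get(c, Fraction(0)) + v
        return Reaction(id=rid, stoich=stoich, direction="forward")

    reactions: dict[str, Reaction] = {}
    planted_steps = []
    for i in range(L):
        rxn = make_reaction(f"RP{i}", path_ids[i], path_ids[i + 1])
        reactions[rxn.id] = rxn
        planted_steps.append(PathwayStep("known", rxn.id, 1, dict(rxn.stoich)))

    overall_stoich: Counter = Counter()
    for step in planted_steps:
        for cid, v in step.stoich.items():
            overall_stoich[cid] += v
    overall = OverallStoichiometry(
        coeffs={c: v for c, v in overall_stoich.items() if v},
        yield_=Fraction(1),
        support=sum(
            1 for c, v in overall_stoich.items()
            if v and c not in (source, target)
        ),
    )
    planted = Pathway(steps=planted_steps, overall=overall, n_novel=0)

    for attempt in range(max_retries):
        decoys: dict[str, Reaction] = {}
        pairs = set()
        tries = 0
        while len(decoys) < spec.n_decoys and tries < 200:
            tries += 1
            a, b = (ids[int(i)] for i in rng.integers(0, spec.n_compounds, 2))
            if a == b or (a, b) in pairs or (b, a) in pairs:
                continue
            if a == source and b == target:
                continue
            pairs.add((a, b))
            rid = f"RD{len(decoys)}"
            decoys[rid] = make_reaction(rid, a, b)
        if len(decoys) < spec.n_decoys:
            break
        trial = {**reactions, **decoys}
        if _shortest_route(trial, TOY_CURRENCY, source, target) == L:
            reactions = trial
            break
    else:
        raise GenerationError(
            "could not place decoys without creating a shorter route"
        )
    if len(reactions) != spec.n_reactions:
        raise GenerationError("decoy generation exhausted the retry budget")

    for rxn in reactions.values():
        if not check_reaction_balance(rxn, compounds).balanced:
            raise GenerationError(f"toy reaction {rxn.id} unbalanced")

    return ToyNetwork(
        compounds=compounds,
        reactions=reactions,
        signatures=signatures,
        currency=TOY_CURRENCY,
        planted_pathway=planted,
        planted_overall=overall,
        source=source,
        target=target,
    )
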