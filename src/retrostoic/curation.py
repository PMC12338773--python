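"""Database curation: filtering reactions/compounds, rule indexing, ID mapping.

The processing pipeline mirrors standard practice for reaction databases:
transport reactions are dropped first, then reactions with generic
(wildcard) or otherwise unusable participants, then reactions that fail
element/charge balance.  Compounds are kept only when they are non-generic,
uniquely identified by structure, and participate in at least one kept
reaction.  The pipeline is idempotent: curating a curated database is a
no-op.

The rule index deduplicates reactions by their moiety-signature delta;
reactions sharing a delta share one rule, which records every parent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .chem_core import (
    DEFAULT_CURRENCY,
    Compound,
    FormulaParseError,
    MoietySignature,
    Reaction,
    ReactionRule,
    RuleExtractionError,
    WILDCARD_TOKENS,
    check_reaction_balance,
    deserialize_delta,
    format_formula,
    format_reaction_string,
    parse_formula,
    parse_reaction_string,
    reaction_rule,
    rule_id_for,
    serialize_delta,
)

__all__ = [
    "CurationReport",
    "NovelStructure",
    "UnmappableCompoundError",
    "curate_database",
    "build_rule_index",
    "map_ids",
    "read_compounds_tsv",
    "write_compounds_tsv",
    "read_reactions_tsv",
    "write_reactions_tsv",
    "read_rules_tsv",
    "write_rules_tsv",
]


@dataclass
class CurationReport:
    reactions_in: int = 0
    reactions_removed_unbalanced: int = 0
    reactions_removed_transport: int = 0
    reactions_removed_generic: int = 0
    reactions_kept: int = 0
    compounds_in: int = 0
    compounds_kept: int = 0
    rules_unique: int = 0
    log: list[str] = field(default_factory=list)

    def check(self) -> None:
        removed = (
            self.reactions_removed_unbalanced
            + self.reactions_removed_transport
            + self.reactions_removed_generic
        )
        assert self.reactions_kept == self.reactions_in - removed
        assert self.compounds_kept <= self.compounds_in

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


@dataclass(frozen=True)
class NovelStructure:
    """Marker for a compound absent from a target namespace: carries its structure."""

    compound_id: str
    structure: str


class UnmappableCompoundError(KeyError):
    pass


# ---------------------------------------------------------------------------
# Curation

def _is_generic(cpd: Compound) -> bool:
    return cpd.is_generic or any(el in WILDCARD_TOKENS for el in cpd.formula)


def curate_database(
    compounds: Mapping[str, Compound],
    reactions: Mapping[str, Reaction],
) -> tuple[dict[str, Compound], dict[str, Reaction], CurationReport]:
    """Filter a raw compound/reaction table pair into a curated database.

    Removal order (each reaction counted once): transport reactions, then
    reactions with a generic or unresolvable participant, then unbalanced
    reactions.  Compounds sharing one structure under several ids are
    treated as unusable participants and recorded in the report log.
    """
    report = CurationReport(
        reactions_in=len(reactions), compounds_in=len(compounds)
    )

    generic = {cid for cid, c in compounds.items() if _is_generic(c)}
    for cid in sorted(generic):
        report.log.append(f"compound {cid}: generic, excluded")

    by_structure: dict[str, list[str]] = {}
    for cid, c in compounds.items():
        if cid in generic or not c.structure:
            continue
        by_structure.setdefault(_canonical_structure(c), []).append(cid)
    duplicated: set[str] = set()
    for struct, ids in sorted(by_structure.items()):
        if len(ids) > 1:
            duplicated.update(ids)
            report.log.append(
                "duplicate structure under ids " + ", ".join(sorted(ids))
            )
    unusable = generic | duplicated

    kept_reactions: dict[str, Reaction] = {}
    for rid, rxn in reactions.items():
        if rxn.is_transport:
            report.reactions_removed_transport += 1
            continue
        bad = sorted(
            cid for cid in rxn.stoich
            if cid in unusable or cid not in compounds
        )
        if bad:
            report.reactions_removed_generic += 1
            report.log.append(
                f"reaction {rid}: unusable participant(s) {', '.join(bad)}"
            )
            continue
        if not check_reaction_balance(rxn, compounds).balanced:
            report.reactions_removed_unbalanced += 1
            continue
        kept_reactions[rid] = rxn
    report.reactions_kept = len(kept_reactions)

    used = {cid for rxn in kept_reactions.values() for cid in rxn.stoich}
    kept_compounds = {
        cid: compounds[cid]
        for cid in sorted(used)
        if cid not in unusable
    }
    report.compounds_kept = len(kept_compounds)
    report.check()
    return kept_compounds, kept_reactions, report


def _canonical_structure(cpd: Compound) -> str:
    if cpd.inchi:
        return cpd.inchi
    from rdkit import Chem

    mol = Chem.MolFromSmiles(cpd.smiles)
    return Chem.MolToSmiles(mol) if mol is not None else cpd.smiles


def build_rule_index(
    reactions: Mapping[str, Reaction],
    compounds: Mapping[str, Compound],
    currency: Iterable[str] = DEFAULT_CURRENCY,
    radius: int = 1,
    signatures: Optional[Mapping[str, MoietySignature]] = None,
    report: Optional[CurationReport] = None,
) -> dict[str, ReactionRule]:
    """Deduplicated moiety-rule index over a curated reaction set.

    Reactions whose rule cannot be extracted (missing signatures) are
    skipped and logged; reactions with identical deltas merge into one rule
    listing all parents.
    """
    index: dict[str, ReactionRule] = {}
    for rid in sorted(reactions):
        try:
            rule = reaction_rule(
                reactions[rid], compounds, currency=currency,
                radius=radius, signatures=signatures,
            )
        except RuleExtractionError as exc:
            if report is not None:
                report.log.append(str(exc))
            continue
        if rule.id in index:
            prev = index[rule.id]
            if prev.delta != rule.delta:  # hash collision guard: compare maps
                raise RuntimeError(
                    f"rule id collision between {prev.parent_reactions} and {rid}"
                )
            index[rule.id] = ReactionRule(
                id=rule.id,
                delta=rule.delta,
                parent_reactions=tuple(sorted(set(prev.parent_reactions) | {rid})),
                source_ec=tuple(sorted(set(prev.source_ec) | set(rule.source_ec))),
                radius=radius,
            )
        else:
            index[rule.id] = rule
    if report is not None:
        report.rules_unique = len(index)
    return index


def map_ids(
    compound: Compound, target_namespace: str
) -> Union[str, NovelStructure]:
    """Foreign id of a compound, or a novel-structure marker when unmapped.

    A compound with neither a cross-reference in the target namespace nor a
    structure raises :class:`UnmappableCompoundError`.
    """
    if target_namespace in compound.xrefs and compound.xrefs[target_namespace]:
        return compound.xrefs[target_namespace]
    if compound.structure:
        return NovelStructure(compound_id=compound.id, structure=compound.structure)
    raise UnmappableCompoundError(
        f"compound {compound.id}: no {target_namespace} mapping and no structure"
    )


# ---------------------------------------------------------------------------
# TSV interfaces

def read_compounds_tsv(path: Union[str, Path]) -> dict[str, Compound]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, Compound] = {}
    for row in df.itertuples(index=False):
        formula = parse_formula(row.formula, allow_wildcards=True) if row.formula else {}
        xrefs = {}
        if getattr(row, "kegg_id", ""):
            xrefs["kegg"] = row.kegg_id
        out[row.id] = Compound(
            id=row.id,
            name=getattr(row, "name", ""),
            formula=formula,
            charge=int(row.charge) if row.charge else 0,
            smiles=getattr(row, "smiles", "") or None,
            inchi=getattr(row, "inchi", "") or None,
            xrefs=xrefs,
            is_generic=str(getattr(row, "is_generic", "0")) in ("1", "true", "True"),
        )
    return out


def write_compounds_tsv(compounds: Mapping[str, Compound], path: Union[str, Path]) -> None:
    rows = []
    for cid in sorted(compounds):
        c = compounds[cid]
        rows.append(
            {
                "id": c.id,
                "name": c.name,
                "formula": format_formula(c.formula),
                "charge": c.charge,
                "smiles": c.smiles or "",
                "inchi": c.inchi or "",
                "kegg_id": c.xrefs.get("kegg", ""),
                "is_generic": int(c.is_generic),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_reactions_tsv(path: Union[str, Path]) -> dict[str, Reaction]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, Reaction] = {}
    for row in df.itertuples(index=False):
        stoich, direction = parse_reaction_string(row.equation)
        out[row.id] = Reaction(
            id=row.id,
            stoich=stoich,
            ec_numbers=[e for e in getattr(row, "ec", "").split(";") if e],
            direction=direction,
            is_transport=str(getattr(row, "is_transport", "0")) in ("1", "true", "True"),
        )
    return out


def write_reactions_tsv(reactions: Mapping[str, Reaction], path: Union[str, Path]) -> None:
    rows = []
    for rid in sorted(reactions):
        r = reactions[rid]
        rows.append(
            {
                "id": r.id,
                "equation": format_reaction_string(r.stoich, r.direction),
                "ec": ";".join(r.ec_numbers),
                "is_transport": int(r.is_transport),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_rules_tsv(path: Union[str, Path]) -> dict[str, ReactionRule]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, ReactionRule] = {}
    for row in df.itertuples(index=False):
        delta = deserialize_delta(row.delta)
        out[row.rule_id] = ReactionRule(
            id=row.rule_id,
            delta=delta,
            parent_reactions=tuple(p for p in row.parents.split(";") if p),
            source_ec=tuple(e for e in row.ec.split(";") if e),
            radius=int(getattr(row, "radius", 1)),
        )
    return out


def write_rules_tsv(rules: Mapping[str, ReactionRule], path: Union[str, Path]) -> None:
    rows = []
    for rule_id in sorted(rules):
        rule = rules[rule_id]
        rows.append(
            {
                "rule_id": rule.id,
                "delta": serialize_delta(rule.delta),
                "parents": ";".join(rule.parent_reactions),
                "ec": ";".join(rule.source_ec),
                "radius": rule.radius,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
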