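"""Core chemistry data model: compounds, reactions, moiety signatures, reaction rules.

A *moiety signature* encodes a molecule as a multiset of atom-centered
environment keys.  Each heavy atom contributes one key of the form

    ``El;Hn;(neighbor,neighbor,...)``

where ``El`` is the element symbol of the center, ``Hn`` the number of
attached hydrogens (omitted when zero), and the parenthesized list holds the
sorted neighbor tokens ``El<order>`` with bond orders ``1``/``2``/``3`` and
``a`` for aromatic bonds.  At radius 2 each neighbor token additionally
carries its own hydrogen count and second-shell neighbors in brackets.
Examples (radius 1): water ``O;H2;()``, the methyl carbon of ethanol
``C;H3;(C1)``, a carbonyl oxygen ``O;(C2)``.

A *reaction rule* is the signed sum of moiety signatures across a reaction,
currency species excluded.  Two reactions with identical signature
differences define the same rule, and a rule can be applied to any substrate
pool that contains its consumed keys — this is what lets the pathway search
propose novel reactions on substrates the database has never seen.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from fractions import Fraction
from functools import reduce
from math import gcd
from typing import Iterable, Mapping, Optional

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Compound",
    "Reaction",
    "MoietySignature",
    "ReactionRule",
    "BalanceReport",
    "ChemError",
    "FormulaParseError",
    "ReactionParseError",
    "CompoundLookupError",
    "StructureError",
    "SignatureUnavailableError",
    "RuleExtractionError",
    "RuleInapplicableError",
    "DEFAULT_CURRENCY",
    "WILDCARD_TOKENS",
    "parse_formula",
    "format_formula",
    "check_reaction_balance",
    "moiety_signature",
    "signature_formula",
    "reaction_rule",
    "rule_id_for",
    "serialize_delta",
    "deserialize_delta",
    "apply_rule",
    "parse_reaction_string",
    "format_reaction_string",
    "integerize",
]


# ---------------------------------------------------------------------------
# Errors

class ChemError(Exception):
    """Base class for chemistry-layer failures."""


class FormulaParseError(ChemError):
    def __init__(self, text: str, pos: int, message: str):
        self.text, self.pos = text, pos
        super().__init__(f"cannot parse formula {text!r} at position {pos}: {message}")


class ReactionParseError(ChemError):
    pass


class CompoundLookupError(ChemError):
    pass


class StructureError(ChemError):
    pass


class SignatureUnavailableError(ChemError):
    """Compound has no structure text; it can only be handled by formula."""


class RuleExtractionError(ChemError):
    pass


class RuleInapplicableError(ChemError):
    def __init__(self, key: str, have: int, need: int):
        self.key, self.have, self.need = key, have, need
        super().__init__(
            f"rule inapplicable: needs {need} x {key!r}, pool has {have}"
        )


# ---------------------------------------------------------------------------
# Constants

#: Formula tokens that mark a generic (wildcard) molecule, e.g. "ROH".
WILDCARD_TOKENS = frozenset({"R", "X", "*"})

#: Conventional currency-metabolite ids used by the packaged fixtures:
#: proton, water, redox couples, and nucleotide phosphate carriers.  Rule
#: extraction excludes these species so that a rule captures only the
#: main-chain transformation; the set is configuration, not a fixed law.
DEFAULT_CURRENCY = frozenset(
    {
        "h", "h2o",
        "nadh", "nad", "nadph", "nadp",
        "fad", "fadh2",
        "atp", "adp", "amp", "pi", "ppi",
    }
)

_PT = Chem.GetPeriodicTable()


def _is_element(symbol: str) -> bool:
    try:
        return _PT.GetAtomicNumber(symbol) > 0
    except Exception:
        return False


# ---------------------------------------------------------------------------
# Domain types

@dataclass(frozen=True)
class Compound:
    """An identified chemical species.

    ``formula`` maps element symbols to non-negative counts (wildcard tokens
    allowed only when ``is_generic``); ``charge`` is the net charge in
    elementary units.  ``smiles``/``inchi`` are optional structure texts and
    ``xrefs`` maps namespace labels (e.g. ``"kegg"``) to foreign ids.
    """

    id: str
    name: str = ""
    formula: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0
    smiles: Optional[str] = None
    inchi: Optional[str] = None
    xrefs: Mapping[str, str] = field(default_factory=dict)
    is_generic: bool = False

    def __post_init__(self):
        for el, n in self.formula.items():
            if n < 0:
                raise ValueError(f"compound {self.id}: negative count for {el}")
            if el in WILDCARD_TOKENS and not self.is_generic:
                object.__setattr__(self, "is_generic", True)
        if not self.formula and self.charge == 0:
            raise ValueError(
                f"compound {self.id}: empty formula (only the bare proton may "
                "carry no elements, and it is charged)"
            )

    @property
    def structure(self) -> Optional[str]:
        return self.smiles or self.inchi


@dataclass
class Reaction:
    """Signed stoichiometry over compound ids (negative = consumed)."""

    id: str
    stoich: dict[str, Fraction]
    ec_numbers: list[str] = field(default_factory=list)
    direction: str = "bidirectional"  # forward | reverse | bidirectional
    is_transport: bool = False

    def __post_init__(self):
        self.stoich = {c: Fraction(v) for c, v in self.stoich.items() if v != 0}
        if not any(v < 0 for v in self.stoich.values()) or not any(
            v > 0 for v in self.stoich.values()
        ):
            raise ValueError(
                f"reaction {self.id}: needs at least one reactant and one product"
            )
        if self.direction not in ("forward", "reverse", "bidirectional"):
            raise ValueError(f"reaction {self.id}: bad direction {self.direction!r}")

    @property
    def reactants(self) -> list[str]:
        return sorted(c for c, v in self.stoich.items() if v < 0)

    @property
    def products(self) -> list[str]:
        return sorted(c for c, v in self.stoich.items() if v > 0)


@dataclass(frozen=True)
class MoietySignature:
    """Multiset of canonical atom-environment keys at a given radius."""

    counts: Mapping[str, int]
    radius: int = 1

    def __post_init__(self):
        object.__setattr__(
            self, "counts", {k: int(v) for k, v in sorted(self.counts.items()) if v}
        )
        if any(v <= 0 for v in self.counts.values()):
            raise ValueError("signature counts must be positive")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")

    def __iter__(self):
        return iter(self.counts.items())


@dataclass(frozen=True)
class ReactionRule:
    """Signed moiety-signature difference of a reaction (currency excluded).

    The id is a canonical hash of the delta map, so identical deltas always
    share one id.
    """

    id: str
    delta: Mapping[str, int]
    parent_reactions: tuple[str, ...] = ()
    source_ec: tuple[str, ...] = ()
    radius: int = 1

    def __post_init__(self):
        object.__setattr__(
            self, "delta", {k: int(v) for k, v in sorted(self.delta.items()) if v}
        )

    def reversed(self) -> "ReactionRule":
        delta = {k: -v for k, v in self.delta.items()}
        return ReactionRule(
            id=rule_id_for(delta),
            delta=delta,
            parent_reactions=self.parent_reactions,
            source_ec=self.source_ec,
            radius=self.radius,
        )


@dataclass(frozen=True)
class BalanceReport:
    element_residuals: Mapping[str, Fraction]
    charge_residual: Fraction
    balanced: bool

    def __bool__(self) -> bool:
        return self.balanced


# ---------------------------------------------------------------------------
# Formula handling

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?|\*)(\d*)")


def parse_formula(text: str, allow_wildcards: bool = False) -> dict[str, int]:
    """Parse a Hill-style elemental formula like ``"C9H11NO3"``.

    Unknown element symbols are rejected with the offending position unless
    ``allow_wildcards`` is set and the token is one of ``R``/``X``/``*``.
    """
    text = text.strip()
    if not text:
        raise FormulaParseError(text, 0, "empty formula")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaParseError(text, pos, f"unexpected character {text[pos]!r}")
        symbol, digits = m.groups()
        if not _is_element(symbol):
            if not (allow_wildcards and symbol in WILDCARD_TOKENS):
                # A two-letter non-element like "Nx" may hide a valid one-letter
                # element; retry with the single-letter prefix.
                if len(symbol) == 2 and _is_element(symbol[0]):
                    symbol, digits = symbol[0], ""
                    m = None
                else:
                    raise FormulaParseError(text, pos, f"unknown element {symbol!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaParseError(text, pos, "zero count")
        counts[symbol] = counts.get(symbol, 0) + n
        pos += len(symbol) + (len(digits) if m else 0)
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Hill order: C first, then H, then other elements alphabetically."""
    keys = sorted(counts)
    ordered = [k for k in ("C", "H") if k in counts] + [
        k for k in keys if k not in ("C", "H")
    ]
    if "C" not in counts:
        ordered = keys
    return "".join(f"{k}{counts[k] if counts[k] != 1 else ''}" for k in ordered if counts[k])


# ---------------------------------------------------------------------------
# Balance checking

def check_reaction_balance(
    rxn: Reaction, compounds: Mapping[str, Compound]
) -> BalanceReport:
    """Element and charge residuals (products minus reactants) of a reaction."""
    residuals: dict[str, Fraction] = {}
    charge = Fraction(0)
    for cid, coeff in rxn.stoich.items():
        try:
            cpd = compounds[cid]
        except KeyError:
            raise CompoundLookupError(
                f"reaction {rxn.id}: unknown compound id {cid!r}"
            ) from None
        for el, n in cpd.formula.items():
            residuals[el] = residuals.get(el, Fraction(0)) + coeff * n
        charge += coeff * cpd.charge
    residuals = {el: r for el, r in residuals.items() if r != 0}
    return BalanceReport(
        element_residuals=residuals,
        charge_residual=charge,
        balanced=not residuals and charge == 0,
    )


# ---------------------------------------------------------------------------
# Moiety signatures

_BOND_ORDER = {
    Chem.BondType.SINGLE: "1",
    Chem.BondType.DOUBLE: "2",
    Chem.BondType.TRIPLE: "3",
    Chem.BondType.AROMATIC: "a",
}


def _order_token(bond) -> str:
    tok = _BOND_ORDER.get(bond.GetBondType())
    if tok is None:
        d = bond.GetBondTypeAsDouble()
        tok = str(int(d)) if float(d).is_integer() else f"{d:g}"
    return tok


def _neighbor_token(atom, bond, parent_idx: int, depth: int) -> str:
    tok = f"{atom.GetSymbol()}{_order_token(bond)}"
    if depth >= 1:
        subs = []
        for b in atom.GetBonds():
            other = b.GetOtherAtom(atom)
            if other.GetIdx() == parent_idx or other.GetAtomicNum() == 1:
                continue
            subs.append(_neighbor_token(other, b, atom.GetIdx(), depth - 1))
        tok += f"H{atom.GetTotalNumHs(includeNeighbors=True)}[{','.join(sorted(subs))}]"
    return tok


def _mol_from_compound(compound: Compound):
    if compound.smiles:
        mol = Chem.MolFromSmiles(compound.smiles)
        if mol is None:
            raise StructureError(
                f"compound {compound.id}: unparseable SMILES {compound.smiles!r}"
            )
        return mol
    if compound.inchi:
        mol = Chem.MolFromInchi(compound.inchi)
        if mol is None:
            raise StructureError(
                f"compound {compound.id}: unparseable InChI {compound.inchi!r}"
            )
        return mol
    raise SignatureUnavailableError(
        f"compound {compound.id} has no structure; signature unavailable"
    )


def moiety_signature(compound: Compound, radius: int = 1) -> MoietySignature:
    """Atom-environment multiset of a compound's heavy atoms.

    Hydrogens are folded into the center key (never centers themselves);
    counts aggregate over topologically equivalent atoms.  Raises
    :class:`SignatureUnavailableError` for structureless compounds and
    :class:`StructureError` for unparseable structure text.
    """
    mol = _mol_from_compound(compound)
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        nbrs = []
        for bond in atom.GetBonds():
            other = bond.GetOtherAtom(atom)
            if other.GetAtomicNum() == 1:
                continue
            nbrs.append(_neighbor_token(other, bond, atom.GetIdx(), radius - 1))
        h = atom.GetTotalNumHs(includeNeighbors=True)
        hpart = f"H{h};" if h else ""
        key = f"{atom.GetSymbol()};{hpart}({','.join(sorted(nbrs))})"
        counts[key] = counts.get(key, 0) + 1
    return MoietySignature(counts=counts, radius=radius)


_KEY_HEAD = re.compile(r"^([A-Z][a-z]?);(?:H(\d+);)?\(")


def signature_formula(counts: Mapping[str, int]) -> dict[str, int]:
    """Element counts (including hydrogen) reconstructed from signature centers."""
    formula: dict[str, int] = {}
    for key, n in counts.items():
        m = _KEY_HEAD.match(key)
        if not m:
            raise ValueError(f"malformed moiety key {key!r}")
        el, h = m.group(1), int(m.group(2) or 0)
        formula[el] = formula.get(el, 0) + n
        if h:
            formula["H"] = formula.get("H", 0) + h * n
    return {el: c for el, c in formula.items() if c}


# ---------------------------------------------------------------------------
# Reaction rules

def serialize_delta(delta: Mapping[str, int]) -> str:
    return "|".join(f"{k}={delta[k]:+d}" for k in sorted(delta) if delta[k])


def deserialize_delta(text: str) -> dict[str, int]:
    delta: dict[str, int] = {}
    if not text:
        return delta
    for part in text.split("|"):
        key, _, val = part.rpartition("=")
        if not key:
            raise ValueError(f"malformed delta entry {part!r}")
        delta[key] = int(val)
    return delta


def rule_id_for(delta: Mapping[str, int]) -> str:
    digest = hashlib.sha256(serialize_delta(delta).encode()).hexdigest()[:12]
    return f"RR{digest}"


def integerize(coeffs: Mapping[str, Fraction]) -> tuple[dict[str, int], int]:
    """Scale rational coefficients to integers; returns (scaled, multiplier)."""
    fracs = {c: Fraction(v) for c, v in coeffs.items()}
    denoms = [v.denominator for v in fracs.values()] or [1]
    lcm = reduce(lambda a, b: a * b // gcd(a, b), denoms, 1)
    return {c: int(v * lcm) for c, v in fracs.items()}, lcm


def reaction_rule(
    rxn: Reaction,
    compounds: Mapping[str, Compound],
    currency: Iterable[str] = DEFAULT_CURRENCY,
    radius: int = 1,
    signatures: Optional[Mapping[str, MoietySignature]] = None,
) -> ReactionRule:
    """Signed signature difference of a reaction over its non-currency species.

    ``signatures`` may pre-supply signatures (required for structureless
    compounds); otherwise they are computed from each compound's structure.
    Missing signatures on non-currency participants raise
    :class:`RuleExtractionError` listing the compounds.
    """
    currency = set(currency)
    int_stoich, _ = integerize(rxn.stoich)
    delta: dict[str, int] = {}
    missing: list[str] = []
    for cid, coeff in int_stoich.items():
        if cid in currency:
            continue
        sig = signatures.get(cid) if signatures else None
        if sig is None:
            try:
                sig = moiety_signature(compounds[cid], radius=radius)
            except KeyError:
                missing.append(cid)
                continue
            except (SignatureUnavailableError, StructureError):
                missing.append(cid)
                continue
        for key, n in sig.counts.items():
            delta[key] = delta.get(key, 0) + coeff * n
    if missing:
        raise RuleExtractionError(
            f"reaction {rxn.id}: no signature for non-currency participant(s) "
            + ", ".join(sorted(missing))
        )
    delta = {k: v for k, v in delta.items() if v}
    return ReactionRule(
        id=rule_id_for(delta),
        delta=delta,
        parent_reactions=(rxn.id,),
        source_ec=tuple(rxn.ec_numbers),
        radius=radius,
    )


def apply_rule(pool: Mapping[str, int], rule: ReactionRule) -> dict[str, int]:
    """Apply a rule's delta to a substrate-side signature pool.

    Raises :class:`RuleInapplicableError` naming the first deficient key when
    the pool cannot supply a consumed moiety.
    """
    out = {k: int(v) for k, v in pool.items() if v}
    for key in sorted(rule.delta):
        change = rule.delta[key]
        if change < 0 and out.get(key, 0) < -change:
            raise RuleInapplicableError(key, out.get(key, 0), -change)
    for key, change in rule.delta.items():
        out[key] = out.get(key, 0) + change
        if out[key] == 0:
            del out[key]
    return out


# ---------------------------------------------------------------------------
# Reaction strings

_ARROWS = ("<=>", "=>", "<=")
_ARROW_DIRECTION = {"<=>": "bidirectional", "=>": "forward", "<=": "reverse"}


def parse_reaction_string(text: str) -> tuple[dict[str, Fraction], str]:
    """Parse ``"1 A + 2 B <=> 1 C"`` into (stoichiometry, direction).

    Coefficients default to 1 and may be rational (``1/2`` or ``0.5``).
    A species repeated on one side, an empty side, or a missing arrow is a
    :class:`ReactionParseError`.
    """
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise ReactionParseError(f"no reaction arrow in {text!r}")
    left, right = text.split(arrow, 1)
    stoich: dict[str, Fraction] = {}

    def add_side(side: str, sign: int):
        terms = [t.strip() for t in side.split("+")]
        # Rejoin terms broken by charges written as trailing '+' (e.g. "NH4+"):
        merged: list[str] = []
        for t in terms:
            if t == "" and merged:
                merged[-1] += "+"
            else:
                merged.append(t)
        if not any(merged):
            raise ReactionParseError(f"empty side in {text!r}")
        for term in merged:
            if not term:
                raise ReactionParseError(f"dangling '+' in {text!r}")
            parts = term.split()
            if len(parts) == 1:
                coeff, cid = Fraction(1), parts[0]
            elif len(parts) == 2:
                try:
                    coeff = Fraction(parts[0])
                except ValueError:
                    raise ReactionParseError(
                        f"bad coefficient {parts[0]!r} in {text!r}"
                    ) from None
                cid = parts[1]
            else:
                raise ReactionParseError(f"cannot parse term {term!r} in {text!r}")
            if cid in stoich and (stoich[cid] > 0) == (sign > 0):
                raise ReactionParseError(
                    f"species {cid!r} repeated on one side of {text!r}"
                )
            stoich[cid] = stoich.get(cid, Fraction(0)) + sign * coeff
        return

    add_side(left, -1)
    add_side(right, +1)
    return {c: v for c, v in stoich.items() if v != 0}, _ARROW_DIRECTION[arrow]


def format_reaction_string(
    stoich: Mapping[str, Fraction], direction: str = "bidirectional"
) -> str:
    """Canonical inverse of :func:`parse_reaction_string` (unit coefficients explicit)."""
    arrow = {v: k for k, v in _ARROW_DIRECTION.items()}[direction]

    def side(items):
        return " + ".join(f"{_fmt_coeff(abs(v))} {c}" for c, v in items)

    left = side(sorted((c, v) for c, v in stoich.items() if v < 0))
    right = side(sorted((c, v) for c, v in stoich.items() if v > 0))
    return f"{left} {arrow} {right}"


def _fmt_coeff(v: Fraction) -> str:
    return str(v.numerator) if v.denominator == 1 else f"{v.numerator}/{v.denominator}"
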