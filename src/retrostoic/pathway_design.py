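"""De novo pathway design over known reactions and moiety rules (novoStoic stage).

Given an overall conversion, the search selects a multiset of steps —
database reactions used as such, or reaction rules applied to new
substrates (novel steps) — whose moiety-signature deltas sum exactly to the
signature difference of the overall conversion.  This *moiety balance* is
the linear relaxation of chemistry that makes de novo design tractable:
currency species are excluded, so every candidate step is a pure
main-chain transformation and the constraint system is one equality per
moiety key.

The MILP enumerates step multisets with integer cuts on binary support
indicators (re-orderings of one multiset are not re-reported).  Each raw
multiset is then *assembled*: steps are ordered so every intermediate is
produced before it is consumed, novel rule applications are instantiated on
concrete substrates and their products resolved against the compound index
(or materialized as hypothetical compounds), and the currency coefficients
of the novel steps are solved jointly so that the pathway's step sum equals
the overall stoichiometry exactly.  Unassemblable solutions are cut and
skipped.
"""

from __future__ import annotations

import hashlib
import warnings
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .chem_core import (
    DEFAULT_CURRENCY,
    Compound,
    MoietySignature,
    Reaction,
    ReactionRule,
    RuleInapplicableError,
    apply_rule,
    check_reaction_balance,
    integerize,
    moiety_signature,
    serialize_delta,
    signature_formula,
)
from .stoich_opt import OverallStoichiometry

__all__ = [
    "PathwayStep",
    "Pathway",
    "HypotheticalCompound",
    "ValidationReport",
    "design_pathways",
    "validate_pathway",
    "resolve_intermediate",
    "build_signature_index",
]


@dataclass
class PathwayStep:
    """One pathway step: a database reaction or a rule applied to a substrate."""

    kind: str  # "known" | "novel"
    ref_id: str  # reaction id (known) or rule id (novel)
    direction: int
    stoich: dict[str, Fraction]
    substrate: Optional[str] = None  # main substrate of a novel step
    product: Optional[str] = None
    dg_estimate: Optional[tuple[float, float]] = None

    @property
    def consumed(self) -> list[str]:
        return sorted(c for c, v in self.stoich.items() if v < 0)

    @property
    def produced(self) -> list[str]:
        return sorted(c for c, v in self.stoich.items() if v > 0)


@dataclass(frozen=True)
class HypotheticalCompound:
    """A pathway intermediate not present in the compound index.

    The formula is reconstructed from the signature centers (element plus
    attached hydrogens per moiety key); the charge is taken as zero.
    """

    id: str
    signature: MoietySignature
    formula: Mapping[str, int]


@dataclass
class Pathway:
    steps: list[PathwayStep]
    overall: OverallStoichiometry
    n_novel: int
    hypotheticals: dict[str, HypotheticalCompound] = field(default_factory=dict)

    def step_sum(self) -> dict[str, Fraction]:
        total: dict[str, Fraction] = {}
        for step in self.steps:
            for cid, v in step.stoich.items():
                total[cid] = total.get(cid, Fraction(0)) + v
        return {c: v for c, v in total.items() if v != 0}


@dataclass
class ValidationReport:
    ok: bool
    failures: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def _hypothetical_id(counts: Mapping[str, int]) -> str:
    digest = hashlib.sha256(serialize_delta(dict(counts)).encode()).hexdigest()[:10]
    return f"NOVEL_{digest}"


def build_signature_index(
    compounds: Mapping[str, Compound],
    currency: Iterable[str] = DEFAULT_CURRENCY,
    radius: int = 1,
) -> dict[str, MoietySignature]:
    """Signatures for every non-currency compound that has a structure."""
    currency = set(currency)
    index: dict[str, MoietySignature] = {}
    for cid in sorted(compounds):
        if cid in currency:
            continue
        cpd = compounds[cid]
        if cpd.structure:
            index[cid] = moiety_signature(cpd, radius=radius)
    return index


def resolve_intermediate(
    sig_counts: Mapping[str, int],
    compounds: Mapping[str, Compound],
    signatures: Mapping[str, MoietySignature],
    radius: int = 1,
) -> Union[list[str], HypotheticalCompound]:
    """Resolve a signature pool to known compound id(s) or a hypothetical.

    An exact signature match returns the matching ids (several for
    signature-degenerate isomers, for the caller to branch on); no match
    returns a :class:`HypotheticalCompound` with a formula derived from the
    signature centers.
    """
    if any(v < 0 for v in sig_counts.values()):
        raise ValueError("signature pool has negative counts")
    target = {k: v for k, v in sig_counts.items() if v}
    matches = [
        cid for cid in sorted(signatures)
        if cid in compounds and dict(signatures[cid].counts) == target
    ]
    if matches:
        return matches
    return HypotheticalCompound(
        id=_hypothetical_id(target),
        signature=MoietySignature(counts=target, radius=radius),
        formula=signature_formula(target),
    )


# ---------------------------------------------------------------------------
# Candidate construction

@dataclass
class _Candidate:
    kind: str
    ref: str
    direction: int
    delta: dict[str, int]
    stoich: Optional[dict[str, Fraction]]  # known candidates only

    @property
    def label(self) -> str:
        arrow = "" if self.direction > 0 else "~rev"
        return f"{self.ref}{arrow}"

    def consumed_mains(self, currency: set[str]) -> list[str]:
        if self.stoich is None:
            return []
        return sorted(
            c for c, v in self.stoich.items() if v < 0 and c not in currency
        )

    def produced_mains(self, currency: set[str]) -> list[str]:
        if self.stoich is None:
            return []
        return sorted(
            c for c, v in self.stoich.items() if v > 0 and c not in currency
        )


def _directed_known(
    reactions: Mapping[str, Reaction],
    compounds: Mapping[str, Compound],
    signatures: Mapping[str, MoietySignature],
    currency: set[str],
) -> list[_Candidate]:
    out: list[_Candidate] = []
    for rid in sorted(reactions):
        rxn = reactions[rid]
        delta: dict[str, int] = {}
        int_stoich, scale = integerize(rxn.stoich)
        usable = True
        for cid, coeff in int_stoich.items():
            if cid in currency:
                continue
            sig = signatures.get(cid)
            if sig is None:
                usable = False
                break
            for key, n in sig.counts.items():
                delta[key] = delta.get(key, 0) + coeff * n
        if not usable or scale != 1:
            continue
        delta = {k: v for k, v in delta.items() if v}
        if not delta:
            continue  # pure currency shuffling cannot advance the main chain
        dirs = {"forward": [1], "reverse": [-1], "bidirectional": [1, -1]}[rxn.direction]
        for d in dirs:
            out.append(
                _Candidate(
                    kind="known",
                    ref=rid,
                    direction=d,
                    delta={k: d * v for k, v in delta.items()},
                    stoich={c: d * v for c, v in rxn.stoich.items()},
                )
            )
    return out


# ---------------------------------------------------------------------------
# Assembly

class _Assembler:
    """Order a step multiset and instantiate novel rule applications."""

    def __init__(
        self,
        compounds: Mapping[str, Compound],
        signatures: Mapping[str, MoietySignature],
        currency: set[str],
        radius: int,
    ):
        self.compounds = compounds
        self.signatures = dict(signatures)
        self.currency = currency
        self.radius = radius
        self.hypotheticals: dict[str, HypotheticalCompound] = {}
        self._failed: set = set()

    def _sig_of(self, cid: str) -> Optional[MoietySignature]:
        if cid in self.signatures:
            return self.signatures[cid]
        hyp = self.hypotheticals.get(cid)
        return hyp.signature if hyp else None

    def assemble(
        self,
        multiset: list[tuple[_Candidate, int]],
        start: Counter,
        goal: Counter,
    ) -> Optional[list[tuple[_Candidate, Optional[str], Optional[str]]]]:
        """First valid ordering as (candidate, substrate, product) triples."""
        remaining = Counter()
        cand_by_idx: dict[int, _Candidate] = {}
        # deterministic step order regardless of solver variable permutation
        ordered_multiset = sorted(
            multiset, key=lambda item: (item[0].kind, item[0].ref, item[0].direction)
        )
        for idx, (cand, count) in enumerate(ordered_multiset):
            cand_by_idx[idx] = cand
            remaining[idx] = count
        self._failed.clear()
        return self._backtrack(remaining, Counter(start), goal, cand_by_idx)

    def _backtrack(self, remaining, pool, goal, cand_by_idx):
        if not +remaining:
            return [] if +pool == +goal else None
        state = (frozenset(remaining.items()), frozenset((+pool).items()))
        if state in self._failed:
            return None
        for idx in sorted(remaining):
            if remaining[idx] <= 0:
                continue
            cand = cand_by_idx[idx]
            if cand.kind == "known":
                placement = self._try_known(cand, pool)
                if placement is None:
                    continue
                new_pool = placement
                remaining[idx] -= 1
                rest = self._backtrack(remaining, new_pool, goal, cand_by_idx)
                remaining[idx] += 1
                if rest is not None:
                    return [(cand, None, None)] + rest
            else:
                for substrate, product, new_pool in self._novel_placements(cand, pool):
                    remaining[idx] -= 1
                    rest = self._backtrack(remaining, new_pool, goal, cand_by_idx)
                    remaining[idx] += 1
                    if rest is not None:
                        return [(cand, substrate, product)] + rest
        self._failed.add(state)
        return None

    def _try_known(self, cand: _Candidate, pool: Counter) -> Optional[Counter]:
        need = {
            cid: int(-v)
            for cid, v in cand.stoich.items()
            if v < 0 and cid not in self.currency
        }
        if any(pool.get(cid, 0) < n for cid, n in need.items()):
            return None
        new_pool = Counter(pool)
        for cid, n in need.items():
            new_pool[cid] -= n
        for cid, v in cand.stoich.items():
            if v > 0 and cid not in self.currency:
                new_pool[cid] += int(v)
        return +new_pool

    def _novel_placements(self, cand: _Candidate, pool: Counter):
        rule = ReactionRule(id=cand.ref, delta=cand.delta)
        for substrate in sorted(+pool):
            sig = self._sig_of(substrate)
            if sig is None:
                continue
            try:
                new_counts = apply_rule(dict(sig.counts), rule)
            except RuleInapplicableError:
                continue
            resolved = resolve_intermediate(
                new_counts, self.compounds, self.signatures, radius=self.radius
            )
            if isinstance(resolved, HypotheticalCompound):
                self.hypotheticals.setdefault(resolved.id, resolved)
                products = [resolved.id]
            else:
                products = resolved
            for product in products:
                if product == substrate:
                    continue
                new_pool = Counter(pool)
                new_pool[substrate] -= 1
                new_pool[product] += 1
                yield substrate, product, +new_pool


# ---------------------------------------------------------------------------
# Currency completion

def _complete_currency(
    ordered: Sequence[tuple[_Candidate, Optional[str], Optional[str]]],
    overall_int: Mapping[str, int],
    compounds: Mapping[str, Compound],
    hypotheticals: Mapping[str, HypotheticalCompound],
    currency: set[str],
) -> Optional[list[dict[str, Fraction]]]:
    """Per-step stoichiometries whose total equals the overall exactly.

    Known steps carry their database stoichiometry.  Each novel step's
    currency coefficients are free integers, constrained per step by
    element/charge balance and globally by the requirement that all steps
    sum to the overall conversion; the minimal total |coefficient| solution
    is taken.  Returns None when no completion exists.
    """

    def formula_charge(cid: str) -> tuple[Mapping[str, int], int]:
        if cid in compounds:
            return compounds[cid].formula, compounds[cid].charge
        hyp = hypotheticals[cid]
        return hyp.formula, 0

    curr_ids = sorted(c for c in currency if c in compounds)
    stoichs: list[dict[str, Fraction]] = []
    novel_idx: list[int] = []
    known_total: Counter = Counter()
    for i, (cand, substrate, product) in enumerate(ordered):
        if cand.kind == "known":
            stoichs.append(dict(cand.stoich))
            for cid, v in cand.stoich.items():
                known_total[cid] += v
        else:
            stoichs.append({substrate: Fraction(-1), product: Fraction(1)})
            novel_idx.append(i)

    required = {
        c: Fraction(overall_int.get(c, 0)) - known_total.get(c, Fraction(0))
        for c in curr_ids
    }
    if not novel_idx:
        # also verify non-currency totals (pool mechanics guarantee them)
        for c in curr_ids:
            if required[c] != 0:
                return None
        return stoichs

    # main-pair totals of novel steps must absorb `required` via currency
    elements = sorted(
        {e for c in curr_ids for e in compounds[c].formula}
        | {
            e
            for i in novel_idx
            for cid in stoichs[i]
            for e in formula_charge(cid)[0]
        }
    )
    n_rows_step = len(elements) + 1
    nn, ncu = len(novel_idx), len(curr_ids)
    nvar = nn * ncu
    # v = vp - vn, integers >= 0; objective min sum(vp+vn)
    ntot = 2 * nvar
    rows, lbs, ubs = [], [], []

    def var(i_local: int, j: int) -> int:
        return i_local * ncu + j

    for i_local, i in enumerate(novel_idx):
        resid = np.zeros(n_rows_step)
        for cid, v in stoichs[i].items():
            f, q = formula_charge(cid)
            for r, e in enumerate(elements):
                resid[r] += float(v) * f.get(e, 0)
            resid[-1] += float(v) * q
        for r in range(n_rows_step):
            row = np.zeros(ntot)
            for j, c in enumerate(curr_ids):
                f, q = formula_charge(c)
                coef = float(f.get(elements[r], 0)) if r < len(elements) else float(q)
                row[var(i_local, j)] = coef
                row[nvar + var(i_local, j)] = -coef
            rows.append(row)
            lbs.append(-resid[r])
            ubs.append(-resid[r])
    for j, c in enumerate(curr_ids):
        row = np.zeros(ntot)
        for i_local in range(nn):
            row[var(i_local, j)] = 1.0
            row[nvar + var(i_local, j)] = -1.0
        rows.append(row)
        lbs.append(float(required[c]))
        ubs.append(float(required[c]))

    bound = 10.0 + max((abs(float(v)) for v in overall_int.values()), default=0.0)
    res = milp(
        np.ones(ntot),
        constraints=LinearConstraint(np.vstack(rows), lbs, ubs),
        integrality=np.ones(ntot),
        bounds=Bounds(np.zeros(ntot), np.full(ntot, bound)),
    )
    if res.status != 0 or res.x is None:
        return None
    v = np.round(res.x[:nvar] - res.x[nvar:]).astype(int)
    for i_local, i in enumerate(novel_idx):
        for j, c in enumerate(curr_ids):
            val = int(v[var(i_local, j)])
            if val:
                stoichs[i][c] = stoichs[i].get(c, Fraction(0)) + val
    return stoichs


# ---------------------------------------------------------------------------
# Main search

def design_pathways(
    overall: OverallStoichiometry,
    reactions: Mapping[str, Reaction],
    rules: Mapping[str, ReactionRule],
    compounds: Mapping[str, Compound],
    signatures: Optional[Mapping[str, MoietySignature]] = None,
    currency: Iterable[str] = DEFAULT_CURRENCY,
    max_steps: int = 10,
    max_novel: int = 2,
    n_pathways: int = 10,
    seed: int = 0,
    radius: int = 1,
    thermo_model=None,
    dg_cap: float = 25.0,
    max_attempts: Optional[int] = None,
) -> list[Pathway]:
    """Enumerate validated pathways realizing an overall conversion.

    The MILP selects step multisets under exact moiety balance, at most
    ``max_steps`` steps and ``max_novel`` novel (rule-derived) steps;
    multisets are enumerated with integer cuts on their support, assembled
    into ordered pathways, completed with currency coefficients, and
    validated.  ``seed`` only permutes solver variable order; the returned
    list is post-sorted by (step count, novel count, step labels).

    When ``thermo_model`` (a fitted group-contribution model) is given,
    directed candidates with predicted ΔrG′° above ``dg_cap`` kJ/mol are
    dropped — concentration tilting can recover roughly 2RT·ln(10^3) ≈ 34
    kJ/mol, so a default of +25 keeps plausibly drivable directions only.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    currency = set(currency)
    if signatures is None:
        signatures = build_signature_index(compounds, currency=currency, radius=radius)

    overall_coeffs_int, scale = integerize(overall.coeffs)
    overall_int = {c: v for c, v in overall_coeffs_int.items() if v}
    overall_scaled = OverallStoichiometry(
        coeffs={c: Fraction(v) for c, v in overall_int.items()},
        yield_=overall.yield_,
        support=overall.support,
        dg_estimate=overall.dg_estimate,
    )

    # required moiety balance: sum over steps = overall signature difference
    b: dict[str, int] = {}
    for cid, coeff in overall_int.items():
        if cid in currency:
            continue
        sig = signatures.get(cid)
        if sig is None:
            raise ValueError(
                f"overall species {cid!r} has no signature and is not currency"
            )
        for key, n in sig.counts.items():
            b[key] = b.get(key, 0) + coeff * n
    b = {k: v for k, v in b.items() if v}

    candidates = _directed_known(reactions, compounds, signatures, currency)
    for rule_id in sorted(rules):
        rule = rules[rule_id]
        if not rule.delta:
            continue
        candidates.append(
            _Candidate(
                kind="novel",
                ref=rule_id,
                direction=1,
                delta=dict(rule.delta),
                stoich=None,
            )
        )

    if thermo_model is not None:
        from .thermo import predict_reaction_dg

        candidates = [
            c for c in candidates
            if predict_reaction_dg(c.delta, thermo_model).mean <= dg_cap
        ]

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))
    candidates = [candidates[i] for i in order]

    keys = sorted(set(b) | {k for c in candidates for k in c.delta})
    nc = len(candidates)
    if nc == 0:
        warnings.warn("no usable step candidates; returning no pathways", stacklevel=2)
        return []

    reachable = {k for c in candidates for k in c.delta}
    untouched = sorted(k for k in b if k not in reachable)
    if untouched:
        warnings.warn(
            "moiety requirement cannot be met; no candidate changes key(s): "
            + ", ".join(untouched),
            stacklevel=2,
        )
        return []

    # layout: [u (nc int), y (nc binary)]
    ntot = 2 * nc
    rows, lbs, ubs = [], [], []
    for key in keys:
        row = np.zeros(ntot)
        for j, cand in enumerate(candidates):
            row[j] = cand.delta.get(key, 0)
        rows.append(row)
        lbs.append(float(b.get(key, 0)))
        ubs.append(float(b.get(key, 0)))
    row = np.zeros(ntot); row[:nc] = 1.0
    rows.append(row); lbs.append(-np.inf); ubs.append(float(max_steps))
    row = np.zeros(ntot)
    for j, cand in enumerate(candidates):
        if cand.kind == "novel":
            row[j] = 1.0
    rows.append(row); lbs.append(-np.inf); ubs.append(float(max_novel))
    for j in range(nc):
        row = np.zeros(ntot); row[j] = 1.0; row[nc + j] = -float(max_steps)
        rows.append(row); lbs.append(-np.inf); ubs.append(0.0)
        row = np.zeros(ntot); row[nc + j] = 1.0; row[j] = -1.0
        rows.append(row); lbs.append(-np.inf); ubs.append(0.0)

    lo = np.zeros(ntot)
    hi = np.concatenate([np.full(nc, float(max_steps)), np.ones(nc)])
    integrality = np.ones(ntot)
    eps = 1.0 / (2.0 * nc + 2.0)
    c_obj = np.zeros(ntot)
    for j, cand in enumerate(candidates):
        c_obj[j] = 1.0 + (0.5 if cand.kind == "novel" else 0.0)
    c_obj[nc:] = eps

    assembler = _Assembler(compounds, signatures, currency, radius)
    start = Counter(
        {cid: -v for cid, v in overall_int.items() if v < 0 and cid not in currency}
    )
    goal = Counter(
        {cid: v for cid, v in overall_int.items() if v > 0 and cid not in currency}
    )

    pathways: list[Pathway] = []
    cut_rows: list[np.ndarray] = []
    cut_ubs: list[float] = []
    attempts = max_attempts if max_attempts is not None else max(20, 10 * n_pathways)
    for _ in range(attempts):
        if len(pathways) >= n_pathways:
            break
        res = milp(
            c_obj,
            constraints=LinearConstraint(
                np.vstack(rows + cut_rows), lbs + [-np.inf] * len(cut_rows),
                ubs + cut_ubs,
            ),
            integrality=integrality,
            bounds=Bounds(lo, hi),
        )
        if res.status != 0 or res.x is None:
            break
        u = np.round(res.x[:nc]).astype(int)
        support = np.where(u > 0)[0]
        # integer cut: this support set may not reappear in full
        cut = np.zeros(ntot)
        cut[nc:] = -1.0
        for j in support:
            cut[nc + j] = 1.0
        cut_rows.append(cut)
        cut_ubs.append(float(len(support)) - 1.0)

        multiset = [(candidates[j], int(u[j])) for j in support]
        ordered = assembler.assemble(multiset, start, goal)
        if ordered is None:
            continue
        stoichs = _complete_currency(
            ordered, overall_int, compounds, assembler.hypotheticals, currency
        )
        if stoichs is None:
            continue
        steps = [
            PathwayStep(
                kind=cand.kind,
                ref_id=cand.ref,
                direction=cand.direction,
                stoich=stoich,
                substrate=substrate,
                product=product,
            )
            for (cand, substrate, product), stoich in zip(ordered, stoichs)
        ]
        used_hyps = {
            cid
            for step in steps
            for cid in step.stoich
            if cid in assembler.hypotheticals
        }
        pw = Pathway(
            steps=steps,
            overall=overall_scaled,
            n_novel=sum(1 for s in steps if s.kind == "novel"),
            hypotheticals={
                cid: assembler.hypotheticals[cid] for cid in sorted(used_hyps)
            },
        )
        if validate_pathway(pw, compounds, currency=currency).ok:
            pathways.append(pw)

    pathways.sort(
        key=lambda p: (
            len(p.steps),
            p.n_novel,
            tuple(s.ref_id for s in p.steps),
        )
    )
    return pathways


def validate_pathway(
    pw: Pathway,
    compounds: Mapping[str, Compound],
    currency: Iterable[str] = DEFAULT_CURRENCY,
) -> ValidationReport:
    """Check step-sum equality, per-step balance, and producibility ordering."""
    if not pw.steps:
        raise ValueError("pathway has no steps")
    currency = set(currency)
    failures: list[str] = []

    total = pw.step_sum()
    expected = {c: v for c, v in pw.overall.coeffs.items() if v != 0}
    if total != expected:
        failures.append(
            f"step sum {_fmt(total)} differs from overall {_fmt(expected)}"
        )

    index = dict(compounds)
    for cid, hyp in pw.hypotheticals.items():
        index[cid] = Compound(id=cid, formula=dict(hyp.formula), charge=0)
    for i, step in enumerate(pw.steps):
        rxn = Reaction(id=f"step{i + 1}", stoich=dict(step.stoich))
        try:
            report = check_reaction_balance(rxn, index)
        except KeyError as exc:
            failures.append(f"step {i + 1}: {exc}")
            continue
        if not report.balanced:
            failures.append(
                f"step {i + 1} unbalanced: residuals {dict(report.element_residuals)}, "
                f"charge {report.charge_residual}"
            )

    pool = Counter(
        {
            cid: int(-v)
            for cid, v in pw.overall.coeffs.items()
            if v < 0 and cid not in currency
        }
    )
    for i, step in enumerate(pw.steps):
        for cid, v in step.stoich.items():
            if v < 0 and cid not in currency:
                if pool.get(cid, 0) < -v:
                    failures.append(
                        f"step {i + 1} consumes {cid} before it is produced"
                    )
                pool[cid] -= int(-v)
        for cid, v in step.stoich.items():
            if v > 0 and cid not in currency:
                pool[cid] += int(v)

    return ValidationReport(ok=not failures, failures=failures)


def _fmt(stoich: Mapping[str, Fraction]) -> str:
    return "{" + ", ".join(f"{c}: {v}" for c, v in sorted(stoich.items())) + "}"
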