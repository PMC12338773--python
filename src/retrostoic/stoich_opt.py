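"""Optimal overall-conversion stoichiometry (the optStoic stage).

Given a source and target compound and a set of allowed co-metabolites,
find the net conversion  ``1 source + co-substrates -> y target +
co-products``  that maximizes the molar yield ``y`` subject to elemental
and charge balance (and optionally an energy cap on the weighted sum of
formation energies).  The yield itself comes from a continuous LP; the
reported stoichiometries are then re-solved as a MILP with integer
coefficients so that printed conversions look like chemical equations.
Alternative optima are enumerated with integer cuts on the binary support
pattern of the co-metabolites, so each returned solution uses a distinct
set of species.

Redox couples (e.g. NAD(P)H/NAD(P)+) are modeled with a single signed
magnitude variable so the pair stays stoichiometrically locked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .chem_core import Compound, Reaction, check_reaction_balance

__all__ = [
    "CoMetaboliteSpec",
    "OverallStoichiometry",
    "InfeasibleBalanceError",
    "UnboundedYieldError",
    "SolverError",
    "max_yield_stoichiometry",
    "enumerate_stoichiometries",
]


class InfeasibleBalanceError(ValueError):
    pass


class UnboundedYieldError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


@dataclass
class CoMetaboliteSpec:
    """Which co-metabolites the overall conversion may consume or produce.

    ``side_constraint`` restricts a species to ``"consume"`` or
    ``"produce"`` (default ``"either"``); ``couples`` lists id pairs whose
    coefficients are locked to equal magnitude and opposite role;
    ``bounds`` caps |coefficient| per id, with ``coefficient_bound`` as the
    default cap used by the integer solve.
    """

    allowed: set[str] = field(default_factory=set)
    side_constraint: dict[str, str] = field(default_factory=dict)
    couples: list[tuple[str, str]] = field(default_factory=list)
    bounds: dict[str, int] = field(default_factory=dict)
    coefficient_bound: int = 10

    def all_ids(self) -> set[str]:
        ids = set(self.allowed)
        for a, b in self.couples:
            ids |= {a, b}
        return ids


@dataclass
class OverallStoichiometry:
    """A balanced net conversion; the source coefficient is fixed at -1."""

    coeffs: dict[str, Fraction]
    yield_: Fraction
    support: int
    dg_estimate: Optional[tuple[float, float]] = None

    @property
    def consumed(self) -> list[str]:
        return sorted(c for c, v in self.coeffs.items() if v < 0)

    @property
    def produced(self) -> list[str]:
        return sorted(c for c, v in self.coeffs.items() if v > 0)

    def as_reaction(self, rid: str = "overall") -> Reaction:
        return Reaction(id=rid, stoich=dict(self.coeffs), direction="forward")


# ---------------------------------------------------------------------------

def _species_vector(cpd: Compound, elements: Sequence[str]) -> np.ndarray:
    v = np.array([float(cpd.formula.get(e, 0)) for e in elements] + [float(cpd.charge)])
    return v


def _problem_elements(compounds: Sequence[Compound]) -> list[str]:
    els: set[str] = set()
    for c in compounds:
        els |= set(c.formula)
    return sorted(els)


def _check_species(compounds: Mapping[str, Compound], ids: Sequence[str]) -> None:
    for cid in ids:
        if cid not in compounds:
            raise KeyError(f"unknown compound id {cid!r}")
        if compounds[cid].is_generic:
            raise ValueError(f"generic compound {cid!r} cannot enter optimization")


def _single_bounds(spec: CoMetaboliteSpec, cid: str, cap: float):
    lo, hi = -cap, cap
    side = spec.side_constraint.get(cid, "either")
    if side == "consume":
        hi = 0.0
    elif side == "produce":
        lo = 0.0
    elif side != "either":
        raise ValueError(f"bad side constraint {side!r} for {cid!r}")
    if cid in spec.bounds:
        b = float(spec.bounds[cid])
        lo, hi = max(lo, -b), min(hi, b)
    return lo, hi


def max_yield_stoichiometry(
    source: str,
    target: str,
    compounds: Mapping[str, Compound],
    spec: Optional[CoMetaboliteSpec] = None,
    energy_cap: Optional[float] = None,
    formation_dg: Optional[Mapping[str, float]] = None,
) -> OverallStoichiometry:
    """Maximum-yield overall conversion from ``source`` to ``target``.

    The returned stoichiometry is the minimal-total-coefficient integral
    solution at the optimal yield.  Raises
    :class:`InfeasibleBalanceError` (naming the unbalançable element when
    identifiable) or :class:`UnboundedYieldError` when an unbounded
    co-metabolite makes the yield diverge.
    """
    sols = enumerate_stoichiometries(
        source, target, compounds, spec=spec, k=1,
        energy_cap=energy_cap, formation_dg=formation_dg,
    )
    if not sols:
        raise InfeasibleBalanceError(
            f"no balanced conversion from {source!r} to {target!r}"
        )
    return sols[0]


def enumerate_stoichiometries(
    source: str,
    target: str,
    compounds: Mapping[str, Compound],
    spec: Optional[CoMetaboliteSpec] = None,
    k: int = 5,
    objective: str = "max-yield-then-min-support",
    energy_cap: Optional[float] = None,
    formation_dg: Optional[Mapping[str, float]] = None,
    max_support: Optional[int] = None,
    integer_yield: bool = False,
) -> list[OverallStoichiometry]:
    """Enumerate up to ``k`` optimal-yield stoichiometries with distinct support.

    Solutions are pairwise distinct in which co-metabolites they use
    (integer cuts on binary support indicators) and are returned sorted by
    (yield desc, support asc, total |coefficient| asc, lexicographic).
    ``objective`` selects the discovery preference:
    ``"max-yield-then-min-support"`` favors few distinct species,
    ``"min-total-coefficients"`` favors small coefficient totals.

    ``integer_yield`` restricts the conversion to whole target molecules
    per source molecule, the convention used for printable overall
    equations; the reported yield is then the largest feasible integer at
    or below the continuous optimum.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if objective not in ("max-yield-then-min-support", "min-total-coefficients"):
        raise ValueError(f"unknown objective {objective!r}")
    spec = spec or CoMetaboliteSpec()
    if source in spec.all_ids() or target in spec.all_ids():
        raise ValueError("source/target must not appear in the co-metabolite spec")
    _check_species(compounds, [source, target, *sorted(spec.all_ids())])

    if source == target:
        return [OverallStoichiometry(coeffs={}, yield_=Fraction(1), support=0)]

    couple_ids = {cid for pair in spec.couples for cid in pair}
    singles = sorted(spec.allowed - couple_ids - {source, target})
    couples = [tuple(pair) for pair in spec.couples]
    species = [compounds[source], compounds[target]]
    species += [compounds[c] for c in singles]
    species += [compounds[c] for pair in couples for c in pair]
    elements = _problem_elements(species)
    n_rows = len(elements) + 1  # + charge

    src_v = _species_vector(compounds[source], elements)
    tgt_v = _species_vector(compounds[target], elements)
    single_vs = [_species_vector(compounds[c], elements) for c in singles]
    couple_vs = [
        _species_vector(compounds[a], elements) - _species_vector(compounds[b], elements)
        for a, b in couples
    ]

    ns, nc = len(singles), len(couples)
    ncols = 1 + ns + nc  # t, singles, couples

    # --- continuous LP for the yield -------------------------------------
    A_eq = np.zeros((n_rows, ncols))
    A_eq[:, 0] = tgt_v
    for j, v in enumerate(single_vs):
        A_eq[:, 1 + j] = v
    for j, v in enumerate(couple_vs):
        A_eq[:, 1 + ns + j] = v
    b_eq = src_v.copy()

    lp_bounds = [(0.0, None)]
    for cid in singles:
        lo, hi = _single_bounds(spec, cid, np.inf)
        lp_bounds.append((None if lo == -np.inf else lo, None if hi == np.inf else hi))
    for a, b in couples:
        cap = min(spec.bounds.get(a, np.inf), spec.bounds.get(b, np.inf))
        lp_bounds.append((None if cap == np.inf else -cap, None if cap == np.inf else cap))

    c_obj = np.zeros(ncols)
    c_obj[0] = -1.0
    A_ub, b_ub = None, None
    if energy_cap is not None:
        if formation_dg is None:
            raise ValueError("energy_cap requires formation_dg estimates")
        row = np.zeros(ncols)
        row[0] = formation_dg.get(target, 0.0)
        for j, cid in enumerate(singles):
            row[1 + j] = formation_dg.get(cid, 0.0)
        for j, (a, b) in enumerate(couples):
            row[1 + ns + j] = formation_dg.get(a, 0.0) - formation_dg.get(b, 0.0)
        A_ub = row.reshape(1, -1)
        b_ub = np.array([energy_cap + formation_dg.get(source, 0.0)])

    res = linprog(c_obj, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=lp_bounds, method="highs")
    if res.status == 3:
        unbounded = [c for c in singles if c not in spec.bounds]
        raise UnboundedYieldError(
            "yield is unbounded; co-metabolites without bounds: "
            + (", ".join(unbounded) or "(none identified)")
        )
    if res.status != 0 or res.x is None:
        raise InfeasibleBalanceError(_infeasibility_diagnostic(
            elements, src_v, tgt_v, single_vs, couple_vs))
    lp_yield = float(res.x[0])
    if lp_yield <= 1e-9:
        raise InfeasibleBalanceError(
            "maximum yield is zero: " + _infeasibility_diagnostic(
                elements, src_v, tgt_v, single_vs, couple_vs)
        )
    ryield = Fraction(lp_yield).limit_denominator(24)
    if abs(float(ryield) - lp_yield) > 1e-6:
        ryield = Fraction(lp_yield).limit_denominator(10_000)

    # --- integer enumeration at the optimal yield ------------------------
    B = float(spec.coefficient_bound)
    nvar = ns + nc
    if nvar == 0:
        coeffs = {source: Fraction(-1), target: ryield}
        return [OverallStoichiometry(coeffs=coeffs, yield_=ryield, support=0)]

    def enumerate_at(num: int, den: int) -> list[OverallStoichiometry]:
        # Each co-metabolite coefficient is split as x = xp - xn with binary
        # use indicators: xp <= B*yp, xp >= yp (and likewise for xn), and
        # yp + yn <= 1, so yp + yn is exactly the "species used" indicator
        # that the integer cuts act on.
        # layout: [xp (nvar), xn (nvar), yp (nvar), yn (nvar)]
        ntot = 4 * nvar
        idx_p, idx_n, idx_yp, idx_yn = 0, nvar, 2 * nvar, 3 * nvar

        def coef_row(row: np.ndarray, j: int, value: float) -> None:
            row[idx_p + j] = value
            row[idx_n + j] = -value

        rows, lbs, ubs = [], [], []
        # balance: sum (xp-xn)*n_e = den*n_src - num*n_tgt
        rhs = den * src_v - num * tgt_v
        for r in range(n_rows):
            row = np.zeros(ntot)
            for j, v in enumerate(single_vs):
                coef_row(row, j, v[r])
            for j, v in enumerate(couple_vs):
                coef_row(row, ns + j, v[r])
            rows.append(row); lbs.append(rhs[r]); ubs.append(rhs[r])
        for j in range(nvar):
            for part, yind in ((idx_p, idx_yp), (idx_n, idx_yn)):
                row = np.zeros(ntot); row[part + j] = 1; row[yind + j] = -B
                rows.append(row); lbs.append(-np.inf); ubs.append(0.0)
                row = np.zeros(ntot); row[yind + j] = 1; row[part + j] = -1
                rows.append(row); lbs.append(-np.inf); ubs.append(0.0)
            row = np.zeros(ntot); row[idx_yp + j] = 1; row[idx_yn + j] = 1
            rows.append(row); lbs.append(-np.inf); ubs.append(1.0)
        if energy_cap is not None:
            row = np.zeros(ntot)
            for j, cid in enumerate(singles):
                coef_row(row, j, formation_dg.get(cid, 0.0))
            for j, (a, b) in enumerate(couples):
                coef_row(row, ns + j,
                         formation_dg.get(a, 0.0) - formation_dg.get(b, 0.0))
            rows.append(row); lbs.append(-np.inf)
            ubs.append(den * (energy_cap + formation_dg.get(source, 0.0))
                       - num * formation_dg.get(target, 0.0))
        if max_support is not None:
            row = np.zeros(ntot)
            for j in range(nvar):
                w = 1.0 if j < ns else 2.0  # a couple occupies two species
                row[idx_yp + j] = w
                row[idx_yn + j] = w
            rows.append(row); lbs.append(-np.inf); ubs.append(float(max_support))

        lo = np.zeros(ntot); hi = np.zeros(ntot)
        for j, cid in enumerate(singles):
            l, h = _single_bounds(spec, cid, B)
            hi[idx_p + j] = max(0.0, h)   # positive part = produced amount
            hi[idx_n + j] = max(0.0, -l)  # negative part = consumed amount
        for j, (a, b) in enumerate(couples):
            cap = min(B, spec.bounds.get(a, B), spec.bounds.get(b, B))
            hi[idx_p + ns + j] = cap
            hi[idx_n + ns + j] = cap
        hi[idx_yp:idx_yp + nvar] = 1.0
        hi[idx_yn:idx_yn + nvar] = 1.0

        integrality = np.ones(ntot)

        eps = 1.0 / (2.0 * nvar + 2.0)
        c = np.zeros(ntot)
        if objective == "max-yield-then-min-support":
            c[idx_yp:] = 1.0
            c[idx_p:idx_p + 2 * nvar] = eps / max(B, 1.0)
        else:
            c[idx_p:idx_p + 2 * nvar] = 1.0
            c[idx_yp:] = eps

        cut_rows: list[np.ndarray] = []
        cut_ubs: list[float] = []
        found: list[OverallStoichiometry] = []
        for _ in range(k):
            all_rows = np.vstack(rows + cut_rows)
            all_lbs = lbs + [-np.inf] * len(cut_rows)
            all_ubs = ubs + cut_ubs
            res = milp(
                c,
                constraints=LinearConstraint(all_rows, all_lbs, all_ubs),
                integrality=integrality,
                bounds=Bounds(lo, hi),
            )
            if res.status != 0 or res.x is None:
                break
            xp = np.round(res.x[idx_p:idx_p + nvar]).astype(int)
            xn = np.round(res.x[idx_n:idx_n + nvar]).astype(int)
            x = xp - xn
            used = np.abs(x) > 0

            coeffs: dict[str, Fraction] = {
                source: Fraction(-1), target: Fraction(num, den)
            }
            support = 0
            for j, cid in enumerate(singles):
                if x[j]:
                    coeffs[cid] = Fraction(int(x[j]), den)
                    support += 1
            for j, (a, b) in enumerate(couples):
                v = int(x[ns + j])
                if v:
                    coeffs[a] = Fraction(v, den)
                    coeffs[b] = Fraction(-v, den)
                    support += 2
            found.append(
                OverallStoichiometry(
                    coeffs=coeffs, yield_=Fraction(num, den), support=support
                )
            )
            # exclude this support set (in either sign role) from later solves
            cut = np.zeros(ntot)
            for j in range(nvar):
                sgn = 1.0 if used[j] else -1.0
                cut[idx_yp + j] = sgn
                cut[idx_yn + j] = sgn
            cut_rows.append(cut)
            cut_ubs.append(float(used.sum()) - 1.0)
        return found

    if integer_yield:
        solutions = []
        for t_int in range(int(np.floor(lp_yield + 1e-9)), 0, -1):
            solutions = enumerate_at(t_int, 1)
            if solutions:
                break
    else:
        solutions = enumerate_at(ryield.numerator, ryield.denominator)

    solutions.sort(
        key=lambda s: (
            -s.yield_,
            s.support,
            sum(abs(v) for c_, v in s.coeffs.items() if c_ not in (source, target)),
            tuple(sorted((c_, str(v)) for c_, v in s.coeffs.items())),
        )
    )
    return solutions


def _infeasibility_diagnostic(elements, src_v, tgt_v, single_vs, couple_vs) -> str:
    labels = list(elements) + ["charge"]
    culprits = []
    for r, lab in enumerate(labels):
        movable = any(abs(v[r]) > 0 for v in single_vs + couple_vs)
        if not movable and abs(src_v[r]) > 0 and abs(tgt_v[r]) == 0:
            culprits.append(lab)
        if not movable and abs(tgt_v[r]) > 0 and abs(src_v[r]) == 0:
            culprits.append(lab)
    if culprits:
        return "cannot balance " + ", ".join(sorted(set(culprits)))
    return "balance equations are infeasible for every allowed co-metabolite set"
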