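"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's solver paths: the
stoichiometry oracle enumerates integer coefficient vectors directly, and
the pathway oracle enumerates ordered reaction sequences by depth-first
search over compound pools.
"""

from __future__ import annotations

import itertools
from collections import Counter
from fractions import Fraction

import numpy as np
import pytest

from retrostoic.chem_core import Compound, parse_formula
from retrostoic.fixtures import make_hxt_demo


@pytest.fixture(scope="session")
def demo():
    return make_hxt_demo()


@pytest.fixture(scope="session")
def small_compounds():
    C = lambda i, f, q=0, **kw: Compound(id=i, formula=parse_formula(f), charge=q, **kw)
    return {
        c.id: c
        for c in [
            C("tyr", "C9H11NO3"),
            C("hxt", "C8H10O3"),
            C("h", "H", 1),
            C("h2o2", "H2O2"),
            C("nh4", "NH4", 1),
            C("co2", "CO2"),
            C("o2", "O2"),
            C("h2o", "H2O"),
            C("nadh", "C21H27N7O14P2", -2),
            C("nad", "C21H26N7O14P2", -1),
            C("glc", "C6H12O6"),
            C("etoh", "C2H6O"),
            C("atp", "C10H12N5O13P3", -4),
            C("adp", "C10H12N5O10P2", -3),
            C("pi", "HO4P", -2),
        ]
    }


def brute_force_max_yield(source, target, compounds, allowed, bound=6, max_t=6):
    """Exhaustive integer search for the best target yield per unit source.

    Scans target coefficients t = max_t..1 and every co-metabolite integer
    vector with |coefficient| <= bound; returns the largest t for which the
    element/charge balance closes exactly, with one witness vector.
    """
    species = [source, target, *allowed]
    elements = sorted({e for s in species for e in compounds[s].formula})

    def vec(cid):
        c = compounds[cid]
        return np.array(
            [c.formula.get(e, 0) for e in elements] + [c.charge], dtype=np.int64
        )

    src, tgt = vec(source), vec(target)
    co = np.stack([vec(c) for c in allowed]) if allowed else np.zeros((0, len(src)))
    rng = range(-bound, bound + 1)
    for t in range(max_t, 0, -1):
        base = t * tgt - src
        for combo in itertools.product(rng, repeat=len(allowed)):
            resid = base + np.asarray(combo, dtype=np.int64) @ co
            if not resid.any():
                return t, dict(zip(allowed, combo))
    return None, None


def dfs_pathway_multisets(reactions, compounds, overall, currency, max_steps):
    """All step multisets forming a valid ordered pathway, by exhaustive DFS.

    A sequence is valid when each step's non-currency reactants are
    available in the running pool (seeded with the overall's consumed
    species) and the full stoichiometric sum over the sequence equals the
    overall coefficients exactly.
    """
    currency = set(currency)
    coeffs = {c: Fraction(v) for c, v in overall.coeffs.items()}
    start = Counter(
        {c: int(-v) for c, v in coeffs.items() if v < 0 and c not in currency}
    )
    goal = Counter(
        {c: int(v) for c, v in coeffs.items() if v > 0 and c not in currency}
    )
    directed = []
    for rid in sorted(reactions):
        rxn = reactions[rid]
        dirs = {"forward": [1], "reverse": [-1], "bidirectional": [1, -1]}[rxn.direction]
        for d in dirs:
            directed.append((rid, d, {c: d * v for c, v in rxn.stoich.items()}))

    results: set = set()

    def recurse(pool, total, used):
        if +pool == +goal:
            net = {c: v for c, v in total.items() if v != 0}
            if net == {c: v for c, v in coeffs.items() if v != 0}:
                results.add(frozenset(Counter(used).items()))
        if len(used) >= max_steps:
            return
        for rid, d, stoich in directed:
            need = {
                c: int(-v) for c, v in stoich.items() if v < 0 and c not in currency
            }
            if any(pool.get(c, 0) < n for c, n in need.items()):
                continue
            new_pool = Counter(pool)
            for c, n in need.items():
                new_pool[c] -= n
            for c, v in stoich.items():
                if v > 0 and c not in currency:
                    new_pool[c] += int(v)
            new_total = dict(total)
            for c, v in stoich.items():
                new_total[c] = new_total.get(c, Fraction(0)) + v
            recurse(+new_pool, new_total, used + [(rid, d)])

    recurse(start, {}, [])
    return results
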