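"""Enzyme candidate retrieval and ranking for novel reaction steps.

A novel step inherits the reaction rule of a cataloged reaction; the
enzymes known to catalyze reactions with that rule are the natural starting
points for re-engineering.  Each candidate is scored for expected activity
on the novel substrate with a pluggable scorer returning a compatibility
probability in [0, 1]; the default scorer measures the multiset Tanimoto
similarity between the moiety signatures of the candidate's native
substrate and the novel substrate (an enzyme is most likely to accept a
molecule resembling the one it evolved for).  User-supplied scorers receive
the enzyme sequence as well and may use any model obeying the [0, 1]
contract.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import pandas as pd

from .chem_core import Compound, MoietySignature, moiety_signature

__all__ = [
    "EnzymeCandidate",
    "RankedCandidate",
    "Scorer",
    "rank_candidates",
    "moiety_tanimoto",
    "read_candidates_tsv",
    "write_candidates_tsv",
]

_AA = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]*$")

#: Scoring contract: (sequence, native substrate, novel substrate) -> [0, 1].
Scorer = Callable[[str, Compound, Compound], float]


@dataclass(frozen=True)
class EnzymeCandidate:
    enzyme_id: str
    organism: str
    sequence: str
    native_substrate: str  # compound id
    ec: str = ""
    rule_id: str = ""

    def __post_init__(self):
        if not _AA.match(self.sequence):
            raise ValueError(
                f"enzyme {self.enzyme_id}: sequence has non-amino-acid letters"
            )


@dataclass(frozen=True)
class RankedCandidate:
    candidate: EnzymeCandidate
    score: float

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


def moiety_tanimoto(a: MoietySignature, b: MoietySignature) -> float:
    """Multiset Tanimoto similarity Σ min / Σ max over moiety keys.

    Symmetric, 1.0 for identical signatures (including the degenerate case
    of two empty signatures), 0.0 for disjoint key sets.
    """
    if a.radius != b.radius:
        raise ValueError(f"radius mismatch: {a.radius} vs {b.radius}")
    keys = set(a.counts) | set(b.counts)
    if not keys:
        return 1.0
    num = sum(min(a.counts.get(k, 0), b.counts.get(k, 0)) for k in keys)
    den = sum(max(a.counts.get(k, 0), b.counts.get(k, 0)) for k in keys)
    return num / den


def _default_scorer_factory(
    compounds: Mapping[str, Compound],
    radius: int,
    signatures: Optional[Mapping[str, MoietySignature]],
) -> Scorer:
    cache: dict[str, MoietySignature] = dict(signatures or {})

    def sig_of(cpd: Compound) -> MoietySignature:
        if cpd.id not in cache:
            cache[cpd.id] = moiety_signature(cpd, radius=radius)
        return cache[cpd.id]

    def scorer(sequence: str, native: Compound, novel: Compound) -> float:
        return moiety_tanimoto(sig_of(native), sig_of(novel))

    return scorer


def rank_candidates(
    rule_id: str,
    novel_substrate: Compound,
    table: Sequence[EnzymeCandidate],
    compounds: Mapping[str, Compound],
    scorer: Optional[Scorer] = None,
    k: int = 5,
    radius: int = 1,
    signatures: Optional[Mapping[str, MoietySignature]] = None,
) -> list[RankedCandidate]:
    """Top-``k`` enzyme candidates for a rule, scored on the novel substrate.

    Candidates are matched by ``rule_id``; each is scored by
    ``scorer(sequence, native substrate, novel substrate)`` and the best
    ``k`` are returned sorted by score (ties broken by enzyme id).  A rule
    with no cataloged candidates yields an empty list with a warning —
    novel steps may genuinely lack catalog entries.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    matches = []
    seen = set()
    for c in table:
        if c.rule_id == rule_id and c not in seen:  # duplicates rank once
            matches.append(c)
            seen.add(c)
    if not matches:
        warnings.warn(f"no enzyme candidates cataloged for rule {rule_id}", stacklevel=2)
        return []
    if scorer is None:
        scorer = _default_scorer_factory(compounds, radius, signatures)
    ranked = []
    for cand in matches:
        native = compounds.get(cand.native_substrate)
        if native is None:
            warnings.warn(
                f"candidate {cand.enzyme_id}: native substrate "
                f"{cand.native_substrate!r} not in compound index; skipped",
                stacklevel=2,
            )
            continue
        score = float(scorer(cand.sequence, native, novel_substrate))
        ranked.append(RankedCandidate(candidate=cand, score=score))
    ranked.sort(key=lambda r: (-r.score, r.candidate.enzyme_id))
    return ranked[:k]


def read_candidates_tsv(path: Union[str, Path]) -> list[EnzymeCandidate]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        EnzymeCandidate(
            enzyme_id=row.enzyme_id,
            organism=getattr(row, "organism", ""),
            sequence=row.sequence,
            native_substrate=row.native_substrate_id,
            ec=getattr(row, "ec", ""),
            rule_id=row.rule_id,
        )
        for row in df.itertuples(index=False)
    ]


def write_candidates_tsv(
    candidates: Sequence[EnzymeCandidate], path: Union[str, Path]
) -> None:
    pd.DataFrame(
        [
            {
                "rule_id": c.rule_id,
                "ec": c.ec,
                "enzyme_id": c.enzyme_id,
                "organism": c.organism,
                "native_substrate_id": c.native_substrate,
                "sequence": c.sequence,
            }
            for c in candidates
        ]
    ).to_csv(path, sep="\t", index=False)
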