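"""Group-contribution estimation of standard reaction Gibbs energies.

The model is linear in moiety space: a reaction with signed moiety delta
``d`` has ΔrG′° ≈ d·β, where β holds one fitted contribution (kJ/mol) per
moiety key.  β is fitted by ridge-regularized least squares on a table of
(reaction delta, measured ΔrG′°) pairs; the prediction uncertainty comes
from the regularized normal matrix and the residual variance.  Condition
transforms (pH, ionic strength) follow the usual proton-binding plus
extended Debye–Hückel corrections, applied at the reaction level, and
concentration adjustments use the thermodynamic reaction quotient
ΔrG′ = ΔrG′° + RT·Σ s_c·ln(c_c).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "R_KJ",
    "T_STANDARD",
    "DEBYE_HUCKEL_ALPHA",
    "DEBYE_HUCKEL_BETA",
    "GroupContributionModel",
    "GibbsEstimate",
    "RankDeficiencyError",
    "fit_group_contribution",
    "predict_reaction_dg",
    "transform_conditions",
    "adjust_concentrations",
]

#: Gas constant, kJ mol^-1 K^-1.
R_KJ = 8.314e-3
#: Reference temperature for fitting, K.
T_STANDARD = 298.15
#: Extended Debye–Hückel parameters: alpha in kJ mol^-1 M^-1/2, beta in M^-1/2.
DEBYE_HUCKEL_ALPHA = 2.91482
DEBYE_HUCKEL_BETA = 1.6


class RankDeficiencyError(ValueError):
    """Unregularized fit on a rank-deficient design; advise ridge_lambda > 0."""


@dataclass
class GroupContributionModel:
    """Fitted per-moiety Gibbs-energy contributions with covariance."""

    beta: dict[str, float]
    covariance: np.ndarray
    keys: list[str]
    ridge_lambda: float
    training_n: int
    residual_sd: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "keys": self.keys,
                "beta": [self.beta[k] for k in self.keys],
                "covariance": self.covariance.tolist(),
                "ridge_lambda": self.ridge_lambda,
                "training_n": self.training_n,
                "residual_sd": self.residual_sd,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroupContributionModel":
        d = json.loads(text)
        return cls(
            beta=dict(zip(d["keys"], d["beta"])),
            covariance=np.asarray(d["covariance"], dtype=float),
            keys=list(d["keys"]),
            ridge_lambda=d["ridge_lambda"],
            training_n=d["training_n"],
            residual_sd=d["residual_sd"],
        )


@dataclass(frozen=True)
class GibbsEstimate:
    """A ΔrG′ estimate (kJ/mol) with 1-sd uncertainty and its conditions."""

    mean: float
    sd: float
    conditions: tuple[float, float, float] = (7.0, 0.0, T_STANDARD)  # pH, I (M), T (K)
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.sd:.2f} kJ/mol"


def fit_group_contribution(
    training: Sequence[tuple[Mapping[str, int], float]],
    ridge_lambda: float = 1e-6,
) -> GroupContributionModel:
    """Fit moiety contributions by ridge least squares.

    ``training`` holds (reaction moiety delta, measured ΔrG′° in kJ/mol)
    pairs.  With ``ridge_lambda == 0`` a rank-deficient design raises
    :class:`RankDeficiencyError`; any positive lambda regularizes it.
    Zero-delta rows (e.g. identity reactions) carry no information and are
    retained only in the residual count.
    """
    if len(training) == 0:
        raise ValueError("need at least one training reaction")
    keys = sorted({k for delta, _ in training for k, v in delta.items() if v})
    n, p = len(training), len(keys)
    X = np.zeros((n, p))
    y = np.zeros(n)
    index = {k: j for j, k in enumerate(keys)}
    for i, (delta, dg) in enumerate(training):
        for k, v in delta.items():
            if v:
                X[i, index[k]] = v
        y[i] = dg
    xtx = X.T @ X
    if ridge_lambda == 0 and (p == 0 or np.linalg.matrix_rank(xtx) < p):
        raise RankDeficiencyError(
            "design matrix is rank-deficient at ridge_lambda=0; "
            "use ridge_lambda > 0"
        )
    A = xtx + ridge_lambda * np.eye(p)
    beta = np.linalg.solve(A, X.T @ y) if p else np.zeros(0)
    resid = y - X @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    covariance = sigma2 * np.linalg.inv(A) if p else np.zeros((0, 0))
    covariance = (covariance + covariance.T) / 2.0
    return GroupContributionModel(
        beta={k: float(b) for k, b in zip(keys, beta)},
        covariance=covariance,
        keys=keys,
        ridge_lambda=ridge_lambda,
        training_n=n,
        residual_sd=math.sqrt(sigma2),
    )


def predict_reaction_dg(
    rxn_delta: Mapping[str, int],
    model: GroupContributionModel,
    unseen_penalty: float = 10.0,
    conditions: tuple[float, float, float] = (7.0, 0.0, T_STANDARD),
) -> GibbsEstimate:
    """Predict ΔrG′° = delta·β with sd = sqrt(deltaᵀ·Σ·delta).

    Moiety keys absent from training contribute 0 to the mean; each unseen
    occurrence inflates the sd by ``unseen_penalty`` kJ/mol and is flagged.
    """
    index = {k: j for j, k in enumerate(model.keys)}
    d = np.zeros(len(model.keys))
    flags: list[str] = []
    penalty = 0.0
    for k, v in rxn_delta.items():
        if not v:
            continue
        j = index.get(k)
        if j is None:
            flags.append(f"unseen moiety {k!r}")
            penalty += unseen_penalty * abs(v)
        else:
            d[j] = v
    mean = float(d @ np.array([model.beta[k] for k in model.keys])) if model.keys else 0.0
    var = float(d @ model.covariance @ d) if model.keys else 0.0
    sd = math.sqrt(max(var, 0.0)) + penalty
    return GibbsEstimate(mean=mean, sd=sd, conditions=conditions, flags=tuple(flags))


def _debye_huckel(ionic_strength: float) -> float:
    sqrt_i = math.sqrt(ionic_strength)
    return DEBYE_HUCKEL_ALPHA * sqrt_i / (1.0 + DEBYE_HUCKEL_BETA * sqrt_i)


def transform_conditions(
    est: GibbsEstimate,
    delta_nH: int,
    delta_z2: int,
    pH: float,
    ionic_strength: float,
    temperature: Optional[float] = None,
) -> GibbsEstimate:
    """Move an estimate from its stored conditions to (pH, I, T).

    ``delta_nH`` is the net proton count change (products minus reactants)
    and ``delta_z2`` the net change in summed squared charges.  The mean
    shifts by ΔN_H·RT·ln(10)·ΔpH plus the extended Debye–Hückel term
    α√I/(1+β√I)·(ΔN_H − Δz²) differenced between the two ionic strengths.
    """
    if not (0.0 <= pH <= 14.0):
        raise ValueError(f"pH {pH} outside [0, 14]")
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    ph0, i0, t0 = est.conditions
    T = temperature if temperature is not None else t0
    flags = list(est.flags)
    if abs(T - T_STANDARD) > 1e-9:
        warnings.warn(
            "transforming at a temperature away from 298.15 K; training "
            "conditions assume the standard temperature",
            stacklevel=2,
        )
        flags.append(f"non-standard temperature {T} K")
    rt_ln10 = R_KJ * T * math.log(10.0)
    mean = est.mean
    mean += delta_nH * rt_ln10 * (pH - ph0)
    mean += (_debye_huckel(ionic_strength) - _debye_huckel(i0)) * (delta_nH - delta_z2)
    return GibbsEstimate(mean=mean, sd=est.sd, conditions=(pH, ionic_strength, T), flags=tuple(flags))


def adjust_concentrations(
    est: GibbsEstimate,
    stoich: Mapping[str, Fraction],
    concentrations: Mapping[str, float],
    exclude: frozenset[str] = frozenset({"h", "h2o"}),
) -> GibbsEstimate:
    """ΔrG′ at given metabolite concentrations (molar).

    Water and the proton are excluded from the reaction quotient (their
    activities are handled by the condition transform); species without an
    entry in ``concentrations`` stay at the 1 M standard state.
    """
    _, _, T = est.conditions
    shift = 0.0
    for cid, conc in concentrations.items():
        if conc <= 0:
            raise ValueError(f"non-positive concentration for {cid!r}")
    for cid, coeff in stoich.items():
        if cid in exclude or cid not in concentrations:
            continue
        shift += float(coeff) * math.log(concentrations[cid])
    return GibbsEstimate(
        mean=est.mean + R_KJ * T * shift,
        sd=est.sd,
        conditions=est.conditions,
        flags=est.flags,
    )
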