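# Methods

`retrostoic` implements a four-stage retro-biosynthesis design workflow:
optimal overall-conversion stoichiometry, de novo pathway search over
moiety-signature reaction rules, group-contribution estimation of standard
reaction Gibbs energies, and similarity-based ranking of enzyme candidates
for novel steps. This note records the models, the numerical choices, and
what the packaged synthetic fixtures do and do not emulate.

## Moiety signatures and reaction rules

A molecule is encoded as a multiset of atom-centered environment keys.
Each heavy atom contributes one key
`El;Hn;(neighbor,...)` — center element, attached hydrogen count (omitted
when zero), and the sorted list of neighbor tokens `El<order>` with bond
orders `1/2/3` and `a` for aromatic bonds (a distinct token avoids
kekulization ambiguity). At radius 2 each neighbor token carries its own
hydrogen count and second-shell neighbors in brackets, excluding the bond
back to the center. Hydrogens are folded into the center key and are never
centers themselves; per-atom formal charges are *not* part of the key —
charge is tracked per compound and balanced at the reaction level only.
The key format is printable and sortable, so signatures and rule deltas
serialize deterministically, and summing the center elements (plus their
hydrogens) of a signature reconstructs the molecular formula — an
invariant the test suite checks and the pathway search relies on to assign
formulas to hypothetical intermediates.

A reaction rule is the signed sum of participant signatures, currency
species excluded, with coefficients applied; its id is a hash of the
canonically serialized delta, so reactions with identical deltas share one
rule that records every parent. Radius 1 is the default (radius 2 is
available); at radius 1 more reactions collapse onto one rule, which is
the behavior the rule-deduplication statistics of reaction databases
reflect. The currency set is configuration: by default proton, water, the
NAD(P) redox couples, FAD/FADH2, and the adenosine phosphates; the
packaged demo additionally treats O2, H2O2, NH4+ and CO2 as currency so
that rules capture pure main-chain transformations.

## Overall stoichiometry (LP/MILP)

Given a source (fixed at coefficient −1), a target, and a co-metabolite
specification (allowed ids, optional consume-/produce-only roles, redox
couples locked through one signed magnitude variable, per-id coefficient
caps), the optimizer maximizes the target coefficient subject to one
equality per element plus one for charge. The yield comes from a
continuous LP (HiGHS via `scipy.optimize.linprog`); reported
stoichiometries are then re-solved as a MILP with integer coefficients
(default |coefficient| ≤ 10) so that printed conversions look like
chemical equations.

Two conventions matter and are deliberate:

- **Integer yield** (`integer_yield=True`): restricts the conversion to
  whole target molecules per source molecule. The continuous carbon
  optimum for a Cn→Cm conversion is generally fractional (n/m); printable
  overall equations use the integral form, and that is the convention the
  packaged demo asserts.
- **Sign roles**: an unbounded co-metabolite that shares an element with
  the target (e.g. CO2 with free sign) makes the yield unbounded — the
  optimizer reports the culprits. The demo's inclusive co-set therefore
  fixes CO2 as produce-only and O2 as consume-only.

Alternative optima are enumerated with integer cuts on the *support
pattern* (the set of co-metabolites used). Each coefficient is split into
non-negative positive/negative integer parts, each tied to a binary use
indicator by `part ≥ binary` and `part ≤ bound·binary` with at most one
side active; this makes the indicator exact, which a single big-M binary
does not (the solver can otherwise flip an unused indicator to escape a
cut without changing the support). Discovery order follows the objective
(few species first, or small coefficient totals first); results are
post-sorted by yield, support size, total |coefficient|, then
lexicographically, so outputs are deterministic.

## Pathway search (MILP with moiety balance)

Candidates are the directed curated reactions (bidirectional reactions
become two candidates; a candidate's delta is its currency-excluded
signature difference) plus the reaction rules. Integer step-use variables
must satisfy, for every moiety key, the exact equality
`Σ steps × delta = Σ overall coefficients × compound signatures`, with
caps on total steps and on novel (rule-derived) steps. The objective
prefers fewer steps and penalizes novel steps at half a step each; step
multisets are enumerated with the same exact-support integer cuts as
above, so re-orderings of one multiset are not re-reported.

Moiety balance is necessary but not sufficient for a real pathway, so
every raw multiset is **assembled**: steps are ordered by backtracking
over a pool of non-currency compounds seeded with the overall's consumed
species (currency is exempt from ordering); a known step requires its
non-currency substrates in the pool; a novel step applies its rule to a
single pool compound's signature and resolves the product against the
compound index — exact signature matches branch over all matching ids
(radius-1 signatures do not separate some positional isomers, e.g.
*m*-/*p*-cresol), and unmatched products become hypothetical compounds
with formulas derived from their signature centers and charge 0. The
backtracking order is fixed by sorting steps on (kind, id, direction), so
assembly is independent of solver variable order; the seed only permutes
MILP variables and the final list is post-sorted.

Novel steps carry no currency stoichiometry of their own, so the currency
coefficients of all novel steps in a candidate pathway are solved
**jointly**: a small integer program balances each novel step elementally
and by charge while forcing the whole pathway's step sum to equal the
overall stoichiometry exactly, minimizing total |currency coefficient|.
Solving per-step in isolation can pick a balanced but different cofactor
completion (e.g. an NAD-coupled deamination instead of the
peroxide-driven one) and silently break the step-sum invariant; the joint
solve makes "steps sum to the overall" a hard constraint. Multisets with
no valid ordering or no currency completion are cut and skipped.
Single-substrate rule application is a known limitation: rules whose
consumed moieties span two non-currency substrates cannot be instantiated
as novel steps.

An optional thermodynamic direction filter drops directed candidates whose
predicted ΔrG′° exceeds a cap (default +25 kJ/mol) when a fitted model is
supplied; concentration tilting across a 10³ metabolite range recovers
roughly 2RT·ln(10³) ≈ 34 kJ/mol, so mildly positive directions remain.

## Group-contribution thermodynamics

ΔrG′° is linear in the rule delta: `mean = delta·β`, with β fitted by
ridge-regularized least squares (default λ = 10⁻⁶; λ = 0 on a
rank-deficient design raises an error advising regularization). The
covariance is σ̂²(XᵀX+λI)⁻¹ with σ̂² the residual variance at
max(n−p, 1) degrees of freedom; the prediction uncertainty is
sd = √(deltaᵀΣdelta), reported as ±1 sd. Moiety keys unseen in training
contribute 0 to the mean and add a conservative 10 kJ/mol to the sd per
occurrence, flagged in the estimate. Linearity gives Hess additivity and
antisymmetry exactly, which the tests assert.

Condition transforms operate at the reaction level: the mean shifts by
ΔN_H·RT·ln(10)·ΔpH plus an extended Debye–Hückel term
α√I/(1+1.6√I)·(ΔN_H − Δz²) with α = 2.91482 kJ·mol⁻¹·M⁻¹/², differenced
between the old and new ionic strengths. This is simpler than a
per-species Legendre transform and sufficient given moiety-level
featurization; pKa estimation and Mg²⁺ binding are out of scope. Fitting
assumes 298.15 K; transforms at other temperatures warn. Concentration
adjustment applies ΔrG′ = ΔrG′° + RT·Σ s·ln c with water and the proton
excluded from the quotient and absent species at the 1 M standard state.

## Enzyme ranking

For a novel step the catalog is filtered by rule id; each candidate is
scored by a pluggable `(sequence, native substrate, novel substrate) →
[0, 1]` contract and the top k (default 5) are returned, ties broken by
enzyme id and duplicate catalog rows deduplicated. The default scorer is
the multiset Tanimoto similarity (Σmin/Σmax over moiety keys) between the
native and novel substrate signatures — a structure-only proxy for
substrate compatibility; the sequence is passed through untouched so a
learned sequence-aware scorer can be plugged in without interface changes.
Scores are opaque compatibility values, not calibrated probabilities.

## Synthetic fixtures: what they do and do not show

`make_hxt_demo` reconstructs a hydroxytyrosol mini-network: six main
compounds (L-tyrosine, tyramine, 4-hydroxyphenylacetaldehyde, tyrosol,
dopamine, hydroxytyrosol) with standard structures, eight currency
species, five cataloged reactions (decarboxylase; tyramine oxidase;
aldehyde reductase; the monooxygenase acting on tyrosol; the
NAD(P)H-dependent tyramine→dopamine monooxygenase), and three rules
derived from named transformations (a one-step
decarboxylation+deamination bypass; a peroxide-driven ring hydroxylation;
an amine→hydroxyl replacement). Both reference overall conversions — the
cofactor-using route
`Tyr + 2NADH + 3H+ + 2O2 → HXT + NH4+ + CO2 + H2O2 + 2NAD+` and the
cofactor-free `Tyr + H+ + H2O2 → HXT + NH4+ + CO2` — balance exactly and
are recovered by the optimizer from formulas alone. The demo's enzyme
catalog and its ΔG training table are synthetic: sequences and organisms
are placeholders, and training values are generated from a fixed
per-moiety contribution vector so that a fitted model reproduces
internally consistent step energies. Passing tests therefore demonstrate
the machinery — balance, enumeration, rule application, fitting — on a
faithful small topology; they say nothing about absolute energies of real
reactions or about real enzyme activities, which require measured
training data and a trained activity model.

`make_toy_network` plants a linear pathway of configurable length among
synthetic CHO compounds whose signatures are generated directly (with
even hydrogen totals so the CO2/H2O/H2 currency closure stays integral),
then adds decoy reactions, regenerating them if graph search finds a
shorter route than the planted one. Toys are the substrate for the oracle
tests: exhaustive DFS over ordered reaction sequences must produce
exactly the step multisets the MILP returns.

## Problem sizes

The packaged analyses are deliberately small: the demo network has 14
compounds, 5 reactions and 3 rules; stoichiometry enumeration uses ≤ 8
co-metabolite variables; toys use 8 compounds and 6 reactions with
4-step search depth; the synthetic recovery study fits 10 moiety
contributions to 50 reactions at 1 kJ/mol noise. The full test suite and
the acceptance script each run in well under a minute on one CPU.
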