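# retrostoic

Retro-biosynthesis pathway design for metabolic engineers: given a source
precursor and a target molecule, find the best net conversion, assemble
reaction steps that realize it — including *novel* steps no database has
cataloged yet — check each step's thermodynamics, and shortlist enzymes
worth re-engineering for the novel chemistry.

The toolkit chains four stages behind one library and CLI:

1. **Overall stoichiometry.** Maximize the molar yield *y* in
   `1 source + co-substrates → y target + co-products` subject to
   elemental and charge balance, `Σ_c s_c·n_e(c) = 0` for every element
   *e* (and charge), via LP/MILP. Alternative optima are enumerated with
   integer cuts on the co-metabolite support, so each solution uses a
   distinct set of species.
2. **Pathway search.** Molecules are encoded as *moiety signatures*
   (multisets of atom-centered environment keys); a reaction rule is the
   signed signature difference across a reaction with currency species
   excluded. The search is a MILP over known reactions and rules under
   exact *moiety balance* — for every key,
   `Σ_steps u_j·Δ_j = Σ_c s_c·sig(c)` — then orders each step multiset,
   instantiates rule applications on concrete substrates, and completes
   novel steps with currency coefficients so the steps sum to the overall
   conversion exactly.
3. **Thermodynamics.** A group-contribution model `ΔrG′° = Δ·β` fitted by
   ridge least squares over moiety keys, with 1-sd uncertainties,
   pH/ionic-strength transforms (proton binding + extended Debye–Hückel),
   and concentration adjustment `ΔrG′ = ΔrG′° + RT·Σ s_c·ln c_c`.
4. **Enzyme selection.** For each novel step, rank cataloged enzymes of
   the parent rule by expected activity on the new substrate (default: a
   moiety-signature Tanimoto score in [0, 1]; any
   `(sequence, native, novel) → [0, 1]` scorer can be plugged in).

See `docs/methods.md` for models, assumptions, and numerical choices.

## Worked example: hydroxytyrosol from L-tyrosine

The packaged demo network (`make_hxt_demo`) covers the biosynthesis of
the antioxidant hydroxytyrosol (HXT, C8H10O3) from L-tyrosine
(C9H11NO3): the four-step cataloged route plus reaction rules that enable
shorter novel routes.

```python
from retrostoic import (
    make_hxt_demo, max_yield_stoichiometry, CoMetaboliteSpec,
    design_pathways, rank_candidates, format_reaction_string,
)

demo = make_hxt_demo()

overall = max_yield_stoichiometry(
    "tyr", "hxt", demo.compounds,
    CoMetaboliteSpec(allowed={"h", "h2o2", "nh4", "co2"}),
)
print("yield:", overall.yield_)
print("overall:", format_reaction_string(overall.coeffs, "forward"))

pathways = design_pathways(
    overall, demo.reactions, demo.rules, demo.compounds,
    signatures=demo.signatures, currency=demo.currency,
    max_steps=5, max_novel=2, n_pathways=10, seed=0,
)
route = next(
    p for p in pathways
    if {s.ref_id for s in p.steps}
    == {"R_TDC", demo.rule_r2_id, demo.rule_r3_id}
)
for i, step in enumerate(route.steps, 1):
    print(f"step {i} [{step.kind}]",
          format_reaction_string(step.stoich, "forward"))

ranked = rank_candidates(
    demo.rule_r3_id, demo.compounds["dopamine"], demo.candidates,
    demo.compounds, signatures=demo.signatures,
)
for r in ranked[:3]:
    print(f"{r.candidate.enzyme_id} ({r.candidate.organism}): {r.score:.2f}")
```

prints

```
yield: 1
overall: 1 h + 1 h2o2 + 1 tyr => 1 co2 + 1 hxt + 1 nh4
step 1 [known] 1 tyr => 1 co2 + 1 tyramine
step 2 [novel] 1 h + 1 h2o + 1 tyramine => 1 nh4 + 1 tyrosol
step 3 [novel] 1 h2o2 + 1 tyrosol => 1 h2o + 1 hxt
enz01 (Synthetica exempli str. 1): 1.00
enz02 (Synthetica exempli str. 2): 0.75
enz04 (Synthetica exempli str. 4): 0.69
```

Reading the output: with only H⁺, H₂O₂, NH₄⁺ and CO₂ allowed as
co-metabolites, the five balance equations force the 1-to-1 conversion
`Tyr + H+ + H2O2 → HXT + NH4+ + CO2` uniquely. The search then finds a
three-step, cofactor-free route: the known tyrosine decarboxylase,
followed by two novel steps — a hydrolytic amine→hydroxyl replacement
releasing NH₄⁺ and a peroxide-driven aromatic ring hydroxylation — whose
currency usage is completed so the steps sum exactly to the overall
conversion. The ranking scores cataloged enzymes of the novel step's
parent rule by substrate similarity; the enzyme whose native substrate
*is* the query scores 1.0. (Demo enzyme entries are synthetic
placeholders.)

The same workflow runs from the shell:

```bash
retrostoic demo-hxt --out demo/
retrostoic curate --compounds demo/compounds.tsv --reactions demo/reactions.tsv \
    --currency demo/currency.txt --out curated/
retrostoic stoic --source tyr --target hxt --compounds demo/compounds.tsv \
    --allow allow.txt --k 10 --out overall.json
retrostoic pathway --overall overall.json --db demo/ --max-steps 5 --out pathways.json
retrostoic run config.toml          # full chain from a TOML config
```

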