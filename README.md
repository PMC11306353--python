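# respiroferm

Computational design logic for **obligate-fermentative** and **controlled
respiro-fermentative** *Escherichia coli* strains.

Aerobic *E. coli* sends electrons from NADH and from metabolite-oxidising
dehydrogenases into the membrane quinone pool (Q/QH₂) and on to oxygen.  A
strain in which *every* quinone-reducing reaction has been removed can no
longer respire: it must balance redox by secreting fermentation products,
even with oxygen present.  Such a strain ferments any substrate/product pair
whose **degree of reduction** balances — and, because the electron transport
chain downstream of the quinone pool is left intact, single quinone-dependent
dehydrogenases can later be re-integrated as "respiratory modules" that dump
a defined electron surplus into the chain, unlocking unbalanced conversions
such as glycerol → lactate or glycerol → isobutanol.  This package implements
the design pipeline behind that engineering programme, for metabolic
engineers and systems biologists working with constraint-based models:

1. **Quinone census** (`respiroferm.census`) — enumerate every
   quinone-reducing reaction of a genome-scale (SBML-FBC) or toy model,
   apply manual curation, classify entries into NAD(P)H:quinone
   oxidoreductases vs quinone-dependent dehydrogenases, detect two-reaction
   **mini-cycles** (a quinone-dependent dehydrogenase plus its immediate
   NAD(P)H-dependent counterpart, e.g. *dld*/*ldhA*, whose net effect is
   NAD(P)H → QH₂), and derive the deletion-locus list of the obligate
   fermenter.
2. **Redox balancing** (`respiroferm.redox`) — exact electron bookkeeping
   with the available-electron convention
   γ = 4·C + H − 2·O − 3·N + 5·P + 6·S − charge (CO₂/H₂O/NH₃ reference):
   a conversion is fermentable iff substrate and product electrons match;
   a positive surplus is the electron-pair duty of a respiratory module.
3. **Strain design** (`respiroferm.design`) — genotype presets (the
   19-locus obligate fermenter, its GlpD reintegration, the ΔldhA +
   isobutanol-pathway producer), aerobic/anaerobic condition logic
   (oxygen-sensitive Pfl and anaerobic AdhE vs NADH-producing Pdh), and FBA
   phenotype prediction: growth feasibility, secretion spectra, growth
   coupling, maximum theoretical yields, and an acetate carbon-label
   reachability heuristic.
4. **Quantitation** (`respiroferm.quant`) — specific uptake rates
   (r = μ·Δc_substrate/Δc_biomass), intracellular-concentration correction
   (biovolume = CDW · 2 µL mg⁻¹), sliding-window growth-rate estimation
   from plate-reader curves (plate→cuvette factor 4.35), and molar yields.

Flux balance analysis is solved with scipy's HiGHS LP backend
(max c·v s.t. S·v = 0, l ≤ v ≤ u); SBML I/O goes through COBRApy.  The
bundled synthetic fixtures (`respiroferm.fixtures`) — a fully
element/charge-balanced toy respiro-fermentative core network and a census
annotation fixture — make every stage testable without downloading a
genome-scale model.

## Worked example

```python
from respiroferm import (
    AEROBIC, NNMINI, NNMINI_GLPD_DLDHA_PIBA, balance_sheet,
    build_toy_model, max_theoretical_yield, percent_of_max_yield,
    predict_phenotype,
)

toy = build_toy_model()

# Obligate fermenter on glucose, aerobic: homolactic and growth-coupled.
p = predict_phenotype(toy, NNMINI, AEROBIC, "EX_glc__D")
print(p.growth_feasible, p.secretion_profile, p.coupled)
# True {'EX_lac__D': 12.874999988125003} True

# Glycerol is one electron pair more reduced than lactate...
sheet = balance_sheet(("glycerol", 1), [("lactate", 1)])
print(sheet.pairs_per_substrate, sheet.verdict)
# 1 unbalanced_excess_electrons

# ...and the isobutanol design caps at 0.5 mol isobutanol per mol glycerol;
# a measured 2.012 mM from 5 mM glycerol is 80% of that maximum.
y = max_theoretical_yield(
    toy, NNMINI_GLPD_DLDHA_PIBA, AEROBIC, "EX_glyc", "EX_ibuoh")
print(y, percent_of_max_yield(2.012, 5.0, y).percent)
# 0.5 80
```

The `respiroferm` command line exposes the same stages
(`respiroferm census`, `balance`, `design`, `quant`, `fixtures`); the
numbered scripts under `analysis/` run the four stages end to end and write
their tables under `results/`.

The 12.87 mmol gCDW⁻¹ h⁻¹ lactate flux above is the secretion at maximal
growth with 10 mmol gCDW⁻¹ h⁻¹ glucose uptake; the empty wild-type
secretion profile, the anaerobic acetate/formate/ethanol spectrum, and the
census ledger (17 enumerated / 6 excluded / 3 added / 14 relevant / 7 + 12
gene groups / 8 mini-cycles, 19 deletion loci) are printed by
`analysis/01_quinone_census.py` and `analysis/03_strain_phenotypes.py`.

Theoretical maxima are not measurements: published endpoint yields
(e.g. 1.78 mol lactate/mol glucose) enter only as inputs to the yield
calculators for comparison against the computed bounds.

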