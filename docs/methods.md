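# Methods

## The design problem

An *E. coli* strain stripped of every reaction that can reduce the membrane
quinone pool cannot use oxygen as an electron acceptor and is forced into
fermentation even aerobically.  Because only the *entry points* into the
electron transport chain are removed — the quinol oxidases, the
proton-motive force and the ATP synthase stay intact — individual
quinone-dependent dehydrogenases can be re-integrated afterwards as
*respiratory modules* that transfer a defined number of electron pairs per
substrate into the chain.  The package implements the four computational
stages of that programme: the census of quinone-reducing reactions, the
degree-of-reduction calculus that states how many electron pairs a module
must carry, FBA verification of the resulting genotypes, and the
quantitation formulas used to evaluate cultures.

## Census and mini-cycles

A reaction is counted as quinone-reducing when its stoichiometry consumes a
quinone and produces the paired quinol in a bounds-allowed direction.
Quinone pairs are configurable identifiers (defaults: ubiquinone-8,
menaquinone-8, 2-demethylmenaquinone-8 in BiGG spelling), so published
SBML-FBC reconstructions and the bundled fixtures use the same code path.
Quinone-variant isoreactions of one gene group collapse to a single entry.

Curation is explicit data, not inference: exclusions are (reaction, reason)
pairs that must reference enumerated reactions (typos fail loudly), and
additions carry a database provenance tag.  Classification follows the
electron donor: NAD(P)H → *NAD(P)H:quinone oxidoreductase*, any other
metabolite → *quinone-dependent dehydrogenase*.  The
enumerated/excluded/added/relevant ledger counts reactions; the 7/12
classification and the mini-cycle tally count **gene groups**, because
operons and isozyme sets are the unit at which loci are deleted.  One
census entry may carry several `|`-separated groups (the promiscuous
NAD(P)H:quinone oxidoreductases; the aerobic/anaerobic G3P dehydrogenase
isozymes), which is how 14 relevant reactions yield 19 gene groups.

A **mini-cycle** is a two-reaction substrate cycle: a quinone-dependent
dehydrogenase combined with its immediate NAD(P)H-dependent counterpart
run in the reductive sense, cancelling to
NAD(P)H + H⁺ + Q → NAD(P)⁺ + QH₂.  Detection is purely stoichiometric and
exact (rational arithmetic): the counterpart's multiplier is solved from
any shared non-cofactor metabolite and the residual must match the carrier
pattern exactly, with protons and water ignored (their compartmental
bookkeeping differs between models).  Bounds and direction encoding of the
counterpart are deliberately ignored, so the result is invariant to how
reversibility is written.  Longer futile loops are out of scope — the
design argument concerns immediate counterparts only.

Deletion targets are the union of the relevant gene groups, mapped to
deletion loci (the *nuo* operon is inactivated via *nuoEFG* because those
subunits are essential for electron transfer; *mdaB/ygiN* is one joint
locus; *sdhABCD*, *glpABC*, *glcDEF* are operon loci), plus the NAD(P)H
counterpart of every mini-cycle whose quinone member is scheduled for later
reintegration (default: *glpD*, which pulls in *gpsA*).  On the bundled
annotation fixture this yields exactly 19 loci.

## Degree-of-reduction calculus

Available electrons per molecule are
γ = 4·C + 1·H − 2·O − 3·N + 5·P + 6·S − charge, the standard
available-electron convention with CO₂, H₂O, NH₃ (and thereby protons and
phosphate) at zero.  The charge term makes anions score identically to
their free acids, so lactate and lactic acid are interchangeable on sheets.
All sheet arithmetic uses exact rationals; verdicts (`balanced`,
`unbalanced_excess_electrons`, `unbalanced_electron_deficit`) never depend
on floating-point tolerances.  Carbon must be conserved across a declared
conversion, with CO₂ (γ = 0) as the implicit make-up product; biomass never
appears on sheets — yields are zero-growth theoretical maxima.  The
combination screen picks, per substrate/product pair, the smallest
substrate coefficient admitting one whole product molecule and the largest
product coefficient under carbon conservation; this is a screening
convention, and the electron verdict then says whether the conversion needs
a module (surplus), nothing (balanced), or an electron donor (deficit,
infeasible by quinone transfer alone, since the quinone pool only accepts
electrons).

## The toy respiro-fermentative network

The toy model is a single-compartment, ~35-reaction core network carrying
exactly the structure the design reasons about: lumped upper glycolysis
(glucose + 2 ATP → 2 DHAP), reversible lumped lower glycolysis
(DHAP ↔ PEP + NADH + ATP), pyruvate kinase, PEP carboxylase/carboxykinase,
the fermentation branches (LdhA, Pdh, Pfl, Pta-AckA, AdhE), glycerol
assimilation (GlpK, GlpD, GpsA), a TCA fragment with glyoxylate shunt
(CS, aconitase, Icd, Icl, MalS, fumarase, Mdh, Mqo, Sdh), and an ETC with
an explicit ubiquinone pool (Ndh, proton-pumping Nuo, terminal oxidase,
ATP synthase, ATP maintenance).  Every non-exchange, non-biomass reaction
is element- and charge-balanced with real molecular formulas, which makes
degree-of-reduction conservation
(Σ consumed electrons = Σ secreted electrons + 4·O₂ uptake) an exact linear
identity of the network — tested numerically to 10⁻⁶.

Numerical and closure choices:

* **Proton-motive force** is a massless, chargeless pseudo-metabolite with
  integer pumping quotients (defaults 4 H⁺ per NADH at Nuo, 4 per quinol at
  the oxidase, 4 per ATP at the synthase).  Real H⁺ stoichiometries are
  non-integer and contested; only qualitative "additional ATP" comparisons
  are ever asserted, never absolute P/O ratios.
* **Biomass** draws the five precursors (pyruvate, acetyl-CoA, OAA,
  2-oxoglutarate, glycerol 3-P) in equal molar amounts plus 10 ATP and
  7 NADH.  Seven equals the NADH co-produced when that precursor set is
  made from glucose (5 from lower glycolysis, 2 from Pdh, 1 from Icd, minus
  1 invested in G3P synthesis), so biomass formation is redox-neutral and
  secreted products remain the only electron valves — the property the
  whole design turns on.  The ATP draw of 10 makes growth ATP-limited, so
  fermentative ATP generation (and with it product secretion) is
  growth-coupled.  Only feasibility, coupling and yields are asserted
  against the biomass reaction, never growth-rate values.
* **G3P supply in ΔgpsA strains**: the engineered genotypes delete *gpsA*
  (the counterpart of the reintegrated GlpD) yet still need glycerol 3-P
  for biomass on glucose.  The toy carries a lumped, gene-less,
  ATP-coupled biosynthetic route (`G3PSYN`: DHAP + NADH + 2 ATP → G3P).
  The ATP coupling removes it from mini-cycle space and makes
  NADH → quinol dumping through G3PSYN + GlpD strictly ATP-costly, so FBA
  never exploits it as a free electron valve.  This stands for the cell's
  unmodelled minimal biosynthetic G3P supply, not for a specific enzyme.
* **Condition logic** is hard switches: aerobically Pfl and AdhE are off
  (oxygen sensitivity and expression control), anaerobically Pdh and the
  O₂ exchange are off.  The NADH inhibition of Pdh is kinetic and cannot be
  encoded in FBA; the switches are a qualitative approximation.
* **LP tolerances**: feasibility 10⁻⁹ (HiGHS primal tolerance); fluxes
  below 10⁻⁶ are reported as zero in secretion profiles and FVA ranges.
  Solutions at degenerate optima are solver-dependent; only objective
  values, feasibility and forced-zero ranges are asserted.  The secretion
  profile applies a parsimony tie-break (total product secretion minimised
  at the growth optimum) so optional by-products of degenerate optima are
  not reported.
* **Maintenance ATP** defaults to 1 mmol gCDW⁻¹ h⁻¹ for growth
  simulations and to 0 for theoretical yields.

With these choices the network reproduces the designed physiology from
first principles: the obligate fermenter is homolactic and growth-coupled
on glucose aerobically, cannot grow on glycerol, regains glycerol growth
with near-stoichiometric lactate secretion once GlpD is back (with acetate
as the LP's optional minor by-product, matching observation), ferments
heterolactically (acetate + formate + ethanol) anaerobically, grows faster
anaerobically than aerobically, and caps isobutanol at 0.5 mol per mol
glycerol.

## Label reachability

The ¹³C-acetate argument — acetate carbon appears only in leucine, proline
and arginine, i.e. in acetyl-CoA- and 2-oxoglutarate-derived pools — is
reproduced as a graph heuristic: breadth-first search over carbon-carrying
edges of reactions that can sustain flux in the designed strain, with CO₂
and catalytic cofactor couples excluded as conduits.  Flux capability is
FVA without a growth requirement and with the fixed-ratio biomass reaction
replaced by independent demand sinks per carbon precursor; with the rigid
biomass draw in place, LP stoichiometry pins acetate uptake in the aerobic
obligate fermenter to exactly zero and would spuriously block the very
first edge.  This is not atom mapping: a reachable pool means a carbon
path exists in the flux-capable subnetwork.  The implicit exclusion of
malate-dehydrogenase backflux in the biological argument falls out of the
capability filter (with Sdh and Mqo deleted, no malate source remains, so
Mdh cannot carry flux).

## Quantitation

* Specific uptake rate r = μ · (c_sub,start − c_sub,end) /
  (c_bio,end − c_bio,start); undefined unless biomass increased.
* Intracellular concentration: c_measured · (vol_EF + biovolume)/vol_EF
  with biovolume = CDW[mg] · 2 µL mg⁻¹ — the printed dilution-correction
  form, implemented verbatim.  Whether a further normalisation to the
  biovolume fraction should follow (to express the value per cell volume
  rather than per corrected extract) is ambiguous in the source
  description; the package implements exactly the printed formula and
  leaves any further normalisation to the caller.
* Growth rate: blank subtraction, plate→cuvette conversion (factor 4.35,
  in that order), then the maximum slope of ln(OD) over sliding windows of
  6 consecutive positive readings.  Windows must reach R² ≥ 0.999 to
  compete (fallback: the best-fitting window): a max-statistic over many
  noisy windows is upward-biased, and at low OD the additive read noise
  dominates the ln-signal; the guard keeps windows whose residual scatter
  is below ~1% of their dynamic range.  The rate is invariant to rescaling
  the OD axis, hence to the plate factor.  The OD→CDW conversion is never
  hardcoded; harvested CDW is a direct input.

The growth-curve generator emulates exponential plate-reader kinetics with
additive Gaussian read noise (default σ = 0.005 OD) on a 15-minute grid.
It has no lag, saturation, or biological replicate variance, so passing
estimator tests demonstrate correct fitting of the exponential phase, not
robustness to full sigmoidal curves.

## Known limitations

* The toy network's biomass composition is fixed; consequently the
  experimentally observed growth improvement from acetate (or pyruvate, or
  casamino-acid) supplementation cannot occur in the model — acetate
  assimilation is exactly redox-pinned at fixed composition.  The package
  makes no claims about supplementation phenotypes.
* Measured quantities — endpoint yields (1.78 mol lactate/mol glucose,
  0.85 mol lactate/mol glycerol), growth rates, NADH/NAD⁺ and ATP pool
  ratios — are wet-lab observables with no quantitative model here; they
  enter only as inputs to the yield calculators for comparison with
  computed theoretical bounds.
* Thermodynamic (loopless) FBA, kinetic regulation (ArcAB/FNR, Pdh
  inhibition), proteome allocation, menaquinone promiscuity (the
  demethylmenaquinone escape route of ubiquinone-synthesis deletion
  strains) and adaptive evolution are out of scope; the mini-cycle search
  covers length-2 cycles only.
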