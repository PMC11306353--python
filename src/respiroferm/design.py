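"""Genotype presets, condition profiles and FBA-based phenotype prediction.

A genotype is a set of deletion loci, optional reaction reintegrations and
optional heterologous modules; a condition profile encodes the qualitative
oxygen logic: the oxygen-sensitive pyruvate formate-lyase (and the
anaerobically expressed AdhE) operate only without oxygen, while the
NADH-producing (and NADH-inhibited) pyruvate dehydrogenase stands in for
acetyl-CoA synthesis aerobically.  These are hard switches — FBA cannot
encode the underlying expression control and allosteric inhibition, so the
profiles approximate them qualitatively.

Phenotype prediction reports growth feasibility, the secretion spectrum at
maximal growth (with total product secretion minimised at the optimum, so
optional by-products of degenerate optima are not reported), a
growth-coupling probe (minimum product secretion at a fixed fraction of
maximal growth), and maximum theoretical product yields at zero growth and
zero maintenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

from . import fixtures
from .model import (
    MetabolicModel,
    ReactionRecord,
    ZERO_FLUX_TOL,
    apply_deletions,
    fba,
    fva,
    _solve,
)

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Genotypes
# --------------------------------------------------------------------------

#: Deletion loci of the obligate-fermentative strain (19 loci; the nuo
#: operon is inactivated via nuoEFG — the encoded subunits are essential for
#: electron transfer — and mdaB/ygiN is a single joint locus).
NNMINI_LOCI: FrozenSet[str] = frozenset({
    "ndh", "nuoEFG", "putA", "glcDEF", "dld", "mqo", "dadA", "poxB", "kefF",
    "wrbA", "fadE", "yieF", "mdaB/ygiN", "glpD", "gpsA", "lldD", "glpABC",
    "sdhABCD", "lhgO",
})

_LOCUS_GENES: Dict[str, Set[str]] = {
    "nuoEFG": {"nuoE", "nuoF", "nuoG"},
    "sdhABCD": {"sdhA", "sdhB", "sdhC", "sdhD"},
    "mdaB/ygiN": {"mdaB", "ygiN"},
    "glpABC": {"glpA", "glpB", "glpC"},
    "glcDEF": {"glcD", "glcE", "glcF"},
}


def locus_to_genes(locus: str) -> Set[str]:
    """Genes removed by deleting one locus (operon loci expand)."""
    return set(_LOCUS_GENES.get(locus, {locus}))


@dataclass(frozen=True)
class Genotype:
    """A strain design: deletions (loci), reintegrations (reaction ids) and
    heterologous modules (module ids, e.g. ``pIBA``)."""

    name: str
    deletions: FrozenSet[str] = frozenset()
    reintegrations: FrozenSet[str] = frozenset()
    heterologous_modules: FrozenSet[str] = frozenset()

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for locus in self.deletions:
            out |= locus_to_genes(locus)
        return out


WILD_TYPE = Genotype(name="wild-type")
NN = Genotype(name="nn", deletions=frozenset({"ndh", "nuoEFG"}))
NNMINI = Genotype(name="nnmini", deletions=NNMINI_LOCI)
NNMINI_GLPD = Genotype(
    name="nnmini+glpD", deletions=NNMINI_LOCI, reintegrations=frozenset({"GLPD"})
)
NNMINI_GLPD_DLDHA_PIBA = Genotype(
    name="nnmini+glpD ΔldhA pIBA",
    deletions=NNMINI_LOCI | {"ldhA"},
    reintegrations=frozenset({"GLPD"}),
    heterologous_modules=frozenset({"pIBA"}),
)

PRESETS: Dict[str, Genotype] = {
    "wild-type": WILD_TYPE,
    "wt": WILD_TYPE,
    "nn": NN,
    "nnmini": NNMINI,
    "nnmini_glpd": NNMINI_GLPD,
    "nnmini_glpd_dldha_piba": NNMINI_GLPD_DLDHA_PIBA,
    "nnmini_glpd_dldh_piba": NNMINI_GLPD_DLDHA_PIBA,
}


def genotype_from_yaml(path: str) -> Genotype:
    """Load a genotype from YAML with keys name, deletions, reintegrations,
    heterologous_modules (the on-disk preset format)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"name", "deletions", "reintegrations",
                          "heterologous_modules"}
    if unknown:
        raise ValueError(f"unknown genotype keys: {sorted(unknown)}")
    return Genotype(
        name=raw.get("name", "custom"),
        deletions=frozenset(raw.get("deletions", ())),
        reintegrations=frozenset(raw.get("reintegrations", ())),
        heterologous_modules=frozenset(raw.get("heterologous_modules", ())),
    )


def get_preset(name: str) -> Genotype:
    key = name.strip().lower().replace("+", "_").replace(" ", "_")
    if key not in PRESETS:
        raise KeyError(
            f"unknown genotype preset {name!r}; available: "
            f"{sorted(set(PRESETS))}"
        )
    return PRESETS[key]


# --------------------------------------------------------------------------
# Conditions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionProfile:
    """Aerobic/anaerobic switching of oxygen-dependent reactions."""

    name: str
    o2_exchange_open: bool
    disabled_reactions: FrozenSet[str]
    o2_exchange_id: str = "EX_o2"
    o2_uptake_bound: float = 1000.0

    def __post_init__(self) -> None:
        if self.name == "anaerobic" and self.o2_exchange_open:
            raise ValueError("anaerobic profile cannot open the O2 exchange")


AEROBIC = ConditionProfile(
    name="aerobic", o2_exchange_open=True,
    disabled_reactions=frozenset({"PFL", "ADHE"}),
)
ANAEROBIC = ConditionProfile(
    name="anaerobic", o2_exchange_open=False,
    disabled_reactions=frozenset({"PDH"}),
)

CONDITIONS: Dict[str, ConditionProfile] = {"aerobic": AEROBIC, "anaerobic": ANAEROBIC}


# --------------------------------------------------------------------------
# Design application
# --------------------------------------------------------------------------


def apply_design(
    model: MetabolicModel,
    genotype: Genotype,
    condition: ConditionProfile,
) -> MetabolicModel:
    """Apply a genotype and a condition profile to a model copy.

    Order: gene deletions (GPR semantics) → reaction reintegrations
    (original bounds restored) → heterologous modules appended → condition
    toggles.  Deletion loci without a counterpart in the model are ignored
    (logged), so genome-scale genotype presets run against reduced models.
    """
    import warnings as _warnings

    genes = genotype.genes
    known = model.genes
    missing = genes - known
    if missing:
        logger.debug(
            "genotype %s: %d loci genes absent from model %s",
            genotype.name, len(missing), model.id,
        )
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        designed = apply_deletions(model, genes)
    for rid in genotype.reintegrations:
        if rid not in designed.reactions:
            raise KeyError(f"reintegration target {rid!r} not in model")
        designed.reactions[rid].lower_bound = model.reactions[rid].lower_bound
        designed.reactions[rid].upper_bound = model.reactions[rid].upper_bound
    for module in genotype.heterologous_modules:
        if module.lower() in ("piba", "piba4"):
            if "ALSS" not in designed.reactions:
                fixtures.add_isobutanol_pathway(designed)
        else:
            raise KeyError(f"unknown heterologous module {module!r}")
    for rid in condition.disabled_reactions:
        if rid in designed.reactions:
            designed.reactions[rid].lower_bound = 0.0
            designed.reactions[rid].upper_bound = 0.0
    if condition.o2_exchange_id in designed.reactions:
        o2 = designed.reactions[condition.o2_exchange_id]
        o2.lower_bound = -condition.o2_uptake_bound if condition.o2_exchange_open else 0.0
    return designed


def _open_uptake(model: MetabolicModel, exchange_id: str, bound: float) -> None:
    if exchange_id not in model.reactions:
        raise KeyError(f"substrate exchange {exchange_id!r} not in model")
    model.reactions[exchange_id].lower_bound = -abs(bound)


def product_exchange_ids(model: MetabolicModel) -> List[str]:
    return sorted(
        rid for rid, r in model.reactions.items() if "product" in r.annotation_tags
    )


# --------------------------------------------------------------------------
# Phenotype prediction
# --------------------------------------------------------------------------


@dataclass
class PhenotypePrediction:
    genotype: str
    condition: str
    substrate: str
    growth_feasible: bool
    max_growth: float = 0.0
    secretion_profile: Dict[str, float] = field(default_factory=dict)
    max_product_yield: Optional[float] = None
    coupled: Optional[bool] = None
    coupled_product: Optional[str] = None


def predict_phenotype(
    model: MetabolicModel,
    genotype: Genotype,
    condition: ConditionProfile,
    substrate: str,
    uptake_bound: float = 10.0,
    product: Optional[str] = None,
    coupling_fraction: float = 0.1,
    growth_threshold: float = 1e-6,
) -> PhenotypePrediction:
    """Predict growth, secretion spectrum, coupling and yield by FBA.

    The secretion profile is taken at maximal growth with total product
    secretion minimised (a parsimony tie-break over degenerate optima); the
    coupling probe asks for the minimum secretion of the (main or given)
    product with growth fixed at ``coupling_fraction`` of its maximum.
    An infeasible problem yields ``growth_feasible=False``, no exception.
    """
    designed = apply_design(model, genotype, condition)
    _open_uptake(designed, substrate, uptake_bound)
    biomass = designed.objective_reaction
    sol = fba(designed, biomass, "max")
    prediction = PhenotypePrediction(
        genotype=genotype.name,
        condition=condition.name,
        substrate=substrate,
        growth_feasible=sol.ok and sol.objective_value > growth_threshold,
    )
    if not prediction.growth_feasible:
        return prediction
    mu_max = sol.objective_value
    prediction.max_growth = mu_max

    products = product_exchange_ids(designed)
    probe = designed.copy()
    probe.reactions[biomass].lower_bound = mu_max - 1e-9 * max(1.0, abs(mu_max))
    probe.reactions[biomass].upper_bound = mu_max + 1e-9 * max(1.0, abs(mu_max))
    parsimony = _solve(probe, {rid: 1.0 for rid in products}, "min")
    flux_source = parsimony if parsimony.ok else sol
    prediction.secretion_profile = {
        rid: flux_source.fluxes[rid]
        for rid in products
        if flux_source.fluxes.get(rid, 0.0) > ZERO_FLUX_TOL
    }

    coupled_product = product or (
        max(prediction.secretion_profile, key=prediction.secretion_profile.get)
        if prediction.secretion_profile
        else None
    )
    if coupled_product is not None:
        probe = designed.copy()
        probe.reactions[biomass].lower_bound = coupling_fraction * mu_max
        low = _solve(probe, {coupled_product: 1.0}, "min")
        prediction.coupled = low.ok and low.objective_value > ZERO_FLUX_TOL
        prediction.coupled_product = coupled_product
        prediction.max_product_yield = max_theoretical_yield(
            model, genotype, condition, substrate, coupled_product
        )
    return prediction


def max_theoretical_yield(
    model: MetabolicModel,
    genotype: Genotype,
    condition: ConditionProfile,
    substrate: str,
    product: str,
    maintenance: float = 0.0,
) -> float:
    """Maximum theoretical product yield (mol product / mol substrate).

    Growth is fixed to zero and maintenance ATP defaults to zero, so the
    bound reflects stoichiometry (carbon and electrons) only.  Returns 0 if
    the product is unreachable in the designed strain.
    """
    designed = apply_design(model, genotype, condition)
    if product not in designed.reactions:
        raise KeyError(f"product exchange {product!r} not in model")
    biomass = designed.objective_reaction
    if biomass:
        designed.reactions[biomass].lower_bound = 0.0
        designed.reactions[biomass].upper_bound = 0.0
    if "ATPM" in designed.reactions:
        designed.reactions["ATPM"].lower_bound = maintenance
    _open_uptake(designed, substrate, 1.0)
    designed.reactions[substrate].upper_bound = 0.0
    sol = fba(designed, product, "max")
    if not sol.ok or sol.objective_value < ZERO_FLUX_TOL:
        logger.info(
            "product %s unreachable from %s in %s/%s",
            product, substrate, genotype.name, condition.name,
        )
        return 0.0
    uptake = -sol.fluxes[substrate]
    if uptake < ZERO_FLUX_TOL:
        return 0.0
    return sol.objective_value / uptake


@dataclass(frozen=True)
class YieldPercent:
    """Measured yield as a percent of the theoretical maximum."""

    exact: float
    percent: int


def percent_of_max_yield(
    measured_product: float, fed_substrate: float, theoretical: float
) -> YieldPercent:
    """Measured product / fed substrate, as a percent of the theoretical
    mol/mol maximum (integer percent for reporting, exact value retained)."""
    if fed_substrate <= 0:
        raise ValueError("fed substrate must be positive")
    if measured_product < 0:
        raise ValueError("measured product must be non-negative")
    if theoretical <= 0:
        raise ValueError("theoretical maximum yield must be positive")
    exact = 100.0 * (measured_product / fed_substrate) / theoretical
    return YieldPercent(exact=exact, percent=int(round(exact)))


# --------------------------------------------------------------------------
# Carbon-label reachability
# --------------------------------------------------------------------------

#: Compounds never used as carbon conduits: CO2 and the catalytic cofactor
#: couples (their carbon skeletons are regenerated, not transmitted).
COFACTOR_CONDUITS: FrozenSet[str] = frozenset({
    "co2", "coa", "atp", "adp", "amp", "pi", "nad", "nadh", "nadp", "nadph",
    "q8", "q8h2", "h", "h2o", "o2", "pmf",
})


def label_reachability(
    designed: MetabolicModel,
    source: str,
    sink_precursors: Sequence[str],
    flux_tol: float = ZERO_FLUX_TOL,
) -> Set[str]:
    """Which precursor pools can carry carbon from a labelled source.

    Breadth-first reachability over the carbon-carrying edges of reactions
    able to sustain flux in the designed strain (flux capability from FVA
    without a growth requirement), with CO2 and cofactor couples excluded as
    conduits.  For the capability probe the fixed-ratio biomass draw is
    replaced by independent demand sinks for its carbon precursors —
    otherwise the rigid biomass stoichiometry spuriously blocks assimilation
    routes that only feed a subset of precursor pools.  This is a
    flux-capability graph heuristic, not atom mapping: a reported reachable
    pool means a carbon path exists in the flux-capable subnetwork, without
    tracing individual atom positions.
    """
    if source not in designed.compounds:
        raise KeyError(f"unknown source compound {source!r}")
    internal = [
        rid for rid, r in designed.reactions.items()
        if not (r.is_exchange or r.is_biomass) and not r.disabled()
    ]
    probe_model = designed.copy()
    for rxn in list(probe_model.reactions.values()):
        if rxn.is_biomass:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
            for met, coeff in rxn.stoichiometry.items():
                if coeff < 0 and met not in COFACTOR_CONDUITS and (
                    probe_model.compounds[met].n_carbon > 0
                ):
                    probe_model.add_reaction(
                        ReactionRecord(
                            id=f"DM_{met}",
                            stoichiometry={met: -1.0},
                            lower_bound=0.0,
                            annotation_tags={"exchange", "demand"},
                        )
                    )
    capability = fva(probe_model, internal, fraction_of_optimum=0.0)

    def carbon_mets(stoich: Mapping[str, float], sign: int) -> List[str]:
        return [
            m for m, c in stoich.items()
            if sign * c > 0
            and m not in COFACTOR_CONDUITS
            and designed.compounds[m].n_carbon > 0
        ]

    edges: Dict[str, Set[str]] = {}
    for rid in internal:
        vmin, vmax = capability[rid]
        stoich = designed.reactions[rid].stoichiometry
        directions = []
        if vmax > flux_tol:
            directions.append(1)
        if vmin < -flux_tol:
            directions.append(-1)
        for d in directions:
            for src in carbon_mets(stoich, -d):
                for dst in carbon_mets(stoich, d):
                    edges.setdefault(src, set()).add(dst)

    reachable = {source}
    frontier = [source]
    while frontier:
        nxt = []
        for met in frontier:
            for dst in edges.get(met, ()):
                if dst not in reachable:
                    reachable.add(dst)
                    nxt.append(dst)
        frontier = nxt
    return {s for s in sink_precursors if s in reachable}


# --------------------------------------------------------------------------
# Reporting
# --------------------------------------------------------------------------


def prediction_report(prediction: PhenotypePrediction) -> Dict:
    return {
        "genotype": prediction.genotype,
        "condition": prediction.condition,
        "substrate": prediction.substrate,
        "growth_feasible": prediction.growth_feasible,
        "max_growth": prediction.max_growth,
        "secretion_profile": dict(sorted(prediction.secretion_profile.items())),
        "max_product_yield": prediction.max_product_yield,
        "coupled": prediction.coupled,
        "coupled_product": prediction.coupled_product,
    }
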