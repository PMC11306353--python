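"""Deterministic synthetic fixtures: a toy respiro-fermentative core network
and a census annotation fixture.

The toy model is a ~35-reaction single-compartment *E. coli* core network
built for reasoning about obligate fermentation and controlled
respiro-fermentation at the same resolution as the strain design itself:
lumped glycolysis, the fermentation branches (D-lactate, acetate, formate,
ethanol), a TCA fragment with the glyoxylate shunt, an electron transport
chain with an explicit ubiquinone pool, glycerol assimilation through
GlpK/GlpD/GpsA, and an optional heterologous isobutanol pathway.  Every
non-exchange, non-biomass reaction is element- and charge-balanced with real
molecular formulas, so degree-of-reduction conservation holds exactly for
any steady-state flux.

Key closure choices (see docs/methods.md for the full rationale):

* Proton-motive force is a massless pseudo-metabolite ``pmf`` with integer
  pumping stoichiometries (defaults 4 per NADH at Nuo, 4 per quinol at the
  oxidase, 4 per ATP at the synthase).  Only qualitative "extra ATP" claims
  should ever be asserted against it.
* The biomass pseudo-reaction draws the five precursors (pyruvate,
  acetyl-CoA, oxaloacetate, 2-oxoglutarate, glycerol 3-phosphate) plus
  10 ATP and 7 NADH.  Seven is exactly the NADH co-produced when the
  precursor set is synthesised from glucose (5 from lower glycolysis, 2 from
  Pdh, 1 from Icd, minus 1 invested in G3P), so biomass formation is
  redox-neutral and secreted products remain the network's only electron
  valves.
* ``G3PSYN`` is a lumped, ATP-coupled biosynthetic glycerol-3-phosphate
  supply (no gene).  It keeps ΔgpsA strains viable on glucose; its ATP
  coupling both excludes it from mini-cycle space and makes any
  NADH→quinone dumping through GlpD+G3PSYN strictly ATP-costly.

The census fixture is a separate miniature network carrying one reaction per
quinone-reducing activity discussed for the genome-scale reconstruction,
with gene groups, curation lists and NAD(P)H-dependent counterpart
reactions arranged to reproduce the published census ledger
(17 enumerated / 6 excluded / 3 added / 14 relevant / 7 oxidoreductase and
12 dehydrogenase gene groups / 8 mini-cycles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .model import (
    Compound,
    DEFAULT_BOUND,
    MetabolicModel,
    ReactionRecord,
    parse_formula,
)

# Biomass draw coefficients.  BIOMASS_NADH equals the NADH co-produced per
# biomass unit by precursor synthesis from glucose (5 GLYCL + 2 PDH + 1 ICD
# - 1 G3PSYN); BIOMASS_ATP makes growth ATP-limited so that fermentative ATP
# generation, and with it product secretion, is growth-coupled.
BIOMASS_ATP = 10.0
BIOMASS_NADH = 7.0

#: Exchange reactions considered organic fermentation/secretion products.
PRODUCT_EXCHANGES = ("EX_lac__D", "EX_ac", "EX_for", "EX_etoh", "EX_ibuoh")


@dataclass
class ToyModelConfig:
    """Stoichiometric knobs of the toy network.

    All pumping quotients are non-negative integers (protons per reaction
    event); ``atp_maintenance`` is the forced lower bound of the ATP
    maintenance reaction in mmol gCDW^-1 h^-1.  The isobutanol pathway
    reductase cofactor defaults to NADH, mirroring the NADH-preferring IlvC
    variant carried by the production plasmid.
    """

    nuo_pmf_per_nadh: int = 4
    oxidase_pmf_per_quinol: int = 4
    atp_per_pmf_quotient: int = 4
    atp_maintenance: float = 1.0
    include_isobutanol_pathway: bool = False
    ilvC_cofactor: str = "nadh"

    def __post_init__(self) -> None:
        for name in ("nuo_pmf_per_nadh", "oxidase_pmf_per_quinol",
                     "atp_per_pmf_quotient"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer")
        if self.atp_maintenance < 0:
            raise ValueError("atp_maintenance must be non-negative")
        if self.ilvC_cofactor not in ("nadh", "nadph"):
            raise ValueError("ilvC_cofactor must be 'nadh' or 'nadph'")


_COMPOUNDS: Dict[str, Tuple[str, str, int]] = {
    # id: (name, formula, charge)
    "glc__D": ("D-glucose", "C6H12O6", 0),
    "glyc": ("glycerol", "C3H8O3", 0),
    "glyc3p": ("glycerol 3-phosphate", "C3H7O6P", -2),
    "dhap": ("dihydroxyacetone phosphate", "C3H5O6P", -2),
    "pep": ("phosphoenolpyruvate", "C3H2O6P", -3),
    "pyr": ("pyruvate", "C3H3O3", -1),
    "lac__D": ("D-lactate", "C3H5O3", -1),
    "accoa": ("acetyl-CoA", "C23H34N7O17P3S", -4),
    "coa": ("coenzyme A", "C21H32N7O16P3S", -4),
    "for": ("formate", "CHO2", -1),
    "ac": ("acetate", "C2H3O2", -1),
    "etoh": ("ethanol", "C2H6O", 0),
    "cit": ("citrate", "C6H5O7", -3),
    "icit": ("isocitrate", "C6H5O7", -3),
    "akg": ("2-oxoglutarate", "C5H4O5", -2),
    "succ": ("succinate", "C4H4O4", -2),
    "fum": ("fumarate", "C4H2O4", -2),
    "mal__L": ("L-malate", "C4H4O5", -2),
    "glx": ("glyoxylate", "C2HO3", -1),
    "oaa": ("oxaloacetate", "C4H2O5", -2),
    "atp": ("ATP", "C10H12N5O13P3", -4),
    "adp": ("ADP", "C10H12N5O10P2", -3),
    "pi": ("phosphate", "HO4P", -2),
    "nad": ("NAD+", "C21H26N7O14P2", -1),
    "nadh": ("NADH", "C21H27N7O14P2", -2),
    "q8": ("ubiquinone-8", "C49H74O4", 0),
    "q8h2": ("ubiquinol-8", "C49H76O4", 0),
    "o2": ("oxygen", "O2", 0),
    "co2": ("carbon dioxide", "CO2", 0),
    "h2o": ("water", "H2O", 0),
    "h": ("proton", "H", 1),
    "pmf": ("proton-motive force", "", 0),
}

_PIBA_COMPOUNDS: Dict[str, Tuple[str, str, int]] = {
    "alac": ("2-acetolactate", "C5H7O4", -1),
    "dhiv": ("2,3-dihydroxy-3-methylbutanoate", "C5H9O4", -1),
    "3mob": ("3-methyl-2-oxobutanoate", "C5H7O3", -1),
    "ibald": ("isobutyraldehyde", "C4H8O", 0),
    "ibuoh": ("isobutanol", "C4H10O", 0),
    "nadp": ("NADP+", "C21H25N7O17P3", -3),
    "nadph": ("NADPH", "C21H26N7O17P3", -4),
}


def _cpd(cid: str, table: Dict[str, Tuple[str, str, int]] = _COMPOUNDS) -> Compound:
    name, formula, charge = table[cid]
    return Compound(
        id=cid, name=name, element_counts=parse_formula(formula), charge=charge
    )


def _rxn(
    rid: str,
    stoich: Dict[str, float],
    lb: float = 0.0,
    ub: float = DEFAULT_BOUND,
    gpr: str = "",
    tags: Optional[set] = None,
    name: str = "",
    group: str = "",
) -> ReactionRecord:
    return ReactionRecord(
        id=rid,
        name=name or rid,
        stoichiometry=dict(stoich),
        lower_bound=lb,
        upper_bound=ub,
        gene_association=gpr,
        annotation_tags=set(tags or ()),
        gene_group=group,
    )


def add_isobutanol_pathway(
    model: MetabolicModel, cofactor: str = "nadh"
) -> MetabolicModel:
    """Append the heterologous isobutanol (pIBA) pathway in place.

    AlsS condenses two pyruvate to acetolactate (one CO2 lost), IlvC/IlvD
    make ketoisovalerate, Kivd decarboxylates it (second CO2), and AdhA
    reduces the aldehyde.  With the NADH-utilising reductase variant the
    pathway consumes exactly the two NADH of lower glycolysis, so two
    glycerols close redox through two GlpD-generated quinols.
    """
    for cid in ("alac", "dhiv", "3mob", "ibald", "ibuoh"):
        if cid not in model.compounds:
            model.add_compound(_cpd(cid, _PIBA_COMPOUNDS))
    red, ox = ("nadh", "nad") if cofactor == "nadh" else ("nadph", "nadp")
    if red not in model.compounds:
        model.add_compound(_cpd(red, _PIBA_COMPOUNDS))
        model.add_compound(_cpd(ox, _PIBA_COMPOUNDS))
    model.add_reaction(_rxn(
        "ALSS", {"pyr": -2, "h": -1, "alac": 1, "co2": 1},
        gpr="alsS", name="acetolactate synthase", tags={"heterologous"},
    ))
    model.add_reaction(_rxn(
        "ILVC", {"alac": -1, red: -1, "h": -1, "dhiv": 1, ox: 1},
        gpr="ilvC", name="ketol-acid reductoisomerase", tags={"heterologous"},
    ))
    model.add_reaction(_rxn(
        "ILVD", {"dhiv": -1, "3mob": 1, "h2o": 1},
        gpr="ilvD", name="dihydroxy-acid dehydratase", tags={"heterologous"},
    ))
    model.add_reaction(_rxn(
        "KIVD", {"3mob": -1, "h": -1, "ibald": 1, "co2": 1},
        gpr="kivd", name="2-ketoisovalerate decarboxylase", tags={"heterologous"},
    ))
    model.add_reaction(_rxn(
        "ADHA", {"ibald": -1, "nadh": -1, "h": -1, "ibuoh": 1, "nad": 1},
        gpr="adhA", name="isobutanol dehydrogenase", tags={"heterologous"},
    ))
    model.add_reaction(_rxn(
        "EX_ibuoh", {"ibuoh": -1}, lb=0.0, tags={"exchange", "product"},
        name="isobutanol exchange",
    ))
    return model


def build_toy_model(config: Optional[ToyModelConfig] = None) -> MetabolicModel:
    """Build the toy respiro-fermentative core network.

    All substrate exchanges are closed by default (uptake is opened per
    scenario); oxygen, CO2, water, proton and phosphate exchanges are free.
    The objective is the biomass pseudo-reaction.
    """
    config = config or ToyModelConfig()
    m = MetabolicModel(model_id="toy_respiroferm_core")
    for cid in _COMPOUNDS:
        m.add_compound(_cpd(cid))

    # --- exchanges ---------------------------------------------------------
    free = {"EX_o2": "o2", "EX_co2": "co2", "EX_h2o": "h2o", "EX_h": "h",
            "EX_pi": "pi"}
    for rid, cid in free.items():
        m.add_reaction(_rxn(rid, {cid: -1}, lb=-DEFAULT_BOUND, tags={"exchange"}))
    for rid, cid in (("EX_glc__D", "glc__D"), ("EX_glyc", "glyc")):
        m.add_reaction(_rxn(rid, {cid: -1}, lb=0.0, tags={"exchange", "substrate"}))
    m.add_reaction(_rxn("EX_ac", {"ac": -1}, lb=0.0,
                        tags={"exchange", "product", "substrate"}))
    for rid, cid in (("EX_lac__D", "lac__D"), ("EX_for", "for"),
                     ("EX_etoh", "etoh")):
        m.add_reaction(_rxn(rid, {cid: -1}, lb=0.0, tags={"exchange", "product"}))

    # --- glycolysis and anaplerosis ---------------------------------------
    m.add_reaction(_rxn(
        "GLCUPT",
        {"glc__D": -1, "atp": -2, "dhap": 2, "adp": 2, "h": 2},
        name="glucose PTS uptake + upper glycolysis (lumped)",
    ))
    m.add_reaction(_rxn(
        "GLYCL",
        {"dhap": -1, "nad": -1, "adp": -1, "pi": -1,
         "pep": 1, "nadh": 1, "atp": 1, "h2o": 1, "h": 1},
        lb=-DEFAULT_BOUND,
        name="lower glycolysis DHAP->PEP (lumped, reversible)",
    ))
    m.add_reaction(_rxn(
        "PYK", {"pep": -1, "adp": -1, "h": -1, "pyr": 1, "atp": 1}, gpr="pykF",
        name="pyruvate kinase",
    ))
    m.add_reaction(_rxn(
        "PPC", {"pep": -1, "co2": -1, "h2o": -1, "oaa": 1, "pi": 1, "h": 1},
        gpr="ppc", name="PEP carboxylase",
    ))
    m.add_reaction(_rxn(
        "PCK", {"oaa": -1, "atp": -1, "pep": 1, "co2": 1, "adp": 1}, gpr="pck",
        name="PEP carboxykinase",
    ))

    # --- fermentation branches --------------------------------------------
    m.add_reaction(_rxn(
        "LDHA", {"pyr": -1, "nadh": -1, "h": -1, "lac__D": 1, "nad": 1},
        gpr="ldhA", name="D-lactate dehydrogenase (NADH)",
    ))
    m.add_reaction(_rxn(
        "DLD", {"lac__D": -1, "q8": -1, "pyr": 1, "q8h2": 1}, gpr="dld",
        name="D-lactate dehydrogenase (ubiquinone)", group="dld",
    ))
    m.add_reaction(_rxn(
        "PDH", {"pyr": -1, "coa": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1},
        gpr="aceE and aceF and lpd", name="pyruvate dehydrogenase",
    ))
    m.add_reaction(_rxn(
        "PFL", {"pyr": -1, "coa": -1, "accoa": 1, "for": 1}, gpr="pflB",
        name="pyruvate formate-lyase",
    ))
    m.add_reaction(_rxn(
        "PTACK",
        {"accoa": -1, "adp": -1, "pi": -1, "ac": 1, "coa": 1, "atp": 1},
        lb=-DEFAULT_BOUND, gpr="pta and ackA",
        name="phosphotransacetylase + acetate kinase (lumped, reversible)",
    ))
    m.add_reaction(_rxn(
        "ADHE",
        {"accoa": -1, "nadh": -2, "h": -2, "etoh": 1, "coa": 1, "nad": 2},
        gpr="adhE", name="aldehyde/alcohol dehydrogenase",
    ))

    # --- glycerol assimilation --------------------------------------------
    m.add_reaction(_rxn(
        "GLPK", {"glyc": -1, "atp": -1, "glyc3p": 1, "adp": 1, "h": 1},
        gpr="glpK", name="glycerol kinase",
    ))
    m.add_reaction(_rxn(
        "GLPD", {"glyc3p": -1, "q8": -1, "dhap": 1, "q8h2": 1}, gpr="glpD",
        name="glycerol 3-phosphate dehydrogenase (ubiquinone)", group="glpD",
    ))
    m.add_reaction(_rxn(
        "GPSA", {"dhap": -1, "nadh": -1, "h": -1, "glyc3p": 1, "nad": 1},
        gpr="gpsA", name="glycerol 3-phosphate dehydrogenase (NADH)",
    ))
    m.add_reaction(_rxn(
        "G3PSYN",
        {"dhap": -1, "nadh": -1, "atp": -2, "h2o": -2,
         "glyc3p": 1, "nad": 1, "adp": 2, "pi": 2, "h": 1},
        name="biosynthetic G3P supply (lumped, ATP-coupled)",
    ))

    # --- TCA fragment + glyoxylate shunt ----------------------------------
    m.add_reaction(_rxn(
        "CS", {"accoa": -1, "oaa": -1, "h2o": -1, "cit": 1, "coa": 1, "h": 1},
        gpr="gltA", name="citrate synthase",
    ))
    m.add_reaction(_rxn(
        "ACONT", {"cit": -1, "icit": 1}, lb=-DEFAULT_BOUND, gpr="acnA or acnB",
        name="aconitase (isozymes)",
    ))
    m.add_reaction(_rxn(
        "ICD", {"icit": -1, "nad": -1, "akg": 1, "co2": 1, "nadh": 1},
        gpr="icd", name="isocitrate dehydrogenase",
    ))
    m.add_reaction(_rxn(
        "ICL", {"icit": -1, "glx": 1, "succ": 1}, gpr="aceA",
        name="isocitrate lyase",
    ))
    m.add_reaction(_rxn(
        "MALS",
        {"accoa": -1, "glx": -1, "h2o": -1, "mal__L": 1, "coa": 1, "h": 1},
        gpr="aceB", name="malate synthase",
    ))
    m.add_reaction(_rxn(
        "FUM", {"fum": -1, "h2o": -1, "mal__L": 1}, lb=-DEFAULT_BOUND,
        gpr="fumA or fumB or fumC", name="fumarase (isozymes)",
    ))
    m.add_reaction(_rxn(
        "MDH", {"mal__L": -1, "nad": -1, "oaa": 1, "nadh": 1, "h": 1},
        lb=-DEFAULT_BOUND, gpr="mdh", name="malate dehydrogenase (NAD)",
    ))
    m.add_reaction(_rxn(
        "MQO", {"mal__L": -1, "q8": -1, "oaa": 1, "q8h2": 1}, gpr="mqo",
        name="malate:quinone oxidoreductase", group="mqo",
    ))
    m.add_reaction(_rxn(
        "SDH", {"succ": -1, "q8": -1, "fum": 1, "q8h2": 1},
        gpr="sdhA and sdhB and sdhC and sdhD",
        name="succinate dehydrogenase", group="sdh",
    ))

    # --- electron transport chain and energy -------------------------------
    m.add_reaction(_rxn(
        "NDH", {"nadh": -1, "h": -1, "q8": -1, "nad": 1, "q8h2": 1}, gpr="ndh",
        name="NADH dehydrogenase II (non-pumping)", group="ndh",
    ))
    nuo = {"nadh": -1, "h": -1, "q8": -1, "nad": 1, "q8h2": 1}
    if config.nuo_pmf_per_nadh:
        nuo["pmf"] = float(config.nuo_pmf_per_nadh)
    m.add_reaction(_rxn(
        "NUO", nuo,
        gpr=" and ".join(f"nuo{c}" for c in "ABCDEFGHIJKLMN"),
        name="NADH dehydrogenase I (proton-pumping)", group="nuo",
    ))
    cyo = {"q8h2": -1, "o2": -0.5, "q8": 1, "h2o": 1}
    if config.oxidase_pmf_per_quinol:
        cyo["pmf"] = float(config.oxidase_pmf_per_quinol)
    m.add_reaction(_rxn(
        "CYO", cyo, gpr="cyoA and cyoB and cyoC and cyoD",
        name="terminal oxidase",
    ))
    m.add_reaction(_rxn(
        "ATPS",
        {"adp": -1, "pi": -1, "h": -1, "pmf": -float(config.atp_per_pmf_quotient),
         "atp": 1, "h2o": 1},
        name="ATP synthase",
    ))
    m.add_reaction(_rxn(
        "ATPM", {"atp": -1, "h2o": -1, "adp": 1, "pi": 1, "h": 1},
        lb=config.atp_maintenance, tags={"maintenance"},
        name="ATP maintenance",
    ))
    m.add_reaction(_rxn(
        "BIOMASS",
        {"pyr": -1, "accoa": -1, "oaa": -1, "akg": -1, "glyc3p": -1,
         "atp": -BIOMASS_ATP, "nadh": -BIOMASS_NADH, "h2o": -BIOMASS_ATP,
         "coa": 1, "adp": BIOMASS_ATP, "pi": BIOMASS_ATP, "nad": BIOMASS_NADH},
        tags={"biomass"}, name="biomass pseudo-reaction",
    ))
    m.objective_reaction = "BIOMASS"
    m.quinone_pairs = [("q8", "q8h2")]

    if config.include_isobutanol_pathway:
        add_isobutanol_pathway(m, config.ilvC_cofactor)

    m.validate()
    from .model import assign_role_tags

    assign_role_tags(m)
    return m


# ---------------------------------------------------------------------------
# Census fixture
# ---------------------------------------------------------------------------

#: Curation lists reproducing the published census.  The reasons are the
#: fixture's own short curation notes standing in for expert curation; the
#: pipeline carries them as free text and never re-derives biology from them.
EXCLUSIONS: Tuple[Tuple[str, str], ...] = (
    ("ASPO3", "biosynthetic L-aspartate oxidase (NAD synthesis), negligible catabolic flux"),
    ("DHORD2", "biosynthetic dihydroorotate dehydrogenase (pyrimidine synthesis)"),
    ("DSBAO1", "periplasmic disulfide-bond formation relay, not a catabolic electron entry"),
    ("FDH4pp", "periplasmic formate dehydrogenase, no formate in aerobic minimal medium"),
    ("HYD1pp", "periplasmic hydrogenase, no hydrogen in aerobic minimal medium"),
    ("GLCDpp", "periplasmic PQQ-dependent glucose dehydrogenase, apo-enzyme in minimal medium"),
)

ADDITIONS: Tuple[str, ...] = ("LHGO", "FADE", "DADA")

_FIX_COMPOUNDS: Dict[str, Tuple[str, str, int]] = {
    **_COMPOUNDS,
    **_PIBA_COMPOUNDS,
    "lac__L": ("L-lactate", "C3H5O3", -1),
    "pro__L": ("L-proline", "C5H9NO2", 0),
    "1pyr5c": ("1-pyrroline-5-carboxylate", "C5H6NO2", -1),
    "glyclt": ("glycolate", "C2H3O3", -1),
    "asp__L": ("L-aspartate", "C4H6NO4", -1),
    "iasp": ("iminoaspartate", "C4H3NO4", -2),
    "dhor__S": ("(S)-dihydroorotate", "C5H5N2O4", -1),
    "orot": ("orotate", "C5H3N2O4", -1),
    "dsbrd": ("reduced dithiol acceptor (synthetic stand-in)", "C2H4S2", 0),
    "dsbox": ("oxidized disulfide acceptor (synthetic stand-in)", "C2H2S2", 0),
    "h2": ("hydrogen", "H2", 0),
    "g15lac": ("glucono-1,5-lactone", "C6H10O6", 0),
    "btcoa": ("butanoyl-CoA", "C25H38N7O17P3S", -4),
    "b2coa": ("crotonoyl-CoA", "C25H36N7O17P3S", -4),
    "ala__D": ("D-alanine", "C3H7NO2", 0),
    "nh4": ("ammonium", "H4N", 1),
    "2hglut": ("L-2-hydroxyglutarate", "C5H6O5", -2),
}


@dataclass
class CensusFixture:
    """Annotation table and curation lists of the census fixture."""

    reactions: pd.DataFrame
    exclusion_list: List[Tuple[str, str]] = field(
        default_factory=lambda: list(EXCLUSIONS)
    )
    addition_list: List[str] = field(default_factory=lambda: list(ADDITIONS))
    reintegration: List[str] = field(default_factory=lambda: ["glpD"])

    def curation_config(self) -> Dict:
        """Curation config dict in the on-disk (YAML/JSON) schema."""
        return {
            "exclusions": [
                {"id": rid, "reason": reason} for rid, reason in self.exclusion_list
            ],
            "additions": [
                {"id": rid, "source": "ecocyc"} for rid in self.addition_list
            ],
            "reintegration": list(self.reintegration),
        }


def build_census_fixture() -> Tuple[MetabolicModel, CensusFixture]:
    """Miniature quinone-reaction network reproducing the published census.

    Seventeen reactions carry the ``quinone_reducing_model`` annotation
    (the model-sourced enumeration), three carry ``quinone_reducing_ecocyc``
    (the database additions), and each of the eight mini-cycle-forming
    dehydrogenase gene groups has an NAD(P)H-dependent counterpart reaction
    present.  Counterparts marked ``_SYN`` are fixture-only inventions where
    the organism's counterpart enzyme is not established.
    """
    m = MetabolicModel(model_id="census_fixture")
    for cid in _FIX_COMPOUNDS:
        m.add_compound(_cpd(cid, _FIX_COMPOUNDS))

    model_tag = {"quinone_reducing_model"}
    ecocyc_tag = {"quinone_reducing_ecocyc"}

    rows: List[Tuple[str, str, str, str]] = []  # id, group, class hint, source

    def census_rxn(rid, stoich, gpr, group, source, name=""):
        tags = model_tag if source == "model" else ecocyc_tag
        m.add_reaction(_rxn(rid, stoich, gpr=gpr, tags=set(tags), group=group,
                            name=name))
        rows.append((rid, group, source))

    # NAD(P)H:quinone oxidoreductases (7 gene groups on 3 reactions).
    census_rxn("NADH5", {"nadh": -1, "h": -1, "q8": -1, "nad": 1, "q8h2": 1},
               "ndh", "ndh", "model", "NADH dehydrogenase II")
    census_rxn("NADH16pp",
               {"nadh": -1, "h": -1, "q8": -1, "nad": 1, "q8h2": 1, "pmf": 4},
               " and ".join(f"nuo{c}" for c in "ABCDEFGHIJKLMN"),
               "nuo", "model", "NADH dehydrogenase I (proton-pumping)")
    census_rxn("NQOR", {"nadph": -1, "h": -1, "q8": -1, "nadp": 1, "q8h2": 1},
               "kefF or wrbA or yieF or mdaB or ygiN",
               "kefF|wrbA|yieF|mdaB|ygiN", "model",
               "NAD(P)H:quinone oxidoreductases (promiscuous isozymes)")

    # Quinone-dependent dehydrogenases annotated in the model.
    census_rxn("SUCDi", {"succ": -1, "q8": -1, "fum": 1, "q8h2": 1},
               "sdhA and sdhB and sdhC and sdhD", "sdh", "model",
               "succinate dehydrogenase")
    census_rxn("LLACD", {"lac__L": -1, "q8": -1, "pyr": 1, "q8h2": 1},
               "lldD", "lldD", "model", "L-lactate dehydrogenase (ubiquinone)")
    census_rxn("POX", {"pyr": -1, "q8": -1, "h2o": -1,
                       "ac": 1, "co2": 1, "q8h2": 1},
               "poxB", "poxB", "model", "pyruvate oxidase")
    census_rxn("DLACD", {"lac__D": -1, "q8": -1, "pyr": 1, "q8h2": 1},
               "dld", "dld", "model", "D-lactate dehydrogenase (ubiquinone)")
    census_rxn("MOX", {"mal__L": -1, "q8": -1, "oaa": 1, "q8h2": 1},
               "mqo", "mqo", "model", "malate:quinone oxidoreductase")
    census_rxn("PROD2", {"pro__L": -1, "q8": -1, "1pyr5c": 1, "h": 1, "q8h2": 1},
               "putA", "putA", "model", "proline dehydrogenase")
    census_rxn("G3PDq", {"glyc3p": -1, "q8": -1, "dhap": 1, "q8h2": 1},
               "glpD or (glpA and glpB and glpC)", "glpD|glpABC", "model",
               "glycerol 3-phosphate dehydrogenase (aerobic/anaerobic isozymes)")
    census_rxn("GLYCTO1", {"glyclt": -1, "q8": -1, "glx": 1, "q8h2": 1},
               "glcD and glcE and glcF", "glcDEF", "model",
               "glycolate dehydrogenase")

    # Curated-out reactions (still model-annotated, hence enumerated).
    census_rxn("ASPO3", {"asp__L": -1, "q8": -1, "iasp": 1, "h": 1, "q8h2": 1},
               "nadB", "nadB", "model", "L-aspartate oxidase")
    census_rxn("DHORD2", {"dhor__S": -1, "q8": -1, "orot": 1, "q8h2": 1},
               "pyrD", "pyrD", "model", "dihydroorotate dehydrogenase")
    census_rxn("DSBAO1", {"dsbrd": -1, "q8": -1, "dsbox": 1, "q8h2": 1},
               "dsbA and dsbB", "dsbAB", "model",
               "disulfide-bond oxidoreductase relay")
    census_rxn("FDH4pp", {"for": -1, "h": -1, "q8": -1, "co2": 1, "q8h2": 1},
               "fdoG and fdoH and fdoI", "fdoGHI", "model",
               "formate dehydrogenase O")
    census_rxn("HYD1pp", {"h2": -1, "q8": -1, "q8h2": 1},
               "hyaA and hyaB and hyaC", "hyaABC", "model", "hydrogenase 1")
    census_rxn("GLCDpp", {"glc__D": -1, "q8": -1, "g15lac": 1, "q8h2": 1},
               "gcd", "gcd", "model", "quinoprotein glucose dehydrogenase")

    # Database-sourced additions (quinone-reducing per EcoCyc, not the model).
    census_rxn("LHGO", {"2hglut": -1, "q8": -1, "akg": 1, "q8h2": 1},
               "lhgO", "lhgO", "ecocyc", "L-2-hydroxyglutarate oxidase")
    census_rxn("FADE", {"btcoa": -1, "q8": -1, "b2coa": 1, "q8h2": 1},
               "fadE", "fadE", "ecocyc", "acyl-CoA dehydrogenase")
    census_rxn("DADA", {"ala__D": -1, "h2o": -1, "q8": -1,
                        "pyr": 1, "nh4": 1, "q8h2": 1},
               "dadA", "dadA", "ecocyc", "D-amino acid dehydrogenase")

    # NAD(P)H-dependent counterparts closing the eight mini-cycles.
    m.add_reaction(_rxn(
        "LDH_D", {"pyr": -1, "nadh": -1, "h": -1, "lac__D": 1, "nad": 1},
        gpr="ldhA", name="D-lactate dehydrogenase (NADH)"))
    m.add_reaction(_rxn(
        "MDH", {"mal__L": -1, "nad": -1, "oaa": 1, "nadh": 1, "h": 1},
        lb=-DEFAULT_BOUND, gpr="mdh", name="malate dehydrogenase (NAD)"))
    m.add_reaction(_rxn(
        "P5CR", {"1pyr5c": -1, "nadph": -1, "h": -2, "pro__L": 1, "nadp": 1},
        gpr="proC", name="pyrroline-5-carboxylate reductase"))
    m.add_reaction(_rxn(
        "GPSA", {"dhap": -1, "nadh": -1, "h": -1, "glyc3p": 1, "nad": 1},
        gpr="gpsA", name="glycerol 3-phosphate dehydrogenase (NADH)"))
    m.add_reaction(_rxn(
        "GHRA", {"glx": -1, "nadph": -1, "h": -1, "glyclt": 1, "nadp": 1},
        gpr="ghrA", name="glyoxylate reductase"))
    m.add_reaction(_rxn(
        "DAADH_SYN",
        {"pyr": -1, "nh4": -1, "nadh": -1, "h": -1,
         "ala__D": 1, "nad": 1, "h2o": 1},
        gpr="daaD_syn",
        name="D-alanine dehydrogenase (synthetic fixture-only counterpart)"))
    m.add_reaction(_rxn(
        "HGDH_SYN", {"akg": -1, "nadh": -1, "h": -1, "2hglut": 1, "nad": 1},
        gpr="hgdh_syn",
        name="2-hydroxyglutarate dehydrogenase (synthetic fixture-only counterpart)"))

    m.quinone_pairs = [("q8", "q8h2")]
    m.validate()
    from .model import assign_role_tags

    assign_role_tags(m)

    table = pd.DataFrame(
        rows, columns=["reaction_id", "gene_group", "quinone_annotation_source"]
    )
    return m, CensusFixture(reactions=table)


# ---------------------------------------------------------------------------
# Growth-curve fixture
# ---------------------------------------------------------------------------


def make_growth_table(
    rate: float,
    od0: float = 0.1,
    hours: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    interval_h: float = 0.25,
) -> pd.DataFrame:
    """Exponential OD600 series with optional Gaussian read noise.

    Emulates plate-reader kinetics sampled every ``interval_h`` hours; noise
    is additive on the OD scale (instrument noise, not biological variance).
    """
    if rate < 0:
        raise ValueError("growth rate must be non-negative")
    if od0 <= 0:
        raise ValueError("initial OD must be positive")
    t = np.arange(0.0, hours + 1e-9, interval_h)
    od = od0 * np.exp(rate * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    return pd.DataFrame({"time_h": t, "od600": od})
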