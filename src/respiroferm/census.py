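"""Quinone-reaction census: enumeration, curation, classification,
mini-cycle detection, and derivation of the deletion-target list.

The census is the first stage of the obligate-fermentation design.  Every
reaction able to transfer electrons into the quinone pool is enumerated from
the model's stoichiometry, manually curated entries are excluded or added,
each remaining activity is classified as an NAD(P)H:quinone oxidoreductase
or a (metabolite-oxidising) quinone-dependent dehydrogenase, and
two-reaction "mini-cycles" are detected: a quinone-dependent dehydrogenase
paired with an immediate NAD(P)H-dependent counterpart whose net effect is
NAD(P)H → quinol electron transfer.  The union of the relevant gene groups,
plus the counterparts of any module scheduled for later reintegration,
yields the deletion loci of the obligate-fermentative genotype.

Counting conventions: the enumerated/excluded/added/relevant ledger counts
reactions (quinone-variant isoreactions of one gene group collapsed), while
the oxidoreductase/dehydrogenase classification and the mini-cycle tally
count gene groups — one entry may carry several ``|``-separated isozyme
groups, each counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .model import MetabolicModel, ReactionRecord

CLASS_OXIDOREDUCTASE = "nadph_quinone_oxidoreductase"
CLASS_DEHYDROGENASE = "quinone_dehydrogenase"

STATUS_RELEVANT = "relevant"
STATUS_EXCLUDED = "excluded"
STATUS_ADDED = "added"

#: Gene-group → deletion-locus merges (operon deletions and the jointly
#: deleted mdaB/ygiN pair); groups not listed map to themselves.
DEFAULT_LOCUS_MAP: Dict[str, str] = {
    "nuo": "nuoEFG",
    "sdh": "sdhABCD",
    "mdaB": "mdaB/ygiN",
    "ygiN": "mdaB/ygiN",
}

#: Compounds ignored in the mini-cycle cancellation test (proton and water
#: bookkeeping varies across models and compartments).
_CANCELLATION_IGNORED = frozenset({"h", "h2o"})

_CARRIER_PAIRS: Tuple[Tuple[str, str], ...] = (("nadh", "nad"), ("nadph", "nadp"))


@dataclass
class CensusEntry:
    """One quinone-reducing activity in the census.

    ``gene_group`` may contain several ``|``-separated isozyme groups;
    ``mini_cycle_partner`` is the NAD(P)H-dependent counterpart reaction id
    (dehydrogenases only).
    """

    reaction_id: str
    gene_group: str
    classification: str = ""
    status: str = STATUS_RELEVANT
    exclusion_reason: str = ""
    mini_cycle_partner: Optional[str] = None
    source: str = "model"

    @property
    def gene_groups(self) -> List[str]:
        return [g for g in self.gene_group.split("|") if g]

    def validate(self) -> None:
        if self.status == STATUS_EXCLUDED:
            if not self.exclusion_reason:
                raise ValueError(f"{self.reaction_id}: excluded without reason")
            if self.classification:
                raise ValueError(f"{self.reaction_id}: excluded entries are unclassified")
        if self.mini_cycle_partner and self.classification != CLASS_DEHYDROGENASE:
            raise ValueError(
                f"{self.reaction_id}: mini-cycle partner on a non-dehydrogenase"
            )


@dataclass(frozen=True)
class CensusCounts:
    enumerated: int
    excluded: int
    added: int
    relevant: int
    oxidoreductases: int
    dehydrogenases: int
    mini_cycles: int

    def as_tuple(self) -> Tuple[int, ...]:
        return (
            self.enumerated, self.excluded, self.added, self.relevant,
            self.oxidoreductases, self.dehydrogenases, self.mini_cycles,
        )


@dataclass
class CensusResult:
    """Curated, classified census with recomputable counts."""

    entries: List[CensusEntry]
    counts: CensusCounts = field(init=False)

    def __post_init__(self) -> None:
        self.recount()

    def recount(self) -> None:
        enumerated = sum(1 for e in self.entries if e.source == "model")
        excluded = sum(1 for e in self.entries if e.status == STATUS_EXCLUDED)
        added = sum(1 for e in self.entries if e.status == STATUS_ADDED)
        relevant = enumerated - excluded + added
        oxi_groups: Set[str] = set()
        deh_groups: Set[str] = set()
        cycle_groups: Set[str] = set()
        for e in self.entries:
            if e.status == STATUS_EXCLUDED:
                continue
            if e.classification == CLASS_OXIDOREDUCTASE:
                oxi_groups.update(e.gene_groups)
            elif e.classification == CLASS_DEHYDROGENASE:
                deh_groups.update(e.gene_groups)
                if e.mini_cycle_partner:
                    cycle_groups.update(e.gene_groups)
        self.counts = CensusCounts(
            enumerated=enumerated,
            excluded=excluded,
            added=added,
            relevant=relevant,
            oxidoreductases=len(oxi_groups),
            dehydrogenases=len(deh_groups),
            mini_cycles=len(cycle_groups),
        )

    def relevant_entries(self) -> List[CensusEntry]:
        return [e for e in self.entries if e.status != STATUS_EXCLUDED]

    def get(self, reaction_id: str) -> CensusEntry:
        for e in self.entries:
            if e.reaction_id == reaction_id:
                return e
        raise KeyError(reaction_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "reaction_id": e.reaction_id,
                    "gene_group": e.gene_group,
                    "classification": e.classification,
                    "status": e.status,
                    "exclusion_reason": e.exclusion_reason,
                    "mini_cycle_partner": e.mini_cycle_partner or "",
                    "source": e.source,
                }
                for e in self.entries
            ]
        )


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


def _quinone_reduction_direction(
    rxn: ReactionRecord, quinone_pairs: Sequence[Tuple[str, str]]
) -> int:
    """+1/-1 if the reaction can reduce a quinone in that direction, else 0."""
    for q_id, qh2_id in quinone_pairs:
        s_q = rxn.stoichiometry.get(q_id, 0.0)
        s_qh2 = rxn.stoichiometry.get(qh2_id, 0.0)
        if s_q < 0 < s_qh2 and rxn.upper_bound > 0:
            return 1
        if s_qh2 < 0 < s_q and rxn.lower_bound < 0:
            return -1
    return 0


def _oriented_stoichiometry(
    rxn: ReactionRecord, direction: int
) -> Dict[str, Fraction]:
    return {m: Fraction(c).limit_denominator(10**6) * direction
            for m, c in rxn.stoichiometry.items()}


def enumerate_quinone_reducing(
    model: MetabolicModel, annotation_source: str = "model"
) -> List[CensusEntry]:
    """Enumerate reactions able to reduce a quinone to its paired quinol.

    Entries are built for every non-exchange reaction whose stoichiometry
    consumes a quinone and produces the paired quinol in a bounds-allowed
    direction; isoreactions sharing a gene group are collapsed to one entry.
    ``annotation_source`` selects entries by their quinone annotation
    provenance tag: ``"model"`` (default; also reactions carrying no
    provenance tag), ``"ecocyc"``, or ``"all"``.
    """
    if not model.quinone_pairs:
        raise ValueError(
            "model has no quinone pairs configured; set MetabolicModel."
            "quinone_pairs or pass quinone identifiers to read_sbml"
        )
    entries: List[CensusEntry] = []
    seen_groups: Dict[str, str] = {}
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        if rxn.is_exchange or rxn.is_biomass:
            continue
        if not _quinone_reduction_direction(rxn, model.quinone_pairs):
            continue
        source = "model"
        if "quinone_reducing_ecocyc" in rxn.annotation_tags:
            source = "ecocyc"
        if annotation_source != "all" and source != annotation_source:
            continue
        group = rxn.gene_group or "|".join(sorted(rxn.genes)) or rxn.id
        if group in seen_groups:
            continue  # quinone-variant isoreaction of an already-seen group
        seen_groups[group] = rid
        entries.append(
            CensusEntry(reaction_id=rid, gene_group=group, source=source)
        )
    return entries


# ---------------------------------------------------------------------------
# Curation and classification
# ---------------------------------------------------------------------------


def classify(entry: CensusEntry, model: MetabolicModel) -> str:
    """Classify one census entry by its electron donor.

    NAD(P)H:quinone oxidoreductases oxidise NADH or NADPH while reducing the
    quinone; everything else (succinate, glycerol 3-phosphate, D-lactate,
    ... donors) is a quinone-dependent dehydrogenase.
    """
    rxn = model.reactions[entry.reaction_id]
    direction = _quinone_reduction_direction(rxn, model.quinone_pairs)
    if direction == 0:
        raise ValueError(f"{entry.reaction_id} reduces no quinone")
    stoich = _oriented_stoichiometry(rxn, direction)
    for reduced, oxidised in _CARRIER_PAIRS:
        if stoich.get(reduced, 0) < 0 < stoich.get(oxidised, 0):
            return CLASS_OXIDOREDUCTASE
    return CLASS_DEHYDROGENASE


def curate(
    entries: Sequence[CensusEntry],
    exclusions: Sequence[Tuple[str, str]] = (),
    additions: Sequence[CensusEntry] = (),
    model: Optional[MetabolicModel] = None,
) -> CensusResult:
    """Apply manual curation and build a :class:`CensusResult`.

    ``exclusions`` are (reaction id, reason) pairs and must reference
    enumerated entries (typos fail loudly); ``additions`` are entries sourced
    outside the model annotation.  If ``model`` is given, classifications are
    (re)computed for all non-excluded entries.
    """
    by_id = {e.reaction_id: e for e in entries}
    unknown = [rid for rid, _ in exclusions if rid not in by_id]
    if unknown:
        raise KeyError(
            f"exclusion ids not among enumerated reactions: {sorted(unknown)}"
        )
    out: List[CensusEntry] = []
    reasons = dict(exclusions)
    for e in entries:
        if e.reaction_id in reasons:
            out.append(
                replace(
                    e,
                    status=STATUS_EXCLUDED,
                    exclusion_reason=reasons[e.reaction_id],
                    classification="",
                    mini_cycle_partner=None,
                )
            )
        else:
            out.append(replace(e, status=STATUS_RELEVANT))
    for e in additions:
        out.append(replace(e, status=STATUS_ADDED))
    if model is not None:
        for i, e in enumerate(out):
            if e.status != STATUS_EXCLUDED:
                out[i] = replace(e, classification=classify(e, model))
    for e in out:
        e.validate()
    return CensusResult(entries=out)


def run_census(
    model: MetabolicModel,
    exclusions: Sequence[Tuple[str, str]] = (),
) -> CensusResult:
    """Convenience pipeline: enumerate (model + database-sourced entries),
    curate, classify and attach mini-cycle partners."""
    enumerated = enumerate_quinone_reducing(model, "model")
    additions = enumerate_quinone_reducing(model, "ecocyc")
    result = curate(enumerated, exclusions, additions, model=model)
    attach_mini_cycles(result, model)
    return result


# ---------------------------------------------------------------------------
# Mini-cycle detection
# ---------------------------------------------------------------------------


def _cycle_pattern_match(
    net: Mapping[str, Fraction], quinone_pairs: Sequence[Tuple[str, str]]
) -> bool:
    """True iff ``net`` is exactly NAD(P)H + H+ + Q → NAD(P)+ + QH2 (scaled).

    Protons and water are ignored (compartmental proton bookkeeping differs
    across models); everything else must cancel.
    """
    net = {m: c for m, c in net.items() if c != 0 and m not in _CANCELLATION_IGNORED}
    for q_id, qh2_id in quinone_pairs:
        for reduced, oxidised in _CARRIER_PAIRS:
            keys = {reduced, oxidised, q_id, qh2_id}
            if set(net) != keys:
                continue
            scale = net[qh2_id]
            if scale <= 0:
                continue
            if (
                net[q_id] == -scale
                and net[reduced] == -scale
                and net[oxidised] == scale
            ):
                return True
    return False


def _counterpart_candidates(model: MetabolicModel) -> List[ReactionRecord]:
    quinone_mets = {m for pair in model.quinone_pairs for m in pair}
    out = []
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        if rxn.is_exchange or rxn.is_biomass:
            continue
        if quinone_mets & set(rxn.stoichiometry):
            continue
        carriers = {m for pair in _CARRIER_PAIRS for m in pair}
        if not carriers & set(rxn.stoichiometry):
            continue
        out.append(rxn)
    return out


def detect_mini_cycles(
    model: MetabolicModel,
    dehydrogenases: Sequence[CensusEntry],
    active_only: bool = False,
) -> List[Tuple[str, str]]:
    """Detect two-reaction NAD(P)H → quinol substrate cycles.

    A pair (quinone reaction, counterpart) is reported iff some linear
    combination of the quinone-reducing reaction with the counterpart run in
    the opposite (reductive) sense cancels all compounds except one NAD(P)H
    (+H+) consumed, one NAD(P)+ produced, and one quinone reduced to quinol.
    Only cycles of length two are considered — the "immediate counterpart"
    notion; direction encoding and bounds of the counterpart are ignored, so
    the result is invariant to how reversibility is written.
    """
    candidates = _counterpart_candidates(model)
    if active_only:
        candidates = [r for r in candidates if not r.disabled()]
    ignore = _CANCELLATION_IGNORED | {
        m for pair in model.quinone_pairs for m in pair
    } | {m for pair in _CARRIER_PAIRS for m in pair}
    pairs: List[Tuple[str, str]] = []
    for entry in dehydrogenases:
        rxn_q = model.reactions[entry.reaction_id]
        direction = _quinone_reduction_direction(rxn_q, model.quinone_pairs)
        if direction == 0:
            continue
        s_q = _oriented_stoichiometry(rxn_q, direction)
        link_mets = [m for m, c in s_q.items() if c != 0 and m not in ignore]
        for rxn_n in candidates:
            if rxn_n.id == entry.reaction_id:
                continue
            s_n = _oriented_stoichiometry(rxn_n, 1)
            lambdas = set()
            for m in link_mets:
                if s_n.get(m, 0) != 0:
                    lambdas.add(-s_q[m] / s_n[m])
            for lam in lambdas:
                net: Dict[str, Fraction] = dict(s_q)
                for m, c in s_n.items():
                    net[m] = net.get(m, Fraction(0)) + lam * c
                if _cycle_pattern_match(net, model.quinone_pairs):
                    pairs.append((entry.reaction_id, rxn_n.id))
                    break
    return pairs


def attach_mini_cycles(result: CensusResult, model: MetabolicModel) -> List[Tuple[str, str]]:
    """Run mini-cycle detection and record partners on the census entries."""
    dehydrogenases = [
        e for e in result.relevant_entries()
        if e.classification == CLASS_DEHYDROGENASE
    ]
    pairs = detect_mini_cycles(model, dehydrogenases)
    partner = dict(pairs)
    for i, e in enumerate(result.entries):
        if e.reaction_id in partner:
            result.entries[i] = replace(e, mini_cycle_partner=partner[e.reaction_id])
    result.recount()
    return pairs


# ---------------------------------------------------------------------------
# Deletion targets and reintegration safety
# ---------------------------------------------------------------------------


def deletion_targets(
    census: CensusResult,
    cycles: Sequence[Tuple[str, str]],
    model: Optional[MetabolicModel] = None,
    reintegration: Iterable[str] = ("glpD",),
    locus_map: Optional[Mapping[str, str]] = None,
) -> Set[str]:
    """Deletion loci of the obligate-fermentative genotype.

    The set is the union of the gene groups of all relevant census entries
    (mapped through ``locus_map`` to deletion loci), plus the NAD(P)H-
    dependent counterpart of every mini-cycle whose quinone member's gene
    group is scheduled for later reintegration — the counterpart must go so
    that reintegrating the module cannot recreate the cycle.
    """
    locus_map = dict(DEFAULT_LOCUS_MAP if locus_map is None else locus_map)
    reintegration = set(reintegration)
    loci: Set[str] = set()
    for entry in census.relevant_entries():
        for group in entry.gene_groups:
            loci.add(locus_map.get(group, group))
    partner_of = {rq: rn for rq, rn in cycles}
    for entry in census.relevant_entries():
        if not set(entry.gene_groups) & reintegration:
            continue
        rn = entry.mini_cycle_partner or partner_of.get(entry.reaction_id)
        if rn is None:
            continue
        if model is not None:
            genes = sorted(model.reactions[rn].genes)
            group = model.reactions[rn].gene_group or "|".join(genes)
        else:
            group = rn
        for g in group.split("|"):
            loci.add(locus_map.get(g, g))
    return loci


@dataclass
class ReintegrationCheck:
    safe: bool
    new_cycles: List[Tuple[str, str]] = field(default_factory=list)


def cycle_safe_reintegration(
    model: MetabolicModel,
    deleted_genes: Set[str],
    module: str,
) -> ReintegrationCheck:
    """Check whether re-enabling a quinone module recreates a mini-cycle.

    The module reaction is re-enabled against the genotype obtained from
    ``deleted_genes``; mini-cycle detection is rerun against the reactions
    still active in that genotype.  Safe iff no new pair appears.
    """
    from .model import apply_deletions
    import warnings as _warnings

    if module not in model.reactions:
        raise KeyError(f"unknown module reaction {module!r}")
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        after = apply_deletions(model, deleted_genes)
    pristine = model.reactions[module]
    target = after.reactions[module]
    target.lower_bound = pristine.lower_bound
    target.upper_bound = pristine.upper_bound
    entry = CensusEntry(
        reaction_id=module,
        gene_group=target.gene_group or "|".join(sorted(target.genes)) or module,
        classification=CLASS_DEHYDROGENASE,
    )
    pairs = detect_mini_cycles(after, [entry], active_only=True)
    return ReintegrationCheck(safe=not pairs, new_cycles=pairs)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def census_report_tsv(result: CensusResult) -> str:
    """TSV report with one row per entry and a counts footer."""
    frame = result.to_frame()
    lines = [frame.to_csv(sep="\t", index=False).rstrip("\n")]
    c = result.counts
    lines.append(
        "# counts\tenumerated={}\texcluded={}\tadded={}\trelevant={}\t"
        "oxidoreductases={}\tdehydrogenases={}\tmini_cycles={}".format(
            c.enumerated, c.excluded, c.added, c.relevant,
            c.oxidoreductases, c.dehydrogenases, c.mini_cycles,
        )
    )
    return "\n".join(lines) + "\n"


def census_report_json(result: CensusResult) -> Dict:
    c = result.counts
    return {
        "entries": result.to_frame().to_dict(orient="records"),
        "counts": {
            "enumerated": c.enumerated,
            "excluded": c.excluded,
            "added": c.added,
            "relevant": c.relevant,
            "oxidoreductases": c.oxidoreductases,
            "dehydrogenases": c.dehydrogenases,
            "mini_cycles": c.mini_cycles,
        },
    }
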