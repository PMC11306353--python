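"""Core metabolic-model data structures and a linear-programming FBA/FVA engine.

The in-memory model is deliberately small: compounds with element counts and
charge, reactions with stoichiometry, flux bounds and a boolean gene
association, and an explicit list of quinone/quinol pairs.  SBML Level-3 FBC
files are read and written through COBRApy, so any published genome-scale
model (e.g. the *E. coli* iML1515 reconstruction) can be loaded with the same
code path as the bundled toy networks.

Flux balance analysis is solved as a plain LP (``S v = 0``, bounds, linear
objective) with the HiGHS backend of :func:`scipy.optimize.linprog`.  Only
objective values, feasibility and forced-zero flux ranges should be asserted
downstream; individual flux values at degenerate optima are solver-dependent.
"""

from __future__ import annotations

import copy
import hashlib
import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

#: Flux bound used for "unconstrained" reactions (mmol gCDW^-1 h^-1 convention).
DEFAULT_BOUND = 1000.0

#: LP feasibility tolerance and the threshold below which a flux is reported zero.
FEASIBILITY_TOL = 1e-9
ZERO_FLUX_TOL = 1e-6

#: Default quinone/quinol identifier pairs (BiGG style, compartment suffixes
#: stripped when matching): ubiquinone-8, menaquinone-8, 2-demethylmenaquinone-8.
DEFAULT_QUINONE_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("q8", "q8h2"),
    ("mqn8", "mqn8h2"),
    ("2dmmq8", "2dmmql8"),
)

NAD_CARRIERS = {"nad": "nadh", "nadp": "nadph"}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-style chemical formula into element counts.

    An empty string denotes a massless pseudo-species (e.g. the proton-motive
    force carrier) and yields an empty mapping.
    """
    if not formula:
        return {}
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element, num = match.groups()
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def format_formula(element_counts: Mapping[str, int]) -> str:
    """Inverse of :func:`parse_formula` (C and H first, then alphabetical)."""
    if not element_counts:
        return ""
    order = sorted(element_counts, key=lambda e: (e not in ("C", "H"), e != "C", e))
    return "".join(
        f"{el}{element_counts[el] if element_counts[el] != 1 else ''}" for el in order
    )


@dataclass
class Compound:
    """A chemical species with elemental composition and charge.

    ``role_tags`` mark cofactor roles used by the census and the reachability
    heuristic: ``quinone``/``quinol`` (paired at model level), ``nad_carrier``,
    ``nadp_carrier``, ``pmf`` (proton-motive force pseudo-species),
    ``biomass_component`` and ``inorganic``.
    """

    id: str
    name: str = ""
    element_counts: Dict[str, int] = field(default_factory=dict)
    charge: int = 0
    compartment: str = "c"
    role_tags: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.element_counts.values()):
            raise ValueError(f"negative element count in compound {self.id}")

    @property
    def formula(self) -> str:
        return format_formula(self.element_counts)

    @property
    def n_carbon(self) -> int:
        return self.element_counts.get("C", 0)


@dataclass
class ReactionRecord:
    """Stoichiometry, bounds and gene association of one model reaction.

    Stoichiometric coefficients are negative for consumed species.  The gene
    association is a boolean expression over gene identifiers where ``and``
    joins members of a complex and ``or`` joins isozymes; an empty expression
    means the reaction cannot be disabled by any gene deletion.
    """

    id: str
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gene_association: str = ""
    annotation_tags: Set[str] = field(default_factory=set)
    name: str = ""
    gene_group: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        return "exchange" in self.annotation_tags or len(self.stoichiometry) == 1

    @property
    def is_biomass(self) -> bool:
        return "biomass" in self.annotation_tags

    @property
    def genes(self) -> Set[str]:
        return gpr_genes(self.gene_association)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def disabled(self) -> bool:
        return self.lower_bound == 0 and self.upper_bound == 0


@dataclass
class FluxSolution:
    """Outcome of one LP solve: status, objective value and the flux vector."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float = float("nan")
    fluxes: Dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


class MetabolicModel:
    """A collection of compounds and reactions with an FBA objective."""

    def __init__(
        self,
        model_id: str = "model",
        compounds: Iterable[Compound] = (),
        reactions: Iterable[ReactionRecord] = (),
        quinone_pairs: Sequence[Tuple[str, str]] = (),
        objective_reaction: Optional[str] = None,
    ) -> None:
        self.id = model_id
        self.compounds: Dict[str, Compound] = {c.id: c for c in compounds}
        self.reactions: Dict[str, ReactionRecord] = {r.id: r for r in reactions}
        self.quinone_pairs: List[Tuple[str, str]] = list(quinone_pairs)
        self.objective_reaction = objective_reaction
        self.metadata: Dict[str, object] = {}

    # -- construction helpers -------------------------------------------------

    def add_compound(self, compound: Compound) -> Compound:
        self.compounds[compound.id] = compound
        return compound

    def add_reaction(self, reaction: ReactionRecord) -> ReactionRecord:
        for met in reaction.stoichiometry:
            if met not in self.compounds:
                raise KeyError(
                    f"reaction {reaction.id} references unknown compound {met!r}"
                )
        self.reactions[reaction.id] = reaction
        return reaction

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- queries --------------------------------------------------------------

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return out

    def exchanges(self) -> List[ReactionRecord]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def validate(self) -> None:
        """Check referential integrity and the quinone-pair invariant."""
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                if met not in self.compounds:
                    raise ValueError(f"{rxn.id}: unknown compound {met}")
        if self.objective_reaction is not None and (
            self.objective_reaction not in self.reactions
        ):
            raise ValueError(f"objective {self.objective_reaction} not in model")
        for q_id, qh2_id in self.quinone_pairs:
            if q_id not in self.compounds or qh2_id not in self.compounds:
                raise ValueError(f"quinone pair ({q_id}, {qh2_id}) not in model")
            self.compounds[q_id].role_tags.add("quinone")
            self.compounds[qh2_id].role_tags.add("quinol")

    def balance_errors(self, tol: float = 1e-9) -> Dict[str, Dict[str, float]]:
        """Element/charge imbalances of non-exchange, non-biomass reactions.

        Reactions containing a compound without a fully specified formula and
        non-zero coefficient on an unknown species are skipped; the
        proton-motive-force pseudo-species is massless and chargeless, hence
        does not exempt its reactions from checking.
        """
        errors: Dict[str, Dict[str, float]] = {}
        for rxn in self.reactions.values():
            if rxn.is_exchange or rxn.is_biomass:
                continue
            totals: Dict[str, float] = {}
            for met, coeff in rxn.stoichiometry.items():
                cpd = self.compounds[met]
                for el, n in cpd.element_counts.items():
                    totals[el] = totals.get(el, 0.0) + coeff * n
                totals["charge"] = totals.get("charge", 0.0) + coeff * cpd.charge
            bad = {k: v for k, v in totals.items() if abs(v) > tol}
            if bad:
                errors[rxn.id] = bad
        return errors


# ---------------------------------------------------------------------------
# GPR boolean expressions
# ---------------------------------------------------------------------------


class _GprParser:
    """Recursive-descent parser for ``and``/``or`` gene association strings."""

    _TOKEN = re.compile(r"\(|\)|[^\s()]+")

    def __init__(self, text: str) -> None:
        self.tokens = self._TOKEN.findall(text)
        self.pos = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            raise ValueError(f"trailing tokens in GPR at {self.peek()!r}")
        return node

    def parse_or(self):
        terms = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.parse_and())
        return ("or", terms) if len(terms) > 1 else terms[0]

    def parse_and(self):
        terms = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            terms.append(self.parse_atom())
        return ("and", terms) if len(terms) > 1 else terms[0]

    def parse_atom(self):
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of GPR expression")
        if tok == "(":
            self.next()
            node = self.parse_or()
            if self.next() != ")":
                raise ValueError("unbalanced parentheses in GPR")
            return node
        if tok == ")":
            raise ValueError("unexpected ')' in GPR")
        return ("gene", self.next())


def _parse_gpr(expression: str):
    expression = expression.strip()
    if not expression:
        return None
    return _GprParser(expression).parse()


def gpr_genes(expression: str) -> Set[str]:
    """All gene identifiers appearing in a gene-association expression."""
    node = _parse_gpr(expression)
    out: Set[str] = set()

    def walk(n) -> None:
        if n is None:
            return
        kind, payload = n
        if kind == "gene":
            out.add(payload)
        else:
            for child in payload:
                walk(child)

    walk(node)
    return out


def evaluate_gpr(expression: str, deleted: Set[str]) -> bool:
    """Evaluate a gene association with the given genes deleted.

    ``and`` requires every member (complexes fail on any member's deletion);
    ``or`` requires at least one isozyme.  An empty expression evaluates true:
    reactions without gene association are never deletable by gene.
    """
    node = _parse_gpr(expression)

    def ev(n) -> bool:
        if n is None:
            return True
        kind, payload = n
        if kind == "gene":
            return payload not in deleted
        if kind == "and":
            return all(ev(c) for c in payload)
        return any(ev(c) for c in payload)

    return ev(node)


def apply_deletions(model: MetabolicModel, genes: Set[str]) -> MetabolicModel:
    """Return a copy of ``model`` with the given genes knocked out.

    A reaction is disabled (bounds set to zero) iff its gene association
    evaluates false under the deletion.  Unknown gene identifiers trigger a
    warning and are otherwise ignored, so genome-scale genotype presets can be
    replayed against reduced models.
    """
    genes = set(genes)
    known = model.genes
    unknown = genes - known
    if unknown:
        warnings.warn(
            f"deletion targets not present in model (ignored): {sorted(unknown)}",
            UserWarning,
            stacklevel=2,
        )
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.gene_association and not evaluate_gpr(rxn.gene_association, genes):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


# ---------------------------------------------------------------------------
# Linear programming
# ---------------------------------------------------------------------------


def _lp_arrays(model: MetabolicModel):
    met_ids = sorted(model.compounds)
    rxn_ids = sorted(model.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    bounds = []
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[rid]
        for met, coeff in rxn.stoichiometry.items():
            S[met_index[met], j] = coeff
        bounds.append((rxn.lower_bound, rxn.upper_bound))
    return met_ids, rxn_ids, S, bounds


def _solve(
    model: MetabolicModel,
    objective_coefs: Mapping[str, float],
    sense: str,
    extra_lb: Optional[Mapping[str, float]] = None,
) -> FluxSolution:
    met_ids, rxn_ids, S, bounds = _lp_arrays(model)
    if extra_lb:
        bounds = [
            (max(lo, extra_lb.get(rid, lo)), hi)
            for (lo, hi), rid in zip(bounds, rxn_ids)
        ]
    c = np.array([objective_coefs.get(rid, 0.0) for rid in rxn_ids])
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
    )
    if res.status == 2:
        return FluxSolution(status="infeasible")
    if res.status == 3:
        return FluxSolution(status="unbounded")
    if not res.success:  # pragma: no cover - solver failure surface
        raise RuntimeError(f"LP solver failure: {res.message}")
    fluxes = dict(zip(rxn_ids, res.x))
    return FluxSolution(
        status="optimal", objective_value=sign * res.fun, fluxes=fluxes
    )


def fba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    sense: str = "max",
) -> FluxSolution:
    """Flux balance analysis: optimise one reaction's flux at steady state."""
    objective = objective or model.objective_reaction
    if objective not in model.reactions:
        raise KeyError(f"objective reaction {objective!r} not in model")
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    return _solve(model, {objective: 1.0}, sense)


def fva(
    model: MetabolicModel,
    reactions: Optional[Sequence[str]] = None,
    fraction_of_optimum: float = 0.0,
    objective: Optional[str] = None,
) -> Dict[str, Tuple[float, float]]:
    """Flux variability analysis at a constrained optimum.

    With ``fraction_of_optimum = 0`` the ranges describe plain flux
    capability; with 1.0 they describe variability at the optimum.  Raises if
    the base problem is infeasible.
    """
    objective = objective or model.objective_reaction
    constrained = model
    if fraction_of_optimum > 0:
        base = fba(model, objective, "max")
        if not base.ok:
            raise RuntimeError(f"FVA base problem is {base.status}")
        constrained = model.copy()
        rxn = constrained.reactions[objective]
        target = fraction_of_optimum * base.objective_value
        rxn.lower_bound = max(rxn.lower_bound, target - 1e-9 * max(1.0, abs(target)))
    else:
        probe = _solve(model, {}, "min")
        if not probe.ok:
            raise RuntimeError(f"FVA base problem is {probe.status}")
    if reactions is None:
        reactions = sorted(model.reactions)
    out: Dict[str, Tuple[float, float]] = {}
    for rid in reactions:
        lo = _solve(constrained, {rid: 1.0}, "min")
        hi = _solve(constrained, {rid: 1.0}, "max")
        if not (lo.ok and hi.ok):  # pragma: no cover
            raise RuntimeError(f"FVA subproblem for {rid} failed")
        vmin, vmax = lo.objective_value, hi.objective_value
        if abs(vmin) < ZERO_FLUX_TOL:
            vmin = 0.0
        if abs(vmax) < ZERO_FLUX_TOL:
            vmax = 0.0
        out[rid] = (min(vmin, vmax), max(vmin, vmax))
    return out


def steady_state_residual(model: MetabolicModel, solution: FluxSolution) -> float:
    """Infinity norm of S·v for an FBA solution (should be ~0)."""
    met_ids, rxn_ids, S, _ = _lp_arrays(model)
    v = np.array([solution.fluxes.get(rid, 0.0) for rid in rxn_ids])
    return float(np.max(np.abs(S @ v))) if len(met_ids) else 0.0


# ---------------------------------------------------------------------------
# SBML I/O through COBRApy
# ---------------------------------------------------------------------------


def assign_role_tags(
    model: MetabolicModel,
    quinone_ids: Sequence[Tuple[str, str]] = DEFAULT_QUINONE_PAIRS,
) -> None:
    """Populate quinone pairs and cofactor role tags from an identifier list.

    Identifiers are matched against compound ids with common compartment
    suffixes (``_c``, ``_p``, ``_e``) stripped, so BiGG-style genome-scale
    models and the suffix-free toy models are both covered.
    """

    def base_id(cid: str) -> str:
        return re.sub(r"_(c|p|e)$", "", cid)

    by_base: Dict[str, List[str]] = {}
    for cid in model.compounds:
        by_base.setdefault(base_id(cid), []).append(cid)

    pairs: List[Tuple[str, str]] = []
    for q_base, qh2_base in quinone_ids:
        for q_cid in by_base.get(q_base, []):
            for qh2_cid in by_base.get(qh2_base, []):
                q = model.compounds[q_cid]
                qh2 = model.compounds[qh2_cid]
                if q.compartment == qh2.compartment:
                    q.role_tags.add("quinone")
                    qh2.role_tags.add("quinol")
                    pairs.append((q_cid, qh2_cid))
    model.quinone_pairs = pairs

    for nad_base, nadh_base in NAD_CARRIERS.items():
        tag = "nad_carrier" if nad_base == "nad" else "nadp_carrier"
        for base in (nad_base, nadh_base):
            for cid in by_base.get(base, []):
                model.compounds[cid].role_tags.add(tag)
    for cid in by_base.get("pmf", []):
        model.compounds[cid].role_tags.add("pmf")


def to_cobra(model: MetabolicModel):
    """Convert to a :class:`cobra.Model` (used for SBML I/O and cross-checks)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for cpd in model.compounds.values():
        met = cobra.Metabolite(
            cpd.id,
            formula=cpd.formula or None,
            name=cpd.name or cpd.id,
            charge=cpd.charge,
            compartment=cpd.compartment or "c",
        )
        mets[cpd.id] = met
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for rec in model.reactions.values():
        rxn = cobra.Reaction(
            rec.id,
            name=rec.name or rec.id,
            lower_bound=rec.lower_bound,
            upper_bound=rec.upper_bound,
        )
        rxns.append(rxn)
    cm.add_reactions(rxns)
    for rec in model.reactions.values():
        rxn = cm.reactions.get_by_id(rec.id)
        rxn.add_metabolites({mets[m]: c for m, c in rec.stoichiometry.items()})
        if rec.gene_association:
            rxn.gene_reaction_rule = rec.gene_association
        notes = {}
        if rec.gene_group:
            notes["gene_group"] = rec.gene_group
        if rec.annotation_tags:
            notes["tags"] = ";".join(sorted(rec.annotation_tags))
        if notes:
            rxn.notes.update(notes)
    if model.objective_reaction:
        cm.objective = model.objective_reaction
    return cm


def from_cobra(
    cobra_model,
    quinone_ids: Sequence[Tuple[str, str]] = DEFAULT_QUINONE_PAIRS,
) -> MetabolicModel:
    """Build a :class:`MetabolicModel` from a :class:`cobra.Model`."""
    model = MetabolicModel(model_id=cobra_model.id or "model")
    for met in cobra_model.metabolites:
        model.add_compound(
            Compound(
                id=met.id,
                name=met.name or "",
                element_counts=dict(met.elements) if met.formula else {},
                charge=int(met.charge) if met.charge is not None else 0,
                compartment=met.compartment or "c",
            )
        )
    objective_ids = {
        r.id for r in cobra_model.reactions if getattr(r, "objective_coefficient", 0)
    }
    for rxn in cobra_model.reactions:
        tags: Set[str] = set()
        notes = dict(rxn.notes or {})
        if "tags" in notes:
            tags |= {t for t in str(notes["tags"]).split(";") if t}
        if len(rxn.metabolites) == 1:
            tags.add("exchange")
        if rxn.id in objective_ids or "biomass" in rxn.id.lower():
            tags.add("biomass")
        model.add_reaction(
            ReactionRecord(
                id=rxn.id,
                name=rxn.name or "",
                stoichiometry={m.id: c for m, c in rxn.metabolites.items()},
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
                gene_association=rxn.gene_reaction_rule or "",
                annotation_tags=tags,
                gene_group=str(notes.get("gene_group", "")),
            )
        )
    if objective_ids:
        model.objective_reaction = sorted(objective_ids)[0]
    assign_role_tags(model, quinone_ids)
    model.metadata["n_genes"] = len(cobra_model.genes)
    model.metadata["n_reactions"] = len(cobra_model.reactions)
    model.metadata["n_metabolites"] = len(cobra_model.metabolites)
    return model


def read_sbml(
    path: str,
    quinone_ids: Sequence[Tuple[str, str]] = DEFAULT_QUINONE_PAIRS,
) -> MetabolicModel:
    """Read an SBML Level-3 FBC model file.

    Species, reactions, bounds and gene-product associations are preserved;
    quinone pairs and cofactor role tags are populated from ``quinone_ids``.
    Parse failures raise ``ValueError`` naming the file; models without FBC
    bounds get COBRApy's defaults with a logged warning.
    """
    from cobra.io import read_sbml_model

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cobra_model = read_sbml_model(path)
    except Exception as exc:  # pathological/unparseable input
        raise ValueError(f"cannot parse SBML file {path!r}: {exc}") from exc
    model = from_cobra(cobra_model, quinone_ids)
    with open(path, "rb") as fh:
        model.metadata["sha256"] = hashlib.sha256(fh.read()).hexdigest()
    model.metadata["source"] = str(path)
    logger.info(
        "read %s: %d metabolites, %d reactions, %d genes",
        path,
        model.metadata["n_metabolites"],
        model.metadata["n_reactions"],
        model.metadata["n_genes"],
    )
    return model


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write the model as SBML Level 3 + FBC v2 (round-trips via read_sbml)."""
    from cobra.io import write_sbml_model

    model.validate()
    write_sbml_model(to_cobra(model), path)
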