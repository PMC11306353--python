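"""Degree-of-reduction electron bookkeeping for fermentation design.

A fermentation is redox-balanced when the available electrons of the
substrate equal those of the secreted products; only then can a strain
without electron transfer to the quinone pool convert the substrate at the
carbon-stoichiometric yield.  The available-electron count ("degree of
reduction") is taken relative to CO2 / H2O / NH3:

    electrons = 4·C + 1·H − 2·O − 3·N + 5·P + 6·S − charge

so CO2, water, protons and phosphate all score zero, and anionic fermentation
products (lactate, acetate) score identically to their free acids.  A surplus
of electron pairs on the substrate side is exactly what a reintegrated
respiratory module (e.g. the quinone-dependent glycerol 3-phosphate
dehydrogenase) must transfer to the quinone pool per substrate molecule.

All arithmetic is exact (:class:`fractions.Fraction`); verdicts never depend
on floating-point tolerances.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .model import Compound, MetabolicModel, FluxSolution, parse_formula

ELECTRON_WEIGHTS = {"C": 4, "H": 1, "O": -2, "N": -3, "P": 5, "S": 6}


def electron_count(element_counts: Mapping[str, int], charge: int = 0) -> int:
    """Available electrons of a species relative to CO2/H2O/NH3.

    Elements without an assigned half-reaction weight (metals, halogens in
    this context) are rejected rather than silently scored zero.
    """
    total = 0
    for element, n in element_counts.items():
        if n < 0:
            raise ValueError("negative element count")
        if element not in ELECTRON_WEIGHTS:
            raise ValueError(f"no electron weight defined for element {element!r}")
        total += ELECTRON_WEIGHTS[element] * n
    return total - charge


def compound_electrons(compound: Compound) -> int:
    return electron_count(compound.element_counts, compound.charge)


@dataclass(frozen=True)
class Species:
    """A named formula+charge used on balance sheets (model-independent)."""

    name: str
    element_counts: Mapping[str, int]
    charge: int = 0

    @property
    def electrons(self) -> int:
        return electron_count(self.element_counts, self.charge)

    @property
    def n_carbon(self) -> int:
        return self.element_counts.get("C", 0)

    @classmethod
    def from_formula(cls, name: str, formula: str, charge: int = 0) -> "Species":
        return cls(name=name, element_counts=parse_formula(formula), charge=charge)


def _builtin_library() -> Dict[str, Species]:
    path = Path(__file__).parent / "data" / "compounds.csv"
    return load_compound_library(path)


def load_compound_library(path: Union[str, Path]) -> Dict[str, Species]:
    """Read a compound library CSV with columns name, formula, charge."""
    out: Dict[str, Species] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sp = Species.from_formula(
                row["name"].strip(), row["formula"].strip(), int(row["charge"])
            )
            out[sp.name] = sp
    return out


def resolve_species(spec: Union[str, Species, Compound]) -> Species:
    """Resolve a species from a library name, a ``FORMULA:CHARGE`` literal,
    a :class:`Species` or a model :class:`Compound`."""
    if isinstance(spec, Species):
        return spec
    if isinstance(spec, Compound):
        return Species(spec.id, dict(spec.element_counts), spec.charge)
    library = _builtin_library()
    if spec in library:
        return library[spec]
    if ":" in spec:
        formula, charge = spec.rsplit(":", 1)
        return Species.from_formula(spec, formula, int(charge))
    try:
        return Species.from_formula(spec, spec, 0)
    except ValueError:
        raise KeyError(
            f"unknown compound {spec!r}; use a library name or 'FORMULA:CHARGE'"
        ) from None


VERDICT_BALANCED = "balanced"
VERDICT_EXCESS = "unbalanced_excess_electrons"
VERDICT_DEFICIT = "unbalanced_electron_deficit"


@dataclass
class BalanceSheet:
    """Electron bookkeeping for one substrate → products conversion.

    ``surplus_pairs`` is (substrate electrons − product electrons) / 2; a
    positive surplus is the number of electron pairs a respiratory module must
    transfer to the quinone pool, a negative one marks an infeasible
    over-reduced product (without an extra electron donor).
    """

    substrate: Tuple[Species, Fraction]
    products: List[Tuple[Species, Fraction]]
    co2_coefficient: Fraction = Fraction(0)

    substrate_electrons: Fraction = field(init=False)
    product_electrons: Fraction = field(init=False)
    surplus_pairs: Fraction = field(init=False)
    pairs_per_substrate: Fraction = field(init=False)
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        sub, n_sub = self.substrate
        if n_sub <= 0 or any(c <= 0 for _, c in self.products):
            raise ValueError("stoichiometric coefficients must be positive")
        self.substrate_electrons = n_sub * sub.electrons
        self.product_electrons = sum(
            (c * p.electrons for p, c in self.products), Fraction(0)
        )
        self.surplus_pairs = (self.substrate_electrons - self.product_electrons) / 2
        self.pairs_per_substrate = self.surplus_pairs / n_sub
        if self.surplus_pairs == 0:
            self.verdict = VERDICT_BALANCED
        elif self.surplus_pairs > 0:
            self.verdict = VERDICT_EXCESS
        else:
            self.verdict = VERDICT_DEFICIT


def balance_sheet(
    substrate: Tuple[Union[str, Species, Compound], Union[int, Fraction]],
    products: Sequence[Tuple[Union[str, Species, Compound], Union[int, Fraction]]],
) -> BalanceSheet:
    """Build a :class:`BalanceSheet`, completing carbon with implicit CO2.

    Carbon must be conserved across the declared conversion; missing product
    carbon is assigned to CO2 (degree of reduction zero, so it never affects
    the electron verdict), excess product carbon is an error.
    """
    sub = resolve_species(substrate[0])
    n_sub = Fraction(substrate[1])
    prods = [(resolve_species(p), Fraction(c)) for p, c in products]
    c_in = n_sub * sub.n_carbon
    c_out = sum((c * p.n_carbon for p, c in prods), Fraction(0))
    co2 = c_in - c_out
    if co2 < 0:
        raise ValueError(
            f"carbon imbalance: products carry {c_out} C but substrate provides {c_in}"
        )
    sheet = BalanceSheet(substrate=(sub, n_sub), products=prods)
    sheet.co2_coefficient = co2
    return sheet


@dataclass(frozen=True)
class RespiratoryModule:
    """A reintegratable quinone-dependent reaction and its electron duty.

    ``pairs_per_substrate`` is the number of electron pairs the module
    transfers to the quinone pool per molecule of the named substrate when the
    substrate is catabolised through it (for GlpD: one pair per glycerol).
    """

    name: str
    reaction_id: str
    substrate: str
    pairs_per_substrate: Fraction


GLPD_MODULE = RespiratoryModule(
    name="GlpD", reaction_id="GLPD", substrate="glycerol",
    pairs_per_substrate=Fraction(1),
)


@dataclass
class ModuleSelection:
    sheet: BalanceSheet
    selected: List[RespiratoryModule]
    feasible: bool
    note: str = ""


def required_module(
    sheet: BalanceSheet, modules: Sequence[RespiratoryModule] = (GLPD_MODULE,)
) -> ModuleSelection:
    """Select respiratory modules matching a sheet's electron-pair surplus.

    Balanced sheets need no module; an electron deficit cannot be fixed by
    quinone transfer (the quinone pool is an electron sink, not a donor) and
    is reported infeasible without an additional electron-donating substrate.
    """
    if sheet.verdict == VERDICT_BALANCED:
        return ModuleSelection(sheet, [], True, "balanced; no module required")
    if sheet.verdict == VERDICT_DEFICIT:
        return ModuleSelection(
            sheet, [], False,
            "electron deficit; infeasible without an extra electron donor",
        )
    matches = [
        m
        for m in modules
        if m.substrate == sheet.substrate[0].name
        and m.pairs_per_substrate == sheet.pairs_per_substrate
    ]
    note = "" if matches else (
        f"no module provides {sheet.pairs_per_substrate} pairs per "
        f"{sheet.substrate[0].name}"
    )
    return ModuleSelection(sheet, matches, bool(matches), note)


def screen_combinations(
    substrates: Sequence[Union[str, Species]],
    products: Sequence[Union[str, Species]],
) -> pd.DataFrame:
    """Balance-sheet screen over substrate × product combinations.

    For each pair the smallest substrate coefficient admitting at least one
    whole product molecule is chosen, the product coefficient maximised under
    carbon conservation, and the remaining carbon assigned to CO2.
    """
    rows = []
    for s in substrates:
        sub = resolve_species(s)
        for p in products:
            prod = resolve_species(p)
            if sub.n_carbon == 0 or prod.n_carbon == 0:
                raise ValueError("screen requires carbon-containing species")
            n_sub = Fraction(1)
            while n_sub * sub.n_carbon < prod.n_carbon:
                n_sub += 1
            n_prod = Fraction(int(n_sub * sub.n_carbon) // prod.n_carbon)
            sheet = balance_sheet((sub, n_sub), [(prod, n_prod)])
            rows.append(
                {
                    "substrate": sub.name,
                    "product": prod.name,
                    "substrate_coeff": n_sub,
                    "product_coeff": n_prod,
                    "co2_coeff": sheet.co2_coefficient,
                    "surplus_pairs": sheet.surplus_pairs,
                    "pairs_per_substrate": sheet.pairs_per_substrate,
                    "verdict": sheet.verdict,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Network-level electron conservation
# ---------------------------------------------------------------------------


def reaction_electron_change(model: MetabolicModel, reaction_id: str) -> float:
    """Net electron creation of one reaction (0 for balanced chemistry)."""
    rxn = model.reactions[reaction_id]
    total = 0.0
    for met, coeff in rxn.stoichiometry.items():
        total += coeff * compound_electrons(model.compounds[met])
    return total


def electron_conservation_residual(
    model: MetabolicModel, solution: FluxSolution
) -> float:
    """Electrons in minus electrons out for a steady-state flux distribution.

    For a network whose internal reactions are element- and charge-balanced,
    Σ_exchanges γ_i·v_i + Σ_pseudo (electron imbalance)·v = 0 holds by linear
    algebra; equivalently electrons consumed = electrons secreted + 4·(O2
    uptake), since γ(O2) = −4.  The returned residual should vanish for any
    feasible flux; the biomass pseudo-reaction's imbalance is accounted via
    its own stoichiometry.
    """
    total = 0.0
    for rid, flux in solution.fluxes.items():
        if abs(flux) < 1e-12:
            continue
        total += flux * reaction_electron_change(model, rid)
    return total
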