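"""Stage 2 — degree-of-reduction balance sheets and the combination screen.

Computes electron balance sheets for the canonical substrate/product pairs
and the full screening matrix over common fermentation substrates and
products, writing the matrix to results/balance_screen.tsv.

Finding: glucose→2 lactate is exactly balanced (24 = 24 electrons), so a
strain with no electron transfer to the quinone pool can ferment glucose
homolactically; glycerol→lactate leaves one surplus electron pair per
glycerol (14 vs 12), which is precisely the duty of the reintegrated
quinone-dependent G3P dehydrogenase; two glycerol→isobutanol leaves two
pairs (28 vs 24), again one per glycerol, so the same module re-balances
isobutanol production.
"""

from pathlib import Path

from respiroferm.redox import (
    GLPD_MODULE,
    balance_sheet,
    required_module,
    screen_combinations,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    cases = [
        (("glucose", 1), [("lactate", 2)]),
        (("glycerol", 1), [("lactate", 1)]),
        (("glycerol", 2), [("isobutanol", 1)]),
        (("glucose", 1), [("isobutanol", 1)]),
    ]
    print("balance sheets:")
    for substrate, products in cases:
        sheet = balance_sheet(substrate, products)
        conversion = (
            f"{substrate[1]} {substrate[0]} -> "
            + " + ".join(f"{c} {p}" for p, c in products)
            + (f" + {sheet.co2_coefficient} CO2" if sheet.co2_coefficient else "")
        )
        print(
            f"  {conversion:42s} e-: {sheet.substrate_electrons} vs "
            f"{sheet.product_electrons}  pairs/substrate: "
            f"{sheet.pairs_per_substrate}  {sheet.verdict}"
        )
        selection = required_module(sheet, [GLPD_MODULE])
        if selection.selected:
            names = ", ".join(m.name for m in selection.selected)
            print(f"    -> respiratory module matching the surplus: {names}")

    matrix = screen_combinations(
        ["glucose", "glycerol", "xylose"],
        ["lactate", "acetate", "ethanol", "isobutanol", "succinate"],
    )
    matrix.to_csv(RESULTS / "balance_screen.tsv", sep="\t", index=False)
    balanced = (matrix["verdict"] == "balanced").sum()
    excess = (matrix["verdict"] == "unbalanced_excess_electrons").sum()
    deficit = (matrix["verdict"] == "unbalanced_electron_deficit").sum()
    print(
        f"\nscreen over {len(matrix)} combinations: {balanced} balanced, "
        f"{excess} with surplus electrons (candidates for controlled "
        f"respiro-fermentation), {deficit} electron-deficient"
    )
    print(f"matrix written to {RESULTS / 'balance_screen.tsv'}")


if __name__ == "__main__":
    main()
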