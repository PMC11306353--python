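"""Stage 1 — quinone-reaction census and deletion-target derivation.

Runs the census on the bundled annotation fixture (the miniature network
standing in for the genome-scale reconstruction) and on the toy core
network, prints the curated ledger, and writes the entry tables plus the
derived deletion loci under results/.

Finding: the fixture reproduces the full census ledger — 17 reactions
enumerated from the model annotation, 6 curated out, 3 added from the
database annotation, 14 relevant; 7 NAD(P)H:quinone oxidoreductase and 12
quinone-dependent dehydrogenase gene groups, of which 8 can form an
NAD(P)H/quinone mini-cycle — and the derived target list is exactly the 19
deletion loci of the obligate-fermentative genotype (gpsA included because
GlpD is scheduled for later reintegration).
"""

import json
from pathlib import Path

from respiroferm import build_census_fixture, build_toy_model
from respiroferm.census import (
    census_report_json,
    census_report_tsv,
    deletion_targets,
    run_census,
)
from respiroferm.fixtures import EXCLUSIONS

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    model, fixture = build_census_fixture()
    census = run_census(model, exclusions=EXCLUSIONS)
    pairs = [
        (e.reaction_id, e.mini_cycle_partner)
        for e in census.entries if e.mini_cycle_partner
    ]
    loci = deletion_targets(
        census, pairs, model=model, reintegration=fixture.reintegration
    )

    (RESULTS / "census_fixture.tsv").write_text(census_report_tsv(census))
    payload = census_report_json(census)
    payload["deletion_targets"] = sorted(loci)
    (RESULTS / "census_fixture.json").write_text(
        json.dumps(payload, indent=2) + "\n"
    )

    c = census.counts
    print("census fixture ledger:")
    print(f"  enumerated (model annotation): {c.enumerated}")
    print(f"  excluded by curation:          {c.excluded}")
    print(f"  added from database:           {c.added}")
    print(f"  relevant:                      {c.relevant}")
    print(f"  NAD(P)H:quinone oxidoreductase gene groups: {c.oxidoreductases}")
    print(f"  quinone-dependent dehydrogenase gene groups: {c.dehydrogenases}")
    print(f"  mini-cycle-forming gene groups: {c.mini_cycles}")
    print(f"  deletion loci ({len(loci)}): {' '.join(sorted(loci))}")

    toy = build_toy_model()
    toy_census = run_census(toy)
    (RESULTS / "census_toy.tsv").write_text(census_report_tsv(toy_census))
    toy_pairs = [
        (e.reaction_id, e.mini_cycle_partner)
        for e in toy_census.entries if e.mini_cycle_partner
    ]
    print("\ntoy core network:")
    print("  quinone-reducing reactions:",
          " ".join(sorted(e.reaction_id for e in toy_census.entries)))
    print("  mini-cycles:", toy_pairs)


if __name__ == "__main__":
    main()
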