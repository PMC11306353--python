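"""Census: enumeration, curation arithmetic, classification, mini-cycles,
deletion-target derivation and reintegration safety."""

from fractions import Fraction
from itertools import product

import pytest
from hypothesis import given, settings, strategies as st

from respiroferm.census import (
    CLASS_DEHYDROGENASE,
    CLASS_OXIDOREDUCTASE,
    CensusEntry,
    CensusResult,
    classify,
    curate,
    cycle_safe_reintegration,
    deletion_targets,
    detect_mini_cycles,
    enumerate_quinone_reducing,
    run_census,
)
from respiroferm.design import NNMINI, NNMINI_LOCI
from respiroferm.fixtures import EXCLUSIONS
from respiroferm.model import Compound, MetabolicModel, ReactionRecord, fva


# --------------------------------------------------------------------------
# Independent oracle: blind rational search for a cancelling combination.
# --------------------------------------------------------------------------

_IGNORE = {"h", "h2o"}


def cancellation_oracle(model, rq_id, rn_id):
    """Brute-force check that some rational multiple of the counterpart,
    combined with the quinone reaction, nets exactly NAD(P)H -> quinol.

    Unlike the detector (which solves for the multiplier from shared
    metabolites), this blindly scans multipliers p/q with |p|,|q| <= 6.
    """
    rq = model.reactions[rq_id]
    rn = model.reactions[rn_id]
    pairs = model.quinone_pairs
    for q_id, qh2_id in pairs:
        s_q = rq.stoichiometry.get(q_id, 0)
        s_qh2 = rq.stoichiometry.get(qh2_id, 0)
        if s_q < 0 < s_qh2:
            direction = 1
        elif s_qh2 < 0 < s_q and rq.lower_bound < 0:
            direction = -1
        else:
            continue
        base = {m: Fraction(c) * direction for m, c in rq.stoichiometry.items()}
        for p, q in product(range(-6, 7), range(1, 7)):
            if p == 0:
                continue
            lam = Fraction(p, q)
            net = dict(base)
            for m, c in rn.stoichiometry.items():
                net[m] = net.get(m, Fraction(0)) + lam * Fraction(c)
            net = {m: c for m, c in net.items() if c != 0 and m not in _IGNORE}
            for red, ox in (("nadh", "nad"), ("nadph", "nadp")):
                want = {red, ox, q_id, qh2_id}
                if set(net) != want:
                    continue
                scale = net[qh2_id]
                if scale > 0 and net[q_id] == -scale and net[red] == -scale \
                        and net[ox] == scale:
                    return True
    return False


class TestEnumerate:
    def test_toy_enumeration(self, toy_model):
        ids = {e.reaction_id for e in enumerate_quinone_reducing(toy_model)}
        assert ids == {"NDH", "NUO", "SDH", "MQO", "GLPD", "DLD"}

    def test_fixture_enumerates_seventeen(self, census_fixture):
        model, _ = census_fixture
        assert len(enumerate_quinone_reducing(model)) == 17
        assert len(enumerate_quinone_reducing(model, "ecocyc")) == 3
        assert len(enumerate_quinone_reducing(model, "all")) == 20

    def test_no_quinone_usage_gives_empty_list(self):
        m = MetabolicModel("bare", quinone_pairs=[("q8", "q8h2")])
        for cid in ("q8", "q8h2", "a", "b"):
            m.add_compound(Compound(id=cid))
        m.add_reaction(ReactionRecord("R", {"a": -1, "b": 1}))
        assert enumerate_quinone_reducing(m) == []

    def test_unconfigured_quinone_pairs_error(self):
        m = MetabolicModel("none")
        m.add_compound(Compound(id="a"))
        m.add_reaction(ReactionRecord("R", {"a": -1}))
        with pytest.raises(ValueError, match="quinone pairs"):
            enumerate_quinone_reducing(m)

    def test_isoreactions_of_one_group_collapse(self, toy_model):
        m = toy_model.copy()
        # a menaquinone variant of GlpD: same gene group, second quinone pool
        m.add_compound(Compound(id="mqn8", element_counts={"C": 51, "H": 56, "O": 2}))
        m.add_compound(Compound(id="mqn8h2", element_counts={"C": 51, "H": 58, "O": 2}))
        m.quinone_pairs.append(("mqn8", "mqn8h2"))
        m.add_reaction(ReactionRecord(
            "GLPD_mq", {"glyc3p": -1, "mqn8": -1, "dhap": 1, "mqn8h2": 1},
            gene_association="glpD", gene_group="glpD",
        ))
        ids = {e.reaction_id for e in enumerate_quinone_reducing(m)}
        assert len(ids & {"GLPD", "GLPD_mq"}) == 1


class TestCurate:
    def test_fixture_relevant_fourteen(self, fixture_census_result):
        assert fixture_census_result.counts.relevant == 14

    def test_no_curation_relevant_equals_enumerated(self, census_fixture):
        model, _ = census_fixture
        result = curate(enumerate_quinone_reducing(model), model=model)
        assert result.counts.relevant == result.counts.enumerated == 17

    def test_exclusions_without_additions(self, census_fixture):
        model, _ = census_fixture
        result = curate(
            enumerate_quinone_reducing(model), EXCLUSIONS, model=model
        )
        assert result.counts.relevant == 11  # 17 - 6

    def test_unknown_exclusion_id_fails_loudly(self, census_fixture):
        model, _ = census_fixture
        with pytest.raises(KeyError, match="NOT_A_REACTION"):
            curate(
                enumerate_quinone_reducing(model),
                [("NOT_A_REACTION", "typo")],
                model=model,
            )

    def test_excluded_entries_carry_reason_and_no_class(self, fixture_census_result):
        for entry in fixture_census_result.entries:
            if entry.status == "excluded":
                assert entry.exclusion_reason
                assert entry.classification == ""
                assert entry.mini_cycle_partner is None

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        n_excl=st.integers(min_value=0, max_value=6),
        n_add=st.integers(min_value=0, max_value=3),
    )
    def test_count_arithmetic_invariant(self, census_fixture, n_excl, n_add):
        """relevant = enumerated - excluded + added, for any curation."""
        model, _ = census_fixture
        enumerated = enumerate_quinone_reducing(model)
        additions = enumerate_quinone_reducing(model, "ecocyc")[:n_add]
        result = curate(enumerated, EXCLUSIONS[:n_excl], additions, model=model)
        c = result.counts
        assert c.relevant == c.enumerated - c.excluded + c.added


class TestClassify:
    def test_nadh_oxidation_is_oxidoreductase(self, toy_model):
        entry = CensusEntry(reaction_id="NDH", gene_group="ndh")
        assert classify(entry, toy_model) == CLASS_OXIDOREDUCTASE

    def test_succinate_donor_is_dehydrogenase(self, toy_model):
        entry = CensusEntry(reaction_id="SDH", gene_group="sdh")
        assert classify(entry, toy_model) == CLASS_DEHYDROGENASE

    def test_nadph_oxidation_is_oxidoreductase(self, census_fixture):
        model, _ = census_fixture
        entry = CensusEntry(reaction_id="NQOR", gene_group="x")
        assert classify(entry, model) == CLASS_OXIDOREDUCTASE

    def test_non_quinone_reaction_rejected(self, toy_model):
        entry = CensusEntry(reaction_id="LDHA", gene_group="ldhA")
        with pytest.raises(ValueError, match="no quinone"):
            classify(entry, toy_model)

    def test_fixture_group_counts(self, fixture_census_result):
        assert fixture_census_result.counts.oxidoreductases == 7
        assert fixture_census_result.counts.dehydrogenases == 12


class TestMiniCycles:
    def test_toy_cycles_contain_known_pairs(self, toy_model):
        census = run_census(toy_model)
        pairs = {
            (e.reaction_id, e.mini_cycle_partner)
            for e in census.entries
            if e.mini_cycle_partner
        }
        assert ("DLD", "LDHA") in pairs
        assert ("GLPD", "GPSA") in pairs
        assert ("MQO", "MDH") in pairs

    def test_fixture_eight_cycle_groups_and_poxb_unpaired(
        self, fixture_census_result
    ):
        assert fixture_census_result.counts.mini_cycles == 8
        assert fixture_census_result.get("POX").mini_cycle_partner is None
        assert fixture_census_result.get("SUCDi").mini_cycle_partner is None
        cycle_groups = set()
        for e in fixture_census_result.entries:
            if e.mini_cycle_partner:
                cycle_groups.update(e.gene_groups)
        assert cycle_groups == {
            "dld", "mqo", "putA", "glpD", "glpABC", "glcDEF", "dadA", "lhgO"
        }

    def test_detector_matches_cancellation_oracle(self, toy_model, census_fixture):
        """Pairwise verdicts agree with a blind rational-multiplier search."""
        fixture_model, _ = census_fixture
        for model in (toy_model, fixture_model):
            census = run_census(
                model,
                exclusions=EXCLUSIONS if model.id == "census_fixture" else (),
            )
            dehydrogenases = [
                e for e in census.relevant_entries()
                if e.classification == CLASS_DEHYDROGENASE
            ]
            detected = set(detect_mini_cycles(model, dehydrogenases))
            candidates = [
                r.id for r in model.reactions.values()
                if not (r.is_exchange or r.is_biomass)
            ]
            for entry in dehydrogenases:
                for rn in candidates:
                    if rn == entry.reaction_id:
                        continue
                    expected = cancellation_oracle(model, entry.reaction_id, rn)
                    assert ((entry.reaction_id, rn) in detected) == expected, (
                        entry.reaction_id, rn,
                    )

    def test_invariant_to_direction_encoding(self, toy_model):
        """Rewriting the counterpart with flipped sign convention changes
        nothing (reversibility is bounds, not stoichiometry)."""
        m = toy_model.copy()
        gpsa = m.reactions["GPSA"]
        gpsa.stoichiometry = {k: -v for k, v in gpsa.stoichiometry.items()}
        gpsa.lower_bound, gpsa.upper_bound = -gpsa.upper_bound, 0.0
        census = run_census(m)
        assert census.get("GLPD").mini_cycle_partner == "GPSA"


class TestDeletionTargets:
    def test_fixture_reproduces_nineteen_loci(self, census_fixture):
        model, fixture = census_fixture
        census = run_census(model, exclusions=EXCLUSIONS)
        pairs = [
            (e.reaction_id, e.mini_cycle_partner)
            for e in census.entries if e.mini_cycle_partner
        ]
        loci = deletion_targets(
            census, pairs, model=model, reintegration=fixture.reintegration
        )
        assert loci == set(NNMINI_LOCI)
        assert len(loci) == 19

    def test_no_reintegration_spares_counterpart(self, census_fixture):
        model, _ = census_fixture
        census = run_census(model, exclusions=EXCLUSIONS)
        pairs = [
            (e.reaction_id, e.mini_cycle_partner)
            for e in census.entries if e.mini_cycle_partner
        ]
        loci = deletion_targets(census, pairs, model=model, reintegration=())
        assert "gpsA" not in loci
        assert loci == set(NNMINI_LOCI) - {"gpsA"}

    def test_empty_census_empty_targets(self):
        empty = CensusResult(entries=[])
        assert deletion_targets(empty, []) == set()


class TestReintegration:
    def test_glpd_into_nnmini_is_safe(self, toy_model):
        check = cycle_safe_reintegration(toy_model, NNMINI.genes, "GLPD")
        assert check.safe
        assert check.new_cycles == []

    def test_glpd_with_gpsa_active_creates_cycle(self, toy_model):
        genes = NNMINI.genes - {"gpsA"}
        check = cycle_safe_reintegration(toy_model, genes, "GLPD")
        assert not check.safe
        assert ("GLPD", "GPSA") in check.new_cycles

    def test_sdh_without_counterpart_is_safe(self, toy_model):
        check = cycle_safe_reintegration(toy_model, NNMINI.genes, "SDH")
        assert check.safe

    def test_unknown_module_rejected(self, toy_model):
        with pytest.raises(KeyError):
            cycle_safe_reintegration(toy_model, set(), "NOPE")


class TestPostDeletionNetwork:
    def test_no_quinol_producing_flux_remains(self, toy_model):
        """After applying the deletion targets, FVA proves every quinol
        producer (and the oxidase) carries zero feasible flux."""
        from respiroferm.model import apply_deletions
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            after = apply_deletions(toy_model, NNMINI.genes)
        after.reactions["EX_glc__D"].lower_bound = -10.0
        quinol_producers = ["NDH", "NUO", "SDH", "MQO", "GLPD", "DLD"]
        ranges = fva(after, quinol_producers + ["CYO"], fraction_of_optimum=0.0)
        for rid, (vmin, vmax) in ranges.items():
            assert (vmin, vmax) == (0.0, 0.0), rid
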