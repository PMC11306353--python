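"""Model core: GPR semantics, deletions, FBA/FVA engine, SBML round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respiroferm.model import (
    Compound,
    MetabolicModel,
    ReactionRecord,
    apply_deletions,
    evaluate_gpr,
    fba,
    fva,
    gpr_genes,
    read_sbml,
    steady_state_residual,
    to_cobra,
    write_sbml,
)

from conftest import brute_force_fba


def chain_model(uptake=5.0):
    """A -> B -> C irreversible chain with bounded uptake."""
    m = MetabolicModel("chain")
    for cid in "ABC":
        m.add_compound(Compound(id=cid))
    m.add_reaction(ReactionRecord("EX_A", {"A": -1}, lower_bound=-uptake,
                                  annotation_tags={"exchange"}))
    m.add_reaction(ReactionRecord("R1", {"A": -1, "B": 1}))
    m.add_reaction(ReactionRecord("R2", {"B": -1, "C": 1}))
    m.add_reaction(ReactionRecord("EX_C", {"C": -1},
                                  annotation_tags={"exchange"}))
    return m


class TestGpr:
    def test_and_complex_disabled_by_any_member(self, toy_model):
        after = apply_deletions(toy_model, {"nuoE", "nuoF", "nuoG"})
        assert after.reactions["NUO"].disabled()
        assert not after.reactions["NDH"].disabled()

    def test_or_isozyme_survives_single_deletion(self, toy_model):
        after = apply_deletions(toy_model, {"acnA"})
        assert not after.reactions["ACONT"].disabled()
        after = apply_deletions(toy_model, {"acnA", "acnB"})
        assert after.reactions["ACONT"].disabled()

    def test_empty_gpr_never_deletable(self, toy_model):
        genes = toy_model.genes
        after = apply_deletions(toy_model, genes)
        assert not after.reactions["GLCUPT"].disabled()
        assert not after.reactions["ATPS"].disabled()

    def test_gene_extraction(self):
        assert gpr_genes("a and (b or c)") == {"a", "b", "c"}
        assert gpr_genes("") == set()

    def test_unknown_gene_warns(self, toy_model):
        with pytest.warns(UserWarning, match="not present"):
            apply_deletions(toy_model, {"no_such_gene"})

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.sets(st.sampled_from(
        ["ndh", "nuoE", "mdh", "mqo", "acnA", "acnB", "ldhA", "pta", "ackA"]
    )))
    def test_matches_cobra_gpr_semantics(self, deleted):
        """Hand-rolled boolean evaluation agrees with COBRApy's GPR.eval."""
        from cobra.core.gene import GPR

        expressions = [
            "ndh",
            "acnA or acnB",
            "pta and ackA",
            "ldhA or (pta and ackA)",
            "(ndh or mdh) and (mqo or acnA)",
        ]
        for expr in expressions:
            assert evaluate_gpr(expr, deleted) == GPR.from_string(expr).eval(deleted)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.sets(st.sampled_from(["ndh", "mqo", "dld", "glpD", "gpsA", "sdhA"])),
        st.sets(st.sampled_from(["ndh", "mqo", "dld", "glpD", "gpsA", "sdhA"])),
    )
    def test_deletions_idempotent_and_monotone(self, toy_model, small, extra):
        once = apply_deletions(toy_model, small)
        twice = apply_deletions(once, small)
        more = apply_deletions(toy_model, small | extra)
        for rid in toy_model.reactions:
            assert once.reactions[rid].disabled() == twice.reactions[rid].disabled()
            if once.reactions[rid].disabled():
                assert more.reactions[rid].disabled()


class TestFba:
    def test_chain_bottleneck(self):
        sol = fba(chain_model(uptake=5.0), "EX_C", "max")
        assert sol.ok
        assert sol.objective_value == pytest.approx(5.0)

    def test_infeasible_forced_flux(self):
        m = chain_model()
        m.reactions["R1"].lower_bound = 10.0  # forces more than uptake allows
        m.reactions["R1"].upper_bound = 10.0
        sol = fba(m, "EX_C", "max")
        assert sol.status == "infeasible"

    def test_toy_nnmini_lactate_yield_two(self, toy_model):
        """Glucose uptake 1 supports at most 2 lactate (homolactic yield)."""
        from respiroferm.design import NNMINI, AEROBIC, apply_design

        m = apply_design(toy_model, NNMINI, AEROBIC)
        m.reactions["EX_glc__D"].lower_bound = -1.0
        m.reactions["BIOMASS"].upper_bound = 0.0
        m.reactions["ATPM"].lower_bound = 0.0
        sol = fba(m, "EX_lac__D", "max")
        assert sol.objective_value == pytest.approx(2.0, abs=1e-8)

    def test_steady_state_residual(self, toy_model):
        m = toy_model.copy()
        m.reactions["EX_glc__D"].lower_bound = -10.0
        sol = fba(m, "BIOMASS", "max")
        assert sol.ok
        assert steady_state_residual(m, sol) <= 1e-6

    def test_matches_brute_force_enumeration(self):
        """LP optimum equals exhaustive vertex enumeration on tiny nets."""
        m = MetabolicModel("branch")
        for cid in "ABCD":
            m.add_compound(Compound(id=cid))
        m.add_reaction(ReactionRecord("EX_A", {"A": -1}, lower_bound=-4,
                                      annotation_tags={"exchange"}))
        m.add_reaction(ReactionRecord("R1", {"A": -1, "B": 1}, upper_bound=3))
        m.add_reaction(ReactionRecord("R2", {"A": -1, "C": 1}, upper_bound=2))
        m.add_reaction(ReactionRecord("R3", {"B": -1, "C": -1, "D": 2}))
        m.add_reaction(ReactionRecord("EX_D", {"D": -1},
                                      annotation_tags={"exchange"}))
        for objective, sense in [("EX_D", "max"), ("R1", "max"), ("R2", "min")]:
            expected = brute_force_fba(m, objective, sense)
            got = fba(m, objective, sense)
            assert got.ok
            assert got.objective_value == pytest.approx(expected, abs=1e-7)

    def test_matches_cobra_on_toy(self, toy_model):
        """Independent LP route (COBRApy/GLPK) agrees with the HiGHS engine."""
        m = toy_model.copy()
        m.reactions["EX_glc__D"].lower_bound = -10.0
        ours = fba(m, "BIOMASS", "max")
        cm = to_cobra(m)
        theirs = cm.optimize()
        assert theirs.status == "optimal"
        assert ours.objective_value == pytest.approx(
            theirs.objective_value, abs=1e-6
        )

    def test_bad_objective_and_sense(self, toy_model):
        with pytest.raises(KeyError):
            fba(toy_model, "NOPE")
        with pytest.raises(ValueError):
            fba(toy_model, "BIOMASS", "sideways")


class TestFva:
    def test_blocked_reaction_is_zero_zero(self):
        m = chain_model()
        m.add_compound(Compound(id="X"))
        m.add_reaction(ReactionRecord("DEAD", {"B": -1, "X": 1}))  # X has no sink
        ranges = fva(m, ["DEAD"], objective="EX_C")
        assert ranges["DEAD"] == (0.0, 0.0)

    def test_reversible_free_shuttle_symmetric(self):
        m = MetabolicModel("shuttle")
        for cid in "AB":
            m.add_compound(Compound(id=cid))
        m.add_reaction(ReactionRecord("EX_A", {"A": -1}, lower_bound=-7,
                                      upper_bound=7, annotation_tags={"exchange"}))
        m.add_reaction(ReactionRecord("EX_B", {"B": -1}, lower_bound=-7,
                                      upper_bound=7, annotation_tags={"exchange"}))
        m.add_reaction(ReactionRecord("SHUTTLE", {"A": -1, "B": 1},
                                      lower_bound=-7, upper_bound=7))
        ranges = fva(m, ["SHUTTLE"], objective="EX_B")
        assert ranges["SHUTTLE"] == (-7.0, 7.0)

    def test_infeasible_base_raises(self):
        m = chain_model()
        m.reactions["R1"].lower_bound = 10.0
        m.reactions["R1"].upper_bound = 10.0
        with pytest.raises(RuntimeError, match="infeasible"):
            fva(m, ["R2"], objective="EX_C")

    def test_min_not_above_max(self, toy_model):
        m = toy_model.copy()
        m.reactions["EX_glc__D"].lower_bound = -10.0
        ranges = fva(m, ["LDHA", "PDH", "NUO"], fraction_of_optimum=1.0,
                     objective="BIOMASS")
        for vmin, vmax in ranges.values():
            assert vmin <= vmax + 1e-9


class TestSbmlRoundTrip:
    def _assert_equal(self, a, b):
        assert set(a.compounds) == set(b.compounds)
        assert set(a.reactions) == set(b.reactions)
        for cid, cpd in a.compounds.items():
            other = b.compounds[cid]
            assert cpd.element_counts == other.element_counts
            assert cpd.charge == other.charge
        for rid, rxn in a.reactions.items():
            other = b.reactions[rid]
            assert rxn.stoichiometry == other.stoichiometry
            assert rxn.lower_bound == other.lower_bound
            assert rxn.upper_bound == other.upper_bound
            assert gpr_genes(rxn.gene_association) == gpr_genes(
                other.gene_association
            )
            assert rxn.annotation_tags == other.annotation_tags

    def test_toy_round_trip(self, toy_model, tmp_path):
        path = tmp_path / "toy.xml"
        write_sbml(toy_model, str(path))
        back = read_sbml(str(path))
        self._assert_equal(toy_model, back)
        assert back.objective_reaction == "BIOMASS"
        assert back.quinone_pairs == [("q8", "q8h2")]

    def test_census_fixture_round_trip(self, census_fixture, tmp_path):
        model, _ = census_fixture
        path = tmp_path / "census.xml"
        write_sbml(model, str(path))
        back = read_sbml(str(path))
        self._assert_equal(model, back)

    def test_or_of_and_gpr_survives(self, toy_model, tmp_path):
        m = toy_model.copy()
        m.reactions["GLPD"].gene_association = "glpD or (glpA and glpB and glpC)"
        path = tmp_path / "gpr.xml"
        write_sbml(m, str(path))
        back = read_sbml(str(path))
        expr = back.reactions["GLPD"].gene_association
        assert gpr_genes(expr) == {"glpD", "glpA", "glpB", "glpC"}
        assert evaluate_gpr(expr, {"glpD"})  # isozyme operon still active
        assert not evaluate_gpr(expr, {"glpD", "glpB"})

    def test_empty_model(self, tmp_path):
        path = tmp_path / "empty.xml"
        write_sbml(MetabolicModel("empty"), str(path))
        back = read_sbml(str(path))
        assert not back.compounds and not back.reactions

    def test_unknown_notes_tolerated(self, toy_model, tmp_path):
        """Unrecognised notes/tags in the file are ignored, not fatal."""
        path = tmp_path / "tagged.xml"
        cm = to_cobra(toy_model)
        cm.reactions.get_by_id("LDHA").notes["unrecognised_key"] = "whatever"
        import cobra.io

        cobra.io.write_sbml_model(cm, str(path))
        back = read_sbml(str(path))
        assert "LDHA" in back.reactions

    def test_unparseable_file_raises_named_error(self, tmp_path):
        path = tmp_path / "junk.xml"
        path.write_text("this is not SBML")
        with pytest.raises(ValueError, match="junk.xml"):
            read_sbml(str(path))

    def test_metadata_counts(self, toy_model, tmp_path):
        path = tmp_path / "toy.xml"
        write_sbml(toy_model, str(path))
        back = read_sbml(str(path))
        assert back.metadata["n_reactions"] == len(toy_model.reactions)
        assert back.metadata["n_genes"] == len(toy_model.genes)
        assert len(back.metadata["sha256"]) == 64


class TestBalanceChecks:
    def test_toy_internal_reactions_balanced(self, toy_model):
        assert toy_model.balance_errors() == {}

    def test_fixture_internal_reactions_balanced(self, census_fixture):
        model, _ = census_fixture
        assert model.balance_errors() == {}

    def test_imbalance_detected(self, toy_model):
        m = toy_model.copy()
        m.reactions["LDHA"].stoichiometry["h"] = -2  # one proton too many
        errs = m.balance_errors()
        assert "LDHA" in errs
        assert errs["LDHA"]["charge"] == pytest.approx(-1)
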