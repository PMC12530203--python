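"""Site classification, pathway enumeration/averaging and per-gene counting."""

from fractions import Fraction as F

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonmk import (
    GeneticCode,
    SiteClass,
    classify_position,
    count_gene,
    divergence_origin,
    enumerate_pathways,
    pathway_average,
)
from codonmk.genetic_code import STOP

from .conftest import make_alignment
from .oracle import brute_force_average

SENSE = GeneticCode.standard().sense_codons
sense_codon = st.sampled_from(SENSE)


@pytest.mark.parametrize(
    "a, b, o, expected",
    [
        ("A", "A", "A", SiteClass.IDENTICAL),
        ("A", "G", "A", SiteClass.POLYMORPHIC),
        ("A", "A", "G", SiteClass.FIXED),
        ("A", "G", "C", SiteClass.POLYMORPHIC),  # three-state: never fixed
    ],
)
def test_classify_position(a, b, o, expected):
    assert classify_position(a, b, o) is expected


def test_classify_position_rejects_unclean_symbols():
    with pytest.raises(ValueError, match="not cleaned"):
        classify_position("A", "N", "A")


class TestEnumeratePathways:
    def test_two_difference_codon_has_both_orderings(self, code):
        ps = enumerate_pathways("TTT", "GTA", code)
        assert len(ps.pathways) == 2 and ps.excluded_pathways == 0
        labels = sorted(
            tuple(step.synonymous for step in path) for path in ps.pathways
        )
        # one pathway F->V->V (nonsyn, syn), the other F->L->V (nonsyn, nonsyn)
        assert labels == [(False, False), (False, True)]

    def test_single_difference_synonymous_step(self, code):
        ps = enumerate_pathways("GTT", "GTA", code)
        assert len(ps.pathways) == 1
        (step,) = ps.pathways[0]
        assert step.synonymous  # Val -> Val

    def test_stop_intermediate_pathway_excluded(self, code):
        ps = enumerate_pathways("TGG", "TAC", code)
        assert ps.excluded_pathways == 1
        (path,) = ps.pathways
        assert [s.to_codon for s in path] == ["TGC", "TAC"]
        assert all(not s.synonymous for s in path)  # Trp->Cys->Tyr

    def test_all_pathways_excluded_falls_back_to_all(self, code):
        # under a code where TGC also terminates, both TGG->TAC orderings
        # pass through a stop; the exclusion rule must then be suspended
        harsher = GeneticCode(
            table_id=0, codon_map={**code.codon_map, "TGC": STOP}
        )
        ps = enumerate_pathways("TGG", "TAC", harsher)
        assert len(ps.pathways) == 2 and ps.excluded_pathways == 0

    def test_identical_codons_rejected(self, code):
        with pytest.raises(ValueError):
            enumerate_pathways("ATG", "ATG", code)


class TestPathwayAverage:
    @pytest.mark.parametrize(
        "origin, target, syn, nonsyn",
        [
            ("TTT", "TTT", F(0), F(0)),
            ("GTT", "GTA", F(1), F(0)),
            ("TTT", "GTA", F(1, 2), F(3, 2)),
            ("TGG", "TAC", F(0), F(2)),  # stop-traversing pathway excluded
        ],
    )
    def test_worked_examples(self, code, origin, target, syn, nonsyn):
        assert pathway_average(origin, target, code) == (syn, nonsyn)

    def test_stop_policy_include_changes_the_mean(self, code):
        # TCA(Ser)->TGT(Cys): the ordering via TGA(stop) is excluded by
        # default but contributes (0 syn, 2 nonsyn) when included
        assert pathway_average("TCA", "TGT", code) == (F(1), F(1))
        assert pathway_average("TCA", "TGT", code, stop_policy="include") == (
            F(1, 2),
            F(3, 2),
        )

    @settings(max_examples=300, derandomize=True)
    @given(origin=sense_codon, target=sense_codon)
    def test_agrees_with_brute_force_and_conserves_steps(self, code, origin, target):
        d = sum(a != b for a, b in zip(origin, target))
        for policy, exclude in [("exclude", True), ("include", False)]:
            syn, nonsyn = pathway_average(origin, target, code, stop_policy=policy)
            assert (syn, nonsyn) == brute_force_average(origin, target, exclude)
            assert syn + nonsyn == d
            # the mean runs over the retained pathways, so the denominator
            # divides their number: d! without exclusion, possibly 4 or 5
            # of the 6 orderings of a triple difference with it
            assert syn.denominator <= 6 and nonsyn.denominator <= 6
            if policy == "include":
                assert 6 % syn.denominator == 0
                assert 6 % nonsyn.denominator == 0


class TestCountGene:
    def test_identical_alignment_counts_nothing(self, code):
        aln = make_alignment("ATGGCTTTT", "ATGGCTTTT", "ATGGCTTTT")
        c = count_gene(aln, code)
        assert c.as_tuple() == (0, 0, 0, 0)
        assert c.codons_used == 3

    def test_single_synonymous_polymorphism(self, code):
        c = count_gene(make_alignment("GTT", "GTA", "GTT"), code)
        assert c.as_tuple() == (F(0), F(0), F(1), F(0))

    def test_multi_hit_divergence_is_pathway_averaged(self, code):
        c = count_gene(make_alignment("TTT", "TTT", "GTA"), code)
        assert c.as_tuple() == (F(1, 2), F(3, 2), F(0), F(0))

    def test_codon_with_polymorphism_and_fixed_difference_decomposes(self, code):
        # ingroups TTT/TTC (pos-3 polymorphism, Phe/Phe), outgroup GTC:
        # divergence runs TTC->GTC (Phe->Val) in the outgroup-context codon
        c = count_gene(make_alignment("TTT", "TTC", "GTC"), code)
        assert c.as_tuple() == (F(0), F(1), F(1), F(0))

    def test_unclean_alignment_is_contract_violation(self, code):
        with pytest.raises(ValueError, match="unclean"):
            count_gene(make_alignment("AT-", "ATG", "ATG"), code)

    @settings(max_examples=100, derandomize=True)
    @given(
        cols=st.lists(
            st.tuples(sense_codon, sense_codon, sense_codon), min_size=1, max_size=12
        ),
        split=st.integers(min_value=0, max_value=12),
    )
    def test_additivity_and_ingroup_symmetry(self, code, cols, split):
        split = min(split, len(cols))
        seqs = ["".join(c[i] for c in cols) for i in range(3)]
        whole = count_gene(make_alignment(*seqs), code)

        left = [s[: 3 * split] for s in seqs]
        right = [s[3 * split :] for s in seqs]
        parts = [make_alignment(*p) for p in (left, right) if p[0]]
        summed = tuple(
            sum(count_gene(p, code).as_tuple()[k] for p in parts) for k in range(4)
        )
        assert whole.as_tuple() == summed

        swapped = count_gene(make_alignment(seqs[1], seqs[0], seqs[2]), code)
        assert swapped.as_tuple() == whole.as_tuple()


def test_divergence_origin_takes_outgroup_state_at_polymorphic_positions():
    assert divergence_origin("TTT", "TTC", "GTC") == "TTC"
    assert divergence_origin("ATG", "ATG", "CCC") == "ATG"
    # symmetric in the two ingroup codons
    assert divergence_origin("TTC", "TTT", "GTC") == "TTC"
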