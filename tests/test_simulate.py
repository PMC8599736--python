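"""Chemistry simulation: nick placement, end repair, ligation, reads."""

import re

import numpy as np
import pytest
from oracles import repair_oracle

from cleavemap.seqcore import CircularRef, revcomp
from cleavemap.simulate import (
    ERROR_FREE,
    CassetteSpec,
    CollisionModel,
    EnzymeModel,
    ErrorModel,
    EventDistribution,
    NickSet,
    RejectedEventError,
    UnlinkedNicksError,
    apply_errors,
    build_plasmid,
    emit_concatemer,
    enzyme_nicks,
    resolve_repair,
    sample_events,
)


def _toy_ref_with(site: str, at: int = 10, L: int = 60) -> CircularRef:
    rng = np.random.default_rng(42)
    seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, L)))
    seq[at : at + len(site)] = site
    return CircularRef("toy", "".join(seq))


class TestEnzymeNicks:
    def test_five_prime_overhang_geometry(self):
        # EcoRI: G^AATTC / CTTAA^G -> nicks at site+1 (top) and site+5 (bottom)
        ref = _toy_ref_with("GAATTC")
        [ns] = enzyme_nicks(EnzymeModel("ecoRI", "GAATTC", 1, 5), ref)
        assert (ns.top, ns.bottom) == (frozenset({11}), frozenset({15}))

    def test_three_prime_overhang_geometry(self):
        # PstI: CTGCA^G / G^ACGTC -> top at site+5, bottom at site+1
        ref = _toy_ref_with("CTGCAG")
        [ns] = enzyme_nicks(EnzymeModel("pstI", "CTGCAG", 5, 1), ref)
        assert (ns.top, ns.bottom) == (frozenset({15}), frozenset({11}))

    def test_blunt_and_no_match(self):
        ref = _toy_ref_with("GAGCTC")
        [ns] = enzyme_nicks(EnzymeModel("eco53k", "GAGCTC", 3, 3), ref)
        assert ns.top == ns.bottom == frozenset({13})
        assert enzyme_nicks(EnzymeModel("x", "AAAAAAAAAA", 5, 5), ref) == []

    def test_reverse_strand_site_mirrors_geometry(self):
        # an asymmetric recognition present only on the bottom strand
        site = "GGATGCCT"  # non-palindromic
        ref_fwd = CircularRef("fwd", "T" * 20 + site + "T" * 32)
        ref_rev = CircularRef("rev", revcomp(ref_fwd.seq))
        enz = EnzymeModel("asym", site, 2, 6)
        [fwd] = enzyme_nicks(enz, ref_fwd)
        [rev] = enzyme_nicks(enz, ref_rev)
        # same physical molecule read on the other strand: overhang sign flips
        # between top/bottom roles but the spacing magnitude is conserved
        d_f = list(fwd.bottom)[0] - list(fwd.top)[0]
        d_r = list(rev.bottom)[0] - list(rev.top)[0]
        assert d_f == d_r == 4


class TestResolveRepair:
    def test_single_nick_pair_passthrough(self):
        assert resolve_repair(NickSet({11}, {15}), 200) == (11, 15)

    def test_multiple_nicks_keep_three_prime_proximal(self):
        # secondary cleavage pulls both reported loci toward apparent 3' overhangs
        assert resolve_repair(NickSet({11, 20}, {8, 15}), 200) == (20, 8)

    def test_blunt(self):
        assert resolve_repair(NickSet({10}, {10}), 200) == (10, 10)

    def test_unlinked_beyond_window(self):
        with pytest.raises(UnlinkedNicksError):
            resolve_repair(NickSet({0}, {100}), 200, window=50)

    def test_matches_sequence_oracle_on_random_sets(self):
        rng = np.random.default_rng(11)
        L = 200
        for _ in range(300):
            w0 = int(rng.integers(0, L))
            tops = [(w0 + int(x)) % L for x in rng.integers(0, 30, rng.integers(1, 3))]
            bots = [(w0 + int(x)) % L for x in rng.integers(0, 30, rng.integers(1, 3))]
            assert resolve_repair(NickSet(tops, bots), L) == repair_oracle(tops, bots, L)

    def test_three_to_five_processing_is_invisible(self):
        # a nick farther from its strand's 3' end than an existing one
        # never changes the outcome (it is repaired away)
        rng = np.random.default_rng(12)
        L = 500
        for _ in range(100):
            w0 = int(rng.integers(0, L))
            top = (w0 + int(rng.integers(10, 25))) % L
            bottom = (w0 + int(rng.integers(10, 25))) % L
            base = resolve_repair(NickSet({top}, {bottom}), L)
            extra_top = (w0 + int(rng.integers(0, (top - w0) % L))) % L  # 5'-ward of top
            extra_bottom = (bottom + int(rng.integers(1, 6))) % L  # 3'-ward in top frame
            got = resolve_repair(NickSet({top, extra_top}, {bottom, extra_bottom}), L)
            assert got == base


@pytest.fixture(scope="module")
def small_cassette():
    rng = np.random.default_rng(5)
    seq = "GA" + "".join("ACGT"[i] for i in rng.integers(0, 4, 97)) + "T"
    return CassetteSpec(seq, anchor_len=20)


class TestBuildPlasmid:
    def test_adenine_run_grows_through_workflow(self, small_cassette):
        # a blunt cut in the middle of GAAAA|GTTTC leaves 4 terminal As;
        # the non-templated dA makes it a 5-adenine run at the junction
        ref = _toy_ref_with("GAAAAGTTTC", at=20, L=300)
        [ns] = enzyme_nicks(EnzymeModel("xmn", "GAANNNNTTC", 5, 5), ref)
        plasmid, truth = build_plasmid(ref, ns, small_cassette)
        insert = plasmid[: truth["insert_len"]]
        assert len(insert) - len(insert.rstrip("A")) == 4
        with_tail = plasmid[: truth["insert_len"] + 1]
        assert len(with_tail) - len(with_tail.rstrip("A")) == 5

    def test_ligation_point_reads_agaga(self, small_cassette):
        # blunt GAG|CTC cut + cassette starting GA: ...GAG + A + GA... junction
        ref = _toy_ref_with("GAGCTC", at=20, L=300)
        [ns] = enzyme_nicks(EnzymeModel("eco53k", "GAGCTC", 3, 3), ref)
        plasmid, truth = build_plasmid(ref, ns, small_cassette)
        assert "AGAGA" in plasmid[truth["insert_len"] - 3 : truth["insert_len"] + 4]

    def test_junction_grammar_unique(self, small_cassette):
        ref = _toy_ref_with("GAATTC", at=20, L=300)
        [ns] = enzyme_nicks(EnzymeModel("ecoRI", "GAATTC", 1, 5), ref)
        plasmid, truth = build_plasmid(ref, ns, small_cassette)
        # exactly one [insert][A][cassette] junction in the circle
        junction = "A" + small_cassette.seq
        circ = plasmid + plasmid[: len(junction) - 1]
        assert circ.count(junction) == 1
        assert plasmid.endswith(small_cassette.seq)

    def test_five_prime_overhang_fill_in_duplicates_bases(self, small_cassette):
        ref = _toy_ref_with("GAATTC", at=20, L=300)
        [ns] = enzyme_nicks(EnzymeModel("ecoRI", "GAATTC", 1, 5), ref)
        plasmid, truth = build_plasmid(ref, ns, small_cassette)
        assert truth["overhang_type"] == "5p" and truth["overhang_len"] == 4
        assert truth["insert_len"] == ref.L + 4  # AATT copied to both ends

    def test_rejects_destroyed_substrate(self, small_cassette):
        ref = _toy_ref_with("GAATTC", at=20, L=300)
        with pytest.raises(RejectedEventError):
            # apparent 3' overhang of 140 removes too much of the substrate
            build_plasmid(
                ref, NickSet({10}, {(10 - 140) % 300}), small_cassette, min_insert=200
            )


class TestSampleEvents:
    def test_degenerate_joint_table(self):
        dist = EventDistribution(joint_pairs={(100, 104): 1.0})
        events = sample_events(dist, 5, 0)
        assert all(e == NickSet({100}, {104}) for e in events)

    def test_collision_points_match_closed_form(self):
        model = CollisionModel(d=4, origin=0, min_half_spacing=1, spread_p=1.0)
        events = sample_events(model, 4000, 123)
        mids = np.array([(list(e.top)[0] + list(e.bottom)[0]) // 2 for e in events])
        expected = np.array([1, 4, 6, 4, 1]) / 16 * len(mids)
        counts = np.bincount(mids, minlength=5)
        sd = np.sqrt(expected * (1 - np.array([1, 4, 6, 4, 1]) / 16))
        assert np.all(np.abs(counts - expected) <= 3 * sd + 1)

    def test_mixture_marginals_recovered(self):
        dist = EventDistribution(
            top_dist={10: 0.5, 12: 0.3, 14: 0.15, 16: 0.05},
            bottom_dist={20: 1.0},
        )
        events = sample_events(dist, 5000, 7)
        tops = np.array([list(e.top)[0] for e in events])
        for pos, p in dist.top_dist.items():
            obs = (tops == pos).sum()
            assert abs(obs - 5000 * p) <= 3 * np.sqrt(5000 * p * (1 - p))
        assert all(e.bottom == frozenset({20}) for e in events)

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            sample_events(EventDistribution(joint_pairs={(1, 2): 1.0}), 0, 0)

    def test_unnormalised_distribution_rejected(self):
        with pytest.raises(ValueError):
            EventDistribution(joint_pairs={(1, 2): 0.5})


class TestEmitConcatemer:
    def test_error_free_tandem_copies(self):
        plasmid = "ACGTTGCA" * 40
        seq, qual = emit_concatemer(plasmid, 3, 0, "+", ERROR_FREE, 0)
        assert seq == plasmid * 3 and len(qual) == len(seq)
        assert set(qual) == {chr(33 + 20)}

    def test_rotation_and_reverse_strand(self):
        plasmid = "AACCGGTTACGT" * 10
        seq, _ = emit_concatemer(plasmid, 2, 5, "-", ERROR_FREE, 0)
        monomer = plasmid[5:] + plasmid[:5]
        assert seq == revcomp(monomer * 2)

    def test_zero_rates_with_multiplier_still_error_free(self):
        err = ErrorModel(0.0, 0.0, 0.0, 10.0)
        plasmid = "AAACCCGGGTTT" * 20
        seq, _ = emit_concatemer(plasmid, 2, 0, "+", err, 1)
        assert seq == plasmid * 2

    def test_substitution_count_within_binomial_bounds(self):
        rng = np.random.default_rng(3)
        plasmid = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        err = ErrorModel(0.01, 0.0, 0.0, 1.0)
        seq, _ = emit_concatemer(plasmid, 10, 0, "+", err, rng)
        truth = plasmid * 10
        assert len(seq) == len(truth)
        mismatches = sum(a != b for a, b in zip(seq, truth))
        n, p = 30000, 0.01
        assert abs(mismatches - n * p) <= 3 * np.sqrt(n * p * (1 - p))

    def test_homopolymer_deletions_upweighted(self):
        # equal parts run and non-run sequence; deletions should concentrate
        # in the runs by roughly the multiplier
        seq = ("AAAAA" + "ACGTG") * 2000
        err = ErrorModel(0.0, 0.0, 0.01, 5.0)
        rng = np.random.default_rng(4)
        out = apply_errors(seq, err, rng)
        n_del = len(seq) - len(out)
        # expected deletions: 10000*0.05 (runs) + 10000*0.01 = 600
        assert 450 <= n_del <= 750

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            emit_concatemer("ACGT" * 10, 0, 0, "+", ERROR_FREE, 0)
        with pytest.raises(ValueError):
            emit_concatemer("ACGT" * 10, 1, 0, "x", ERROR_FREE, 0)


class TestErrorModelValidation:
    @pytest.mark.parametrize("kwargs", [
        {"substitution": 0.6},
        {"deletion": -0.1},
        {"homopolymer_deletion_multiplier": 0.5},
    ])
    def test_invalid_rates(self, kwargs):
        with pytest.raises(ValueError):
            ErrorModel(**kwargs)
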