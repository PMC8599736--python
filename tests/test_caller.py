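"""Cassette location, flank alignment, orientation and triangulation."""

import dataclasses

import numpy as np
import pytest

from cleavemap.caller import (
    DISTANT_NICKS,
    FLANK_AMBIGUOUS,
    FLANK_NO_HIT,
    MISSING_3P_ANCHOR,
    MISSING_5P_ANCHOR,
    MULTIPLE_CASSETTES,
    OK,
    CallError,
    CallerParams,
    align_flank,
    call_library,
    call_read,
    extract_flanks,
    locate_cassette,
)
from cleavemap.consensus import ConsensusRead
from cleavemap.seqcore import CircularRef, circ_substr, revcomp
from cleavemap.simulate import ERROR_FREE, NickSet, build_plasmid, enzyme_nicks


def _cread(seq: str, rid: str = "c", repeats: int = 5) -> ConsensusRead:
    return ConsensusRead(rid, seq, repeats, 20.0, len(seq))


@pytest.fixture(scope="module")
def event(ref, cassette):
    """An error-free EcoRI-style 5'-overhang event on the toy reference."""
    enz_site = circ_substr(ref, 100, 12)
    from cleavemap.simulate import EnzymeModel

    [nicks] = enzyme_nicks(EnzymeModel("ev", enz_site, 3, 7), ref)
    plasmid, truth = build_plasmid(ref, nicks, cassette)
    return plasmid, truth


class TestLocateCassette:
    def test_canonical_form_stable_under_rotation(self, event, cassette, params):
        plasmid, _ = event
        canon0, span0, _ = locate_cassette(plasmid, cassette, params)
        for rot in (17, 1200, len(plasmid) - 5):
            rotated = plasmid[rot:] + plasmid[:rot]
            canon, span, strand = locate_cassette(rotated, cassette, params)
            assert (canon, span) == (canon0, span0) and strand == "+"

    def test_reverse_complement_canonicalises_identically(self, event, cassette, params):
        plasmid, _ = event
        canon0, span0, _ = locate_cassette(plasmid, cassette, params)
        canon, span, strand = locate_cassette(revcomp(plasmid), cassette, params)
        assert (canon, span) == (canon0, span0) and strand == "-"

    def test_anchor_mutation_is_fatal(self, event, cassette, params):
        plasmid, truth = event
        a5_start = truth["insert_len"] + 1
        mutated = list(plasmid)
        mutated[a5_start + 3] = "A" if plasmid[a5_start + 3] != "A" else "C"
        with pytest.raises(CallError) as err:
            locate_cassette("".join(mutated), cassette, params)
        assert err.value.code == MISSING_5P_ANCHOR

    def test_missing_3p_anchor(self, event, cassette, params):
        plasmid, _ = event
        truncated = plasmid[: len(plasmid) - 10]  # clips the 3' anchor
        with pytest.raises(CallError) as err:
            locate_cassette(truncated, cassette, params)
        assert err.value.code == MISSING_3P_ANCHOR

    def test_second_cassette_copy_rejected(self, event, cassette, params):
        plasmid, _ = event
        doubled_anchor = plasmid[:300] + cassette.anchor5 + plasmid[300:]
        with pytest.raises(CallError) as err:
            locate_cassette(doubled_anchor, cassette, params)
        assert err.value.code == MULTIPLE_CASSETTES


class TestExtractFlanks:
    def test_flank5_matches_reference_end(self, ref, event, cassette, params):
        plasmid, truth = event
        canon, span, _ = locate_cassette(plasmid, cassette, params)
        flank5, flank3, overlap = extract_flanks(canon, span, params)
        b, t = truth["reported_bottom"], truth["reported_top"]
        assert flank5 == circ_substr(ref, (b - 20) % ref.L, 20)
        assert flank3 == circ_substr(ref, t, 20)
        assert not overlap

    def test_trim_zero_keeps_nontemplated_da(self, event, cassette):
        plasmid, _ = event
        p0 = CallerParams(junction_trim=0)
        canon, span, _ = locate_cassette(plasmid, cassette, p0)
        flank5, _, _ = extract_flanks(canon, span, p0)
        assert flank5.endswith("A")  # the dA tail is retained

    def test_insert_too_short(self, cassette, params):
        # a consensus that is nearly all cassette
        tiny = "ACGTACGTAC" + "A" + cassette.seq
        canon, span, _ = locate_cassette(tiny, cassette, params)
        with pytest.raises(CallError) as err:
            extract_flanks(canon, span, params)
        assert err.value.code == FLANK_NO_HIT


class TestAlignFlank:
    def test_exact_unique_hit(self, ref, params):
        flank = circ_substr(ref, 400, 20)
        hit = align_flank(flank, ref, params)
        assert (hit.top_start, hit.top_end) == (400, 419)
        assert hit.strand == "+" and hit.score == 20

    def test_reverse_strand_hit(self, ref, params):
        flank = revcomp(circ_substr(ref, 400, 20))
        hit = align_flank(flank, ref, params)
        assert (hit.top_start, hit.top_end) == (400, 419)
        assert hit.strand == "-"

    def test_one_substitution_rescued_with_score_18(self, ref, params):
        flank = list(circ_substr(ref, 700, 20))
        flank[10] = "A" if flank[10] != "A" else "C"
        hit = align_flank("".join(flank), ref, params)
        assert (hit.top_start, hit.top_end) == (700, 719)
        assert hit.score == 18  # 19 matches - 1 mismatch

    def test_engineered_repeat_is_ambiguous(self, ref, params):
        repeat = circ_substr(ref, 50, 20)
        seq = ref.seq[:2000] + repeat + ref.seq[2020:]
        two_loci = CircularRef("dup", seq)
        with pytest.raises(CallError) as err:
            align_flank(repeat, two_loci, params)
        assert err.value.code == FLANK_AMBIGUOUS

    def test_garbage_has_no_hit(self, ref, params):
        rng = np.random.default_rng(0)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
        # a random 20-mer aligns somewhere with a weak score only
        with pytest.raises(CallError) as err:
            align_flank(junk, ref, params)
        assert err.value.code in (FLANK_NO_HIT, FLANK_AMBIGUOUS)


class TestTriangulation:
    def test_multi_nick_event_reports_three_prime_proximal(self, ref, cassette, params):
        # secondary nicks: top {11,20}, bottom {8,15} -> call (20, 8), 3' overhang 12
        plasmid, truth = build_plasmid(ref, NickSet({11, 20}, {8, 15}), cassette)
        assert (truth["reported_top"], truth["reported_bottom"]) == (20, 8)
        call = call_read(_cread(plasmid), ref, cassette, params)
        assert call.status == OK
        assert (call.top_nick, call.bottom_nick) == (20, 8)
        assert (call.overhang_type, call.overhang_len) == ("3p", 12)

    def test_blunt_event(self, ref, cassette, params):
        plasmid, _ = build_plasmid(ref, NickSet({500}, {500}), cassette)
        call = call_read(_cread(plasmid), ref, cassette, params)
        assert call.status == OK and call.top_nick == call.bottom_nick == 500
        assert call.overhang_type == "blunt"

    def test_distant_nicks_classified(self, ref, cassette):
        p = dataclasses.replace(CallerParams(), max_nick_separation=10)
        plasmid, _ = build_plasmid(ref, NickSet({500}, {480}), cassette)
        call = call_read(_cread(plasmid), ref, cassette, p)
        assert call.status == DISTANT_NICKS

    def test_cassette_interior_mutations_do_not_affect_calls(self, ref, cassette, params):
        plasmid, truth = build_plasmid(ref, NickSet({300}, {304}), cassette)
        base = call_read(_cread(plasmid), ref, cassette, params)
        # mutate cassette bases between the anchors
        interior = truth["insert_len"] + 1 + 25  # inside cassette, past anchor5
        mutated = list(plasmid)
        for off in range(0, 200, 40):
            i = interior + off
            mutated[i] = "A" if plasmid[i] != "A" else "G"
        call = call_read(_cread("".join(mutated)), ref, cassette, params)
        assert (call.top_nick, call.bottom_nick) == (base.top_nick, base.bottom_nick)
        assert call.status == OK


class TestCallLibrary:
    def test_error_free_library_fully_recovered(self, ref, cassette, params):
        rng = np.random.default_rng(1)
        creads, want = [], {}
        for i in range(20):
            t = int(rng.integers(0, ref.L))
            b = (t + int(rng.integers(-6, 7))) % ref.L
            plasmid, truth = build_plasmid(ref, NickSet({t}, {b}), cassette)
            rid = f"lib{i}"
            rot = int(rng.integers(len(plasmid)))
            creads.append(_cread(plasmid[rot:] + plasmid[:rot], rid))
            want[rid] = (truth["reported_top"], truth["reported_bottom"])
        calls, summary = call_library(creads, ref, cassette, params)
        assert summary == {OK: 20}
        assert all((c.top_nick, c.bottom_nick) == want[c.read_id] for c in calls)

    def test_one_broken_anchor_counted(self, ref, cassette, params):
        plasmid, _ = build_plasmid(ref, NickSet({100}, {100}), cassette)
        good = _cread(plasmid, "good")
        a5 = len(plasmid) - len(cassette.seq)
        broken_seq = plasmid[:a5 + 2] + ("A" if plasmid[a5 + 2] != "A" else "C") + plasmid[a5 + 3 :]
        broken = _cread(broken_seq, "broken")
        calls, summary = call_library([good, broken], ref, cassette, params)
        assert summary[OK] == 1 and summary[MISSING_5P_ANCHOR] == 1
        assert sum(summary.values()) == len(calls) == 2

    def test_min_repeats_gate(self, ref, cassette, params):
        plasmid, _ = build_plasmid(ref, NickSet({100}, {100}), cassette)
        creads = [_cread(plasmid, f"r{r}", repeats=r) for r in range(1, 11)]
        calls, summary = call_library(creads, ref, cassette, params, min_repeats=5)
        assert len(calls) == 6  # repeats 5..10 attempted
        assert {c.read_id for c in calls} == {f"r{r}" for r in range(5, 11)}
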