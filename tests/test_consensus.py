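"""Majority-rule representative fingerprints, tie rules, trueness codes."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, strategies as st

from conftest import make_profile
from ssrcurate.consensus import (
    build_representative,
    majority_fingerprint,
    propagate_trueness,
    resolve_ties,
)
from ssrcurate.distance import MolecularGroup
from ssrcurate.model import Marker, MarkerPanel, TruenessCode


@pytest.fixture
def m_panel():
    return MarkerPanel((Marker("M", repeat_unit=2),))


def profs(panel, *allele_lists):
    return [
        make_profile(f"s{i}", {"M": alleles}, panel)
        for i, alleles in enumerate(allele_lists)
    ]


def test_unanimity(mini_panel):
    members = [
        make_profile(f"s{i}", {"M1": [100, 104], "M2": [151], "M3": [200, 203]},
                     mini_panel)
        for i in range(4)
    ]
    rep = majority_fingerprint(members, mini_panel)
    assert rep.alleles == {"M1": (100, 104), "M2": (151,), "M3": (200, 203)}
    assert rep.is_fully_resolved


def test_majority_per_position(m_panel):
    rep = majority_fingerprint(
        profs(m_panel, [100, 104], [100, 104], [100, 106]), m_panel
    )
    assert rep.alleles["M"] == (100, 104)


def test_two_member_tie_yields_check(m_panel):
    rep = majority_fingerprint(profs(m_panel, [100, 104], [100, 106]), m_panel)
    assert rep.alleles["M"] == (100, None)
    assert rep.check_candidates[("M", 1)] == (104, 106)


def test_missing_members_removed_before_vote(m_panel):
    rep = majority_fingerprint(
        profs(m_panel, [100, 104], [100, 104], []), m_panel
    )
    assert rep.alleles["M"] == (100, 104)


def test_marker_missing_everywhere_left_out_with_warning(mini_panel):
    members = [make_profile("s0", {"M1": [100]}, mini_panel)]
    rep = majority_fingerprint(members, mini_panel)
    assert "M2" not in rep.alleles
    assert any("M2" in w for w in rep.warnings)


def test_modal_allele_count_prefers_larger_on_tie(m_panel):
    # one diploid and one triploid call: the triploid signal is kept
    rep = majority_fingerprint(
        profs(m_panel, [100, 104], [100, 104, 108]), m_panel
    )
    assert len(rep.alleles["M"]) == 3


def test_empty_member_list_rejected(m_panel):
    with pytest.raises(ValueError, match="empty"):
        majority_fingerprint([], m_panel)


# --- tie resolution rules -------------------------------------------------

def test_rule_r1_prefers_combination_observed_in_members(m_panel):
    # position 1 resolves to 100 (3-1) while position 2 ties 2-2 between 104
    # and 106; the full combination (100,106) is observed verbatim in two
    # members against one for (100,104), so R1 settles the tie on 106
    members = profs(m_panel, [100, 104], [102, 104], [100, 106], [100, 106])
    rep = majority_fingerprint(members, m_panel)
    assert rep.alleles["M"] == (100, None)
    assert rep.check_candidates[("M", 1)] == (104, 106)
    resolved = resolve_ties(rep, members, m_panel)
    assert resolved.alleles["M"] == (100, 106)
    assert any(e["rule"] == "R1" for e in resolved.resolution_log)


def test_rule_r2_prefers_more_heterogeneous(m_panel):
    # position 1 resolves to 100; position 2 ties between 100 and 104. The
    # candidate combination (100,100) collapses to a single variant while
    # (100,104) keeps two; with both combinations observed equally often
    # (R1 tie), R2 picks the more heterogeneous one.
    members = profs(
        m_panel,
        [100, 104], [100, 104], [98, 100], [98, 100],
        [100], [100], [100, 106],
    )
    rep = majority_fingerprint(members, m_panel)
    assert rep.alleles["M"] == (100, None)
    assert rep.check_candidates[("M", 1)] == (100, 104)
    resolved = resolve_ties(rep, members, m_panel)
    assert resolved.alleles["M"] == (100, 104)
    assert any(e["rule"] == "R2" for e in resolved.resolution_log)


def test_rule_r3_prefers_whole_repeat_spacing(m_panel):
    # perfect 2-bp repeat: difference to 100 must be even -> 104 wins over 103
    members = profs(m_panel, [100, 103], [100, 104])
    rep = majority_fingerprint(members, m_panel)
    assert ("M", 1) in rep.check_flags
    resolved = resolve_ties(rep, members, m_panel)
    assert resolved.alleles["M"] == (100, 104)
    assert any(e["rule"] == "R3" for e in resolved.resolution_log)


def test_unresolvable_tie_stays_check():
    panel = MarkerPanel((Marker("M", repeat_unit=None),))  # no repeat known
    members = [
        make_profile("a", {"M": [100, 103]}, panel),
        make_profile("b", {"M": [100, 104]}, panel),
    ]
    rep = resolve_ties(majority_fingerprint(members, panel), members, panel)
    assert rep.alleles["M"] == (100, None)
    assert rep.check_candidates[("M", 1)] == (103, 104)
    assert any(e["status"] == "unresolved" for e in rep.resolution_log)


def test_knife_edge_duplicate_goes_to_review_not_silent_flip(m_panel):
    """Duplicating a minority member at a one-vote margin cannot silently
    flip a strict-majority value: the position either keeps its value or is
    sent back to review as a tie."""
    members = profs(m_panel, [100, 104], [100, 104], [100, 106])
    base = majority_fingerprint(members, m_panel)
    assert base.alleles["M"] == (100, 104)  # carried 2-1
    dup = members + profs(m_panel, [100, 106])  # now 2-2
    again = majority_fingerprint(dup, m_panel)
    assert again.alleles["M"][0] == 100
    # position 2 is a tie for review, never a silent switch to 106
    assert again.alleles["M"][1] in (104, None)
    assert again.check_candidates.get(("M", 1)) == (104, 106)


def test_duplication_stability(m_panel):
    members = profs(m_panel, [100, 104], [100, 104], [100, 106])
    base = resolve_ties(majority_fingerprint(members, m_panel), members, m_panel)
    dup = members + [members[0]]
    again = resolve_ties(majority_fingerprint(dup, m_panel), dup, m_panel)
    assert again.alleles == base.alleles


@given(st.permutations(range(5)))
def test_member_order_invariance(order):
    panel = MarkerPanel((Marker("M", repeat_unit=2),))
    allele_lists = [[100, 104], [100, 104], [100, 106], [102, 104], [100, 104]]
    members = [
        make_profile(f"s{i}", {"M": allele_lists[i]}, panel) for i in range(5)
    ]
    base = majority_fingerprint(members, panel)
    shuffled = [members[i] for i in order]
    rep = majority_fingerprint(shuffled, panel)
    assert rep.alleles == base.alleles
    assert rep.check_candidates == base.check_candidates


# --- trueness propagation -------------------------------------------------

@pytest.mark.parametrize(
    "codes, expected",
    [({4, 1, 5}, 1), ({2, 5}, 5), ({0}, 0), ({3, 4, 0}, 3), ({0, 4}, 4)],
)
def test_propagate_trueness_examples(codes, expected):
    got = propagate_trueness([TruenessCode(c) for c in codes])
    assert got == TruenessCode(expected)


def test_propagate_trueness_exhaustive_up_to_size_4():
    """Every multiset over {0..5} up to size 4 yields the minimum under the
    desirability order 1 > 5 > 2 > 3 > 4 > 0 (enumeration oracle)."""
    order = (1, 5, 2, 3, 4, 0)
    for size in range(1, 5):
        for combo in itertools.combinations_with_replacement(range(6), size):
            want = min(combo, key=order.index)
            got = propagate_trueness([TruenessCode(c) for c in combo])
            assert got.code == want


def test_propagate_trueness_idempotent_and_foldable():
    codes = [TruenessCode(c) for c in (3, 5, 4)]
    once = propagate_trueness(codes)
    assert propagate_trueness([once]) == once
    folded = codes[0]
    for c in codes[1:]:
        folded = propagate_trueness([folded, c])
    assert folded == once


def test_propagate_trueness_empty_rejected():
    with pytest.raises(ValueError):
        propagate_trueness([])


def test_build_representative_metadata(m_panel):
    members = [
        make_profile("a", {"M": [100, 104]}, m_panel,
                     cultivar_name_given="Williams", trueness_code=TruenessCode(4)),
        make_profile("b", {"M": [100, 104]}, m_panel,
                     cultivar_name_given="Williams", trueness_code=TruenessCode(1)),
        make_profile("c", {"M": [100, 104]}, m_panel,
                     cultivar_name_given="Conference"),
    ]
    group = MolecularGroup("Pyr_0001", ("a", "b", "c"), sports=("Red Williams",))
    rep = build_representative(group, {p.sample_id: p for p in members}, m_panel)
    assert rep.cultivar_name == "Williams"  # majority of recorded names
    assert rep.trueness_code == TruenessCode(1)  # best code wins
    assert rep.sports == ("Red Williams",)
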