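"""Binary encoding, retraceability, variant frequencies, accounting."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import make_profile
from ssrcurate.consensus import RepresentativeGenotype, build_representative
from ssrcurate.distance import (
    MolecularGroup,
    name_groups,
    pairwise_distances,
    threshold_cluster,
)
from ssrcurate.model import Marker, MarkerPanel
from ssrcurate.qc import (
    binarize,
    binary_dice_similarity,
    collection_summary,
    retrace_representatives,
    retraceable_fraction,
    variant_frequencies,
)
from ssrcurate.reference import build_collection_records
from ssrcurate.simulate import SimConfig, simulate_collection


@pytest.fixture
def m1_panel():
    return MarkerPanel((Marker("M1", 2),))


def test_binarize_enumeration(m1_panel):
    a = make_profile("a", {"M1": [100, 104]}, m1_panel)
    b = make_profile("b", {"M1": [100, 106]}, m1_panel)
    enc = binarize([a, b], m1_panel)
    assert enc.variant_index == [("M1", 100), ("M1", 104), ("M1", 106)]
    assert enc.vector("a").tolist() == [1, 1, 0]
    assert enc.vector("b").tolist() == [1, 0, 1]


def test_binarize_identical_profiles_and_missing(mini_panel):
    a = make_profile("a", {"M1": [100, 104], "M2": [150]}, mini_panel)
    b = make_profile("b", {"M1": [100, 104], "M2": [150]}, mini_panel)
    c = make_profile("c", {"M1": [100, 104]}, mini_panel)  # M2 missing
    enc = binarize([a, b, c], mini_panel)
    assert np.array_equal(enc.vector("a"), enc.vector("b"))
    assert enc.vector("c").tolist() == [1, 1, 0]  # zeros at the M2 variant


def test_binary_dice_similarity_cases():
    u = np.array([1, 1, 0, 0], dtype=np.uint8)
    v = np.array([1, 0, 1, 0], dtype=np.uint8)
    assert binary_dice_similarity(u, u) == 1.0
    assert binary_dice_similarity(u, 1 - u) == 0.0
    assert binary_dice_similarity(u, v) == 0.5  # 2*1/(2+2)
    zero = np.zeros(4, dtype=np.uint8)
    assert binary_dice_similarity(zero, zero) == 1.0
    assert binary_dice_similarity(u, v) == binary_dice_similarity(v, u)
    with pytest.raises(ValueError, match="length"):
        binary_dice_similarity(u, np.zeros(5))


def _run_groups(profiles, panel, cutoff=0.2):
    matrix = pairwise_distances(profiles, panel, 1)
    groups = name_groups(threshold_cluster(matrix, cutoff))
    by_id = {p.sample_id: p for p in profiles}
    reps = [build_representative(g, by_id, panel) for g in groups]
    return groups, reps, by_id


def test_retrace_member_match_and_synthetic(m1_panel):
    members = [
        make_profile("a", {"M1": [100, 104]}, m1_panel),
        make_profile("b", {"M1": [100, 104]}, m1_panel),
    ]
    group = MolecularGroup("Pyr_0001", ("a", "b"))
    rep = build_representative(group, {p.sample_id: p for p in members}, m1_panel)
    report = retrace_representatives([rep], members, [group], m1_panel)
    assert bool(report.loc[0, "retraceable"]) is True
    assert report.loc[0, "best_similarity"] == 1.0

    # a representative differing from every member at one variant is synthetic
    synthetic = RepresentativeGenotype(
        group_id="Pyr_0001", alleles={"M1": (100, 106)}
    )
    report2 = retrace_representatives([synthetic], members, [group], m1_panel)
    assert bool(report2.loc[0, "retraceable"]) is False
    assert report2.loc[0, "best_similarity"] < 1.0


def test_retrace_unresolved_rep_is_unverifiable(m1_panel):
    members = [make_profile("a", {"M1": [100, 104]}, m1_panel)]
    group = MolecularGroup("Pyr_0001", ("a",))
    rep = RepresentativeGenotype(
        group_id="Pyr_0001",
        alleles={"M1": (100, None)},
        check_candidates={("M1", 1): (104, 106)},
    )
    report = retrace_representatives([rep], members, [group], m1_panel)
    assert bool(report.loc[0, "unverifiable"]) is True
    assert np.isnan(retraceable_fraction(report))


def test_single_member_groups_always_retraceable():
    profiles, truth = simulate_collection(
        SimConfig(n_cultivars=8, trees_per_cultivar=(1, 1),
                  replicates_per_tree=(1, 1), miscall_rate=0.1, seed=13)
    )
    groups, reps, _ = _run_groups(profiles, truth.panel)
    report = retrace_representatives(reps, profiles, groups, truth.panel)
    assert report["retraceable"].astype(bool).all()
    assert retraceable_fraction(report) == 1.0


def test_retrace_agrees_with_allele_set_equality_oracle():
    """Retraceable iff some member has identical allele sets at every marker
    (tolerance-0 equality, computed independently of the binary encoding)."""
    profiles, truth = simulate_collection(
        SimConfig(n_cultivars=12, trees_per_cultivar=(2, 4),
                  miscall_rate=0.08, missing_rate=0.08, seed=23)
    )
    groups, reps, by_id = _run_groups(profiles, truth.panel)
    report = retrace_representatives(reps, profiles, groups, truth.panel)
    flags = dict(zip(report["group_id"], report["retraceable"]))
    for g, rep in zip(groups, reps):
        if not rep.is_fully_resolved:
            continue
        want = any(
            all(
                rep.allele_set(m).alleles == by_id[s].alleles_at(m)
                for m in truth.panel.names
            )
            for s in g.member_sample_ids
        )
        assert bool(flags[g.group_id]) == want


def test_variant_frequencies(m1_panel):
    members = [
        make_profile(s, {"M1": a}, m1_panel)
        for s, a in [
            ("a", [100, 104]), ("b", [100, 104]),
            ("c", [100, 104]), ("d", [100, 106]),
        ]
    ]
    group = MolecularGroup("Pyr_0001", tuple(p.sample_id for p in members))
    rep = build_representative(group, {p.sample_id: p for p in members}, m1_panel)
    fr = variant_frequencies(rep, members)
    assert fr.frequencies[("M1", 0)] == 1.0
    assert fr.frequencies[("M1", 1)] == 0.75  # 3 of 4 members carry 104
    assert fr.average_score == pytest.approx(
        np.mean(list(fr.frequencies.values()))
    )


def test_variant_frequencies_unanimous_group(mini_panel):
    members = [
        make_profile(f"s{i}", {"M1": [100, 104], "M2": [150]}, mini_panel)
        for i in range(3)
    ]
    group = MolecularGroup("Pyr_0001", tuple(p.sample_id for p in members))
    rep = build_representative(group, {p.sample_id: p for p in members},
                               mini_panel)
    fr = variant_frequencies(rep, members)
    assert set(fr.frequencies.values()) == {1.0}
    assert fr.average_score == 1.0


def test_majority_positions_exceed_half_among_voters():
    """A strict-majority position wins more than half of the count-conforming
    voters' ballots on simulated groups."""
    profiles, truth = simulate_collection(
        SimConfig(n_cultivars=10, trees_per_cultivar=(4, 6),
                  miscall_rate=0.1, seed=31)
    )
    groups, reps, by_id = _run_groups(profiles, truth.panel)
    from collections import Counter

    for g, rep in zip(groups, reps):
        members = [by_id[s] for s in g.member_sample_ids]
        for marker, values in rep.alleles.items():
            n_pos = len(values)
            voters = [
                m.alleles_at(marker)
                for m in members
                if len(m.alleles_at(marker)) == n_pos
            ]
            for pos, afl in enumerate(values):
                if afl is None:
                    continue
                votes = Counter(v[pos] for v in voters)
                # only strict-majority winners are covered (plurality wins
                # and rule-resolved ties may sit at or below half)
                if votes[afl] * 2 <= sum(votes.values()):
                    continue
                carrying = sum(1 for v in voters if afl in v)
                assert carrying * 2 > len(voters)


def test_collection_summary_empty_and_conservation():
    empty = collection_summary(pd.DataFrame())
    assert empty.loc["Total"].sum() == 0

    records = build_collection_records()
    summary = collection_summary(records)
    per_location = summary.drop(index="Total")
    assert (summary.loc["Total"] == per_location.sum(axis=0)).all()


def test_collection_summary_from_profiles():
    profiles, truth = simulate_collection(SimConfig(n_cultivars=6, seed=3))
    summary = collection_summary(profiles)
    assert summary.loc["Total", "samples"] == len(profiles)
    assert summary.loc["Total", "molecular"] == len(profiles)
    assert summary.loc["Total", "trees"] == len(
        {p.tree_id for p in profiles if p.tree_id}
    )
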