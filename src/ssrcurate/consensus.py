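"""Representative ("synthetic") fingerprints per molecular group.

One consensus genotype is compiled per molecular group by per-position
majority rule: per marker, members with failed amplification are dropped, the
modal allele count among the remaining members fixes the number of positions,
and per position (alleles sorted ascending) the most frequent AFL is taken.
A tie yields the literal flag ``CHECK`` instead of a value; flagged positions
are then resolved by ordered curation rules (prefer a combination observed
verbatim in a member; prefer the more heterogeneous combination; prefer
allele spacings that are whole repeat units), every resolution being logged
for human review.  The group's trueness-to-type code is the most desirable
member code under the GFG order 1 > 5 > 2 > 3 > 4 > 0.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from .distance import MolecularGroup
from .model import AlleleSet, MarkerPanel, SSRProfile, TruenessCode

CHECK = "CHECK"


@dataclass
class RepresentativeGenotype:
    """Per-group consensus fingerprint.

    ``alleles`` maps marker name -> positional values (ascending vote slots);
    ``None`` marks a position still flagged CHECK, whose tied candidates are
    kept in ``check_candidates``.  A marker amplified in no member is absent
    from ``alleles`` entirely.
    """

    group_id: str
    alleles: dict[str, tuple[Optional[int], ...]]
    cultivar_name: str = ""
    check_candidates: dict[tuple[str, int], tuple[int, ...]] = field(
        default_factory=dict
    )
    trueness_code: Optional[TruenessCode] = None
    retraceable: Optional[bool] = None
    ploidy: Optional[int] = None
    punq: Optional[str] = None
    sports: tuple[str, ...] = ()
    resolution_log: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def check_flags(self) -> set[tuple[str, int]]:
        return {
            (marker, i)
            for marker, values in self.alleles.items()
            for i, v in enumerate(values)
            if v is None
        }

    @property
    def is_fully_resolved(self) -> bool:
        return not self.check_flags

    def allele_set(self, marker: str) -> AlleleSet:
        """Distinct resolved variants at a marker (unresolved positions
        excluded)."""
        values = self.alleles.get(marker, ())
        return AlleleSet.from_calls(marker, [v for v in values if v is not None])

    def variant_sets(self) -> dict[str, tuple[int, ...]]:
        """Marker -> distinct resolved AFLs, for binary encoding/QC."""
        return {m: self.allele_set(m).alleles for m in self.alleles}


def majority_fingerprint(
    members: Sequence[SSRProfile],
    panel: MarkerPanel,
    group_id: str = "",
) -> RepresentativeGenotype:
    """Per-position majority consensus over the group members.

    Per marker: members missing the marker are removed; the modal allele
    count among the remaining members fixes the position count (ties prefer
    the larger count, keeping triploid signal); only members with that count
    vote; per sorted position the most frequent AFL wins, a tie becoming a
    CHECK flag with its candidate values recorded.
    """
    if not members:
        raise ValueError("empty member list")
    for m in members:
        m.validate_against(panel)
    rep = RepresentativeGenotype(group_id=group_id, alleles={})
    for name in panel.names:
        amplified = [m.alleles_at(name) for m in members if m.alleles_at(name)]
        if not amplified:
            rep.warnings.append(f"{name}: amplified in no member; left missing")
            continue
        count_votes = Counter(len(a) for a in amplified)
        top = max(count_votes.values())
        n_positions = max(c for c, v in count_votes.items() if v == top)
        voters = [a for a in amplified if len(a) == n_positions]
        values: list[Optional[int]] = []
        for pos in range(n_positions):
            votes = Counter(a[pos] for a in voters)
            best = max(votes.values())
            winners = sorted(afl for afl, v in votes.items() if v == best)
            if len(winners) == 1:
                values.append(winners[0])
            else:
                values.append(None)
                rep.check_candidates[(name, pos)] = tuple(winners)
        rep.alleles[name] = tuple(values)
    return rep


def _rule_filter(
    combos: list[tuple[int, ...]],
    member_variant_sets: list[tuple[int, ...]],
    resolved: tuple[int, ...],
    repeat_unit: Optional[int],
) -> tuple[list[tuple[int, ...]], str]:
    """Apply the ordered tie rules, returning survivors and the last rule
    that narrowed the field.

    A 'combo' is one assignment of candidates to the flagged positions; the
    marker's candidate variant set is the distinct union of resolved values
    and the combo.
    """

    def variant_set(combo: tuple[int, ...]) -> tuple[int, ...]:
        return tuple(sorted(set(resolved + combo)))

    survivors = combos
    rule = "R4"
    # R1: combination observed verbatim in a member; most frequent wins.
    counts = [
        sum(1 for mv in member_variant_sets if mv == variant_set(c))
        for c in survivors
    ]
    if max(counts) > 0:
        best = max(counts)
        kept = [c for c, k in zip(survivors, counts) if k == best]
        if len(kept) < len(survivors):
            rule = "R1"
        survivors = kept
        if len(survivors) == 1:
            return survivors, "R1"
    # R2: more heterogeneous (more distinct alleles at the marker).
    widths = [len(variant_set(c)) for c in survivors]
    best_w = max(widths)
    kept = [c for c, w in zip(survivors, widths) if w == best_w]
    if len(kept) < len(survivors):
        rule = "R2"
    survivors = kept
    if len(survivors) == 1:
        return survivors, "R2"
    # R3: allele spacings that are whole repeat units.
    if repeat_unit:
        def conforms(c: tuple[int, ...]) -> bool:
            vs = variant_set(c)
            return all(
                (b - a) % repeat_unit == 0
                for a, b in itertools.combinations(vs, 2)
            )

        kept = [c for c in survivors if conforms(c)]
        if kept and len(kept) < len(survivors):
            rule = "R3"
            survivors = kept
        if len(survivors) == 1:
            return survivors, "R3"
    return survivors, rule


def resolve_ties(
    rep: RepresentativeGenotype,
    members: Sequence[SSRProfile],
    panel: MarkerPanel,
) -> RepresentativeGenotype:
    """Resolve CHECK flags by the ordered curation rules, logging every
    decision; unresolvable ties legally remain CHECK for human review."""
    out = replace(
        rep,
        alleles=dict(rep.alleles),
        check_candidates=dict(rep.check_candidates),
        resolution_log=list(rep.resolution_log),
        warnings=list(rep.warnings),
    )
    flagged_markers = sorted({m for (m, _) in out.check_candidates})
    for name in flagged_markers:
        values = list(out.alleles[name])
        positions = [i for i, v in enumerate(values) if v is None]
        candidates = [out.check_candidates[(name, i)] for i in positions]
        resolved = tuple(v for v in values if v is not None)
        member_variant_sets = [
            m.alleles_at(name) for m in members if m.alleles_at(name)
        ]
        combos = list(itertools.product(*candidates))
        marker = panel.get(name)
        survivors, rule = _rule_filter(
            combos, member_variant_sets, resolved, marker.repeat_unit
        )
        if len(survivors) == 1:
            combo = survivors[0]
            for i, pos in enumerate(positions):
                values[pos] = combo[i]
                del out.check_candidates[(name, pos)]
                out.resolution_log.append(
                    {
                        "group_id": out.group_id,
                        "marker": name,
                        "position": pos + 1,
                        "candidates": "/".join(
                            str(c) for c in candidates[i]
                        ),
                        "chosen": combo[i],
                        "rule": rule,
                        "status": "resolved",
                    }
                )
            out.alleles[name] = tuple(values)
        else:
            for i, pos in enumerate(positions):
                remaining = sorted({c[i] for c in survivors})
                out.check_candidates[(name, pos)] = tuple(remaining)
                out.resolution_log.append(
                    {
                        "group_id": out.group_id,
                        "marker": name,
                        "position": pos + 1,
                        "candidates": "/".join(str(c) for c in remaining),
                        "chosen": CHECK,
                        "rule": rule,
                        "status": "unresolved",
                    }
                )
    return out


def propagate_trueness(member_codes: Sequence[TruenessCode]) -> TruenessCode:
    """Most desirable code present, under the GFG order 1 > 5 > 2 > 3 > 4 > 0.

    At least one true-to-type member makes the whole cultivar true-to-type.
    """
    if not member_codes:
        raise ValueError("no trueness codes to propagate")
    return min(member_codes, key=lambda c: c.rank)


def build_representative(
    group: MolecularGroup,
    profiles_by_id: Mapping[str, SSRProfile],
    panel: MarkerPanel,
    resolve: bool = True,
    ploidy: Optional[int] = None,
    punq: Optional[str] = None,
) -> RepresentativeGenotype:
    """Full consensus for one molecular group: majority vote, tie resolution,
    trueness propagation and cultivar-name resolution (most common recorded
    name among members, ties to the lexicographically smallest)."""
    members = [profiles_by_id[sid] for sid in group.member_sample_ids]
    rep = majority_fingerprint(members, panel, group_id=group.group_id)
    if resolve:
        rep = resolve_ties(rep, members, panel)
    codes = [m.trueness_code for m in members if m.trueness_code is not None]
    rep.trueness_code = propagate_trueness(codes) if codes else None
    if group.cultivar_name:
        rep.cultivar_name = group.cultivar_name
    else:
        names = Counter(
            m.cultivar_name_given for m in members if m.cultivar_name_given
        )
        if names:
            best = max(names.values())
            rep.cultivar_name = min(n for n, k in names.items() if k == best)
    rep.sports = group.sports
    rep.ploidy = ploidy
    rep.punq = punq
    return rep
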