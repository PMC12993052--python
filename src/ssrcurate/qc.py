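"""Quality checks on the compiled dataset.

Three checks mirror the curation workflow: (1) retraceability — each
representative genotype is binarized over the observed (marker, AFL) variants
and compared to its member samples by binary Dice similarity; a group with no
100 % match is flagged synthetic; (2) per-position frequencies of the
representative AFL among amplified members, with the group average, to expose
variable markers; (3) collection accounting per location (samples, distinct
trees, distinct accessions, molecular and pomological coverage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .consensus import RepresentativeGenotype
from .distance import MolecularGroup
from .model import MarkerPanel, SSRProfile


@dataclass
class BinaryEncoding:
    """0/1 vectors over the ordered (marker, AFL) variant index."""

    variant_index: list[tuple[str, int]]
    vectors: dict[str, np.ndarray]

    def vector(self, key: str) -> np.ndarray:
        return self.vectors[key]


def _encode(
    items: Mapping[str, Mapping[str, tuple[int, ...]]],
    panel: MarkerPanel,
) -> BinaryEncoding:
    """Binarize keyed variant-set mappings over their joint variant index."""
    variants: set[tuple[str, int]] = set()
    for sets in items.values():
        for marker, alleles in sets.items():
            for a in alleles:
                variants.add((marker, a))
    order = {name: i for i, name in enumerate(panel.names)}
    index = sorted(variants, key=lambda v: (order[v[0]], v[1]))
    pos = {v: i for i, v in enumerate(index)}
    vectors = {}
    for key, sets in items.items():
        vec = np.zeros(len(index), dtype=np.uint8)
        for marker, alleles in sets.items():
            for a in alleles:
                vec[pos[(marker, a)]] = 1
        vectors[key] = vec
    return BinaryEncoding(variant_index=index, vectors=vectors)


def binarize(profiles: Sequence[SSRProfile], panel: MarkerPanel) -> BinaryEncoding:
    """Convert profiles to binary presence vectors over every (marker, AFL)
    variant observed anywhere in the dataset; a missing marker contributes
    all-zeros for its variants."""
    if not profiles:
        raise ValueError("no profiles to binarize")
    items = {
        p.sample_id: {m: p.alleles_at(m) for m in panel.names} for p in profiles
    }
    return _encode(items, panel)


def binary_dice_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Dice-Sørensen similarity 2|u∧v| / (|u|+|v|) on 0/1 vectors.

    Defined as 1.0 when both vectors are all-zero (degenerate but total).
    """
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError("vector length mismatch")
    nu = int(u.sum())
    nv = int(v.sum())
    if nu + nv == 0:
        return 1.0
    both = int(np.logical_and(u, v).sum())
    return 2.0 * both / (nu + nv)


def retrace_representatives(
    reps: Sequence[RepresentativeGenotype],
    profiles: Sequence[SSRProfile],
    groups: Sequence[MolecularGroup],
    panel: MarkerPanel,
) -> pd.DataFrame:
    """Per group: is the representative retraceable to a measured member?

    A group is retraceable iff some member sample reaches binary Dice
    similarity exactly 1.0 with the representative; otherwise the
    representative is a truly synthetic fingerprint.  Representatives with
    unresolved CHECK positions are reported unverifiable (retraceable NA).
    Comparison is within the representative's own group.
    """
    by_id = {p.sample_id: p for p in profiles}
    groups_by_id = {g.group_id: g for g in groups}
    rows = []
    for rep in reps:
        group = groups_by_id[rep.group_id]
        members = [by_id[sid] for sid in group.member_sample_ids]
        if not members:
            raise ValueError(f"group {rep.group_id}: zero members")
        if not rep.is_fully_resolved:
            rows.append(
                {
                    "group_id": rep.group_id,
                    "retraceable": pd.NA,
                    "best_similarity": np.nan,
                    "best_sample": "",
                    "unverifiable": True,
                }
            )
            continue
        items: dict[str, dict[str, tuple[int, ...]]] = {
            p.sample_id: {m: p.alleles_at(m) for m in panel.names}
            for p in members
        }
        rep_sets = rep.variant_sets()
        items["__rep__"] = {m: rep_sets.get(m, ()) for m in panel.names}
        enc = _encode(items, panel)
        rep_vec = enc.vector("__rep__")
        best_sim = -1.0
        best_sample = ""
        exact = False
        for p in members:
            vec = enc.vector(p.sample_id)
            # exact retrace means identical variant support, which is robust
            # to float comparison
            if np.array_equal(vec, rep_vec):
                exact = True
            sim = binary_dice_similarity(vec, rep_vec)
            if sim > best_sim or (sim == best_sim and p.sample_id < best_sample):
                best_sim = sim
                best_sample = p.sample_id
        rows.append(
            {
                "group_id": rep.group_id,
                "retraceable": exact,
                "best_similarity": best_sim,
                "best_sample": best_sample,
                "unverifiable": False,
            }
        )
    return pd.DataFrame(rows)


def retraceable_fraction(retrace_report: pd.DataFrame) -> float:
    """Fraction of verifiable groups whose representative matches a member."""
    verifiable = retrace_report[~retrace_report["unverifiable"]]
    if len(verifiable) == 0:
        return float("nan")
    return float(verifiable["retraceable"].astype(bool).mean())


@dataclass
class FrequencyReport:
    """Per-position frequency of the representative AFL among amplified
    members, plus the group average."""

    group_id: str
    frequencies: dict[tuple[str, int], float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def average_score(self) -> float:
        if not self.frequencies:
            return float("nan")
        return float(np.mean(list(self.frequencies.values())))


def variant_frequencies(
    rep: RepresentativeGenotype,
    members: Sequence[SSRProfile],
) -> FrequencyReport:
    """Frequency of each resolved representative AFL across the group.

    Per position: members carrying the representative AFL at that marker
    (exact, tolerance 0) over members amplified at that marker.  Unresolved
    CHECK positions are skipped; markers amplified in no member are omitted
    with a warning.
    """
    report = FrequencyReport(group_id=rep.group_id)
    for marker, values in rep.alleles.items():
        amplified = [m for m in members if m.alleles_at(marker)]
        if not amplified:
            report.warnings.append(f"{marker}: amplified in no member")
            continue
        for pos, afl in enumerate(values):
            if afl is None:
                continue
            carrying = sum(1 for m in amplified if afl in m.alleles_at(marker))
            report.frequencies[(marker, pos)] = carrying / len(amplified)
    return report


RECORD_COLUMNS = [
    "sample_id",
    "location",
    "tree_id",
    "accession_id",
    "has_molecular",
    "has_pomological",
    "is_final",
]


def profiles_to_records(profiles: Sequence[SSRProfile]) -> pd.DataFrame:
    """Adapt genotyped profiles onto the sample-record table used by
    collection_summary.

    Genotyped profiles all carry molecular data; a pomological assessment is
    inferred from the trueness code (code 4 = "not assessed" pomologically).
    """
    rows = []
    for p in profiles:
        has_pom = p.trueness_code is not None and p.trueness_code.code != 4
        rows.append(
            {
                "sample_id": p.sample_id,
                "location": p.location,
                "tree_id": p.tree_id,
                "accession_id": p.accession_id,
                "has_molecular": True,
                "has_pomological": has_pom,
                "is_final": True,
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def collection_summary(
    data: Union[pd.DataFrame, Sequence[SSRProfile]],
) -> pd.DataFrame:
    """Per-location and total accounting of the collection.

    Accepts either a sample-record table (columns ``RECORD_COLUMNS``) or a
    list of profiles.  Counts per location: final samples, distinct non-empty
    tree ids among final samples, distinct non-empty accession ids among
    final samples, samples with molecular data, samples with pomological
    data.  The total row is the column sum of the per-location rows.
    """
    if not isinstance(data, pd.DataFrame):
        data = profiles_to_records(list(data))
    columns = ["samples", "trees", "accessions", "molecular", "pomological"]
    if data.empty:
        return pd.DataFrame(
            [[0] * len(columns)], index=pd.Index(["Total"], name="location"),
            columns=columns,
        )
    missing = [c for c in RECORD_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"sample-record table lacks columns: {missing}")
    rows = {}
    for loc, sub in data.groupby("location", sort=True):
        final = sub[sub["is_final"].astype(bool)]
        rows[loc] = [
            int(final.shape[0]),
            int(final.loc[final["tree_id"] != "", "tree_id"].nunique()),
            int(final.loc[final["accession_id"] != "", "accession_id"].nunique()),
            int(sub["has_molecular"].astype(bool).sum()),
            int(sub["has_pomological"].astype(bool).sum()),
        ]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    out.index.name = "location"
    out.loc["Total"] = out.sum(axis=0)
    return out
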