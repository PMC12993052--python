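"""Tolerance-aware Dice-Sørensen distances and threshold clustering.

The pairwise distance between two samples is

    d = 1 - 2 * (number of common alleles) / (n_alleles_1 + n_alleles_2)

summed over the markers amplified in *both* samples.  "Common" alleles are
counted by a maximum-cardinality matching in which allele x of one sample may
pair with allele y of the other iff |x - y| <= tolerance (1 bp by default,
absorbing routine fragment-sizing wobble), each allele pairing at most once.
Samples within the distance cut-off (0.2 by default, i.e. >= 80 % identity)
are grouped into molecular groups, each presumed to be one cultivar together
with its sports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .model import AlleleSet, MarkerPanel, SSRProfile

DEFAULT_TOLERANCE_BP = 1
DEFAULT_CUTOFF = 0.2
DEFAULT_PREFIX = "Pyr_"


def count_common_alleles(a: AlleleSet, b: AlleleSet, tolerance_bp: int = 0) -> int:
    """Size of a maximum matching between the two allele lists where alleles
    may pair iff they differ by at most ``tolerance_bp``.

    Both lists are sorted, so the greedy two-pointer sweep (match the two
    current heads when within tolerance, else advance the smaller) attains
    the maximum matching; an exchange argument shows no larger matching
    exists for interval-compatibility on a line.
    """
    if a.marker != b.marker:
        raise ValueError(f"marker mismatch: {a.marker!r} vs {b.marker!r}")
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    i = j = matched = 0
    xs, ys = a.alleles, b.alleles
    while i < len(xs) and j < len(ys):
        if abs(xs[i] - ys[j]) <= tolerance_bp:
            matched += 1
            i += 1
            j += 1
        elif xs[i] < ys[j]:
            i += 1
        else:
            j += 1
    return matched


def dice_distance(
    p: SSRProfile,
    q: SSRProfile,
    panel: MarkerPanel,
    tolerance_bp: int = DEFAULT_TOLERANCE_BP,
) -> float:
    """Dice-Sørensen distance over the markers amplified in both profiles.

    Returns ``nan`` when the profiles share no amplified marker (the pair is
    not comparable); callers must treat that as "no evidence", not identity.
    Markers missing in either profile are excluded from numerator and
    denominator so amplification failure does not inflate the distance
    between true replicates.
    """
    common = 0
    total = 0
    for name in panel.names:
        xa = p.allele_sets.get(name)
        xb = q.allele_sets.get(name)
        if xa is None or xb is None or xa.is_missing or xb.is_missing:
            continue
        common += count_common_alleles(xa, xb, tolerance_bp)
        total += len(xa) + len(xb)
    if total == 0:
        return math.nan
    d = 1.0 - (2.0 * common) / total
    # guard floating error at the boundaries
    return min(1.0, max(0.0, d))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix; nan marks incomparable pairs."""

    sample_ids: list[str]
    values: np.ndarray
    tolerance_bp: int
    missing_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match sample_ids")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.sample_ids
        )


def pairwise_distances(
    profiles: Sequence[SSRProfile],
    panel: MarkerPanel,
    tolerance_bp: int = DEFAULT_TOLERANCE_BP,
) -> DistanceMatrix:
    """Full symmetric distance matrix over the profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    n = len(profiles)
    values = np.zeros((n, n), dtype=float)
    missing: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            d = dice_distance(profiles[i], profiles[j], panel, tolerance_bp)
            values[i, j] = values[j, i] = d
            if math.isnan(d):
                missing.append((profiles[i].sample_id, profiles[j].sample_id))
    return DistanceMatrix(
        sample_ids=[p.sample_id for p in profiles],
        values=values,
        tolerance_bp=tolerance_bp,
        missing_pairs=missing,
    )


def threshold_cluster(
    matrix: DistanceMatrix,
    cutoff: float = DEFAULT_CUTOFF,
    linkage_method: str = "single",
) -> list[set[str]]:
    """Flat clusters of samples at the distance cut-off (inclusive).

    ``single`` (default): connected components of the graph joining pairs
    with distance <= cutoff — the minimal "grouped together" reading; note
    single linkage can chain.  ``complete``: scipy complete-linkage flat
    clusters, for users worried about chaining; incomparable (nan) pairs are
    treated as distance 1.0 in that mode.  Pairs that are incomparable never
    contribute an edge in single-linkage mode.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    vals = matrix.values
    n = matrix.n
    if linkage_method == "single":
        with np.errstate(invalid="ignore"):
            adj = (vals <= cutoff) & ~np.isnan(vals)
        np.fill_diagonal(adj, True)
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    elif linkage_method == "complete":
        filled = np.where(np.isnan(vals), 1.0, vals)
        np.fill_diagonal(filled, 0.0)
        z = linkage(squareform(filled, checks=False), method="complete")
        labels = fcluster(z, t=cutoff, criterion="distance")
        n_comp = labels.max()
    else:
        raise ValueError(f"unknown linkage method: {linkage_method!r}")
    components: dict[int, set[str]] = {}
    for sid, lab in zip(matrix.sample_ids, labels):
        components.setdefault(int(lab), set()).add(sid)
    return list(components.values())


@dataclass(frozen=True)
class MolecularGroup:
    """A named cluster of samples presumed to be one cultivar (plus sports)."""

    group_id: str
    member_sample_ids: tuple[str, ...]
    cultivar_name: str = ""
    sports: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.member_sample_ids:
            raise ValueError(f"group {self.group_id}: no members")
        object.__setattr__(
            self, "member_sample_ids", tuple(sorted(self.member_sample_ids))
        )

    @property
    def size(self) -> int:
        return len(self.member_sample_ids)


def name_groups(
    components: Sequence[set[str]], prefix: str = DEFAULT_PREFIX
) -> list[MolecularGroup]:
    """Assign running group ids like ``Pyr_0001``.

    Ordering is deterministic: descending size, ties broken by the
    lexicographically smallest member id. Numbers are zero-padded to four
    digits, widening if there are more than 9999 groups.
    """
    for comp in components:
        if not comp:
            raise ValueError("empty component")
    all_ids = [sid for comp in components for sid in comp]
    if len(all_ids) != len(set(all_ids)):
        raise ValueError("components do not form a partition")
    ordered = sorted(components, key=lambda c: (-len(c), min(c)))
    width = max(4, len(str(len(ordered))))
    return [
        MolecularGroup(group_id=f"{prefix}{i:0{width}d}", member_sample_ids=tuple(comp))
        for i, comp in enumerate(ordered, start=1)
    ]
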