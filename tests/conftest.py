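"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import permutations
from typing import Mapping, Sequence

import pytest
from hypothesis import HealthCheck, settings

from ssrcurate.model import AlleleSet, Marker, MarkerPanel, SSRProfile

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def mini_panel() -> MarkerPanel:
    """Three dinucleotide markers, one with an allele grid."""
    return MarkerPanel(
        (
            Marker("M1", repeat_unit=2, grid=(100, 104, 108)),
            Marker("M2", repeat_unit=2),
            Marker("M3", repeat_unit=3),
        )
    )


def make_profile(
    sample_id: str,
    alleles: Mapping[str, Sequence[int]],
    panel: MarkerPanel,
    **meta,
) -> SSRProfile:
    """Build a profile over the panel; unlisted markers become missing."""
    sets = {
        name: AlleleSet.from_calls(name, alleles.get(name, ()))
        for name in panel.names
    }
    return SSRProfile(sample_id=sample_id, allele_sets=sets, **meta)


def brute_force_common(
    a: Sequence[int], b: Sequence[int], tolerance: int
) -> int:
    """Maximum-cardinality matching by exhaustive enumeration of injective
    assignments — the independent oracle for count_common_alleles."""
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    if not small:
        return 0
    best = 0
    for assignment in permutations(range(len(large)), len(small)):
        matched = sum(
            1
            for i, j in enumerate(assignment)
            if abs(small[i] - large[j]) <= tolerance
        )
        best = max(best, matched)
    return best


def pair_confusion(
    true_labels: Sequence, pred_labels: Sequence
) -> tuple[int, int, int]:
    """(pairs together in both, pairs together in pred, pairs together in
    truth) by brute force over all sample pairs."""
    n = len(true_labels)
    both = pred = true = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_t = true_labels[i] == true_labels[j]
            same_p = pred_labels[i] == pred_labels[j]
            both += same_t and same_p
            pred += same_p
            true += same_t
    return both, pred, true
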