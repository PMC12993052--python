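"""Core data model for multi-allelic SSR (microsatellite) fingerprints.

A sample's genotype at one SSR marker is the set of amplified allele
fragment lengths (AFLs, integer base pairs after binning).  Pear cultivars
are diploid or triploid, so a marker usually carries one to three distinct
variants (up to four are tolerated for unusual profiles).  A marker with no
amplification product is recorded as an empty allele set (missing data).
Homozygous markers store their single variant once: the Dice-Sørensen sums
count distinct variants, matching the binary per-variant encoding used for
retraceability checks downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Optional, Sequence

MAX_ALLELES = 4

#: trueness-to-type codes used by the German Fruit Genebank (GFG) to grade
#: the certainty of a cultivar's identity from combined pomological and
#: molecular evidence.
TRUENESS_LABELS: dict[int, str] = {
    0: "deceased",
    1: "true-to-type",
    2: "true-to-type (group/mutant)",
    3: "not determined",
    4: "not assessed",
    5: "true-to-type with reservations",
}

#: total order of desirability, most desirable first: 1 > 5 > 2 > 3 > 4 > 0.
TRUENESS_DESIRABILITY: tuple[int, ...] = (1, 5, 2, 3, 4, 0)


@dataclass(frozen=True)
class TruenessCode:
    """One GFG trueness-to-type code (integer 0-5)."""

    code: int

    def __post_init__(self) -> None:
        if self.code not in TRUENESS_LABELS:
            raise ValueError(f"unknown trueness-to-type code: {self.code!r}")

    @property
    def label(self) -> str:
        return TRUENESS_LABELS[self.code]

    @property
    def rank(self) -> int:
        """Position in the desirability order (0 = most desirable)."""
        return TRUENESS_DESIRABILITY.index(self.code)


@dataclass(frozen=True)
class Marker:
    """One SSR locus: a name, the repeat-unit length in bp (if known) and an
    optional allele grid of canonical AFL bin centres."""

    name: str
    repeat_unit: Optional[int] = None
    grid: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("marker name must be non-empty")
        if self.repeat_unit is not None and self.repeat_unit < 1:
            raise ValueError(f"{self.name}: repeat_unit must be positive")
        if self.grid is not None:
            g = tuple(int(v) for v in self.grid)
            if not g:
                raise ValueError(f"{self.name}: grid must be non-empty when given")
            if any(v <= 0 for v in g):
                raise ValueError(f"{self.name}: grid values must be positive")
            if any(b <= a for a, b in zip(g, g[1:])):
                raise ValueError(f"{self.name}: grid must be strictly increasing")
            object.__setattr__(self, "grid", g)


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker set; the order defines column order on output."""

    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names in panel")
        object.__setattr__(self, "_by_name", {m.name: m for m in self.markers})

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self) -> Iterator[Marker]:
        return iter(self.markers)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name  # type: ignore[attr-defined]

    def get(self, name: str) -> Marker:
        try:
            return self._by_name[name]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"marker {name!r} not in panel") from None

    def with_grids(self, grids: Mapping[str, Sequence[int]]) -> "MarkerPanel":
        """Return a copy of the panel with allele grids attached."""
        new = []
        for m in self.markers:
            if m.name in grids:
                new.append(replace(m, grid=tuple(int(v) for v in grids[m.name])))
            else:
                new.append(m)
        return MarkerPanel(tuple(new))


@dataclass(frozen=True)
class AlleleSet:
    """Distinct AFL variants of one sample at one marker, sorted ascending.

    Empty means missing data (failed amplification).
    """

    marker: str
    alleles: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        al = tuple(int(a) for a in self.alleles)
        if any(b <= a for a, b in zip(al, al[1:])):
            raise ValueError(
                f"{self.marker}: alleles must be strictly increasing, got {al}"
            )
        if len(al) > MAX_ALLELES:
            raise ValueError(f"{self.marker}: more than {MAX_ALLELES} alleles: {al}")
        if any(a <= 0 for a in al):
            raise ValueError(f"{self.marker}: AFLs must be positive, got {al}")
        object.__setattr__(self, "alleles", al)

    @classmethod
    def from_calls(cls, marker: str, calls: Sequence[int]) -> "AlleleSet":
        """Build from raw calls: deduplicate and sort."""
        return cls(marker, tuple(sorted(set(int(c) for c in calls))))

    @property
    def is_missing(self) -> bool:
        return not self.alleles

    def __len__(self) -> int:
        return len(self.alleles)


@dataclass(frozen=True)
class SSRProfile:
    """One sample's fingerprint plus its collection metadata."""

    sample_id: str
    allele_sets: Mapping[str, AlleleSet]
    tree_id: str = ""
    accession_id: str = ""
    location: str = ""
    cultivar_name_given: str = ""
    trueness_code: Optional[TruenessCode] = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        object.__setattr__(self, "allele_sets", dict(self.allele_sets))
        for name, aset in self.allele_sets.items():
            if aset.marker != name:
                raise ValueError(
                    f"allele set keyed {name!r} but labelled {aset.marker!r}"
                )

    def validate_against(self, panel: MarkerPanel) -> None:
        """Check the profile covers exactly the panel's markers."""
        have = set(self.allele_sets)
        want = set(panel.names)
        if have != want:
            missing = sorted(want - have)
            extra = sorted(have - want)
            raise ValueError(
                f"{self.sample_id}: profile/panel mismatch "
                f"(missing markers {missing}, unknown markers {extra})"
            )

    def alleles_at(self, marker: str) -> tuple[int, ...]:
        aset = self.allele_sets.get(marker)
        return aset.alleles if aset is not None else ()

    @property
    def n_alleles(self) -> int:
        return sum(len(a) for a in self.allele_sets.values())


def check_unique_sample_ids(profiles: Sequence[SSRProfile]) -> None:
    seen: set[str] = set()
    for p in profiles:
        if p.sample_id in seen:
            raise ValueError(f"duplicate sample_id: {p.sample_id!r}")
        seen.add(p.sample_id)
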