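"""Reference constants for the German Fruit Genebank (GFG) pear collection.

The 17-marker ECPGR Malus/Pyrus SSR panel used for the pear inventory, and
the published per-location sample accounting of the collection.  Size windows
per marker are plausible dinucleotide-SSR fragment ranges used by the
synthetic-data generator; the published dataset stores binned integer AFLs,
so only the marker names and repeat units matter for reading real data.
"""

from __future__ import annotations

import pandas as pd

from .model import Marker, MarkerPanel

#: (name, repeat unit bp, (low, high) fragment-size window in bp).
#: Repeat units: these loci are dinucleotide microsatellites; CH02b10 is a
#: perfect 2-bp repeat. Size windows are generator defaults, not data.
PEAR_SSR_PANEL_SPEC: tuple[tuple[str, int, tuple[int, int]], ...] = (
    ("CH01d08", 2, (232, 294)),
    ("CH01d09", 2, (130, 184)),
    ("CH01f07a", 2, (170, 224)),
    ("CH02b10", 2, (108, 162)),
    ("CH03d12", 2, (100, 158)),
    ("CH03g07", 2, (120, 190)),
    ("CH04e03", 2, (178, 232)),
    ("CH05c06", 2, (80, 134)),
    ("EMPc11", 2, (120, 164)),
    ("EMPc117", 2, (90, 134)),
    ("GD147", 2, (110, 162)),
    ("GD96", 2, (120, 180)),
    ("CH-Vf1", 2, (130, 184)),
    ("CH04c07", 2, (90, 144)),
    ("CH05a02", 2, (120, 174)),
    ("GD142", 2, (110, 170)),
    ("NZ05g8", 2, (100, 154)),
)

MARKER_SIZE_WINDOWS: dict[str, tuple[int, int]] = {
    name: window for name, _, window in PEAR_SSR_PANEL_SPEC
}


def default_panel() -> MarkerPanel:
    """The 17-marker pear SSR panel (no allele grids attached)."""
    return MarkerPanel(
        tuple(Marker(name, repeat_unit=ru) for name, ru, _ in PEAR_SSR_PANEL_SPEC)
    )


#: Published per-location accounting of the GFG pear collection:
#: (location, final samples, trees, accessions, samples with molecular data,
#: samples with pomological data).
GFG_COLLECTION_COUNTS: tuple[tuple[str, int, int, int, int, int], ...] = (
    ("Hermann Cordes Nursery KG", 167, 166, 95, 173, 184),
    ("Competence Centre of Fruit Production - Lake Constance", 293, 293, 147, 293, 293),
    ("State Education and Research Institute for Viticulture and Pomology Weinsberg",
     46, 46, 24, 48, 50),
    ("Julius Kuehn Institute - Institute for Breeding Research on Fruit Crops",
     250, 250, 132, 256, 243),
    ("State Institute for Agriculture and Horticulture Saxony-Anhalt",
     168, 168, 56, 168, 168),
    ("Federal Plant Variety Office - Testing Station Wurzen", 261, 243, 109, 268, 270),
    ("Nonprofit Association: Teaching and Research Institution for Horti- and "
     "Arboriculture", 242, 242, 137, 249, 250),
    ("Triesdorf Agricultural Education Centre", 510, 510, 271, 538, 540),
    ("References Brogdale", 8, 0, 8, 8, 0),
)


def build_collection_records() -> pd.DataFrame:
    """Deterministically expand the per-location counts into per-sample rows.

    Returns a sample-record table (one row per collected sample) whose
    per-location aggregation reproduces the published accounting exactly:
    final samples, distinct trees and accessions among final samples, samples
    with molecular data and samples with pomological data. Tree/accession
    identifiers are synthetic placeholders; only their multiplicity matters.
    """
    rows = []
    for li, (loc, n_final, n_trees, n_acc, n_mol, n_pom) in enumerate(
        GFG_COLLECTION_COUNTS, start=1
    ):
        if n_final > n_mol:
            raise ValueError(f"{loc}: more final samples than molecular samples")
        slug = f"L{li:02d}"
        n_records = max(n_mol, n_pom)
        for i in range(n_records):
            has_mol = i < n_mol
            is_final = i < n_final
            has_pom = i < n_pom
            if is_final and n_trees:
                # first n_trees final samples get distinct trees; the rest are
                # replicates of the first tree
                tree = f"{slug}_T{min(i, n_trees - 1) + 1:04d}"
            else:
                tree = ""
            if is_final and n_acc:
                acc = f"{slug}_A{(i % n_acc) + 1:04d}"
            else:
                acc = ""
            rows.append(
                {
                    "sample_id": f"{slug}_S{i + 1:04d}",
                    "location": loc,
                    "tree_id": tree,
                    "accession_id": acc,
                    "has_molecular": has_mol,
                    "has_pomological": has_pom,
                    "is_final": is_final,
                }
            )
    return pd.DataFrame(rows)
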