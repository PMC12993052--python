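"""Readers and writers for the tabular formats the pipeline touches.

Three profile dialects:

* ``wide-csv`` — one row per sample, one column per marker position
  (``CH02b10_1``, ``CH02b10_2``, ...), the common fragment-analysis export.
* ``long-csv`` — one row per (sample, marker, allele); a marker with failed
  amplification keeps one row with an empty allele cell so samples survive a
  round trip.
* ``gfg-xlsx`` — the four-sheet workbook layout of the published genebank
  deposit (representative genotypes, column legend, per-position variant
  frequencies, frequency legend); header strings are configurable.

Empty cells, ``NA`` and ``0`` all parse to missing data.  AFLs are integers;
decimal sizes are accepted only for markers with an allele grid, through
:func:`snap_to_grid`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .consensus import CHECK, RepresentativeGenotype
from .distance import MolecularGroup
from .model import (
    AlleleSet,
    Marker,
    MarkerPanel,
    SSRProfile,
    TruenessCode,
    check_unique_sample_ids,
)
from .qc import FrequencyReport

PathLike = Union[str, Path]

META_COLUMNS = [
    "sample_id",
    "tree_id",
    "accession_id",
    "location",
    "cultivar_name",
    "trueness",
]

MISSING_TOKENS = {"", "na", "nan", "none", "0", "0.0"}


def snap_to_grid(
    raw_afl: float, marker: Marker, tolerance: int = 1
) -> Optional[int]:
    """Snap a raw fragment size to the marker's allele grid.

    Returns the nearest grid value within ``tolerance`` bp (ties broken
    toward the smaller grid value) or ``None`` when no grid value is close
    enough — the caller must surface unassigned calls.
    """
    if marker.grid is None or not marker.grid:
        raise ValueError(f"{marker.name}: no allele grid configured")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    best = min(marker.grid, key=lambda g: (abs(raw_afl - g), g))
    if abs(raw_afl - best) <= tolerance:
        return int(best)
    return None


def _parse_afl(
    cell: object, marker: Marker, where: str, grid_tolerance: int
) -> Optional[int]:
    """One allele cell -> AFL in bp, None for missing; raises on bad input."""
    if cell is None:
        return None
    text = str(cell).strip()
    if text.lower() in MISSING_TOKENS:
        return None
    try:
        value = float(text)
    except ValueError:
        raise ValueError(f"{where}: non-integer AFL {text!r}") from None
    if value <= 0:
        return None
    if value == int(value):
        return int(value)
    if marker.grid is not None:
        snapped = snap_to_grid(value, marker, grid_tolerance)
        if snapped is None:
            raise ValueError(
                f"{where}: raw size {value} not within {grid_tolerance} bp of "
                f"the {marker.name} allele grid"
            )
        return snapped
    raise ValueError(
        f"{where}: non-integer AFL {text!r} and marker {marker.name} has no "
        "allele grid to snap to"
    )


def _parse_trueness(cell: object) -> Optional[TruenessCode]:
    text = str(cell).strip() if cell is not None else ""
    if text == "" or text.lower() in {"na", "nan", "none"}:
        return None
    return TruenessCode(int(float(text)))


def _read_table(source: PathLike, **kw) -> pd.DataFrame:
    return pd.read_csv(source, dtype=str, keep_default_na=False, **kw)


def _wide_marker_columns(
    columns: Sequence[str], panel: MarkerPanel
) -> dict[str, list[str]]:
    """Map marker name -> its position columns, in position order."""
    out: dict[str, list[tuple[int, str]]] = {name: [] for name in panel.names}
    for col in columns:
        if col in META_COLUMNS:
            continue
        name, _, pos = col.rpartition("_")
        if name in panel.names and pos.isdigit():
            out[name].append((int(pos), col))
        else:
            raise ValueError(f"unknown marker column: {col!r}")
    return {
        name: [c for _, c in sorted(cols)] for name, cols in out.items()
    }


def _profile_from_fields(
    sample_id: str,
    row: "pd.Series",
    allele_sets: dict[str, AlleleSet],
) -> SSRProfile:
    return SSRProfile(
        sample_id=sample_id,
        allele_sets=allele_sets,
        tree_id=str(row.get("tree_id", "") or ""),
        accession_id=str(row.get("accession_id", "") or ""),
        location=str(row.get("location", "") or ""),
        cultivar_name_given=str(row.get("cultivar_name", "") or ""),
        trueness_code=_parse_trueness(row.get("trueness", "")),
    )


def read_profiles(
    source: PathLike,
    panel: MarkerPanel,
    dialect: str = "wide-csv",
    grid_tolerance: int = 1,
) -> list[SSRProfile]:
    """Read sample profiles in one of the supported dialects."""
    if dialect == "wide-csv":
        profiles = _read_wide(source, panel, grid_tolerance)
    elif dialect == "long-csv":
        profiles = _read_long(source, panel, grid_tolerance)
    elif dialect == "gfg-xlsx":
        profiles = _read_gfg_sheet1(source, panel, grid_tolerance)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    check_unique_sample_ids(profiles)
    return profiles


def _read_wide(
    source: PathLike, panel: MarkerPanel, grid_tolerance: int
) -> list[SSRProfile]:
    df = _read_table(source)
    if "sample_id" not in df.columns:
        raise ValueError("wide-csv requires a sample_id column")
    marker_cols = _wide_marker_columns(df.columns, panel)
    profiles = []
    for idx, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        allele_sets = {}
        for name in panel.names:
            marker = panel.get(name)
            calls = []
            for col in marker_cols[name]:
                afl = _parse_afl(
                    row[col], marker, f"row {idx + 2}, column {col}", grid_tolerance
                )
                if afl is not None:
                    calls.append(afl)
            allele_sets[name] = AlleleSet.from_calls(name, calls)
        profiles.append(_profile_from_fields(sid, row, allele_sets))
    return profiles


def _read_long(
    source: PathLike, panel: MarkerPanel, grid_tolerance: int
) -> list[SSRProfile]:
    df = _read_table(source)
    for col in ("sample_id", "marker", "allele"):
        if col not in df.columns:
            raise ValueError(f"long-csv requires a {col} column")
    calls: dict[str, dict[str, list[int]]] = {}
    meta: dict[str, pd.Series] = {}
    order: list[str] = []
    for idx, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        name = str(row["marker"]).strip()
        if name not in panel.names:
            raise ValueError(f"unknown marker column: {name!r} (row {idx + 2})")
        if sid not in calls:
            calls[sid] = {m: [] for m in panel.names}
            meta[sid] = row
            order.append(sid)
        afl = _parse_afl(
            row["allele"], panel.get(name), f"row {idx + 2}", grid_tolerance
        )
        if afl is not None:
            calls[sid][name].append(afl)
    profiles = []
    for sid in order:
        allele_sets = {
            m: AlleleSet.from_calls(m, calls[sid][m]) for m in panel.names
        }
        profiles.append(_profile_from_fields(sid, meta[sid], allele_sets))
    return profiles


def _n_positions(
    counts: Sequence[int], minimum: int = 2, cap: int = 4
) -> int:
    return min(cap, max([minimum, *counts]))


def write_profiles(
    profiles: Sequence[SSRProfile],
    panel: MarkerPanel,
    destination: PathLike,
    dialect: str = "wide-csv",
) -> None:
    """Write profiles in wide or long CSV."""
    if dialect == "wide-csv":
        _write_wide(profiles, panel, destination)
    elif dialect == "long-csv":
        _write_long(profiles, panel, destination)
    else:
        raise ValueError(f"unknown dialect for profile output: {dialect!r}")


def _meta_fields(p: SSRProfile) -> list[str]:
    return [
        p.sample_id,
        p.tree_id,
        p.accession_id,
        p.location,
        p.cultivar_name_given,
        "" if p.trueness_code is None else str(p.trueness_code.code),
    ]


def _write_wide(
    profiles: Sequence[SSRProfile], panel: MarkerPanel, destination: PathLike
) -> None:
    widths = {
        name: _n_positions([len(p.alleles_at(name)) for p in profiles])
        for name in panel.names
    }
    header = list(META_COLUMNS)
    for name in panel.names:
        header += [f"{name}_{i + 1}" for i in range(widths[name])]
    with open(destination, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for p in profiles:
            row = _meta_fields(p)
            for name in panel.names:
                alleles = p.alleles_at(name)
                row += [str(a) for a in alleles]
                row += [""] * (widths[name] - len(alleles))
            writer.writerow(row)


def _write_long(
    profiles: Sequence[SSRProfile], panel: MarkerPanel, destination: PathLike
) -> None:
    header = list(META_COLUMNS[:1]) + ["marker", "allele"] + META_COLUMNS[1:]
    with open(destination, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for p in profiles:
            meta = _meta_fields(p)
            for name in panel.names:
                alleles = p.alleles_at(name) or ("",)
                for a in alleles:
                    writer.writerow([meta[0], name, str(a)] + meta[1:])


# ---------------------------------------------------------------------------
# representative genotypes: CSV and the four-sheet genebank workbook
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GfgLayout:
    """Configurable header strings of the deposit-style workbook."""

    sheet_genotypes: str = "Representative genotypes"
    sheet_legend: str = "Legend"
    sheet_frequencies: str = "AFL frequencies"
    sheet_freq_legend: str = "Frequency legend"
    col_cultivar: str = "Cultivar name"
    col_group: str = "Molecular group"
    col_trueness: str = "Trueness-to-type"
    col_sports: str = "Sports"
    col_punq: str = "PUNQ"
    col_ploidy: str = "Ploidy"
    col_retraceable: str = "Retraceable to accession"
    col_average: str = "Average"


DEFAULT_GFG_LAYOUT = GfgLayout()

REP_META = ["cultivar_name", "group_id", "trueness", "sports", "punq", "ploidy",
            "retraceable"]


def _rep_widths(
    reps: Sequence[RepresentativeGenotype], panel: MarkerPanel
) -> dict[str, int]:
    return {
        name: _n_positions([len(r.alleles.get(name, ())) for r in reps])
        for name in panel.names
    }


def _rep_row(
    rep: RepresentativeGenotype, panel: MarkerPanel, widths: dict[str, int]
) -> list[str]:
    if not rep.alleles:
        raise ValueError(f"group {rep.group_id}: no consensus computed")
    row = [
        rep.cultivar_name,
        rep.group_id,
        "" if rep.trueness_code is None else str(rep.trueness_code.code),
        "; ".join(rep.sports),
        rep.punq or "",
        "" if rep.ploidy is None else str(rep.ploidy),
        "" if rep.retraceable is None else str(rep.retraceable),
    ]
    for name in panel.names:
        values = rep.alleles.get(name, ())
        cells = [CHECK if v is None else str(v) for v in values]
        row += cells + [""] * (widths[name] - len(cells))
    return row


def _marker_headers(panel: MarkerPanel, widths: dict[str, int]) -> list[str]:
    cols = []
    for name in panel.names:
        cols += [f"{name}_{i + 1}" for i in range(widths[name])]
    return cols


def write_representatives_csv(
    reps: Sequence[RepresentativeGenotype],
    panel: MarkerPanel,
    destination: PathLike,
) -> None:
    if not reps:
        raise ValueError("no representative genotypes to write")
    widths = _rep_widths(reps, panel)
    header = REP_META + _marker_headers(panel, widths)
    with open(destination, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rep in sorted(reps, key=lambda r: r.group_id):
            writer.writerow(_rep_row(rep, panel, widths))


def read_representatives_csv(
    source: PathLike, panel: MarkerPanel
) -> list[RepresentativeGenotype]:
    """Parse representatives back (CHECK cells stay unresolved positions)."""
    df = _read_table(source)
    marker_cols = _wide_marker_columns(
        [c for c in df.columns if c not in REP_META], panel
    )
    reps = []
    for idx, row in df.iterrows():
        alleles: dict[str, tuple[Optional[int], ...]] = {}
        candidates: dict[tuple[str, int], tuple[int, ...]] = {}
        for name in panel.names:
            values: list[Optional[int]] = []
            for col in marker_cols[name]:
                cell = str(row[col]).strip()
                if cell == CHECK:
                    values.append(None)
                elif cell.lower() in MISSING_TOKENS:
                    continue
                else:
                    values.append(int(float(cell)))
            if values:
                alleles[name] = tuple(values)
                for i, v in enumerate(values):
                    if v is None:
                        candidates[(name, i)] = ()
        reps.append(
            RepresentativeGenotype(
                group_id=str(row["group_id"]).strip(),
                cultivar_name=str(row.get("cultivar_name", "") or ""),
                alleles=alleles,
                check_candidates=candidates,
                trueness_code=_parse_trueness(row.get("trueness", "")),
                sports=tuple(
                    s.strip()
                    for s in str(row.get("sports", "") or "").split(";")
                    if s.strip()
                ),
                punq=str(row.get("punq", "") or "") or None,
                ploidy=(
                    int(float(row["ploidy"]))
                    if str(row.get("ploidy", "")).strip() not in ("", "nan")
                    else None
                ),
            )
        )
    return reps


def write_representative_dataset(
    reps: Sequence[RepresentativeGenotype],
    panel: MarkerPanel,
    destination: PathLike,
    frequency_reports: Optional[Sequence[FrequencyReport]] = None,
    layout: GfgLayout = DEFAULT_GFG_LAYOUT,
) -> None:
    """Write the four-sheet deposit-style XLSX workbook.

    Sheet 1: representative genotypes with identity metadata and per-position
    AFLs (unresolved positions carry the literal token CHECK); sheet 2: column
    legend; sheet 3: per-position frequencies of the representative variant
    plus the group average; sheet 4: frequency legend.
    """
    if not reps:
        raise ValueError("no representative genotypes to write")
    widths = _rep_widths(reps, panel)
    marker_headers = _marker_headers(panel, widths)
    meta_headers = [
        layout.col_cultivar,
        layout.col_group,
        layout.col_trueness,
        layout.col_sports,
        layout.col_punq,
        layout.col_ploidy,
        layout.col_retraceable,
    ]
    ordered = sorted(reps, key=lambda r: r.group_id)
    sheet1 = pd.DataFrame(
        [_rep_row(r, panel, widths) for r in ordered],
        columns=meta_headers + marker_headers,
    )
    legend_rows = [
        (layout.col_cultivar, "resolved cultivar name of the molecular group"),
        (layout.col_group, "molecular group identifier (running number)"),
        (layout.col_trueness, "GFG trueness-to-type code, 0-5"),
        (layout.col_sports, "names of sports (mutants) merged into the group"),
        (layout.col_punq, "Pyrus UNiQue genotype code (external alignment)"),
        (layout.col_ploidy, "ploidy level from flow cytometry (passthrough)"),
        (layout.col_retraceable,
         "True when the representative matches a measured member sample"),
    ] + [
        (col, "allele fragment length in bp; CHECK marks an unresolved tie")
        for col in marker_headers
    ]
    sheet2 = pd.DataFrame(legend_rows, columns=["column", "explanation"])

    freq_by_group = {
        fr.group_id: fr for fr in (frequency_reports or [])
    }
    freq_rows = []
    for rep in ordered:
        fr = freq_by_group.get(rep.group_id)
        row: dict[str, object] = {layout.col_group: rep.group_id}
        if fr is not None:
            for (marker, pos), value in fr.frequencies.items():
                row[f"{marker}_{pos + 1}"] = round(value, 4)
            row[layout.col_average] = round(fr.average_score, 4)
        freq_rows.append(row)
    sheet3 = pd.DataFrame(
        freq_rows, columns=[layout.col_group] + marker_headers + [layout.col_average]
    )
    sheet4 = pd.DataFrame(
        [
            (layout.col_group, "molecular group identifier"),
            ("<marker>_<position>",
             "frequency of the representative AFL among members amplified at "
             "the marker, 0-1"),
            (layout.col_average, "mean frequency over resolved positions"),
        ],
        columns=["column", "explanation"],
    )
    with pd.ExcelWriter(destination, engine="openpyxl") as writer:
        sheet1.to_excel(writer, sheet_name=layout.sheet_genotypes, index=False)
        sheet2.to_excel(writer, sheet_name=layout.sheet_legend, index=False)
        sheet3.to_excel(writer, sheet_name=layout.sheet_frequencies, index=False)
        sheet4.to_excel(writer, sheet_name=layout.sheet_freq_legend, index=False)


def _read_gfg_sheet1(
    source: PathLike,
    panel: MarkerPanel,
    grid_tolerance: int,
    layout: GfgLayout = DEFAULT_GFG_LAYOUT,
) -> list[SSRProfile]:
    """Read sheet 1 of the deposit workbook as profiles (one per group).

    CHECK cells are unresolved ties, not AFLs, and parse to no allele.
    """
    df = pd.read_excel(
        source, sheet_name=layout.sheet_genotypes, dtype=str, keep_default_na=False
    )
    meta_map = {
        layout.col_cultivar: "cultivar_name",
        layout.col_trueness: "trueness",
    }
    marker_cols = _wide_marker_columns(
        [c for c in df.columns
         if c not in (layout.col_cultivar, layout.col_group, layout.col_trueness,
                      layout.col_sports, layout.col_punq, layout.col_ploidy,
                      layout.col_retraceable)],
        panel,
    )
    profiles = []
    for idx, row in df.iterrows():
        sid = str(row[layout.col_group]).strip()
        allele_sets = {}
        for name in panel.names:
            marker = panel.get(name)
            calls = []
            for col in marker_cols[name]:
                cell = str(row[col]).strip()
                if cell == CHECK:
                    continue
                afl = _parse_afl(
                    cell, marker, f"row {idx + 2}, column {col}", grid_tolerance
                )
                if afl is not None:
                    calls.append(afl)
            allele_sets[name] = AlleleSet.from_calls(name, calls)
        meta = {v: row.get(k, "") for k, v in meta_map.items()}
        profiles.append(
            SSRProfile(
                sample_id=sid,
                allele_sets=allele_sets,
                cultivar_name_given=str(meta.get("cultivar_name", "") or ""),
                trueness_code=_parse_trueness(meta.get("trueness", "")),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# molecular groups and panel files
# ---------------------------------------------------------------------------

def write_groups_csv(
    groups: Sequence[MolecularGroup], destination: PathLike
) -> None:
    with open(destination, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group_id", "cultivar_name", "sports", "sample_id"])
        for g in sorted(groups, key=lambda g: g.group_id):
            for sid in g.member_sample_ids:
                writer.writerow(
                    [g.group_id, g.cultivar_name, "; ".join(g.sports), sid]
                )


def read_groups_csv(source: PathLike) -> list[MolecularGroup]:
    df = _read_table(source)
    groups = []
    for gid, sub in df.groupby("group_id", sort=True):
        first = sub.iloc[0]
        groups.append(
            MolecularGroup(
                group_id=str(gid),
                member_sample_ids=tuple(str(s) for s in sub["sample_id"]),
                cultivar_name=str(first.get("cultivar_name", "") or ""),
                sports=tuple(
                    s.strip()
                    for s in str(first.get("sports", "") or "").split(";")
                    if s.strip()
                ),
            )
        )
    return groups


def write_panel(panel: MarkerPanel, destination: PathLike) -> None:
    """Plain-text panel file: name, repeat unit, optional comma-joined grid."""
    with open(destination, "w") as fh:
        fh.write("# marker\trepeat_unit\tgrid\n")
        for m in panel:
            ru = "-" if m.repeat_unit is None else str(m.repeat_unit)
            grid = "-" if not m.grid else ",".join(str(v) for v in m.grid)
            fh.write(f"{m.name}\t{ru}\t{grid}\n")


def read_panel(source: PathLike) -> MarkerPanel:
    markers = []
    with open(source) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed panel line: {line!r}")
            name = parts[0]
            ru = None if parts[1] == "-" else int(parts[1])
            grid = None
            if len(parts) > 2 and parts[2] not in ("-", ""):
                grid = tuple(int(v) for v in parts[2].split(","))
            markers.append(Marker(name, repeat_unit=ru, grid=grid))
    return MarkerPanel(tuple(markers))
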