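"""End-to-end curation run: read -> distances -> cluster -> name ->
consensus -> tie resolution -> trueness -> retrace -> frequencies -> summary.

Every stage's outputs are written as CSV under the output directory together
with a machine-readable ``manifest.json`` recording parameters and per-stage
counts.  The manifest carries no timestamps, so identical inputs and
configuration produce byte-identical outputs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .consensus import RepresentativeGenotype, build_representative
from .distance import (
    DEFAULT_CUTOFF,
    DEFAULT_PREFIX,
    DEFAULT_TOLERANCE_BP,
    MolecularGroup,
    name_groups,
    pairwise_distances,
    threshold_cluster,
)
from .io import (
    read_panel,
    read_profiles,
    write_groups_csv,
    write_profiles,
    write_representative_dataset,
    write_representatives_csv,
)
from .model import MarkerPanel, SSRProfile
from .qc import (
    collection_summary,
    retrace_representatives,
    retraceable_fraction,
    variant_frequencies,
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Parameters of a curation run; the defaults are the published ones
    (±1 bp allele tolerance, 0.2 distance cut-off, ``Pyr_`` group prefix)."""

    profiles: str = ""
    panel: str = ""
    out_dir: str = "curation_out"
    dialect: str = "wide-csv"
    tolerance_bp: int = DEFAULT_TOLERANCE_BP
    cutoff: float = DEFAULT_CUTOFF
    group_prefix: str = DEFAULT_PREFIX
    linkage: str = "single"
    resolve_ties: bool = True
    write_distances: bool = True
    write_xlsx: bool = False
    seed: int = 0


def run_pipeline(
    config: RunConfig,
    profiles: Optional[Sequence[SSRProfile]] = None,
    panel: Optional[MarkerPanel] = None,
) -> dict:
    """Execute the full curation run and return the manifest.

    ``profiles``/``panel`` may be passed in memory; otherwise they are read
    from the paths in the config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    stage = "read"
    try:
        if panel is None:
            panel = read_panel(config.panel)
        if profiles is None:
            profiles = read_profiles(config.profiles, panel, config.dialect)
        profiles = list(profiles)
        if len(profiles) < 2:
            raise ValueError("need at least two samples to curate")
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
        raise StageError(stage, str(exc)) from exc

    try:
        stage = "distances"
        matrix = pairwise_distances(profiles, panel, config.tolerance_bp)
        for a, b in matrix.missing_pairs:
            warnings.append(f"incomparable pair (no shared marker): {a}, {b}")
        if config.write_distances:
            matrix.to_dataframe().to_csv(out / "distances.csv")

        stage = "cluster"
        components = threshold_cluster(matrix, config.cutoff, config.linkage)
        groups = name_groups(components, config.group_prefix)

        stage = "consensus"
        by_id = {p.sample_id: p for p in profiles}
        reps: list[RepresentativeGenotype] = []
        for g in groups:
            rep = build_representative(
                g, by_id, panel, resolve=config.resolve_ties
            )
            warnings.extend(f"{g.group_id}: {w}" for w in rep.warnings)
            reps.append(rep)

        stage = "retrace"
        retrace = retrace_representatives(reps, profiles, groups, panel)
        retraceable = dict(
            zip(retrace["group_id"], retrace["retraceable"])
        )
        for rep in reps:
            flag = retraceable.get(rep.group_id)
            rep.retraceable = None if pd.isna(flag) else bool(flag)

        stage = "frequencies"
        freq_reports = [
            variant_frequencies(
                rep, [by_id[s] for s in groups_by_id(groups)[rep.group_id]]
            )
            for rep in reps
        ]

        stage = "summary"
        summary = collection_summary(profiles)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    stage = "write"
    try:
        write_profiles(profiles, panel, out / "profiles_clean.csv", "wide-csv")
        write_groups_csv(groups, out / "groups.csv")
        write_representatives_csv(reps, panel, out / "representatives.csv")
        _write_consensus_log(reps, out / "consensus_log.csv")
        retrace.to_csv(out / "retrace.csv", index=False)
        _write_frequencies(freq_reports, out / "frequencies.csv")
        summary.to_csv(out / "summary.csv")
        if config.write_xlsx:
            write_representative_dataset(
                reps, panel, out / "representative_dataset.xlsx", freq_reports
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    n_unresolved = sum(len(r.check_flags) for r in reps)
    manifest = {
        "tool": {"name": "ssrcurate", "version": __version__},
        "parameters": {
            "tolerance_bp": config.tolerance_bp,
            "cutoff": config.cutoff,
            "group_prefix": config.group_prefix,
            "linkage": config.linkage,
            "resolve_ties": config.resolve_ties,
            "dialect": config.dialect,
            "seed": config.seed,
        },
        "counts": {
            "samples": len(profiles),
            "markers": len(panel),
            "incomparable_pairs": len(matrix.missing_pairs),
            "groups": len(groups),
            "sum_group_sizes": sum(g.size for g in groups),
            "unresolved_check_flags": n_unresolved,
            "retraceable_groups": int(
                sum(bool(v) for v in retrace["retraceable"] if not pd.isna(v))
            ),
            "retraceable_fraction": _round_or_nan(
                retraceable_fraction(retrace)
            ),
        },
        "warnings": warnings,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def groups_by_id(groups: Sequence[MolecularGroup]) -> dict[str, tuple[str, ...]]:
    return {g.group_id: g.member_sample_ids for g in groups}


def _round_or_nan(x: float) -> float:
    try:
        return round(float(x), 6)
    except (TypeError, ValueError):
        return float("nan")


def _write_consensus_log(
    reps: Sequence[RepresentativeGenotype], destination: Union[str, Path]
) -> None:
    fields = ["group_id", "marker", "position", "candidates", "chosen", "rule",
              "status"]
    with open(destination, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for rep in sorted(reps, key=lambda r: r.group_id):
            for entry in rep.resolution_log:
                writer.writerow(entry)


def _write_frequencies(freq_reports, destination: Union[str, Path]) -> None:
    with open(destination, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group_id", "marker", "position", "frequency"])
        for fr in sorted(freq_reports, key=lambda f: f.group_id):
            for (marker, pos), value in sorted(fr.frequencies.items()):
                writer.writerow([fr.group_id, marker, pos + 1, f"{value:.6f}"])
            if fr.frequencies:
                writer.writerow(
                    [fr.group_id, "AVERAGE", "", f"{fr.average_score:.6f}"]
                )
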