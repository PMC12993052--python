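"""Synthetic genebank collections with known ground truth.

Emulates the structure of a clonal fruit collection genotyped at a
multi-allelic SSR panel: each cultivar has a fixed true genotype (two alleles
per marker for diploids, three for triploids, drawn from per-marker allele
pools spaced by the repeat unit); several trees per cultivar and replicate
samples per tree are emitted, perturbed by per-allele ±1 bp sizing error,
per-(sample, marker) amplification failure and per-sample mislabeling of the
recorded cultivar name.  Every perturbation is logged so the emitted profiles
can be replayed exactly from the truth — the basis of the recovery tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .distance import MolecularGroup, dice_distance
from .model import AlleleSet, MarkerPanel, SSRProfile, TruenessCode
from .reference import MARKER_SIZE_WINDOWS, default_panel

#: locations loosely mirroring a multi-partner genebank network
SITE_LABELS = tuple(f"Site_{c}" for c in "ABCDEFGH")


@dataclass
class SimConfig:
    """Generator settings; defaults describe a realistic curated collection.

    Rates are probabilities in [0, 1].  ``ploidy_mix`` is (diploid, triploid)
    proportions; pear collections carry roughly one triploid cultivar in ten.
    ``min_cultivar_distance`` keeps true genotypes separated (rejection
    sampling), emulating the fact that distinct cultivars are far apart at a
    17-marker panel.
    """

    n_cultivars: int = 50
    panel: Optional[MarkerPanel] = None
    ploidy_mix: tuple[float, float] = (0.9, 0.1)
    trees_per_cultivar: tuple[int, int] = (1, 3)
    replicates_per_tree: tuple[int, int] = (1, 2)
    miscall_rate: float = 0.02
    missing_rate: float = 0.05
    mislabel_rate: float = 0.02
    sport_rate: float = 0.02
    trueness_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.1, 3: 0.1, 4: 0.15, 5: 0.1, 0: 0.05}
    )
    pool_size_range: tuple[int, int] = (5, 15)
    min_cultivar_distance: float = 0.3
    tolerance_bp: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_cultivars < 1:
            raise ValueError("n_cultivars must be >= 1")
        for rate in (
            self.miscall_rate,
            self.missing_rate,
            self.mislabel_rate,
            self.sport_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if abs(sum(self.ploidy_mix) - 1.0) > 1e-9:
            raise ValueError("ploidy_mix must sum to 1")
        if self.panel is not None and len(self.panel) == 0:
            raise ValueError("panel has zero markers")
        probs = self.trueness_distribution
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("trueness_distribution must sum to 1")
        if self.trees_per_cultivar[0] < 1 or self.replicates_per_tree[0] < 1:
            raise ValueError("at least one tree and one replicate per cultivar")


@dataclass
class SimTruth:
    """Ground truth of a simulated collection."""

    panel: MarkerPanel
    genotypes: dict[str, dict[str, tuple[int, ...]]]
    cultivar_names: dict[str, str]
    sample_to_cultivar: dict[str, str]
    sports: dict[str, tuple[str, ...]]
    perturbations: list[dict]

    def replay(self, sample_id: str) -> dict[str, tuple[int, ...]]:
        """Reapply the logged perturbations of one sample to its cultivar's
        true genotype; must reproduce the emitted allele content exactly."""
        genotype = {
            m: list(a)
            for m, a in self.genotypes[self.sample_to_cultivar[sample_id]].items()
        }
        for ev in self.perturbations:
            if ev["sample_id"] != sample_id:
                continue
            if ev["kind"] == "miscall":
                calls = genotype[ev["marker"]]
                calls[calls.index(ev["from"])] = ev["to"]
            elif ev["kind"] == "missing":
                genotype[ev["marker"]] = []
        return {m: tuple(sorted(set(c))) for m, c in genotype.items()}


def _build_pools(
    panel: MarkerPanel, config: SimConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-marker allele pools: k variants spaced by the repeat unit inside
    the marker's size window."""
    lo_k, hi_k = config.pool_size_range
    pools = {}
    for marker in panel:
        ru = marker.repeat_unit or 2
        window = MARKER_SIZE_WINDOWS.get(marker.name, (100, 160))
        k = int(rng.integers(lo_k, hi_k + 1))
        span = window[1] - window[0]
        k = min(k, span // ru + 1)
        max_start = window[1] - ru * (k - 1)
        n_starts = max((max_start - window[0]) // ru + 1, 1)
        start = window[0] + ru * int(rng.integers(0, n_starts))
        pools[marker.name] = start + ru * np.arange(k)
    return pools


def _draw_genotype(
    panel: MarkerPanel,
    pools: dict[str, np.ndarray],
    ploidy: int,
    rng: np.random.Generator,
) -> dict[str, tuple[int, ...]]:
    return {
        m.name: tuple(
            sorted(set(int(a) for a in rng.choice(pools[m.name], size=ploidy)))
        )
        for m in panel
    }


def simulate_collection(
    config: SimConfig,
) -> tuple[list[SSRProfile], SimTruth]:
    """Generate a collection and its ground truth; deterministic under seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = config.panel if config.panel is not None else default_panel()
    if len(panel) == 0:
        raise ValueError("panel has zero markers")
    pools = _build_pools(panel, config, rng)
    panel = panel.with_grids({m: pools[m].tolist() for m in pools})

    # true cultivar genotypes, kept mutually distant by rejection sampling
    genotypes: dict[str, dict[str, tuple[int, ...]]] = {}
    names: dict[str, str] = {}
    sports: dict[str, tuple[str, ...]] = {}
    truth_profiles: dict[str, SSRProfile] = {}
    for c in range(1, config.n_cultivars + 1):
        cv = f"CV_{c:04d}"
        ploidy = 2 if rng.random() < config.ploidy_mix[0] else 3
        for attempt in range(1000):
            g = _draw_genotype(panel, pools, ploidy, rng)
            cand = SSRProfile(
                sample_id=cv,
                allele_sets={m: AlleleSet(m, a) for m, a in g.items()},
            )
            if all(
                dice_distance(cand, other, panel, config.tolerance_bp)
                > config.min_cultivar_distance
                for other in truth_profiles.values()
            ):
                break
        else:
            raise ValueError(
                "could not draw sufficiently distinct cultivar genotypes; "
                "loosen min_cultivar_distance or enlarge the panel/pools"
            )
        genotypes[cv] = g
        truth_profiles[cv] = cand
        names[cv] = f"Cultivar {c:04d}"
        if rng.random() < config.sport_rate:
            sports[cv] = (f"{names[cv]} Sport",)
        else:
            sports[cv] = ()

    codes = sorted(config.trueness_distribution)
    code_probs = [config.trueness_distribution[c] for c in codes]
    cultivar_ids = list(genotypes)

    profiles: list[SSRProfile] = []
    perturbations: list[dict] = []
    sample_to_cultivar: dict[str, str] = {}
    sample_no = 0
    for cv in cultivar_ids:
        n_trees = int(rng.integers(
            config.trees_per_cultivar[0], config.trees_per_cultivar[1] + 1
        ))
        site = SITE_LABELS[int(rng.integers(0, len(SITE_LABELS)))]
        for t in range(1, n_trees + 1):
            tree_id = f"{cv}_T{t}"
            accession = f"{cv}_A{t}"
            n_rep = int(rng.integers(
                config.replicates_per_tree[0], config.replicates_per_tree[1] + 1
            ))
            for _ in range(n_rep):
                sample_no += 1
                sid = f"S{sample_no:05d}"
                sample_to_cultivar[sid] = cv
                allele_sets = {}
                for m in panel.names:
                    calls = list(genotypes[cv][m])
                    for a in list(calls):
                        if rng.random() < config.miscall_rate:
                            delta = 1 if rng.random() < 0.5 else -1
                            calls[calls.index(a)] = a + delta
                            perturbations.append(
                                {
                                    "sample_id": sid,
                                    "kind": "miscall",
                                    "marker": m,
                                    "from": a,
                                    "to": a + delta,
                                }
                            )
                    if rng.random() < config.missing_rate:
                        calls = []
                        perturbations.append(
                            {"sample_id": sid, "kind": "missing", "marker": m}
                        )
                    allele_sets[m] = AlleleSet.from_calls(m, calls)
                given_name = names[cv]
                if len(cultivar_ids) > 1 and rng.random() < config.mislabel_rate:
                    other = cv
                    while other == cv:
                        other = cultivar_ids[
                            int(rng.integers(0, len(cultivar_ids)))
                        ]
                    given_name = names[other]
                    perturbations.append(
                        {
                            "sample_id": sid,
                            "kind": "mislabel",
                            "from": names[cv],
                            "to": given_name,
                        }
                    )
                code = int(rng.choice(codes, p=code_probs))
                profiles.append(
                    SSRProfile(
                        sample_id=sid,
                        allele_sets=allele_sets,
                        tree_id=tree_id,
                        accession_id=accession,
                        location=site,
                        cultivar_name_given=given_name,
                        trueness_code=TruenessCode(code),
                    )
                )
    truth = SimTruth(
        panel=panel,
        genotypes=genotypes,
        cultivar_names=names,
        sample_to_cultivar=sample_to_cultivar,
        sports=sports,
        perturbations=perturbations,
    )
    return profiles, truth


@dataclass(frozen=True)
class RecoveryScores:
    """Clustering agreement with the true cultivar partition."""

    adjusted_rand_index: float
    precision: float
    recall: float


def _pair_counts(labels: Sequence[int]) -> int:
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    return int((counts * (counts - 1) // 2).sum())


def evaluate_recovery(
    inferred: Sequence[MolecularGroup], truth: SimTruth
) -> RecoveryScores:
    """Pairwise co-membership precision/recall and ARI of the inferred
    molecular groups against the true cultivar partition."""
    pred: dict[str, str] = {}
    for g in inferred:
        for sid in g.member_sample_ids:
            if sid not in truth.sample_to_cultivar:
                raise ValueError(f"sample {sid!r} not in truth")
            pred[sid] = g.group_id
    sample_ids = sorted(pred)
    true_labels = [truth.sample_to_cultivar[s] for s in sample_ids]
    pred_labels = [pred[s] for s in sample_ids]
    t_codes = {c: i for i, c in enumerate(dict.fromkeys(true_labels))}
    p_codes = {c: i for i, c in enumerate(dict.fromkeys(pred_labels))}
    t = [t_codes[c] for c in true_labels]
    p = [p_codes[c] for c in pred_labels]
    ari = float(adjusted_rand_score(t, p))
    # co-membership pairs from the contingency table
    joint = Counter(zip(t, p))
    both = int(sum(k * (k - 1) // 2 for k in joint.values()))
    same_pred = _pair_counts(p)
    same_true = _pair_counts(t)
    precision = both / same_pred if same_pred else 1.0
    recall = both / same_true if same_true else 1.0
    return RecoveryScores(
        adjusted_rand_index=ari, precision=precision, recall=recall
    )
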