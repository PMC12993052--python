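# ssrcurate

Curation of multi-allelic SSR (microsatellite) fingerprints in clonal
germplasm collections — deduplicating field genebanks into *molecular
groups*, compiling one representative genotype per cultivar, and quality
checking the result.

## The problem

Fruit genebanks conserve named cultivars as grafted clones spread over many
trees, accessions and partner sites. Names drift, labels get swapped, and the
same historic cultivar (including its *sports*, somatic mutants that SSR
panels cannot distinguish) is often held under several entries. Genotyping
every tree at a standard SSR panel (here: the 17-marker ECPGR Malus/Pyrus
set used for European pear collections) makes the duplicates visible — but
turning thousands of noisy per-sample allele calls into one clean, citable
fingerprint per cultivar is a curation pipeline of its own. That pipeline is
what this package implements:

1. **Tolerance-aware Dice–Sørensen distance.** A sample's genotype at marker
   *m* is its set of allele fragment lengths (AFLs, integer bp). For samples
   *i, j*:

   d(i, j) = 1 − 2·Σₘ cₘ(i, j) / (Σₘ nₘ(i) + Σₘ nₘ(j))

   where nₘ is the number of distinct alleles and cₘ is the size of a
   maximum matching between the two allele sets in which alleles may pair
   when they differ by at most 1 bp (routine fragment-sizing wobble). Markers
   that failed to amplify in either sample are excluded from both sums.
2. **Threshold clustering.** Samples within distance 0.2 (≥ 80 % identity)
   are joined; connected components become molecular groups named
   `Pyr_0001`, `Pyr_0002`, … (descending size).
3. **Representative ("synthetic") fingerprints.** Per group and marker
   position, the most common AFL wins a majority vote; ties are flagged
   `CHECK` and resolved by ordered curation rules (combination observed
   verbatim in a member → more heterogeneous combination → allele spacings
   that are whole repeat units → human review), with every decision logged.
   The group's trueness-to-type code is the most desirable member code under
   the genebank hierarchy 1 ≻ 5 ≻ 2 ≻ 3 ≻ 4 ≻ 0.
4. **QC.** Representatives are binarized over (marker, AFL) variants and
   matched back against their members by binary Dice similarity: a group
   with no exact (100 %) match is a truly *synthetic* fingerprint. Variant
   frequencies per position and collection accounting tables complete the
   report.
5. **Synthetic collections.** A seeded generator emulates a genebank
   (diploid/triploid cultivars, replicate trees, ±1 bp miscalls, failed
   amplification, mislabels) with a replayable ground-truth log, so the whole
   pipeline is testable end to end without external data.

## Worked example

```python
from ssrcurate import (SimConfig, simulate_collection, pairwise_distances,
                       threshold_cluster, name_groups, build_representative,
                       retrace_representatives, retraceable_fraction,
                       evaluate_recovery)

profiles, truth = simulate_collection(SimConfig(
    n_cultivars=5, trees_per_cultivar=(2, 3), miscall_rate=0.05, seed=7))
panel = truth.panel
print(f"{len(profiles)} samples at {len(panel)} markers")

matrix = pairwise_distances(profiles, panel, tolerance_bp=1)
groups = name_groups(threshold_cluster(matrix, cutoff=0.2))
scores = evaluate_recovery(groups, truth)
print(f"{len(groups)} molecular groups, ARI = {scores.adjusted_rand_index:.2f}")

by_id = {p.sample_id: p for p in profiles}
reps = [build_representative(g, by_id, panel) for g in groups]
print(f"unresolved CHECK positions: {sum(len(r.check_flags) for r in reps)}")
report = retrace_representatives(reps, profiles, groups, panel)
print(report[["group_id", "retraceable", "best_similarity"]].to_string(index=False))
print(f"retraceable fraction: {100 * retraceable_fraction(report):.0f}%")
```

prints

```
15 samples at 17 markers
5 molecular groups, ARI = 1.00
unresolved CHECK positions: 1
group_id retraceable  best_similarity
Pyr_0001       False         0.969697
Pyr_0002       False         0.969697
Pyr_0003       False         0.983607
Pyr_0004        <NA>              NaN
Pyr_0005        True         1.000000
retraceable fraction: 25%
```

All five cultivars are recovered exactly (ARI = 1.0) despite a deliberately
high 5 % per-allele sizing-error rate. The consensus step left one tied
position for review (`CHECK`), which makes group `Pyr_0004` unverifiable
until a curator settles it; of the four verifiable groups only one
representative matches a measured sample bit-exactly — the other three are
synthetic fingerprints whose best member similarity (0.97–0.98) and
per-position variant frequencies tell the curator where the disagreement
lives. At realistic noise (≈ 2 % miscalls) most groups are retraceable.

The same run is available from the shell:

```sh
curate simulate --n-cultivars 5 --seed 7 --out sim/
curate run --profiles sim/profiles.csv --panel sim/panel.txt --out curated/
```

which writes `groups.csv`, `representatives.csv` (ties as `CHECK`),
`consensus_log.csv` (one row per resolved/unresolved tie with the rule
applied), `retrace.csv`, `frequencies.csv`, `summary.csv` and a
deterministic `manifest.json`; `--xlsx` adds the four-sheet workbook layout
used by the published genebank deposit.

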