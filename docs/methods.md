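# Methods

## Data model

A sample's genotype at one SSR marker is the **set of distinct allele
fragment lengths** (AFLs, integer bp after binning), at most four per marker
(diploid and triploid pear cultivars carry 1–3; a fourth is tolerated for
unusual profiles). A single-peak marker contributes **one** allele to every
sum below — no homozygote doubling — consistent with the per-variant binary
encoding used for retraceability. An empty set means failed amplification
(missing data); on input, empty cells, `NA` and `0` all parse to missing.
Raw decimal sizes are accepted only for markers with an allele grid, via
nearest-grid snapping within a tolerance (ties toward the smaller grid
value); the snap is idempotent on grid values.

## Distance and clustering

The pairwise distance is one minus the Dice–Sørensen overlap,

    d = 1 − 2·Σ_m c_m / (Σ_m n_m(i) + Σ_m n_m(j)),

with the common-allele count `c_m` defined as a **maximum-cardinality
matching** in which allele *x* may pair with allele *y* iff |x − y| ≤ the
tolerance (default 1 bp), each allele pairing at most once. On sorted allele
lists the greedy two-pointer sweep attains the maximum (verified exhaustively
against brute-force enumeration in the tests). Multiplicity handling is not
uniquely determined by the verbal definition "common alleles"; maximum
matching is the least-surprising total rule and makes the count symmetric
and monotone in the tolerance.

Markers missing in either sample are excluded from numerator **and**
denominator, so amplification failure does not inflate the distance between
true replicates. A pair with no jointly amplified marker has no defined
distance (`NaN`): such pairs get no clustering edge and are listed in the QC
warnings rather than silently treated as identical or maximally distant.

Molecular groups are the **connected components** of the graph joining pairs
with distance ≤ the cut-off (default 0.2, i.e. ≥ 80 % identity; the cut-off
is inclusive). Components are the minimal reading of "grouped together at a
cut-off" (single linkage); the known chaining risk is why a complete-linkage
mode is exposed (`linkage="complete"`), in which incomparable pairs are
treated as distance 1.0. The cut-off is a parameter, not auto-selected; the
distance matrix can be written out for inspecting its distribution. Group
ids are `<prefix><running number>` (default `Pyr_`, zero-padded to four
digits, widening past 9999); the running order — descending size, ties by
smallest member id — is a determinism choice, not a semantic one.

## Consensus fingerprints

Per group and marker: members missing the marker are dropped; the **modal
allele count** among the remaining members fixes the number of positions
(ties prefer the larger count so triploid signal is not truncated to
diploid); only members with that count vote; per position (alleles sorted
ascending) the most frequent AFL wins; a tied vote yields the literal flag
`CHECK` instead of a value. "Position" is therefore defined on
ascending-sorted alleles — the operational reading of per-position voting
when member allele counts vary.

`CHECK` positions are then passed through ordered curation rules, applied to
the Cartesian product of tied candidates within the marker and filtered
progressively:

* **R1** — keep the combinations observed verbatim in the most members
  (prefer a fingerprint that exists in a measured sample);
* **R2** — keep the combinations with more distinct alleles (the more
  heterozygous call: a tied candidate that collapses onto an already-resolved
  allele is usually a dropped peak);
* **R3** — when the marker's repeat unit is known, keep combinations whose
  pairwise allele differences are whole repeat units (perfect-repeat loci
  should not yield off-ladder spacings; this is what rescues ±1 bp sizing
  ties);
* **R4** — otherwise the flag stays `CHECK` for human review.

A flag is resolved only when a unique combination survives, and every
decision (candidates, winner, rule) is logged — reviewability is part of the
contract, since the published workflow requires the output to be reviewed.
The precedence R1→R4 follows from "chosen from an existing sample if
possible"; beyond that the ordering is this package's choice.

The group's trueness-to-type code is the hierarchy minimum of the member
codes under 1 ≻ 5 ≻ 2 ≻ 3 ≻ 4 ≻ 0 (one true-to-type member certifies the
cultivar); members without an assessed code are skipped rather than mapped
to "not assessed". Cultivar names are resolved by the most common recorded
member name (ties to the lexicographically smallest); ploidy and PUNQ codes
are passthrough metadata. Sports cannot be separated molecularly and are
carried as names only.

### Majority voting is knife-edge sensitive — by design

Every sample votes once (replicates included), matching "most common AFL
across the samples of the group". A consequence worth stating: no multiset
majority can be invariant under duplicating an **arbitrary** member — a
duplicate of a one-vote-margin minority turns a 2-1 majority into a 2-2 tie,
and a duplicate of a rule-resolved tie's loser turns the tie into a strict
majority the other way. What *is* guaranteed, and tested: duplicating a
member never silently flips a strict-majority value to a different value —
at worst the position is sent back to review — and consensus is exactly
stable for unanimous groups and for positions carried by a margin of two or
more. Deduplicating identical profiles before voting would restore full
duplication invariance but would discard replicate agreement as evidence,
and is not done.

## QC

**Retraceability.** Representatives and members are binarized over the
ordered index of all observed (marker, AFL) variants; similarity is binary
Dice, 2|u∧v|/(|u|+|v|) (defined as 1.0 for two all-zero vectors, a logged
degenerate case). A group is *retraceable* iff some member matches its
representative at similarity exactly 1.0 — equivalently, identical variant
supports, which is how the comparison is computed, avoiding float equality.
Matching here is exact on variants (no ±1 bp): tolerance lives upstream in
grid snapping and distance calculation, not in the binary encoding.
Representatives still carrying `CHECK` are reported unverifiable, not false.
Comparison is within the representative's own group (the question is whether
the cultivar's fingerprint was actually measured in one of its samples).

**Variant frequencies.** Per resolved position: the fraction of members
amplified at the marker that carry the representative AFL (exact), plus the
arithmetic mean over positions. Members missing the marker are excluded from
the denominator. High-variability markers and doubtful consensus calls show
up as low frequencies.

**Collection accounting.** Per-location counts of final samples, distinct
trees and accessions among final samples, and molecular/pomological
coverage, with a totals row equal to the column sums. Because genotyped
profiles alone cannot express samples that were molecularly analysed but
later dropped, the summary accepts a per-sample record table with
`has_molecular`/`has_pomological`/`is_final` flags; a profile list is
adapted onto it (genotyped ⇒ molecular, trueness code ≠ "not assessed" ⇒
pomological). A deterministic builder expands the published per-location row
counts of the German pear collection into such records for checksum tests.

## Synthetic collections

The generator emulates a multi-site clonal genebank: per-marker allele pools
of 5–15 variants spaced by the repeat unit inside marker-specific size
windows (90–300 bp; dinucleotide repeat units — real allele spectra for
European pear are not published at this granularity, so pools and windows
are invented and draws are uniform); cultivar genotypes of 2 (diploid, 90 %)
or 3 (triploid, 10 %) alleles drawn with replacement and stored as distinct
sets; rejection sampling keeps true genotypes at pairwise distance > 0.3
(distinct cultivars are far apart at 17 markers); 1–3 trees per cultivar and
1–2 replicate samples per tree by default; 2 % of cultivars carry a named
sport. Perturbations, in order: per-allele ±1 bp miscall (default 2 %,
direction fair), per-(sample, marker) amplification failure (default 5 %),
per-sample mislabel of the *recorded name only* (default 2 % — mislabels are
the curation problem, not a genotyping error). Trueness codes are drawn from
a plausible curated-collection distribution (half true-to-type). All draws
come from one seeded `numpy` Generator, so a fixed seed reproduces the
collection byte-for-byte, and every perturbation is logged so the truth
replays exactly to the emitted profiles.

What the generator does **not** emulate: realistic allele-frequency spectra,
null alleles and allelic dropout correlated within markers, plate effects,
pedigree structure, or mutation accumulation in sports (sports share the
genotype exactly). Passing recovery tests therefore demonstrate the
pipeline's arithmetic and its robustness to independent sizing noise — not
performance on any particular real collection.

### Expected consensus error rates

With per-allele miscall rate ε split evenly over ±1 bp and n voters, a
position is silently flipped when ≥ ⌈n/2⌉+… — concretely, when more voters
miscall the same allele in the same direction than report it correctly; for
n = 5, ε = 0.1 that is ≈ 2·10·0.9²·0.05³ ≈ 2·10⁻³ per position, ≈ 6–7 % per
group over ~32 positions (ties, by contrast, are mostly rescued by R3
because ±1 bp errors break the repeat-unit spacing). Recovery experiments
therefore use groups of 5–10 members, where the measured recovery is ≈ 95 %;
at 2 % miscalls recovery is effectively complete. The simulated retraceable
fraction is similarly noise- and group-size-dependent (≈ 65 % under default
noise with small groups) and is not calibrated to reproduce any particular
collection's published fraction.

## Numerical and determinism choices

Distances are clamped to [0, 1] against float rounding; retrace equality is
integer/set-based, never float; vote ties break by flagging, name ties by
lexicographic order; group numbering is fixed by (size desc, smallest member
id). Problem sizes in tests and the acceptance script (50 cultivars,
250–400 samples) keep full runs in seconds while leaving binomial noise
small at the asserted thresholds. Pipeline outputs (CSV + JSON manifest)
contain no timestamps, so identical inputs and configuration give
byte-identical reruns; the optional XLSX export is excluded from that
guarantee because the zip container embeds write times.

## Known limitations

* Single-linkage components can chain distinct cultivars through
  intermediate noisy samples; the complete-linkage option and the distance
  histogram are the mitigations, and the cut-off is never auto-selected.
* The deposit workbook's exact header strings are not standardized; the
  layout object carries configurable defaults.
* Consensus positions are sorted-rank positions, not locus phases; with
  heavy dropout the modal-count rule can place minority triploid calls out
  of scope.
* Trueness propagation trusts member codes; it does not re-derive them from
  pomology.
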