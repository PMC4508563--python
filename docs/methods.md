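# Methods

This note documents the models and procedures implemented in `panbin`, the
parameters that matter, the synthetic-data model used to validate them, and
the numerical and design choices made where the design was genuinely open.

## Ortholog inference

### Alignment

All pairwise comparisons use exact Smith–Waterman local alignment with
affine gaps (Gotoh), computed by Biopython's C pairwise aligner. Defaults
are BLOSUM62 with gap open 11 and gap extend 1 in the BLAST convention (a
gap of length L costs 11 + L). Per-hit statistics are derived from the
optimal traceback:

- **percent identity** — identical columns / all aligned columns (gap
  columns count in the denominator);
- **percent positives** — columns with a positive substitution score,
  plus identical-residue columns (the latter matters only for rare X–X
  columns and keeps identity ≤ positives as an invariant; BLAST itself
  counts matrix-positive columns only);
- **coverage** — aligned span / sequence length, on each side separately.

Because the DP is exact, `all_vs_all` is deterministic and complete: every
pair scoring at or above the reporting floor (raw score 40 by default)
yields a hit. For large gene sets an optional prescreen skips pairs sharing
fewer than `min_kmer_matches` exact 5-mers. The prescreen is deterministic
(exact k-mer counting, not heuristic seeding) and is off by default; the
end-to-end pipeline profile enables it at 2 shared 5-mers, where two
250-residue proteins at 90% identity share ~145 5-mers in expectation while
unrelated pairs share ~0.02, so the screen removes essentially no true
family pair at the identities the pipeline targets. When score ties admit
several co-optimal tracebacks the reported statistics come from the
aligner's first traceback; scores are symmetric, per-hit statistics are
guaranteed to mirror only when the optimum is unique.

Externally computed hits in 12-column BLAST tabular format can replace the
built-in aligner anywhere (the 12-column dialect has no positives column;
positives are then conservatively set equal to identity).

### Reciprocal best hits and the AAI window

Per ordered genome pair, each gene's best hit is chosen by score, with ties
broken by higher identity and then lexicographically smaller subject id, so
results are reproducible. A provisional ortholog pair requires reciprocity
and coverage ≥ `min_cov` (default 0.70) on **both** sequences; the
single-sided reading is available via `cov_mode="query"`. The both-sided
default is the conservative choice: it rejects domain-only matches that a
query-only rule admits.

The provisional pairs' identities define the genome pair's AAI (mean) and
spread (population SD, so a 2-pair set still yields a defined window). The
identity filter removes pairs with identity < mean − `aai_window`·SD
(default 2.0), **one-sided**: discarding pairs for being *too similar*
would have no biological meaning. AAI is computed in a single pass on the
coverage-passing provisional set — no iteration, since re-estimating the
mean after filtering would make the criterion self-referential.

### Markov clustering

Accepted pairs across all genome pairs form an undirected graph with edge
weight identity/100 (raw score optional). Families are read off MCL:
self-loops are set to each node's maximum incident edge weight, columns are
normalized, and expansion (matrix squaring) alternates with inflation
(elementwise power `inflation`, default 2.0, then renormalization), pruning
entries below 1e-5, until the iterate changes by less than 1e-8 or 200
iterations (non-convergence returns the current clustering with a flag).
Clusters are attractor rows' supports, with overlapping supports merged.
Clustering runs per connected component — mathematically identical, since
expansion and inflation never create cross-component entries, and it keeps
the dense linear algebra on family-sized matrices. Family identifiers are
assigned by (size descending, smallest member id), so reruns are stable.

Multi-genome consolidation beyond MCL (three-way merging, synteny-based
splitting of multi-copy groups) is deliberately out of scope; groups with
more than one member per genome are reported by `flag_multicopy` for manual
examination instead.

## Core / flexible partition

Family presence is the number of distinct genomes with ≥ 1 member. CORE
requires presence ≥ `core_min_genomes`, defaulting to ⌈13/17·G⌉ — the 13-of-17
rule generalized proportionally, chosen because most bins are incomplete and
an all-genomes core would conflate absence from the lineage with absence
from the bin. UNIQUE covers single-genome families and all singletons;
everything else is shared non-core. The partition identity
(total genes = family genes + singletons) is asserted rather than assumed.

The category breakdown table cross-tabulates partition classes against an
externally supplied gene → COG-letter map; genes with two or more letters
are counted once under "Multiple assignments", genes with none (or only
unknown letters, which warn) under "Unassigned".

## Pan-genome accumulation

Accumulation deliberately uses a second, looser criterion than orthology —
≥ 50% positives over > 50% of the protein length, pairwise against each
prior genome — mirroring the two distinct protocols of the analysis this
package reproduces. "Protein length" is read as the length of the gene
being classified (query side).

Per trial, genomes are added in a random order; per step the counts are:

- `new` — genes of the added genome with no qualifying hit in any prior
  genome;
- `pan` — cumulative non-redundant gene count (`pan(k) = pan(k−1) + new(k)`,
  asserted per trial);
- `shared` — genes of the trial's **first** genome with qualifying hits in
  every genome added so far (the Tettelin core-curve convention; the
  alternative, order-free intersection has no per-step reference genome).

Normalization divides each count by the median protein count of the genomes
included *up to that step of that trial*; a global-median mode is available
(`global_median=True`) since the step-contextual reading is a choice, not a
given. Orders are sampled without replacement; when G! ≤ trials all G!
permutations are enumerated (exhaustion rule). Qualifying-hit sets are
precomputed once per ordered genome pair, so trials are pure set
operations.

Power fits are ordinary least squares on log y = log a + b·log x, exact on
noiseless power-law input. The new-gene fit excludes step 1 by default:
the first genome's full gene count is not an accumulation observation
(a flag includes it).

## Completeness and contamination

Completeness is 100 × distinct markers found / expected markers, reported
as an integer percent (rounded half away from zero, matching the precision
convention of bin-quality tables; full precision is retained internally).
Markers hit in ≥ 2 copies are contamination flags, sorted by copy count.
Marker identification itself (HMM search) is upstream; the module consumes
(gene, marker) hit tables.

Relative completeness is the fraction of the designated standard genome's
ortholog-family complement present in the scored bin — an intersection of
family sets, not a ratio of CSCG percentages. The two notions disagree
whenever the reference lineage lacks universal markers, which is exactly
the situation the metric exists for; by construction the standard scores
100% against itself.

## Composition and coverage signatures

%G+C uses fully contained windows (default 120 nt, step 30); N is excluded
from the denominator, all-N windows yield NaN. Tetranucleotide vectors tile
the scaffold in 5 kb windows (trailing partial windows ≥ 4 nt kept), count
overlapping 4-mers that do not span tile boundaries, skip 4-mers containing
non-ACGT characters, and normalize to frequencies summing to 1. Counting is
strand-specific over all 256 tetramers in lexicographic order; a canonical
136-dimensional reverse-complement collapse is available but off by
default, since the convention of the original binning scripts is unknown
and the 256-vector is lossless. Mean coverage is Σdepth / declared scaffold
length with absent positions contributing zero — the declared length comes
from the scaffold FASTA, never from the maximum observed position, so
unsequenced tails count.

## tRNA anticodon-loop usage

Positions 38/39/40 are located at fixed offsets +4/+5/+6 from the anticodon
start (anticodon at standard positions 34–36). This avoids full Sprinzl
alignment and is valid for canonical cloverleaves, where no length variation
occurs between the anticodon and position 40; records too short for the
offsets are skipped with a warning, and a stored anticodon that disagrees
with the sequence is an error. U is mapped to T at parse time (gene-space
convention). Counts are pooled across genomes within a group — the analysis
is population-level, not per-genome. Comparisons report Δ = freq_A − freq_B
per (isotype, position) cell for a chosen nucleotide, masking cells with
fewer than `min_n` (default 5) records in either group to avoid frequencies
estimated from one or two genes. Reference usage (e.g. database-derived
tabulations) arrives as TSV with counts or frequencies, auto-detected by
row sums.

## Synthetic-data model

The generator emulates a set of genome bins from one phylum:

| parameter | default | meaning |
|---|---|---|
| `n_genomes` | 17 | bins in the comparison |
| `n_core_families` | 200 | families placed in every genome |
| `n_flex_families` | 150 | families present per genome with `flex_presence_prob` (0.5) |
| `n_unique_per_genome` | 50 | fresh random genes per genome |
| `mean_protein_len` | 250 | gamma-distributed lengths (dispersion 0.3, min 50) |
| `within_family_identity` | 0.9 | expected pairwise identity within a family |
| `dropout_rate` | 0.0 | per-gene deletion probability (bin incompleteness) |
| `n_marker_families` | 105 | marker (CSCG-like) families drawn from the core |

Each family has one ancestral random protein; every member genome receives
a copy with i.i.d. substitutions, uniform over the 19 alternative residues,
with the per-copy rate p solving (1−p)² + p²/19 = target identity — simple
and analytically invertible, and symmetric by construction (expected
identity depends only on the family, not the order of comparison). Unique
genes are drawn fresh rather than diverged from any ancestor, so truth
labels are clean. Gene order within a genome is randomized. RNG streams are
keyed per genome and per family from the master seed, so adding genomes
never perturbs earlier ones, and dropout is applied last.

The tRNA generator emits records on a fixed 75-nt cloverleaf-like scaffold
with the anticodon at a known offset (canonical anticodons per isotype) and
positions 38–40 sampled from a per-(isotype, position) distribution that
must sum to 1 (±1e-9); unspecified positions are uniform.

**What the generator does not model:** indels within families (alignments
of family members are gap-free in truth), lateral transfer, composition
signal in protein sequences, contamination chimeras beyond injected
duplicate markers, realistic nucleotide genomes, and any correlation
between dropout and genomic location. Passing the planted-recovery suites
therefore shows the inference machinery is correct under the stated noise
model, not that real divergent proteomes will cluster as cleanly; with real
data the alignment statistics, not the clustering logic, carry the
additional uncertainty.

## Problem sizes and validation

The planted-recovery suite runs the full pipeline at the default study
shape — 17 genomes, 200 core + 150 flexible families, ~325 genes per
genome, within-family identity 0.9 — once without dropout (family recovery
is scored by Adjusted Rand Index against the planted assignment, ≥ 0.99)
and once at 15% dropout. Under dropout, the ≥13/17 core rule is scored
against the *attainable* core: planted core families whose surviving
members still span ≥ 13 genomes. The distinction matters: a core family
survives in ≥ 13 of 17 genomes with probability P(Bin(17, 0.85) ≥ 13) ≈
0.90, so recall against all planted core families is capped near 90% by the
dropout process itself, independent of any inference; recall against the
attainable core isolates what the pipeline controls (measured: 1.00, with
~1% false core calls). Smaller fixtures (5 genomes, 30+15 families) back
the per-module tests, and the alignment engine is checked against an
exhaustive enumeration of all local alignments on ≥ 500 short
reduced-alphabet pairs.

## Known limitations

- Exact DP without E-values: the reporting floor is a raw score, so hit
  lists are not calibrated for database size; external BLAST tabular input
  is the escape hatch for large inputs.
- The AAI window assumes the provisional identity distribution is roughly
  unimodal; a genome pair dominated by two divergence strata would get a
  too-wide window.
- MCL on identity weights does not use coverage or score information beyond
  the BBH filters.
- The 12-column tabular carrier is lossy for alignments with gaps at the
  block level (coordinates are reconstructed from coverage spans on write).
- Accumulation at G ≥ ~10 with 100 trials samples a vanishing fraction of
  order space; means are unbiased but trial-to-trial SDs understate the
  full permutation spread.
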