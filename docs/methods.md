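# Methods

This note documents the models and procedures implemented in `lichenbgc`,
the parameters that matter, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## MinHash sketching and Mash distance

Each genome is reduced to the bottom-`s` set of hashed canonical k-mers.
A k-mer's canonical form is the lexicographic minimum of itself and its
reverse complement, so a genome and its reverse complement sketch
identically. k-mers containing N are skipped (not substituted), and
k-mers never span contig boundaries.

k-mers are packed two bits per base into a 64-bit integer (first base
most significant, so integer order equals lexicographic order; this
limits `k` to 32, and `k ≥ 11` is required for meaningful sketches) and
scrambled with a SplitMix64 finalizer offset by a fixed seed of 42. The
hash is vectorized over numpy arrays and platform-stable, so sketches are
bit-reproducible across machines — the reason for choosing an explicit
integer finalizer over an environment-dependent hash.

Defaults `k = 21`, `s = 1000` are the customary Mash defaults for genome
comparison; at 1000 hashes the Jaccard estimator's standard error is
about `sqrt(j(1−j)/1000)`, giving roughly ±10–30% relative error on Mash
distances in the 0.005–0.05 range — adequate because the decision cutoffs
(0.005, 0.04) sit between well-separated distance modes. The Jaccard
estimate follows the Mash convention: among the `min(s, |union|)`
smallest hashes of the union of both sketches, the shared fraction.

The distance `d = −(1/k)·ln(2j/(1+j))` is capped at 1.0, and `j = 0` maps
to the cap (infinitely distant genomes). `1 − d` approximates ANI.

## Dereplication and species delineation

Average-linkage agglomerative clustering (scipy) of the all-pairs matrix
is cut so that merges with linkage distance ≤ cutoff are kept. Two
cutoffs with standing defaults:

- `0.005` (99.5% ANI) — dereplication of clonal re-isolates; the
  representative of each cluster is the lexicographically smallest
  genome id, a deterministic and id-stable choice.
- `0.04` (96% ANI) — putative species delineation; 96% ANI is the
  conventional prokaryotic species boundary.

scipy's linkage implementation breaks merge ties deterministically, so
cluster assignments are reproducible. Cluster ids are renumbered
contiguously from 0 in order of first appearance in the input id list.

## BGC catalog

Regions use 0-based half-open coordinates throughout; converters at the
I/O boundary handle external conventions. The region-JSON dialect is a
flat list of records (id, coordinates, products, contig-edge flag, gene
stubs, contig length); a separate reader extracts the same fields from
genuine antiSMASH 5 result JSON. The >5000 bp rule is applied to *contig*
length — the filter antiSMASH runs under — not region length; records
without a recorded contig length are assumed pre-filtered and retained.

Chemical classification maps each antiSMASH product subtype to one of
NRP, Polyketide, RiPP, Terpene, Saccharide or Other via a packaged table;
regions whose subtypes span more than one class are "hybrid", while
several subtypes within one class stay in that class. Unknown subtypes
fall back to Other with a warning rather than an error, since the
antiSMASH vocabulary grows between releases.

## Region-to-reference similarity

The score counts *distinct* query genes with at least one hit to the
reference, divided by the region's gene count, capped at 1. Distinct-gene
counting makes the score invariant to duplicated HSP rows and is the only
reading under which the maximum is 1. A second mode divides instead by
the number of distinct reference genes hit — the convention used when the
emphasis is on how much of the *reference* is covered; both modes agree
on the canonical 4/4 worked example. Bitscores are carried through for
provenance but do not enter the score. The link-table cutoff (default
0.2) is inclusive.

## GCF membership

Membership strata follow the BiG-SLiCE convention at clustering threshold
900: core `d ≤ 900`, putative `900 < d ≤ 1800`, orphan `d > 1800`, with
boundaries inclusive on the left-hand class. The thresholds are
parameters with these values as defaults. Percentages in summary tables
are rounded half-up to two decimals, matching the usual printed style.
Computing `d` itself (BiG-SLiCE pHMM featurization) is out of scope: the
tables are consumed, not produced. BGCs appearing in several datasets are
treated as distinct records; `dataset_label` disambiguates.

Dataset comparison reports GCF-set intersections for every label
combination plus each dataset's unique fraction; prevalence ranks GCFs by
the number of distinct genomes carrying a member BGC, ties broken
lexicographically.

## Molecular-family networking

Compound fingerprints are Morgan (circular) fingerprints, radius 2, 2048
bits, computed with RDKit; 2048 bits is the common width (the radius is
the scientifically meaningful parameter, the width only controls hash
collisions) and is recorded alongside outputs. Two references are joined
when the *maximum* Tanimoto over their compound pairs reaches 0.5 —
maximum because a reference is one node regardless of how many congeners
it lists, so a single sufficiently similar compound pair justifies the
edge. Thresholds are inclusive. References without a parsable compound
form no chemical edges; unparsable SMILES are logged and skipped rather
than fatal.

A molecular family is a connected component containing at least one query
node and at least one reference node: a component with no reference has
no chemistry anchor and is not an MF, and isolated queries are reported
separately. The `min_size` display filter (6 reproduces the usual
network-figure convention) affects only the reported list; totals always
refer to the unfiltered families, and both counts are exposed because
published MF tallies are ambiguous about which is meant.

## Synthetic data: what it does and does not emulate

Generators draw from one `numpy.random.default_rng(seed)` per call; there
is no global random state, and every byte of output is a function of
(parameters, seed).

- **Genomes** are i.i.d. base draws at a target GC (default 0.7,
  actinomycete-typical). Mutation applies independent per-site
  substitutions to a uniformly chosen different base. A strain panel
  derives one ancestor per species from a common root at `between_rate`
  (default 0.08) and strains from ancestors at `within_rate` (default
  0.002), giving intra-species distances near `2·within_rate` and
  inter-species near `2·between_rate` — cleanly separated by the 0.04
  cutoff. Real genomes have repeats, skew and horizontal transfer that
  compress Mash distances; passing tests show the estimator and
  clustering logic are correct, not that real assemblies are this
  well-separated.
- **BGC regions** draw product types from a weight table (defaults
  reflecting the NRP/PK-heavy class mix of actinomycete surveys), mark
  two sampled distinct types as hybrids with probability 0.2, set the
  contig-edge flag at rate 0.372 (the short-read assembly regime), and
  draw lengths uniform on 5–60 kb (mean 32.5 kb, matching the ~32 kb
  means such surveys report). Genes are coordinate stubs every ~2.5 kb;
  no sequence realism is attempted or needed downstream.
- **Reference libraries** anchor each planted compound family on one of
  ≥20 packaged drug-like scaffolds and decorate it with small
  substituents (single atoms or an ethyl chain added at a random
  position), which keeps within-family Tanimoto high. The planted
  property — within-family max-Tanimoto ≥ 0.5, between-family < 0.5 — is
  *verified at generation time*; violating members are re-decorated and,
  failing that, the family is rebuilt on a fresh scaffold, so downstream
  family-recovery tests are exact, not probabilistic.
- **Hit tables** plant `ceil(score · n_query_genes)` distinct hit genes
  per link, so planted scores are recovered exactly when
  `score · n_genes` is integral; noise links touch one gene of regions
  with > 5 genes, keeping noise scores strictly below the 0.2 cutoff.
- **GCF tables** draw each BGC's stratum from planted (core, putative,
  orphan) fractions and its `d` uniformly within the stratum's range
  ([0, 900], (900, 1800], (1800, 3000]). Default fractions are the exact
  count ratios typical of large actinomycete collections
  (0.6025/0.3598/0.0377).

## Problem sizes

The test suite and the end-to-end CLI demo run on deliberately small
instances — 50–200 kb genomes, panels of ≤ 12 strains, 200 regions, 3–4
compound families — chosen so planted effects are still recovered with
wide margins (e.g. rate recovery at 200 kb/s=1000 averages 20 seeds;
species recovery uses a 16× separation between within- and between-rates).
Scaling to hundreds of real assemblies is linear in pair count for the
distance matrix and quadratic in reference count for chemical edges.

## Known limitations

- The Mash distance → substitution-rate identity assumes i.i.d.
  substitutions and unique k-mers; repeat-rich genomes bias it.
- Gene stubs carry no sequence, so hit tables must come from an external
  homology search in real use.
- The membership analytics trust the input `d` values entirely.
- Percent rounding is half-up decimal; tables produced by other tools may
  use banker's rounding and differ in the last digit.
- The study-supplement ingester (`membership.read_dataset_s2`) matches
  columns heuristically by name; a spreadsheet with renamed columns needs
  manual mapping.
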