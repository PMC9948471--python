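# Methods

This note documents the models, decision rules and numerical choices behind
`longbin`, and what the synthetic benchmarks do and do not demonstrate.

## Synthetic communities (`longbin.simdata`)

**Genome model.** Each genome is drawn from an order-3 Markov chain over
{A,C,G,T}. The 64×4 transition table is sampled per genome from a symmetric
Dirichlet (concentration 5 — enough spread to give every genome a distinct,
stable tetranucleotide signature without near-deterministic contexts), then
exponentially tilted: G/C emission probabilities are multiplied by a common
factor `t`, renormalized per context, and `t` is solved by bisection so that
the chain's exact stationary GC (computed from the 64-state context chain)
equals the requested `gc_target`. Realized GC then deviates from target only
by sampling noise (<0.01 for ≥50 kb). The composition-based binners in this
package depend on genomes having distinct k-mer signatures; this model makes
that property explicit and controllable rather than incidental.

**Populations.** Intra-population diversity — the property that makes
hyper-diverse clades unassemblable — is modelled as independent per-strain
substitution at rate `d ∈ [0, 0.05]` (Binomial(L, d) sites per strain,
substitutions only). No indels, recombination or site-rate heterogeneity:
strains stay coordinate-aligned to the parent, so exact identities
(strain↔parent ≈ 1−d, strain↔strain ≈ 1−2d) are available as closed-form
test oracles.

**Markers.** A 16S-like marker family is simulated as one random ancestor
(default 1,500 bp) with per-taxon descendants at 10% divergence — mutually
alignable, separable by identity, like real rRNA. A genome embeds its marker
exactly once by slice replacement at a recorded position and strand.

**Reads.** Long mode draws lengths from a normal truncated at `min_length`
— mean 14,300 bp by default, the reported mean of the CCS read sets this
workflow targets; spread (sd 3,600) and error rate (0.005) are package
choices, since only the mean is commonly reported, and are configuration,
not claims about any instrument. Short mode emits 150 bp pairs from
~400 bp fragments. Read counts per member are multinomial with weights
`abundance × genome length`; start positions are uniform, wrapping through
the origin on circular replicons (truth intervals recorded with `end` beyond
`L`, i.e. modulo-L coordinates). Errors are applied after extraction:
80% substitutions, 10% single-base insertions, 10% single-base deletions of
the per-base rate. No quality-value simulation and no chimeras — identity
thresholds (95–99%) stay meaningful for near-accurate long reads, which is
the regime this analysis assumes. Demo and test communities use scaled-down
genomes (40–150 kb) and read sets (10²–10⁴ reads); every statistical check
accounts for its own sampling error, so the scale affects precision, not
correctness.

## Alignment engine (`longbin.mapping`)

Identity is `matches / alignment columns`, gap columns counted — the
convention all thresholds in this package assume. The engine is
seed-and-extend: exact k-mer seeds (k=15 for ≥90% identity contracts, k=11
below; sampled with a stride derived from the minimum alignment length) are
looked up in a hash index of the references, grouped by reference and
diagonal band, and each band is extended by banded edit-distance alignment
(edlib, band bound 1.5× the error budget implied by the identity gate) of
the read region against the implied reference window. The semi-global path
is then trimmed to its maximum-scoring local sub-path under match +1,
mismatch/gap −2 (run-level Kadane — exact, since an optimal window begins
and ends on match runs). When a reference window is clipped at sequence
bounds, the query region is clipped to the positions reachable within the
seed diagonals, so partial (end-hanging) alignments are still found.

Best-hit ties break by higher identity, then lexicographically smallest
subject id, then smallest subject start — RPKG is reproducible run-to-run.
Seeding is probabilistic: at the stated gates (e.g. 95%/50 bp) seed survival
exceeds 0.999 for the read lengths used; the engine is validated against a
full Smith–Waterman oracle (Biopython `PairwiseAligner` with the same column
scores) on ≤2 kb pairs, at ±0.5 identity points and ±5 bp interval
agreement. All identity/length gates are inclusive (≥) at the stated value.

## Marker genes (`longbin.marker16s`)

Candidates are local alignments of each sequence against the marker
reference set gated at Karlin–Altschul `E = K·m·n·e^(−λS) < 10⁻⁵` with the
+1/−2 match/mismatch scheme (λ solved from
`¼e^λ + ¾e^(−2λ) = 1`; gaps −5 open / −2 extend; K fixed at 0.3 — the gate
is a permissive screen, so the constant's precision is immaterial).
Validation replaces a covariance-model check with reference-model coverage:
a candidate must cover ≥50% of its best reference. Classification assigns
the best-identity reference's taxonomy when the read class passes its gates
(short: ≥80% identity and ≥90 aligned bases; long: segment ≥1,000 bases and
≥80% identity — the long-read identity floor is not separately standardized,
so 80% is applied to both classes and is configurable). Dereplication is
greedy longest-first at 97% identity over ≥90% of the candidate's length.
Taxon profiles pool groups at ≤1% (strictly "larger than" survives) into
"other" in the display table only; full counts are retained.

## Binning (`longbin.binning`)

**Contig binning.** Contigs ≥5 kb get the modal gene taxonomy when its
fraction over *all* genes (unlabeled ones count in the denominator; a config
switch excludes them) reaches 50%; an exact two-way tie cannot name one
taxon and is unclassified. Features per contig: top tetranucleotide-PCA
components (default 3), GC, and z-scored log10(RPKG+0.1) per metagenome
(RPKG spans orders of magnitude; the offset keeps zeros finite). The
original analysis binned with human curation; the automated surrogate is
DBSCAN within each taxonomy stratum with an adaptive radius
`max(eps, 2.5 × median nearest-neighbour distance)` — within-genome
neighbours sit far closer than contigs of different genomes in the whitened
feature space, so the radius tracks the local noise scale and degrades
gracefully when a stratum holds one genome. Unclassified contigs and noise
points join the nearest cluster within that cluster's 95th-percentile
internal radius, else stay unbinned. On the five-genome benchmark (distinct
signatures, GC 35–65%, three differential-coverage metagenomes) ARI ≥ 0.90.

**Seeded read binning.** Reads matching known genomes at ≥97% identity over
≥50% of their length are removed first. Features are trinucleotide-profile
PCA (plus log coverage when supplied), whitened. Seeds within 1.0 of each
other (single linkage) merge into one cluster; reads join their nearest
seed-cluster centroid within a gate of 2.5. Both gates were calibrated on
synthetic populations: at 2% internal divergence, seeds of one population
chain at <1 while distinct populations stay >1.4 apart. How the original
tool's "sensitivity" setting maps onto a distance gate is not recoverable,
so the gate is configuration. After the initial assignment, centroids are
re-estimated from members and reads re-assigned (≤3 deterministic
iterations): a single seed read is a noisy centroid estimate — its embedded
marker gene biases its own composition — and refinement removes that bias.

**Redundancy removal** follows greedy incremental clustering semantics
(`-G 0 -aS 0.9 -c 0.99 -g 1`): longest first, a read is redundant when a
local alignment to a kept read reaches 99% identity and covers ≥90% of the
*shorter* sequence, and it joins the best-matching (highest identity) kept
read. The operation is idempotent.

**Scaffolding** builds an overlap graph from dovetail alignments (≥99%
identity over >1,000 columns, ≤20 bp overhang at the joined ends) over
oriented reads; only unambiguous simple paths (internal nodes with exactly
one incoming and one outgoing overlap) are stitched, the earlier read's base
winning at disagreements; forks are never merged across, which is what
preserves strain structure.

## Recruitment (`longbin.recruitment`)

One best-hit alignment per read (multi-hit reads would inflate breadth);
breadth is the union of subject intervals over the unmasked genome length.
rRNA-like regions are masked out of both the mapping and the normalizing
length — the marker family is shared across taxa, so unmasked recruitment
cross-recruits marker reads between genomes and corrupts ANIr for rare
genomes (visible in the demo if masking is disabled). ANIr averages read
identities unweighted by alignment length (a length-weighted switch exists).
The presence rule is exactly "less than 3 RPKG → absent" and "<70% breadth →
absent", i.e. both bounds inclusive on the keep side. Multi-genome sweeps
take one best hit per read across the whole genome set (configurable).
Fragment ANI uses consecutive 1,020-bp fragments, keeping fragments at ≥30%
identity over ≥70% of their length; the symmetric variant averages both
directions and `ani(a,a) = 100` exactly. Peptide alignment for AAI is local
BLOSUM62 with affine gaps 11/1; a hit counts toward RBH only when it covers
≥50% of the query peptide and reaches 30% identity — without the coverage
gate, short high-identity local alignments between unrelated peptides
produce spurious network edges.

## Assembly QC (`longbin.assembly_qc`)

Circularity: an independent contig must align ≥250 bp at ≥95% identity
within the terminal window (2 × 250 bp — bounding the window keeps
mid-genome hits from counting) of *both* ends of the linearized genome,
reaching each terminus, with the two matches adjacent on the contig in
junction order on one strand. The same-contig, junction-consistent reading
is the default; requiring only either end is deliberately not sufficient. A
direct terminal repeat ≥250 bp at ≥95% is accepted as an independent
(assembler-style) circularity signal and reported separately. End hits that
never combine consistently give "ambiguous"; no evidence gives "linear"
(flagged when no contigs were supplied). Completeness and contamination are
percentages of a pluggable single-copy marker list present at all / more
than once; the reference-genome filter keeps genomes with completeness ≥40
and contamination ≤5 (the discard phrasing is strict, so boundary values are
kept).

## What the benchmarks show — and don't

Synthetic genomes have stronger, cleaner composition signatures than real
genomes, no repeats beyond chance, no mobile elements, and uniform read
sampling without GC bias; gene tables carry configurable but idealized
taxonomy noise. Passing benchmarks therefore demonstrates the correctness of
the decision rules, normalizations and clustering machinery under the stated
statistical models — not field performance on real metagenomes, where
composition separability and marker detectability are worse. The binning
gates (DBSCAN radius, seed gates) are calibrated to these synthetic
conditions and exposed as configuration for real data.

## Reproducibility

Every stochastic component takes an explicit seed; pipeline runs write a
resolved config copy and a SHA-256 checksum manifest, and identical
config+seed reproduce byte-identical tables. Exported coordinates are
1-based inclusive in tables (noted in headers) and 0-based half-open
internally.
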