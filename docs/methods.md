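# Methods

This note documents the models and procedures implemented in `hcoclass`,
the parameters that matter, the design decisions taken where several
readings were defensible, and what the synthetic data do and do not show.

## Scope and data model

The unit of analysis is one amino-acid sequence of the catalytic subunit
(subunit I) of a heme-copper oxygen reductase (HCO) or a nitric-oxide
reductase (NOR). The label set is closed: A1, A2, B, C, NOR, plus
UNCLASSIFIED as a classifier output only. A `ReferenceSet` couples
records with their curated labels and maintains a strict bijection
between the two.

Sequences are normalized on ingestion: uppercased, `*` stops stripped,
and the rare ambiguity codes B/Z/J/U/O folded to X with a logged warning
(rejecting them would make the tool unusable on real database records;
X participates in BLOSUM62 scoring). FASTA ids are the header token up
to the first whitespace, the remainder is preserved as description, so
label tables join on the id.

## Curation filters

Applied in a fixed order — length, metal ligands, redundancy — each
producing a report that conserves input ids, so stage-by-stage
accounting always sums to the input.

1. **Length ≥ 400** (default). Shorter entries are fragments that cannot
   carry the full channel fingerprints; the boundary value is kept.
2. **Six histidine ligands.** The record is globally aligned to an anchor
   sequence annotated with the six His positions (heme and Cu_B/Fe
   ligands); a gap or substitution at any mapped position fails. A
   record passes if it passes against *any* configured anchor (one HCO
   anchor, one NOR anchor by default) — the weakest reading consistent
   with checking a family-wide property without a fixed numbering.
3. **Redundancy.** Exact duplicate residue strings collapse first; then,
   among records sharing a species key (first two tokens of the
   taxonomy string — the binomial) *and* a type label, only one
   survives. All tie-breaks are by lexicographically smallest id, making
   curation deterministic. Duplicate detection is by exact sequence, not
   accession, since accessions are not always available.

All filters are idempotent; a curated set re-curated is unchanged.

## Alignment and similarity

Pairwise alignments are exact dynamic programming (no word-hit
heuristics): Smith–Waterman for local comparisons, Needleman–Wunsch
(end gaps penalized) for anchor-numbering transfer. Scoring is BLOSUM62
with affine gaps, open 11 / extend 1 — the classical protein-search
defaults. Traceback is deterministic (first optimal path of the
underlying aligner), which matters only for tie cases; optimal *scores*
are what the tests pin against an independent Gotoh implementation.

The similarity score of a directed comparison is

    sim(q → s) = 100 · positives / L_q

with *positives* the aligned residue pairs of positive substitution
score and `L_q` the number of alignment columns across the aligned query
segment, gap columns included (the "alignment length" convention that
accompanies a positives count). Directed values for the two orientations
are averaged; self-similarities are fixed at 100. A single best local
alignment is used per pair (not a sum of multiple segments) — a
documented choice, defensible for full-length subunit comparisons where
one dominant segment exists.

E-values use the Karlin–Altschul form `E = K·m·n·exp(−λS)` with the
gapped-BLOSUM62 constants λ = 0.267, K = 0.041 and the two sequence
lengths as m, n. No composition-based adjustment is applied: the E-value
exists to drive the 0.01 accept/discard rule and hit ordering, and
ranking by E at fixed lengths is ranking by raw score.

## Fingerprint typing

Anchor numbering is transferred onto a query through the global
alignment column map (anchor position → query position or gap). Evidence
is a fixed ten-feature vocabulary, each feature `present`, `absent` or
`gap`:

* `d_channel`: Tyr35, Asn113, Asp124, Asn131, Ser134, Ser193, Asn199 all
  present at their mapped positions (exact residue identity; a per-role
  tolerance would belong in profile data, not code).
* `d_channel_glu278` / `d_channel_tyr_at_278`: what occupies position
  278 — Glu defines A1, Tyr defines A2.
* `k_channel_A`: Lys354, Thr351, Ser291, Tyr280 (Tyr-I).
* `alt_k_channel_B`: Tyr-I retained, Thr/Ser/Tyr at the 354/351/291
  positions.
* `alt_k_channel_C`: Tyr-II — any tyrosine aligned within the helix-VII
  interval of the anchor — plus Ser/Tyr at the 351/291 positions. An
  interval test is the only implementable reading of a residue located
  only "in helix VII".
* `nor_motif_1` / `nor_motif_2`: the alignment-free motifs
  `H-X-(Arom)-X-E` and `H-H-X-(Arom)-(Arom)-X17-E`. Arom = {F, Y, W}
  (His excluded: the motifs spell their His explicitly); `X17` is
  exactly 17 arbitrary residues.

The decision rule is a fixed priority: both NOR motifs → NOR; D-channel
with Glu278 → A1; with Tyr278 → A2; D-channel absent with the C-type
alternative K-channel → C; with the B-type one → B; anything else is
undetermined (full evidence returned for downstream use, e.g. by the
best-hit classifier). The table is a pure function of the evidence
vector and is tested by exhaustive enumeration.

## Best-hit classification and benchmark

Hits against the labelled reference set are ranked by ascending E-value,
ties by descending raw score then ascending subject id. With no hit
under the cutoff (default 0.01) the status is `no_hit` and the reported
message is "cannot be classified". Top-1 transfers the best hit's label
unconditionally; top-k (k = 2, 3, 5) requires the first k passing hits
to agree, else `unclassified`. With fewer than k passing hits, agreement
is evaluated over those available and the result flagged as truncated —
small reference sets should not be forced into refusals.

Leave-one-out cross-validation classifies each reference sequence
against the remaining ones. Counting: a correct prediction increments
Tp(true type); a wrong one increments Fp(predicted) and Fn(true);
unclassified/no-hit increments Fn(true) and the unclassified counter, so
Σ(Tp+Fn) always equals the number of queries. Precision and recall are
Tp/(Tp+Fp) and Tp/(Tp+Fn); empty denominators yield NaN (reported as
"NA"), never 0 or 1, to avoid silently inflating a benchmark. The
"global" statistic is micro-averaged over the pooled counts — with
imbalanced classes this is the standard single-number summary, and when
every query is classified it makes global precision equal global recall.

## Network and trees

The similarity network has one node per sequence (type as attribute) and
one weighted edge per unordered pair with similarity ≥ `min_edge`
(default 0, i.e. all nonzero relationships). Cluster statistics are
arithmetic means of pairwise similarities, within types (unordered
distinct pairs; NaN for singletons) and between types (all cross pairs).
No layout is computed; the graph exports as a TSV edge list or GraphML
for external viewers.

Distances are the linear transform `d = (100 − sim)/100`. No
multiple-substitution (e.g. Kimura) correction is applied: the tree's
role here is clustering consistency, not branch-length estimation.
Neighbor joining is the classical Saitou–Nei agglomeration with two
documented numerical choices: Q-matrix ties break on the
lexicographically smallest pair of representative leaf names (full
determinism), and a negative branch length is clamped to zero with the
deficit moved to its sibling, preserving the pair's distance sum (the
final trifurcation only clamps). On additive matrices NJ is exact; the
tests require exact topology recovery and path-length reconstruction to
1e−9 on random additive matrices of 5–12 leaves.

Bootstrap support operates on a user-supplied fixed multiple alignment —
this package does not build MSAs — by column resampling: per replicate,
p-distances (gapped columns excluded pairwise) feed NJ, and internal
edges of the full-alignment tree are annotated with the frequency of
their bipartition among replicates. The default of 100 replicates is a
desk-scale choice; the replicate count trades precision of the support
estimate against runtime, nothing else.

## Synthetic data: what it emulates, what it does not

`simulate` builds five type templates of 520 residues from one random
ancestor scaffold at 50% between-template divergence — deep but
globally alignable homology, like the real families — each carrying its
full fingerprint at the canonical positions (role positions reuse the
reference numbering, e.g. Asp124 at template position 124; His ligands
at 94/276/325/326/411/413; Tyr-II interval 430–460). A ±3 window around
every anchored feature is held identical across templates: functional
residues sit in conserved context in real alignments, and those flanks
are what keeps anchor-numbering transfer exact. Templates are designed
once (deterministic seed), verified to self-type, scrubbed of spurious
NOR motifs, and frozen as packaged data labelled synthetic; they are not
copies of database entries.

Families are drawn by independent per-site substitution (uniform over
the 19 alternatives). With `protect_fingerprint` (the default), role
positions, the Tyr-II interval and a 24-residue window downstream of
every histidine are immutable, and His is excluded from the substitution
alphabet. Both NOR motifs are His-anchored and fit inside such a window,
so protected mutation can neither destroy a planted fingerprint nor
create a spurious one — which is what makes 100% fingerprint recovery a
meaningful invariant rather than a statistical accident.

The benchmark conditions are five families × 30 sequences at 15%
per-site substitution (the network/classifier checks) and 20% for the
fingerprint-robustness check; these sizes keep the full all-vs-all
(22,350 ordered alignments) at a few minutes on one CPU. At 15%
substitution within-type mean similarity lands near 80–84% with
cross-type means near 41–46% — the same qualitative structure (tight
type clusters, weaker but nonzero between-cluster similarity) that
validates real curated sets.

What passing these tests does **not** show: the generator has no indels,
no rate heterogeneity, no compositional bias, and between-family
divergence is homogeneous, so real-data performance near type boundaries
(e.g. sequences lacking channel residues entirely, which are
undetermined by fingerprints and must be resolved by best-hit transfer)
is not measured here. Real reference sets also contain label noise and
fragmentary entries that the curation filters, not the classifier, must
absorb.

## Degenerate inputs and numerical notes

Empty local alignments (no positive-scoring residue pair) carry span 0
and undefined similarity; `all_vs_all` maps them to similarity 0.
Self-comparisons are never aligned; the diagonal is 100 by definition.
The Q-matrix of neighbor joining is evaluated on the upper triangle only
(floating-point subtraction order makes the two triangles differ in the
last bit). Seeds: every stochastic routine takes an explicit integer
seed; derived seeds stay below 2^31.
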