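# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic data does and does not emulate,
and the design decisions taken where the methods left genuine freedom.

## Data model

A template alignment is a gapped multiple sequence alignment over the RNA
alphabet; symbols are uppercased and T→U-normalized at ingest, gap
characters (`-`, `.`, `~`) are unified, and non-IUPAC symbols become gaps
with a warning. IUPAC ambiguity codes are retained as literal symbols in
rows but count as gaps in every statistic, because the composition
denominator enumerates only A/C/G/U. Columns are 0-based internally;
every serialized or logged coordinate is 1-based inclusive.

A sequence is *5'-partial at column i* when its first non-gap column lies
beyond *i* (3'-partial symmetrically). Taxonomy is a rooted tree of named
nodes built from semicolon-separated lineage strings; a taxon's sequence
set is its whole subtree.

## Column statistics and blocks

**Conservation** C_i is the fraction of counted sequences bearing a
nucleotide at column *i*; partial sequences are excluded from numerator
and denominator, so truncated sequences do not depress conservation at
the columns they miss. If every sequence is excluded, C_i := 0 with a
warning. A consequence worth knowing: a column outside every sequence's
span cannot exist in a valid alignment, and the first and last columns
are always conserved among the sequences that reach them.

**Composition** N_i(p) is the fraction of nucleotide-bearing sequences at
*i* carrying *p*; it has no partial-sequence exclusion (a gap simply does
not carry a nucleotide) and always sums to 1 on non-empty columns.

**Blocks.** Columns with root conservation strictly greater than the
cutoff (default 0.80) are highly conserved; blocks hold a fixed count of
them (default 16, within the recommended 15–20; the toy fixtures use 5).
A block runs from the column after the previous block's last conserved
column through its own last conserved column; the final block extends to
the alignment end and may hold fewer conserved columns. Block boundaries
are fixed at the root; within each taxon the conserved set is recomputed
by the same rule inside each block's interval, so a block may hold, say,
six conserved columns in a subgroup and five in its parent.

**The block score.** For a subsequence placed on a block's conserved
columns Y, occupying Z ⊆ Y with nucleotides S_j,

    SC(b) = (Σ_{i∈Z} C_i) / |Y| + w · (Σ_{j∈Z} N_j(S_j)) / |Z|,

with composition weight w = 0.8, so the ceiling is 1 + w = 1.8. The
conservation term divides by |Y| (missing conserved columns are
penalized); the composition term divides by |Z|. An empty Z scores 0 with
a warning. C and N are always those of the *scoring taxon*, not the root.
Per-taxon statistics carry each block's per-sequence scores, their mean,
and the min/max residue counts per block (used only to bound candidate
subsequence lengths during matching).

Statistics exist for every taxon with at least `min_sequences` template
sequences (default 5, within the conventional 3–10 range) and for all of
their ancestors.

## The block-profile aligner

Taxon selection: an exact name-hint match against the template taxonomy
selects the lowest ancestor-or-self with statistics; otherwise a
superficial pass (strict stage only, no taxonomy climb) is run against
every statistics-bearing taxon at depth ≤ 6 and the taxon aligning the
most residues wins, ties to the shallower node.

**Strict stage.** A block is eligible at the lowest taxon of the lineage
where its mean score reaches 0.9 × max (1.62 by default). Candidate
placements map the block's conserved columns to strictly increasing query
positions inside the window between already-anchored neighbours; every
conserved column must receive a residue whose nucleotide was *observed*
at that column in the scoring taxon (the operational meaning of
"extremely similar" here), and the residue run between two matched
columns may exceed the template columns between them by at most 2.
Candidates are ranked by score, then fewest indels, then leftmost
position. One match commits per sweep — the highest-scoring one anywhere,
with the margin over its runner-up placement as tie-break — so strong
blocks anchor the windows before weak ones are decided. Blocks with fewer
than 4 conserved columns never anchor via this stage: a 2–3-column match
carries too little signal and a wrong early anchor poisons every
neighbour.

**Relaxed stage.** The threshold drops once by the relaxation factor
(×0.8 → 1.296) and deletions of conserved columns become legal. Rather
than re-enumerating per block — where thousands of near-tied placements
make the commit order fragile — each maximal run of unmatched blocks
between two anchors is placed *jointly* by a dynamic program maximizing
the summed per-column gain (C_i + w·N_i)/|Y_b|, with bounded insertions,
up to 12 consecutive deletions, and a 1e-4 per-position penalty for
drifting off the anchor-implied diagonal (a pure tie-break, far below any
composition signal). Each block's realized score is then evaluated with
the exact formula and the block commits only if it clears the threshold.
A config flag allows further geometric relaxations (default off).

**Fill.** Remaining residues are placed order-preservingly between their
flanking anchors by the same per-column gain, with residues that do not
fit reported as insertion annotations `(residue, after-column)`; the
template is never widened.

## The structure-descriptor engine

**Descriptor (stage 1).** Base pairs at column level are reduced to a
nested skeleton (greedy, first-kept wins; crossing pairs are set aside as
tertiary constraints and not searched). Maximal stacked runs form
helices; the ordered element list (helix 5'/3' strands, hairpin loops,
internal/multistem regions, tails) tiles the columns 5'→3'. For the root
and every taxon with `min_sequences` members, each element carries a
length histogram (non-gap residue counts, frequency-weighted),
per-position nucleotide profiles (5'-anchored; helix 5' strands anchored
at their loop-proximal end), and per-helix mispair histograms
(column-level pairs with both residues present that are not
AU/UA/GC/CG/GU/UG). The section cutoff is the minimum over template
members of the summed log2 length- and mispair-weights, which makes the
template self-consistent by construction. The descriptor serializes as a
versioned YAML document (structure, sections, cutoffs); reader and writer
round-trip losslessly. The weight arithmetic (log-sum of frequencies,
min-member cutoff) is this package's documented formulation.

**Search (stage 2).** Elements rank by the expected number of chance
occurrences in an i.i.d. uniform sequence of the query's length
(profile-support product × length multiplicity × length); lower is more
stringent. Search seeds at the best occurrences of the top-ranked element
(falling back to the next rank if no complete model emerges) and extends
one adjacent element per round, alternating 5'/3' while both sides are
open. Candidate lengths come from the histogram (by weight), then — if
exception budget remains — out-of-support lengths up to the maximum
observed + 2. Out-of-histogram lengths and out-of-profile residues cost
one exception each (helix strands are charged per strand, so one extra
helix pair costs two); residues beyond every observed length carry no
per-residue charge — the length exception already prices them. Each round
checks helix pairing (mispairs beyond the histogram cost an exception)
and the elongating weight score against the cutoff. Among complete
models the best total score wins, where residues left outside the covered
span are charged 6 bits each so in-profile coverage always beats
truncation; otherwise the best partial (most elements, then score). The
search is exhaustive within a node budget and fully deterministic.

**Alignment (stage 3).** Requires a complete model; partial models raise
an error (the CLI offers `--fallback block`). The query splits into
per-element fragments; the reference is the template sequence maximizing
the per-element average of 0.5·length-agreement + 0.5·anchored identity
(the equal weighting is this package's choice; ties go to template
order). Helix fragments are juxtaposed onto the reference's strand
columns anchored at the closing pair, overflow continuing into the
element's spare columns and then insertion annotations at the loop-distal
end. Single-strand fragments are placed by an order-preserving DP over
the element's columns maximizing conservation + w·composition, with a
bonus of 2.0 (above the 1.8 gain ceiling) for the reference's own
columns: equal-length fragments therefore land exactly on the reference's
columns, and only residues the reference cannot explain are decided by
conservation. This makes juxtaposition against the chosen reference the
primary rule and conservation the arbiter of length mismatches.

## Evaluation metrics

PSI(i, j) = |B|/|E| with B the both-occupied and E the either-occupied
column sets; columns gapped in both rows are ignored; |E| = 0 is an
error. As written this measures co-occupancy, not residue identity, so a
matched-residue variant (identical nucleotides within B, over |E|) is
exposed behind `mode="identity"`; identity *binning* of diverged rRNA
pairs is generally only meaningful with the variant. The default remains
the verbatim co-occupancy form.

Accuracy compares *stacks*: each reference column in E contributes the
pair (residue ordinal in i or gap-state, residue ordinal in j or
gap-state); S is the set of reference stacks reproduced exactly in the
test alignment and accuracy = |S|/|E|. Stacking against a gap is a stack
state and must match to count. The measure is symmetric in i and j, and
accuracy(test, test) ≡ 1. Binned summaries are left-closed, right-open,
last bin closed; empty bins are absent, not zero.

## Synthetic data

`synth_template` builds templates from repeating 100-column units: a
19-column conserved strand, an 8-bp helix, a 17-column loop with a
10-column variable region, the closing strand, and a 48-column connector
with a 20-column variable region. A random root ancestor (helix partners
complementary) is mutated per taxon and again per sequence at the
substitution rate (default 0.05 per residue; helix substitutions are
compensatory except a 10% fraction left as mispairs); indels occur only
inside the variable regions (default rate 0.02 per variable column),
where every third column starts empty to provide insertion capacity. The
grid itself is therefore the truth: each residue's correct column is its
column in the generating row. `synth_queries` derives queries from rows
by substitutions (never indels, which would invalidate the truth) and
optional end-truncation; `sample_from_descriptor` draws sequences from a
descriptor's histograms and profiles, with the length vector
rejection-sampled against the cutoff and helix pairs drawn canonically,
so sampled sequences satisfy the descriptor without exceptions.

What this emulates: taxonomic structure, column-wise conservation
gradients, localized indel hotspots, compensatory helix evolution. What
it does not: rate heterogeneity along a real phylogeny, alignment
ambiguity in repetitive regions, chimeras, sequencing error, and the
scale and curation history of real rRNA templates. Passing the synthetic
benchmarks therefore demonstrates correctness of the machinery under the
stated generative assumptions, not field accuracy on curated 16S data.

Problem sizes used by the test suite: the worked-example template
(10 × 34), a 200-column synthetic template for unit-level checks, and a
600-column, 30-sequence template (3 taxa × 10, substitution 0.05, seed 1)
for the leave-one-out self-recovery benchmark; structure-search
completeness uses 200 descriptor-sampled sequences; scaling is asserted
as a log-log trend over 40/80/160-sequence templates.

## Numerical and degenerate-input conventions

Score comparisons use a 1e-12 slack; the candidate search and the
extension search carry node budgets (1e5–2e5) that truncate, never
corrupt, their enumerations; all tie-breaks (leftmost position, fewest
indels, descriptor order, template order, shallower taxon) are explicit
and deterministic, and every random fixture is seeded. Degenerate cases:
all-excluded columns score conservation 0 with a warning; empty
subsequences score 0 with a warning; an alignment with no highly
conserved columns cannot be partitioned (error); queries aligning zero
blocks come back as reportable unaligned results, not exceptions.

## Known limitations

Statistics rebuild from scratch on template edits (no incremental
update). The relaxed stage's joint placement assumes anchors from the
strict stage are trustworthy; a template whose every block is ambiguous
at the strict threshold (as engineered in parts of the toy fixture)
can mis-place low-information blocks. Helix strands are constrained
independently, so a full inserted pair costs two exceptions. Pseudoknots
are flagged, never searched. The original descriptor syntax of the tool
family this package modernizes was not published; the YAML dialect here
is its own documented format.
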