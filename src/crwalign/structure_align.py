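"""Structure-guided alignment into the template: stage 3.

A query with a complete structure model is split into fragments, one per
structural element.  The template sequence most similar to the query —
judged per element by fragment-length agreement and sequence identity,
weighted equally — becomes the reference.  Helix fragments are juxtaposed
structurally: residues are assigned position-by-position onto the
reference's helix columns anchored at the helix's closing (loop-proximal)
pair, with gaps pushed to the loop-distal end on length mismatch.
Single-strand fragments are placed by conservation: an order-preserving
dynamic program maximizes the summed composition values of the assigned
columns (with a whisper of preference for the reference's own columns).
Residues that exceed an element's column capacity become insertion
annotations; the template is never widened.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config import Config
from .core import (
    GAP,
    AlignedSequence,
    ConfigurationError,
    QuerySequence,
    TaxonomyTree,
    TemplateAlignment,
)
from .descriptor import (
    Descriptor,
    Element,
    PartialModelError,
    build_descriptor,
)
from .stats import ColumnStats, column_profile
from .structure_search import StructureInstance, extend_model


@dataclass
class Fragment:
    element_index: int
    kind: str
    start: int  # query interval, inclusive; empty fragment: end < start
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def residues(self, sequence: str) -> str:
        return sequence[self.start : self.end + 1]


@dataclass
class StructureAlignmentResult:
    query: QuerySequence
    row: str
    reference_id: str
    instance: StructureInstance
    insertions: list[tuple[int, int]] = field(default_factory=list)
    # (query residue index, column after which it sits)


def fragment_sequence(instance: StructureInstance) -> list[Fragment]:
    """Split a completely modelled query into per-element fragments.

    Fragments tile the matched span in element order; partial models are
    rejected (stage 3 requires the sequence to be complete).
    """
    if not instance.complete:
        raise PartialModelError(
            f"structure model for {instance.query_id!r} is partial; "
            "stage 3 requires a complete model"
        )
    frags = [
        Fragment(idx, "", s, e)
        for idx, (s, e) in sorted(instance.intervals.items())
    ]
    return frags


def _element_residue_columns(
    seq: AlignedSequence, element: Element
) -> list[int]:
    return [c for c in element.columns if seq.symbols[c] != GAP]


def _identity(a: str, b: str, anchor_end: bool) -> float:
    """Fraction of matching residues under 5'-anchored comparison (or
    3'-anchored for helix 5' strands)."""
    if not a and not b:
        return 1.0
    if anchor_end:
        a, b = a[::-1], b[::-1]
    hits = sum(1 for x, y in zip(a, b) if x == y)
    return hits / max(len(a), len(b))


def choose_reference(
    fragments: Sequence[Fragment],
    query_sequence: str,
    template: TemplateAlignment,
    descriptor: Descriptor,
    length_weight: float = 0.5,
) -> AlignedSequence:
    """The template sequence most similar to the query, element by element.

    Similarity per element = length_weight * length agreement
    + (1 - length_weight) * anchored identity, averaged over elements;
    ties go to template order.
    """
    if not len(template):
        raise ConfigurationError("empty template")
    elements = descriptor.structure.elements
    best: Optional[tuple[float, int]] = None
    best_seq = template.sequences[0]
    for order, seq in enumerate(template.sequences):
        total = 0.0
        for frag in fragments:
            el = elements[frag.element_index]
            ref_res = "".join(
                seq.symbols[c] for c in _element_residue_columns(seq, el)
            )
            q_res = frag.residues(query_sequence)
            if not ref_res and not q_res:
                agree = 1.0
            else:
                agree = min(len(ref_res), len(q_res)) / max(
                    len(ref_res), len(q_res), 1
                )
            ident = _identity(q_res, ref_res, anchor_end=el.kind == "helix5")
            total += length_weight * agree + (1 - length_weight) * ident
        score = total / max(len(fragments), 1)
        key = (-score, order)
        if best is None or key < best:
            best, best_seq = key, seq
    return best_seq


def _place_helix_strand(
    frag: Fragment,
    element: Element,
    reference: AlignedSequence,
    assignment: dict[int, int],
    insertions: list[tuple[int, int]],
) -> None:
    """Assign helix-strand residues onto columns anchored at the closing pair.

    The 5' strand anchors at its 3' end, the 3' strand at its 5' end.
    Reference-occupied columns are used first, then the element's spare
    columns continuing outward; residues beyond the column capacity are
    recorded as insertions at the loop-distal end.
    """
    ref_cols = _element_residue_columns(reference, element)
    spare = [c for c in element.columns if c not in set(ref_cols)]
    if element.kind == "helix5":
        cols = list(reversed(ref_cols)) + sorted(
            (c for c in spare), reverse=True
        )
        residues = list(range(frag.end, frag.start - 1, -1))
        distal_anchor = element.columns[0] - 1
    else:
        cols = ref_cols + sorted(spare)
        residues = list(range(frag.start, frag.end + 1))
        distal_anchor = element.columns[-1]
    for k, q in enumerate(residues):
        if k < len(cols):
            assignment[q] = cols[k]
        else:
            insertions.append((q, distal_anchor))


def _place_single_strand(
    frag: Fragment,
    element: Element,
    reference: AlignedSequence,
    profile: Sequence[ColumnStats],
    query_sequence: str,
    assignment: dict[int, int],
    insertions: list[tuple[int, int]],
) -> None:
    """Conservation-driven placement.

    An order-preserving DP maximizes the summed per-column gain
    (conservation + weighted composition, plus a dominant bonus for the
    reference's own columns) of the assigned columns.  Equal-length
    fragments therefore land exactly on the reference's columns; length
    mismatches are resolved by conservation, with true insertions
    drifting into low-conservation columns.
    """
    residues = list(range(frag.start, frag.end + 1))
    columns = element.columns
    m, n = len(residues), len(columns)
    if m == 0:
        return
    ref_occupied = set(_element_residue_columns(reference, element))
    # exceeds the largest possible conservation+composition gain (1.8), so
    # the DP juxtaposes the fragment against the reference's own columns
    # wherever it can, and falls back to conservation only for residues
    # the reference cannot explain
    REF_BONUS = 2.0
    EPS_INS = 1e-6
    NEG = float("-inf")
    dp = [[0.0] * (n + 1) for _ in range(m + 1)]
    back = [[0] * (n + 1) for _ in range(m + 1)]  # 0 skip col, 1 assign, 2 skip res
    for i in range(m + 1):
        for j in range(n + 1):
            if i == 0 and j == 0:
                continue
            best, move = NEG, 0
            if j > 0 and dp[i][j - 1] > best:
                best, move = dp[i][j - 1], 0
            if i > 0 and j > 0:
                nt = query_sequence[residues[i - 1]]
                col = columns[j - 1]
                cs = profile[col]
                gain = cs.conservation + 0.8 * cs.composition.get(nt, 0.0)
                if col in ref_occupied:
                    gain += REF_BONUS
                cand = dp[i - 1][j - 1] + gain
                if cand > best:
                    best, move = cand, 1
            if i > 0:
                cand = dp[i - 1][j] - EPS_INS
                if cand > best:
                    best, move = cand, 2
            dp[i][j], back[i][j] = best, move
    i, j = m, n
    while i > 0 or j > 0:
        move = back[i][j]
        if move == 0:
            j -= 1
        elif move == 1:
            assignment[residues[i - 1]] = columns[j - 1]
            i -= 1
            j -= 1
        else:
            anchor = columns[j - 1] if j else element.columns[0] - 1
            insertions.append((residues[i - 1], anchor))
            i -= 1


def align_by_structure(
    instance: StructureInstance,
    template: TemplateAlignment,
    descriptor: Descriptor,
    profile: Optional[Sequence[ColumnStats]] = None,
    reference: Optional[AlignedSequence] = None,
) -> StructureAlignmentResult:
    """Build the query's gapped template row from its structure model."""
    fragments = fragment_sequence(instance)
    if profile is None:
        profile = column_profile(template.sequences, template.width)
    if reference is None:
        reference = choose_reference(
            fragments, instance.sequence, template, descriptor
        )
    elements = descriptor.structure.elements
    assignment: dict[int, int] = {}
    insertions: list[tuple[int, int]] = []
    for frag in fragments:
        el = elements[frag.element_index]
        if frag.length == 0:
            continue
        if el.is_helix:
            _place_helix_strand(frag, el, reference, assignment, insertions)
        else:
            _place_single_strand(
                frag,
                el,
                reference,
                profile,
                instance.sequence,
                assignment,
                insertions,
            )
    row = [GAP] * template.width
    for q, col in assignment.items():
        row[col] = instance.sequence[q]
    # residues outside the matched span (flanks) are insertions
    span_lo = min(s for s, _ in instance.intervals.values())
    span_hi = max(e for _, e in instance.intervals.values())
    for q in range(0, span_lo):
        insertions.append((q, -1))
    for q in range(span_hi + 1, len(instance.sequence)):
        insertions.append((q, template.width - 1))
    insertions.sort()
    query = QuerySequence(instance.query_id, instance.sequence)
    return StructureAlignmentResult(
        query, "".join(row), reference.id, instance, insertions
    )


def align_with_structure(
    template: TemplateAlignment,
    taxonomy: TaxonomyTree,
    queries: Sequence[QuerySequence],
    descriptor: Optional[Descriptor] = None,
    taxon: str = "root",
    config: Config = Config(),
) -> list[StructureAlignmentResult]:
    """Full stage 1-3 pipeline for a batch of queries.

    Raises :class:`PartialModelError` for queries whose structure model is
    incomplete; callers wanting a fallback should catch it and use the
    block-profile engine.
    """
    if descriptor is None:
        descriptor = build_descriptor(
            template, taxonomy, min_sequences=config.min_sequences
        )
    section = taxon if taxon in descriptor.sections else "root"
    profile = column_profile(template.sequences, template.width)
    out = []
    for q in queries:
        inst = extend_model(
            q.symbols,
            descriptor,
            taxon=section,
            max_exceptions=config.max_exceptions,
            query_id=q.id,
        )
        out.append(
            align_by_structure(inst, template, descriptor, profile=profile)
        )
    return out
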