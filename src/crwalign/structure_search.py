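"""Seed-and-extend identification of descriptor elements in a sequence.

Stage 2 of the structure engine.  Elements are ranked by stringency — the
expected number of chance occurrences of the element in an i.i.d. random
sequence of the query's length (frequency-profile support x length-range
multiplicity); lower expectation = more stringent = better seed.  Search
starts from the best occurrences of the most stringent element and
extends the placed span alternately 5' and 3', one adjacent element per
round, choosing each element's length from its observed histogram.  A
consistency check runs every round: residues must be drawn from the
element's per-position profile support, helix strands must pair with no
more mispairs than the template ever showed, and the elongating model's
total log-weight must stay above the descriptor's cutoff.  Observations
outside the histograms cost one exception each against a user budget;
with budget exhausted the extension dies and the best partial model is
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .core import FormatError
from .descriptor import (
    ROOT_SECTION,
    Descriptor,
    Element,
    ElementConstraint,
    TaxonSection,
    is_canonical,
)
from .io import structure_to_string, write_structure

_LOG_EPS = -20.0  # log2 weight charged to exception observations


@dataclass
class SeedRanking:
    """Elements ordered by stringency (ascending chance-occurrence score)."""

    scores: dict[int, float]  # element index -> expected chance matches
    order: list[int]


@dataclass
class StructureInstance:
    """A (possibly partial) placement of descriptor elements on a sequence.

    ``intervals`` maps element index to (start, end) inclusive, 0-based;
    a zero-length element has end = start - 1.
    """

    query_id: str
    sequence: str
    intervals: dict[int, tuple[int, int]] = field(default_factory=dict)
    complete: bool = False
    exceptions_used: int = 0
    score: float = 0.0
    trace: list[str] = field(default_factory=list)

    def element_length(self, index: int) -> int:
        s, e = self.intervals[index]
        return e - s + 1

    def pairs(self, descriptor: Descriptor) -> list[tuple[int, int]]:
        """Sequence-level base pairs implied by the placed helices.

        Pair positions count from the helix's closing (loop-proximal)
        end; with unequal strand lengths the shorter strand limits the
        pair count, leaving distal residues unpaired.
        """
        out = []
        for el in descriptor.structure.elements:
            if el.kind != "helix5" or el.index not in self.intervals:
                continue
            sister = el.sister
            if sister not in self.intervals:
                continue
            s5, e5 = self.intervals[el.index]
            s3, e3 = self.intervals[sister]
            n = min(e5 - s5 + 1, e3 - s3 + 1)
            for t in range(n):
                out.append((e5 - t, s3 + t))
        return sorted(out)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------


def _chance_probability(constraint: ElementConstraint) -> float:
    """P(an i.i.d. uniform window realizes the element), summed over its
    observed lengths."""
    p = 0.0
    for L, w in constraint.length_weights.items():
        q = 1.0
        for k in range(L):
            support = len(constraint.profile[k]) if k < len(constraint.profile) else 4
            q *= support / 4.0
        p += w * q
    return p


def rank_elements(
    descriptor: Descriptor,
    sequence_length: int,
    taxon: str = ROOT_SECTION,
) -> SeedRanking:
    """Stringency ranking: expected chance matches, ascending; ties break
    by element order."""
    section = descriptor.section(taxon)
    scores = {
        c.element_index: _chance_probability(c) * sequence_length
        for c in section.constraints
    }
    order = sorted(scores, key=lambda i: (scores[i], i))
    return SeedRanking(scores, order)


# ---------------------------------------------------------------------------
# Matching primitives
# ---------------------------------------------------------------------------


def _content(
    fragment: str, element: Element, constraint: ElementConstraint
) -> tuple[float, int]:
    """(log2 profile score, out-of-profile residue count) for a fragment
    read in the element's anchoring order."""
    if element.kind == "helix5":
        fragment = fragment[::-1]
    score, bad = 0.0, 0
    for k, nt in enumerate(fragment):
        if k >= len(constraint.profile):
            continue  # beyond every observed length: priced by the
            # length exception alone, no per-residue information
        freq = constraint.profile[k].get(nt, 0.0)
        if freq > 0.0:
            score += math.log2(freq)
        else:
            bad += 1
            score += _LOG_EPS
    return score, bad


def _helix_mispairs(
    seq: str, i5: tuple[int, int], i3: tuple[int, int]
) -> int:
    s5, e5 = i5
    s3, e3 = i3
    n = min(e5 - s5 + 1, e3 - s3 + 1)
    return sum(
        1 for t in range(n) if not is_canonical(seq[e5 - t], seq[s3 + t])
    )


# ---------------------------------------------------------------------------
# Extension search
# ---------------------------------------------------------------------------


class _Search:
    """Depth-first extension with backtracking over element lengths."""

    def __init__(
        self,
        sequence: str,
        descriptor: Descriptor,
        section: TaxonSection,
        max_exceptions: int,
        budget: int = 200_000,
    ):
        self.seq = sequence
        self.desc = descriptor
        self.section = section
        self.max_exc = max_exceptions
        self.elements = descriptor.structure.elements
        self.constraints = section.constraints
        self.budget = budget
        self.best: Optional[dict] = None  # complete solutions
        self.best_partial: Optional[dict] = None

    # candidate lengths for an element, in-support first by weight
    def _length_options(self, c: ElementConstraint, exc_left: int):
        opts = [
            (L, math.log2(w), 0)
            for L, w in sorted(
                c.length_weights.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]
        if exc_left > 0:
            support = set(c.length_weights)
            hi = max(support) + 2
            for L in range(0, hi + 1):
                if L not in support:
                    opts.append((L, _LOG_EPS, 1))
        return opts

    def _record(self, placed: dict[int, tuple[int, int]], score: float,
                exc: int) -> None:  # score ranks solutions; cutoff uses wscore
        n = len(self.elements)
        # residues outside the covered span are "unexplained": charged
        # well below any in-profile observation, so a model that covers
        # more of the sequence without exceptions always ranks higher
        lo = min(s for s, _ in placed.values())
        hi = max(e for _, e in placed.values())
        score = score - 6.0 * (lo + (len(self.seq) - 1 - hi))
        entry = {
            "intervals": dict(placed),
            "score": score,
            "exceptions": exc,
            "complete": len(placed) == n,
        }
        key = (len(placed), score, -exc)
        if entry["complete"]:
            if self.best is None or (
                score,
                -exc,
            ) > (self.best["score"], -self.best["exceptions"]):
                self.best = entry
        else:
            if self.best_partial is None or key > (
                len(self.best_partial["intervals"]),
                self.best_partial["score"],
                -self.best_partial["exceptions"],
            ):
                self.best_partial = entry

    def extend(
        self,
        placed: dict[int, tuple[int, int]],
        lo_el: int,
        hi_el: int,
        lo_pos: int,
        hi_pos: int,
        score: float,
        wscore: float,
        exc: int,
        go_left: bool,
    ) -> None:
        """``placed`` covers elements lo_el..hi_el at positions
        lo_pos..hi_pos (inclusive); extend one element on the chosen side.
        """
        self.budget -= 1
        if self.budget <= 0:
            return
        self._record(placed, score, exc)
        left_open = lo_el > 0
        right_open = hi_el < len(self.elements) - 1
        if not left_open and not right_open:
            return
        if not left_open:
            go_left = False
        if not right_open:
            go_left = True
        idx = lo_el - 1 if go_left else hi_el + 1
        el = self.elements[idx]
        c = self.constraints[idx]
        next_dir = not go_left  # alternate when both sides stay open
        for L, lw, exc_len in self._length_options(c, self.max_exc - exc):
            if go_left:
                start, end = lo_pos - L, lo_pos - 1
                if start < 0:
                    continue
            else:
                start, end = hi_pos + 1, hi_pos + L
                if end >= len(self.seq):
                    continue
            fragment = self.seq[start : end + 1]
            cscore, bad = _content(fragment, el, c)
            new_exc = exc + exc_len + bad
            if new_exc > self.max_exc:
                continue
            new_score = score + lw + cscore
            new_wscore = wscore + (lw if exc_len == 0 else 0.0)
            # consistency: helix pairing once both strands are down
            sister = el.sister
            if el.is_helix and sister is not None and sister in placed:
                i5 = (start, end) if el.kind == "helix5" else placed[sister]
                i3 = placed[sister] if el.kind == "helix5" else (start, end)
                m = _helix_mispairs(self.seq, i5, i3)
                h5c = self.constraints[min(el.index, sister)]
                mw = (
                    h5c.mispair_weights
                    if h5c.mispair_weights is not None
                    else {0: 1.0}
                )
                if m in mw:
                    new_score += math.log2(mw[m])
                    new_wscore += math.log2(mw[m])
                else:
                    new_exc += 1
                    new_score += _LOG_EPS
                    if new_exc > self.max_exc:
                        continue
            # elongating-model weight cutoff (exceptions charged nothing)
            if new_wscore < self.section.cutoff - 1e-9:
                continue
            placed[idx] = (start, end)
            self.extend(
                placed,
                min(lo_el, idx),
                max(hi_el, idx),
                start if go_left else lo_pos,
                end if not go_left else hi_pos,
                new_score,
                new_wscore,
                new_exc,
                next_dir,
            )
            del placed[idx]


def find_seed_occurrences(
    sequence: str,
    element: Element,
    constraint: ElementConstraint,
    limit: int = 30,
) -> list[tuple[int, int, float]]:
    """(start, length, log2 score) occurrences of one element, best first."""
    out = []
    for L, w in constraint.length_weights.items():
        if L == 0:
            continue
        lw = math.log2(w)
        for start in range(0, len(sequence) - L + 1):
            cscore, bad = _content(
                sequence[start : start + L], element, constraint
            )
            if bad == 0:
                out.append((start, L, lw + cscore))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out[:limit]


def extend_model(
    sequence: str,
    descriptor: Descriptor,
    taxon: str = ROOT_SECTION,
    max_exceptions: int = 0,
    query_id: str = "query",
) -> StructureInstance:
    """Identify the descriptor's structure in ``sequence``.

    Seeds are tried in stringency order; from each seed occurrence the
    model is extended with backtracking, and the best-scoring complete
    model wins.  If no seed yields a complete model the best partial one
    (most elements, then score) is returned; if no seed matches at all,
    the instance is empty and partial.
    """
    section = descriptor.section(taxon)
    ranking = rank_elements(descriptor, len(sequence), taxon)
    inst = StructureInstance(query_id, sequence)
    search = _Search(sequence, descriptor, section, max_exceptions)
    for seed_idx in ranking.order:
        el = descriptor.structure.elements[seed_idx]
        c = section.constraints[seed_idx]
        occs = find_seed_occurrences(sequence, el, c)
        if not occs:
            continue
        for start, L, score in occs:
            seed_lw = math.log2(
                c.length_weights[L]
            )
            search.extend(
                {seed_idx: (start, start + L - 1)},
                seed_idx,
                seed_idx,
                start,
                start + L - 1,
                score,
                seed_lw,
                0,
                go_left=True,
            )
        if search.best is not None:
            inst.trace.append(f"seed element {seed_idx} ({el.kind})")
            break
        inst.trace.append(f"seed element {seed_idx} ({el.kind}): no complete model")
    sol = search.best or search.best_partial
    if sol is None:
        inst.trace.append("no seed occurrence found")
        return inst
    inst.intervals = sol["intervals"]
    inst.complete = sol["complete"]
    inst.exceptions_used = sol["exceptions"]
    inst.score = sol["score"]
    return inst


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_structure(
    instance: StructureInstance,
    descriptor: Descriptor,
    dest=None,
    fmt: str = "ct",
):
    """Write the instance's implied per-sequence structure as CT, bpseq, or
    dot-bracket (1-based positions); returns the text when dest is None."""
    if not instance.intervals:
        raise FormatError("empty structure instance")
    pairs = instance.pairs(descriptor)
    if dest is None:
        return structure_to_string(
            instance.sequence, pairs, fmt, name=instance.query_id
        )
    write_structure(instance.sequence, pairs, dest, fmt, name=instance.query_id)
    return None
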