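"""Structure descriptors: stage 1 of the structure-based engine.

From a template alignment and its column-level secondary-structure model
this module derives an ordered list of structural elements (helix strands
and single-strand regions tiling the columns 5'->3') and measures, for
the whole template and for each well-populated taxon, the constraints a
new sequence must satisfy: per-element length histograms with frequency
weights, per-position nucleotide profiles, helix mispair histograms, and
a weight-score cutoff (the lowest total log-weight realized by any
template sequence, which guarantees every template member satisfies its
own descriptor).

The descriptor serializes to a versioned YAML text document with
``elements``, ``sections`` (root + phylogeny), and ``cutoff`` blocks; the
reader/writer pair round-trips losslessly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from .core import (
    NUCLEOTIDES,
    AlignedSequence,
    FormatError,
    TaxonomyTree,
    TemplateAlignment,
)

DESCRIPTOR_FORMAT_VERSION = 1

CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

ROOT_SECTION = "root"


class StructureFormatError(FormatError):
    """Invalid secondary-structure input (column paired twice, ...)."""


class PartialModelError(FormatError):
    """An operation requiring a complete structure model got a partial one."""


# ---------------------------------------------------------------------------
# Structure model: pairs -> ordered elements
# ---------------------------------------------------------------------------


@dataclass
class Element:
    """One structural element's footprint on the alignment columns.

    Helices contribute two elements (their 5' and 3' strands) that share
    a ``helix_id``; ``sister`` is the element index of the other strand.
    """

    index: int
    kind: str  # helix5 | helix3 | tail5 | tail3 | hairpin | loop
    columns: list[int]
    helix_id: Optional[int] = None
    sister: Optional[int] = None

    @property
    def is_helix(self) -> bool:
        return self.kind in ("helix5", "helix3")


@dataclass
class StructureModel:
    width: int
    pairs: list[tuple[int, int]]  # nested pairs, i < j
    tertiary: list[tuple[int, int]]  # crossing pairs, set aside
    elements: list[Element]

    def partner_map(self) -> dict[int, int]:
        out = {}
        for i, j in self.pairs:
            out[i], out[j] = j, i
        return out


def derive_elements(
    width: int, pairs: Sequence[tuple[int, int]]
) -> StructureModel:
    """Build the ordered element list from column-level base pairs.

    Maximal runs of stacked nested pairs form helices; everything else is
    single-strand.  Crossing (pseudoknotted) pairs are set aside as
    tertiary constraints and excluded from the element ordering.
    """
    norm = []
    seen: set[int] = set()
    for i, j in pairs:
        i, j = (i, j) if i < j else (j, i)
        if not (0 <= i < j < width):
            raise StructureFormatError(f"pair {(i + 1, j + 1)} out of range")
        if i in seen or j in seen:
            raise StructureFormatError(
                f"column {i + 1 if i in seen else j + 1} paired twice"
            )
        seen.update((i, j))
        norm.append((i, j))
    norm.sort()

    nested: list[tuple[int, int]] = []
    tertiary: list[tuple[int, int]] = []
    for p in norm:  # greedy: keep the pair unless it crosses a kept one
        i, j = p
        if any(a < i < b < j or i < a < j < b for a, b in nested):
            tertiary.append(p)
        else:
            nested.append(p)

    # helices: maximal runs of stacked pairs
    helices: list[list[tuple[int, int]]] = []
    for p in nested:
        if helices and p[0] == helices[-1][-1][0] + 1 and p[1] == helices[-1][-1][1] - 1:
            helices[-1].append(p)
        else:
            helices.append([p])

    partner_strand: dict[int, int] = {}  # column -> helix id
    for h, run in enumerate(helices):
        for i, j in run:
            partner_strand[i] = h
            partner_strand[j] = h

    elements: list[Element] = []
    helix_elements: dict[tuple[int, str], int] = {}
    col = 0
    paired_cols = sorted(partner_strand)
    first_paired = paired_cols[0] if paired_cols else None
    last_paired = paired_cols[-1] if paired_cols else None
    while col < width:
        if col in partner_strand:
            h = partner_strand[col]
            run = helices[h]
            strand5 = [i for i, _ in run]
            strand3 = sorted(j for _, j in run)
            if col == strand5[0]:
                kind, cols = "helix5", strand5
            else:
                kind, cols = "helix3", strand3
            el = Element(len(elements), kind, cols, helix_id=h)
            helix_elements[(h, kind)] = el.index
            elements.append(el)
            col = cols[-1] + 1
        else:
            start = col
            while col < width and col not in partner_strand:
                col += 1
            cols = list(range(start, col))
            if first_paired is None or start > last_paired:
                kind = "tail3" if first_paired is not None else "loop"
            elif col - 1 < first_paired:
                kind = "tail5"
            else:
                prev = elements[-1]
                nxt_col = col  # first paired column after the run
                nxt_h = partner_strand.get(nxt_col)
                if (
                    prev.kind == "helix5"
                    and nxt_h == prev.helix_id
                ):
                    kind = "hairpin"
                else:
                    kind = "loop"
            elements.append(Element(len(elements), kind, cols))
    for (h, kind), idx in helix_elements.items():
        sister_kind = "helix3" if kind == "helix5" else "helix5"
        elements[idx].sister = helix_elements[(h, sister_kind)]
    return StructureModel(width, nested, tertiary, elements)


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------


@dataclass
class ElementConstraint:
    """Observed constraint distributions for one element in one taxon."""

    element_index: int
    kind: str
    length_weights: dict[int, float]  # residue count -> frequency
    profile: list[dict[str, float]]  # per position (see anchoring note)
    mispair_weights: Optional[dict[int, float]] = None  # helix5 strands only

    @property
    def lengths(self) -> list[int]:
        return sorted(self.length_weights)

    @property
    def max_mispairs(self) -> int:
        if not self.mispair_weights:
            return 0
        return max(self.mispair_weights)


@dataclass
class TaxonSection:
    taxon: str
    n_sequences: int
    constraints: list[ElementConstraint]
    cutoff: float  # minimum per-sequence total log2 weight


@dataclass
class Descriptor:
    structure: StructureModel
    sections: dict[str, TaxonSection] = field(default_factory=dict)
    version: int = DESCRIPTOR_FORMAT_VERSION

    def section(self, taxon: str = ROOT_SECTION) -> TaxonSection:
        if taxon not in self.sections:
            raise KeyError(f"no descriptor section for taxon {taxon!r}")
        return self.sections[taxon]


def is_canonical(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


def _element_residues(seq: AlignedSequence, element: Element) -> str:
    return "".join(
        seq.symbols[c] for c in element.columns if seq.symbols[c] != "-"
    )


def _anchored(residues: str, element: Element) -> str:
    """Residues in profile-position order: helix 5' strands are anchored at
    their loop-proximal (3') end, everything else at the 5' end."""
    return residues[::-1] if element.kind == "helix5" else residues


def _sequence_mispairs(
    seq: AlignedSequence, model: StructureModel
) -> dict[int, int]:
    """Per-helix mispair count at column level (both residues present but
    not a canonical pair)."""
    out: dict[int, int] = {}
    partner = {}
    helix_of = {}
    for el in model.elements:
        if el.kind == "helix5":
            helix_of[el.helix_id] = el
    for h, el in helix_of.items():
        sister = model.elements[el.sister]
        m = 0
        for i, j in zip(el.columns, reversed(sister.columns)):
            a, b = seq.symbols[i], seq.symbols[j]
            if a != "-" and b != "-" and not is_canonical(a, b):
                m += 1
        out[h] = m
    return out


def _build_section(
    taxon: str,
    members: Sequence[AlignedSequence],
    model: StructureModel,
) -> TaxonSection:
    n = len(members)
    constraints: list[ElementConstraint] = []
    per_seq_log: dict[str, float] = {s.id: 0.0 for s in members}
    mispairs = {s.id: _sequence_mispairs(s, model) for s in members}
    for el in model.elements:
        lengths: dict[int, int] = {}
        maxlen = 0
        anchored: dict[str, str] = {}
        for s in members:
            res = _anchored(_element_residues(s, el), el)
            anchored[s.id] = res
            lengths[len(res)] = lengths.get(len(res), 0) + 1
            maxlen = max(maxlen, len(res))
        length_weights = {L: c / n for L, c in sorted(lengths.items())}
        profile: list[dict[str, float]] = []
        for k in range(maxlen):
            counts = dict.fromkeys(NUCLEOTIDES, 0)
            total = 0
            for s in members:
                res = anchored[s.id]
                if k < len(res) and res[k] in counts:
                    counts[res[k]] += 1
                    total += 1
            profile.append(
                {p: counts[p] / total for p in NUCLEOTIDES if counts[p]}
                if total
                else {}
            )
        mispair_weights = None
        if el.kind == "helix5":
            mcounts: dict[int, int] = {}
            for s in members:
                m = mispairs[s.id][el.helix_id]
                mcounts[m] = mcounts.get(m, 0) + 1
            mispair_weights = {m: c / n for m, c in sorted(mcounts.items())}
            for s in members:
                per_seq_log[s.id] += math.log2(
                    mispair_weights[mispairs[s.id][el.helix_id]]
                )
        for s in members:
            per_seq_log[s.id] += math.log2(
                length_weights[len(anchored[s.id])]
            )
        constraints.append(
            ElementConstraint(
                el.index, el.kind, length_weights, profile, mispair_weights
            )
        )
    cutoff = min(per_seq_log.values())
    return TaxonSection(taxon, n, constraints, cutoff)


def build_descriptor(
    template: TemplateAlignment,
    taxonomy: TaxonomyTree,
    min_sequences: int = 5,
    pairs: Optional[Sequence[tuple[int, int]]] = None,
) -> Descriptor:
    """Derive the full descriptor: root section plus per-taxon sections for
    every taxon holding at least ``min_sequences`` template sequences."""
    if pairs is None:
        pairs = template.pairs
    if not pairs:
        raise StructureFormatError("template carries no base-pair annotation")
    model = derive_elements(template.width, pairs)
    desc = Descriptor(model)
    desc.sections[ROOT_SECTION] = _build_section(
        ROOT_SECTION, template.sequences, model
    )
    for node in taxonomy.nodes():
        if node.name == taxonomy.root.name:
            continue
        members = template.taxon_sequences(taxonomy, node.name)
        if len(members) >= min_sequences:
            desc.sections[node.name] = _build_section(
                node.name, members, model
            )
    return desc


# ---------------------------------------------------------------------------
# Serialization (versioned YAML)
# ---------------------------------------------------------------------------


def descriptor_to_dict(desc: Descriptor) -> dict:
    model = desc.structure
    return {
        "format_version": desc.version,
        "structure": {
            "width": model.width,
            "pairs": [[i + 1, j + 1] for i, j in model.pairs],
            "tertiary": [[i + 1, j + 1] for i, j in model.tertiary],
            "elements": [
                {
                    "index": el.index,
                    "kind": el.kind,
                    "columns": [c + 1 for c in el.columns],
                    "helix_id": el.helix_id,
                    "sister": el.sister,
                }
                for el in model.elements
            ],
        },
        "sections": {
            name: {
                "n_sequences": sec.n_sequences,
                "cutoff": sec.cutoff,
                "elements": [
                    {
                        "index": c.element_index,
                        "kind": c.kind,
                        "length_weights": {
                            str(k): v for k, v in c.length_weights.items()
                        },
                        "profile": c.profile,
                        "mispair_weights": (
                            {str(k): v for k, v in c.mispair_weights.items()}
                            if c.mispair_weights is not None
                            else None
                        ),
                    }
                    for c in sec.constraints
                ],
            }
            for name, sec in desc.sections.items()
        },
    }


def descriptor_from_dict(data: dict) -> Descriptor:
    if data.get("format_version") != DESCRIPTOR_FORMAT_VERSION:
        raise FormatError("unsupported descriptor format version")
    sd = data["structure"]
    elements = [
        Element(
            e["index"],
            e["kind"],
            [c - 1 for c in e["columns"]],
            helix_id=e["helix_id"],
            sister=e["sister"],
        )
        for e in sd["elements"]
    ]
    model = StructureModel(
        sd["width"],
        [(i - 1, j - 1) for i, j in sd["pairs"]],
        [(i - 1, j - 1) for i, j in sd["tertiary"]],
        elements,
    )
    desc = Descriptor(model)
    for name, sec in data["sections"].items():
        constraints = [
            ElementConstraint(
                c["index"],
                c["kind"],
                {int(k): v for k, v in c["length_weights"].items()},
                c["profile"],
                (
                    {int(k): v for k, v in c["mispair_weights"].items()}
                    if c["mispair_weights"] is not None
                    else None
                ),
            )
            for c in sec["elements"]
        ]
        desc.sections[name] = TaxonSection(
            name, sec["n_sequences"], constraints, sec["cutoff"]
        )
    return desc


def write_descriptor(desc: Descriptor, dest) -> None:
    data = descriptor_to_dict(desc)
    if hasattr(dest, "write"):
        yaml.safe_dump(data, dest, sort_keys=True)
    else:
        with open(dest, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def read_descriptor(source) -> Descriptor:
    if hasattr(source, "read"):
        data = yaml.safe_load(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    return descriptor_from_dict(data)
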