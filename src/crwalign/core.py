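"""Shared data model: taxonomy tree, aligned sequences, template alignments.

Everything downstream (profile statistics, both alignment engines, the
evaluation metrics) operates on these containers.  Coordinates are 0-based
internally; every serialized or logged coordinate is 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

NUCLEOTIDES = ("A", "C", "G", "U")
GAP = "-"
GAP_CHARS = frozenset("-.~")
# IUPAC ambiguity codes are kept as literal symbols but counted as gaps by
# the statistics (only A/C/G/U enter conservation/composition counts).
IUPAC = frozenset("ACGURYSWKMBDHVN")


class CrwalignError(Exception):
    """Base class for package errors."""


class FormatError(CrwalignError):
    """Malformed input (unequal lengths, bad structure file, ...)."""


class TreeIntegrityError(CrwalignError):
    """Taxonomy tree violates its invariants (cycle, detached node, ...)."""


class ConfigurationError(CrwalignError):
    """A run was requested with inconsistent or missing configuration."""


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


@dataclass
class TaxonNode:
    name: str
    rank: str = ""
    parent: Optional["TaxonNode"] = None
    children: list["TaxonNode"] = field(default_factory=list)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TaxonNode({self.name!r})"


class TaxonomyTree:
    """A rooted tree of named taxa.

    Nodes are unique by name.  Built either node-by-node (:meth:`add_node`)
    or from semicolon-separated lineage strings (:meth:`from_lineages`).
    """

    def __init__(self, root_name: str = "root", root_rank: str = "root"):
        self.root = TaxonNode(root_name, root_rank)
        self._nodes: dict[str, TaxonNode] = {root_name: self.root}

    # -- construction -------------------------------------------------
    def add_node(self, name: str, parent: str, rank: str = "") -> TaxonNode:
        if name in self._nodes:
            node = self._nodes[name]
            if node.parent is not None and node.parent.name != parent:
                raise TreeIntegrityError(
                    f"taxon {name!r} already attached under {node.parent.name!r}"
                )
            return node
        if parent not in self._nodes:
            raise TreeIntegrityError(f"unknown parent taxon {parent!r}")
        node = TaxonNode(name, rank, parent=self._nodes[parent])
        self._nodes[parent].children.append(node)
        self._nodes[name] = node
        return node

    @classmethod
    def from_lineages(cls, lineages: Iterable[str]) -> "TaxonomyTree":
        """Build a tree from strings like ``"bacteria;bacilli;bacillales"``.

        The first component of every lineage must be the (shared) root.
        """
        tree: Optional[TaxonomyTree] = None
        for lineage in lineages:
            parts = [p.strip() for p in lineage.split(";") if p.strip()]
            if not parts:
                continue
            if tree is None:
                tree = cls(root_name=parts[0])
            elif parts[0] != tree.root.name:
                raise TreeIntegrityError(
                    f"lineage root {parts[0]!r} != tree root {tree.root.name!r}"
                )
            for parent, child in zip(parts, parts[1:]):
                tree.add_node(child, parent)
        if tree is None:
            raise TreeIntegrityError("no lineages supplied")
        return tree

    # -- queries ------------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self._nodes

    def node(self, name: str) -> TaxonNode:
        try:
            return self._nodes[name]
        except KeyError:
            raise TreeIntegrityError(f"unknown taxon {name!r}") from None

    def nodes(self) -> list[TaxonNode]:
        """All nodes in deterministic (preorder) order."""
        out: list[TaxonNode] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def lineage(self, name: str) -> list[TaxonNode]:
        """Path root -> node, consecutive elements parent/child."""
        node = self.node(name)
        path = [node]
        seen = {id(node)}
        while node.parent is not None:
            node = node.parent
            if id(node) in seen:
                raise TreeIntegrityError(f"cycle reaching {name!r}")
            seen.add(id(node))
            path.append(node)
        if node is not self.root:
            raise TreeIntegrityError(f"taxon {name!r} detached from root")
        return list(reversed(path))

    def depth(self, name: str) -> int:
        return len(self.lineage(name)) - 1

    def descendants_or_self(self, name: str) -> list[TaxonNode]:
        out: list[TaxonNode] = []
        stack = [self.node(name)]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out


# ---------------------------------------------------------------------------
# Sequences and alignments
# ---------------------------------------------------------------------------


def normalize_symbols(raw: str, seq_id: str = "?") -> str:
    """Uppercase, T->U, unify gap characters; non-IUPAC symbols become gaps."""
    out = []
    bad: set[str] = set()
    for ch in raw.upper().replace("T", "U"):
        if ch in GAP_CHARS:
            out.append(GAP)
        elif ch in IUPAC:
            out.append(ch)
        else:
            bad.add(ch)
            out.append(GAP)
    if bad:
        warnings.warn(
            f"sequence {seq_id!r}: non-IUPAC symbols {sorted(bad)} treated as gaps"
        )
    return "".join(out)


@dataclass
class AlignedSequence:
    """One gapped row of a template alignment."""

    id: str
    taxon: str
    symbols: str  # uppercase RNA + IUPAC + '-'

    def __post_init__(self) -> None:
        nongap = [i for i, c in enumerate(self.symbols) if c != GAP]
        self._first = nongap[0] if nongap else None
        self._last = nongap[-1] if nongap else None

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def first_nongap(self) -> Optional[int]:
        return self._first

    @property
    def last_nongap(self) -> Optional[int]:
        return self._last

    def is_partial_at(self, col: int) -> bool:
        """True if this row is 5'-partial after, or 3'-partial before, ``col``.

        A sequence whose first non-gap column lies beyond ``col`` (or last
        non-gap column before it) is excluded from conservation counts there.
        """
        if self._first is None:
            return True
        return col < self._first or col > self._last

    def nucleotide_at(self, col: int) -> Optional[str]:
        """The A/C/G/U at ``col``, or None for gap/ambiguity symbols."""
        c = self.symbols[col]
        return c if c in NUCLEOTIDES else None

    def degapped(self) -> str:
        return "".join(c for c in self.symbols if c != GAP)

    def residue_columns(self) -> list[int]:
        """Columns occupied by non-gap symbols, in order."""
        return [i for i, c in enumerate(self.symbols) if c != GAP]


@dataclass
class QuerySequence:
    """An unaligned input sequence, optionally with a taxonomic name hint."""

    id: str
    symbols: str
    taxon_hint: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.symbols:
            raise FormatError(f"query {self.id!r} is empty")
        self.symbols = normalize_symbols(self.symbols, self.id).replace(GAP, "")
        if not self.symbols:
            raise FormatError(f"query {self.id!r} has no usable symbols")

    def __len__(self) -> int:
        return len(self.symbols)


class TemplateAlignment:
    """A gapped multiple sequence alignment with per-row taxon labels.

    Optionally carries a column-level base-pairing map (used by the
    structure engine): a list of ``(i, j)`` column pairs, 0-based.
    """

    def __init__(
        self,
        sequences: Sequence[AlignedSequence],
        pairs: Optional[Sequence[tuple[int, int]]] = None,
    ):
        seqs = list(sequences)
        if not seqs:
            raise FormatError("empty alignment")
        width = len(seqs[0])
        for s in seqs:
            if len(s) != width:
                raise FormatError(
                    f"sequence {s.id!r} length {len(s)} != alignment width {width}"
                )
        self.sequences: list[AlignedSequence] = seqs
        self.width = width
        self._by_id = {s.id: s for s in seqs}
        if len(self._by_id) != len(seqs):
            raise FormatError("duplicate sequence identifiers")
        self.pairs: list[tuple[int, int]] = sorted(tuple(p) for p in pairs or [])
        for i, j in self.pairs:
            if not (0 <= i < width and 0 <= j < width) or i == j:
                raise FormatError(f"invalid column pair {(i + 1, j + 1)}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, seq_id: str) -> AlignedSequence:
        return self._by_id[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def taxon_sequences(
        self, taxonomy: TaxonomyTree, taxon: str
    ) -> list[AlignedSequence]:
        """Rows whose taxon lies in the subtree rooted at ``taxon``."""
        members = {n.name for n in taxonomy.descendants_or_self(taxon)}
        return [s for s in self.sequences if s.taxon in members]

    def drop(self, seq_id: str) -> "TemplateAlignment":
        """A copy of the alignment without one row (leave-one-out helper)."""
        return TemplateAlignment(
            [s for s in self.sequences if s.id != seq_id], pairs=self.pairs
        )


def ingest_alignment(
    records: Iterable[tuple[str, str]],
    taxon_map: Mapping[str, str],
    pairs: Optional[Sequence[tuple[int, int]]] = None,
) -> TemplateAlignment:
    """Build a :class:`TemplateAlignment` from (id, gapped sequence) records.

    Symbols are normalized (uppercase, T->U, gap unification); rows must all
    have the same length and every id must appear in ``taxon_map``.
    """
    seqs = []
    for seq_id, raw in records:
        if seq_id not in taxon_map:
            raise FormatError(f"sequence {seq_id!r} missing from taxon map")
        seqs.append(
            AlignedSequence(seq_id, taxon_map[seq_id], normalize_symbols(raw, seq_id))
        )
    return TemplateAlignment(seqs, pairs=pairs)
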