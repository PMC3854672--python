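"""Readers and writers for the standard formats the pipeline touches.

Alignments travel as gapped FASTA or Stockholm (via biopython), taxonomy as
a two-column TSV of ``sequence_id<TAB>lineage`` with semicolon-separated
lineages, and secondary structure as CT, bpseq, or dot-bracket.  All readers
tolerate CRLF line endings and trailing whitespace.  Serialized coordinates
are 1-based inclusive.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Optional, TextIO

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    GAP,
    FormatError,
    QuerySequence,
    TaxonomyTree,
    TemplateAlignment,
    ingest_alignment,
)


def _open(path_or_handle, mode: str = "r"):
    if hasattr(path_or_handle, "read") or hasattr(path_or_handle, "write"):
        return path_or_handle, False
    return open(path_or_handle, mode), True


# ---------------------------------------------------------------------------
# Alignments / sequences
# ---------------------------------------------------------------------------


def read_gapped_records(source, fmt: str = "fasta") -> list[tuple[str, str]]:
    """(id, gapped sequence) pairs from a FASTA or Stockholm file."""
    handle, close = _open(source)
    try:
        if fmt == "stockholm":
            aln = AlignIO.read(handle, "stockholm")
            return [(rec.id, str(rec.seq)) for rec in aln]
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    finally:
        if close:
            handle.close()


def read_template(
    alignment_source,
    taxonomy_source,
    fmt: str = "fasta",
) -> tuple[TemplateAlignment, TaxonomyTree]:
    """Load a template alignment plus its taxonomy TSV."""
    records = read_gapped_records(alignment_source, fmt)
    if not records:
        raise FormatError("no sequences in alignment input")
    taxon_map, tree = read_taxonomy(taxonomy_source)
    return ingest_alignment(records, taxon_map), tree


def write_alignment(
    alignment: TemplateAlignment, dest, fmt: str = "fasta"
) -> None:
    records = [
        SeqRecord(Seq(s.symbols), id=s.id, description="")
        for s in alignment.sequences
    ]
    handle, close = _open(dest, "w")
    try:
        if fmt == "stockholm":
            AlignIO.write(MultipleSeqAlignment(records), handle, "stockholm")
        else:
            SeqIO.write(records, handle, "fasta")
    finally:
        if close:
            handle.close()


def write_rows(rows: Iterable[tuple[str, str]], dest) -> None:
    """Write (id, gapped row) pairs as FASTA."""
    handle, close = _open(dest, "w")
    try:
        for seq_id, row in rows:
            handle.write(f">{seq_id}\n{row}\n")
    finally:
        if close:
            handle.close()


def read_queries(source, fmt: str = "fasta") -> list[QuerySequence]:
    return [
        QuerySequence(seq_id, raw.replace(GAP, "").replace(".", ""))
        for seq_id, raw in read_gapped_records(source, fmt)
    ]


# ---------------------------------------------------------------------------
# Taxonomy TSV
# ---------------------------------------------------------------------------


def read_taxonomy(source) -> tuple[dict[str, str], TaxonomyTree]:
    """Parse ``sequence_id<TAB>root;...;taxon`` lines.

    Returns the id->leaf-taxon map and the taxonomy tree implied by the
    union of lineages.
    """
    handle, close = _open(source)
    try:
        taxon_map: dict[str, str] = {}
        lineages: list[str] = []
        for raw in handle:
            line = raw.rstrip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"bad taxonomy line: {line!r}")
            seq_id, lineage = parts[0].strip(), parts[1].strip()
            taxon_map[seq_id] = lineage.split(";")[-1].strip()
            lineages.append(lineage)
        if not taxon_map:
            raise FormatError("empty taxonomy file")
        return taxon_map, TaxonomyTree.from_lineages(lineages)
    finally:
        if close:
            handle.close()


def write_taxonomy(
    taxon_map: dict[str, str], tree: TaxonomyTree, dest
) -> None:
    handle, close = _open(dest, "w")
    try:
        for seq_id, taxon in taxon_map.items():
            lineage = ";".join(n.name for n in tree.lineage(taxon))
            handle.write(f"{seq_id}\t{lineage}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Secondary structure: CT / bpseq / dot-bracket
# ---------------------------------------------------------------------------


def read_structure(source, fmt: str) -> tuple[str, list[tuple[int, int]]]:
    """Return (sequence, pairs) with 0-based pair indices, i < j."""
    handle, close = _open(source)
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    if fmt == "ct":
        return _parse_ct(text)
    if fmt == "bpseq":
        return _parse_bpseq(text)
    if fmt in ("dbn", "dot-bracket", "bracket"):
        return _parse_dbn(text)
    raise FormatError(f"unsupported structure format {fmt!r}")


def _dedupe_pairs(partner: dict[int, int]) -> list[tuple[int, int]]:
    pairs = set()
    for i, j in partner.items():
        if j < 0:
            continue
        if partner.get(j, -1) != i:
            raise FormatError(f"asymmetric pair {(i + 1, j + 1)}")
        pairs.add((min(i, j), max(i, j)))
    return sorted(pairs)


def _parse_ct(text: str) -> tuple[str, list[tuple[int, int]]]:
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty CT file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError("bad CT header") from None
    seq = []
    partner: dict[int, int] = {}
    for ln in lines[1 : n + 1]:
        f = ln.split()
        idx = int(f[0]) - 1
        seq.append(f[1].upper())
        j = int(f[4]) - 1
        partner[idx] = j
    if len(seq) != n:
        raise FormatError("CT row count != header length")
    return "".join(seq), _dedupe_pairs(partner)


def _parse_bpseq(text: str) -> tuple[str, list[tuple[int, int]]]:
    seq = []
    partner: dict[int, int] = {}
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        f = ln.split()
        if len(f) != 3:
            raise FormatError(f"bad bpseq line: {ln!r}")
        idx = int(f[0]) - 1
        seq.append(f[1].upper())
        partner[idx] = int(f[2]) - 1
    return "".join(seq), _dedupe_pairs(partner)


_OPEN = "([{<"
_CLOSE = ")]}>"


def _parse_dbn(text: str) -> tuple[str, list[tuple[int, int]]]:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    lines = [ln for ln in lines if not ln.startswith((">", "#"))]
    if len(lines) < 2:
        raise FormatError("dot-bracket needs a sequence line and a structure line")
    seq, struct = lines[0].upper(), lines[1].split()[0]
    if len(seq) != len(struct):
        raise FormatError("sequence/structure length mismatch")
    stacks: dict[int, list[int]] = {k: [] for k in range(len(_OPEN))}
    pairs = []
    for i, ch in enumerate(struct):
        if ch in _OPEN:
            stacks[_OPEN.index(ch)].append(i)
        elif ch in _CLOSE:
            k = _CLOSE.index(ch)
            if not stacks[k]:
                raise FormatError(f"unbalanced bracket at position {i + 1}")
            pairs.append((stacks[k].pop(), i))
        elif ch not in ".,_-:":
            raise FormatError(f"unknown structure symbol {ch!r}")
    if any(stacks.values()):
        raise FormatError("unbalanced brackets")
    return seq, sorted(pairs)


def write_structure(
    sequence: str,
    pairs: list[tuple[int, int]],
    dest,
    fmt: str,
    name: str = "structure",
) -> None:
    """Write a per-sequence structure (0-based pairs) as CT, bpseq, or dbn."""
    partner = {i: -1 for i in range(len(sequence))}
    for i, j in pairs:
        if partner[i] != -1 or partner[j] != -1:
            raise FormatError("position paired twice")
        partner[i], partner[j] = j, i
    handle, close = _open(dest, "w")
    try:
        if fmt == "ct":
            handle.write(f"{len(sequence)} {name}\n")
            for i, c in enumerate(sequence):
                nxt = i + 2 if i + 1 < len(sequence) else 0
                handle.write(f"{i + 1} {c} {i} {nxt} {partner[i] + 1} {i + 1}\n")
        elif fmt == "bpseq":
            for i, c in enumerate(sequence):
                handle.write(f"{i + 1} {c} {partner[i] + 1}\n")
        elif fmt in ("dbn", "dot-bracket", "bracket"):
            symbols = ["."] * len(sequence)
            for i, j in pairs:
                symbols[i], symbols[j] = "(", ")"
            handle.write(f">{name}\n{sequence}\n{''.join(symbols)}\n")
        else:
            raise FormatError(f"unsupported structure format {fmt!r}")
    finally:
        if close:
            handle.close()


def structure_to_string(sequence, pairs, fmt: str, name: str = "structure") -> str:
    buf = _io.StringIO()
    write_structure(sequence, pairs, buf, fmt, name)
    return buf.getvalue()
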