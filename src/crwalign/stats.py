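"""Taxonomy-stratified alignment statistics for the block-profile aligner.

For each taxonomic node with enough template sequences (and all of its
ancestors) this module computes, per alignment column, the conservation
value C_i (fraction of counted sequences bearing a nucleotide; sequences
that start after or end before the column are excluded) and the nucleotide
composition N_i(p) (fraction of nucleotide-bearing sequences carrying p).

Columns with C_i above the conservation cutoff at the root are "highly
conserved"; the alignment is tiled into blocks each holding a fixed count
of them (the last block may hold fewer).  Within each block and taxon,
every template sequence's subsequence receives the score

    SC(b) = (sum_{i in Z} C_i) / |Y|  +  w * (sum_{j in Z} N_j(S_j)) / |Z|

where Y is the taxon's conserved-column set for the block, Z the subset
where the sequence has a nucleotide, S_j its nucleotide there, and w the
heuristic composition weight (default 0.8, so the maximum score is 1.8).
Block averages of these scores drive the aligner's block ordering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .config import Config
from .core import (
    NUCLEOTIDES,
    AlignedSequence,
    CrwalignError,
    TaxonomyTree,
    TemplateAlignment,
)

STATS_FORMAT_VERSION = 1


class EmptyColumnError(CrwalignError):
    """Composition requested for a column with no nucleotides in the taxon."""


class UnpartitionableError(CrwalignError):
    """No highly conserved columns: the alignment cannot be tiled into blocks."""


# ---------------------------------------------------------------------------
# Column-level statistics
# ---------------------------------------------------------------------------


def conservation_value(
    sequences: Sequence[AlignedSequence], col: int
) -> float:
    """C_i: nucleotide-bearing fraction of the counted sequences at ``col``.

    Partial sequences (first non-gap after ``col`` or last non-gap before
    it) are excluded from both numerator and denominator.  If every
    sequence is excluded the value is defined as 0 (with a warning).
    """
    counted = [s for s in sequences if not s.is_partial_at(col)]
    if not counted:
        warnings.warn(f"column {col + 1}: all sequences partial; conservation := 0")
        return 0.0
    with_nt = sum(1 for s in counted if s.nucleotide_at(col) is not None)
    return with_nt / len(counted)


def composition_values(
    sequences: Sequence[AlignedSequence], col: int
) -> dict[str, float]:
    """N_i(p): per-nucleotide fraction among nucleotide-bearing sequences."""
    counts = dict.fromkeys(NUCLEOTIDES, 0)
    for s in sequences:
        nt = s.nucleotide_at(col)
        if nt is not None:
            counts[nt] += 1
    total = sum(counts.values())
    if total == 0:
        raise EmptyColumnError(f"no nucleotides at column {col + 1}")
    return {p: counts[p] / total for p in NUCLEOTIDES}


@dataclass
class ColumnStats:
    conservation: float
    composition: dict[str, float]  # all-zero when the column is empty
    counted: int  # sequences entering the conservation denominator


def column_profile(
    sequences: Sequence[AlignedSequence], width: int
) -> list[ColumnStats]:
    """Conservation + composition for every column of the alignment."""
    out = []
    for col in range(width):
        counted = [s for s in sequences if not s.is_partial_at(col)]
        if counted:
            with_nt = sum(1 for s in counted if s.nucleotide_at(col) is not None)
            cons = with_nt / len(counted)
        else:
            cons = 0.0
        counts = dict.fromkeys(NUCLEOTIDES, 0)
        for s in sequences:
            nt = s.nucleotide_at(col)
            if nt is not None:
                counts[nt] += 1
        total = sum(counts.values())
        comp = (
            {p: counts[p] / total for p in NUCLEOTIDES}
            if total
            else dict.fromkeys(NUCLEOTIDES, 0.0)
        )
        out.append(ColumnStats(cons, comp, len(counted)))
    return out


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------


@dataclass
class Block:
    index: int  # 0-based block number
    start: int  # first column (0-based, inclusive)
    end: int  # last column (0-based, inclusive)
    conserved_columns: list[int]  # root-level conserved columns in the block

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def partition_blocks(
    root_profile: Sequence[ColumnStats],
    conserved_per_block: int,
    conservation_threshold: float,
) -> list[Block]:
    """Tile the alignment into blocks of ``conserved_per_block`` conserved columns.

    Conserved means strictly greater than the threshold.  A block runs from
    the column after the previous block's last conserved column through its
    own last conserved column; the final block extends to the alignment end
    and may hold fewer conserved columns.
    """
    if conserved_per_block < 1:
        raise ValueError("conserved_per_block must be >= 1")
    conserved = [
        i for i, cs in enumerate(root_profile)
        if cs.conservation > conservation_threshold
    ]
    if not conserved:
        raise UnpartitionableError("no highly conserved columns at the root")
    width = len(root_profile)
    blocks: list[Block] = []
    start = 0
    for k in range(0, len(conserved), conserved_per_block):
        chunk = conserved[k : k + conserved_per_block]
        last = k + conserved_per_block >= len(conserved)
        end = width - 1 if last else chunk[-1]
        blocks.append(Block(len(blocks), start, end, chunk))
        start = end + 1
    return blocks


# ---------------------------------------------------------------------------
# Block scoring (the SC(b) statistic)
# ---------------------------------------------------------------------------


def subsequence_block_score(
    placement: Mapping[int, str],
    conserved_columns: Sequence[int],
    profile: Sequence[ColumnStats],
    composition_weight: float = 0.8,
) -> float:
    """SC(b) of a subsequence placed on a block's conserved columns.

    ``placement`` maps conserved columns to the nucleotide the subsequence
    holds there (its keys are Z); ``conserved_columns`` is the taxon's
    conserved set Y for the block; ``profile`` gives the scoring taxon's
    per-column statistics.  An empty placement scores 0 (with a warning).
    """
    y = list(conserved_columns)
    if not y:
        return 0.0
    z = [c for c in y if c in placement]
    if not z:
        warnings.warn("empty subsequence over block conserved columns; score := 0")
        return 0.0
    cons = sum(profile[c].conservation for c in z) / len(y)
    comp = sum(profile[c].composition.get(placement[c], 0.0) for c in z) / len(z)
    return cons + composition_weight * comp


def sequence_block_placement(
    seq: AlignedSequence, conserved_columns: Sequence[int]
) -> dict[int, str]:
    """A template row's natural placement: its nucleotides at the conserved columns."""
    out = {}
    for c in conserved_columns:
        nt = seq.nucleotide_at(c)
        if nt is not None:
            out[c] = nt
    return out


# ---------------------------------------------------------------------------
# Per-taxon statistics
# ---------------------------------------------------------------------------


@dataclass
class BlockStatistics:
    block: Block
    conserved_columns: list[int]  # recomputed within this taxon
    sequence_scores: dict[str, float]
    mean_score: float
    min_nucleotides: int  # fewest residues any member has in the block
    max_nucleotides: int


@dataclass
class TaxonStatistics:
    taxon: str
    n_sequences: int
    columns: list[ColumnStats]
    blocks: list[BlockStatistics] = field(default_factory=list)


def build_taxon_statistics(
    alignment: TemplateAlignment,
    taxonomy: TaxonomyTree,
    config: Config = Config(),
) -> dict[str, TaxonStatistics]:
    """Statistics for every taxon meeting ``min_sequences`` plus their ancestors.

    Block boundaries are fixed at the root; each taxon's conserved-column
    set is recomputed (same >cutoff rule) within each block's interval, so
    a block may hold different conserved columns in different taxa.
    """
    # eligibility: subtree count >= min_sequences, then close under ancestry
    eligible: set[str] = set()
    for node in taxonomy.nodes():
        n = len(alignment.taxon_sequences(taxonomy, node.name))
        if n >= config.min_sequences:
            eligible.add(node.name)
    included: set[str] = set()
    for name in eligible:
        included.update(n.name for n in taxonomy.lineage(name))
    if not included:
        included = {taxonomy.root.name}

    root_seqs = alignment.taxon_sequences(taxonomy, taxonomy.root.name)
    root_profile = column_profile(root_seqs, alignment.width)
    blocks = partition_blocks(
        root_profile, config.block_size, config.conservation_cutoff
    )

    out: dict[str, TaxonStatistics] = {}
    for node in taxonomy.nodes():  # deterministic preorder
        if node.name not in included:
            continue
        members = alignment.taxon_sequences(taxonomy, node.name)
        if not members:
            continue
        profile = (
            root_profile
            if node.name == taxonomy.root.name
            else column_profile(members, alignment.width)
        )
        ts = TaxonStatistics(node.name, len(members), profile)
        for block in blocks:
            conserved = [
                c
                for c in range(block.start, block.end + 1)
                if profile[c].conservation > config.conservation_cutoff
            ]
            scores: dict[str, float] = {}
            for s in members:
                placement = sequence_block_placement(s, conserved)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    scores[s.id] = subsequence_block_score(
                        placement, conserved, profile, config.composition_weight
                    )
            nt_counts = [
                sum(
                    1
                    for c in range(block.start, block.end + 1)
                    if s.symbols[c] != "-"
                )
                for s in members
            ]
            ts.blocks.append(
                BlockStatistics(
                    block=block,
                    conserved_columns=conserved,
                    sequence_scores=scores,
                    mean_score=sum(scores.values()) / len(scores) if scores else 0.0,
                    min_nucleotides=min(nt_counts),
                    max_nucleotides=max(nt_counts),
                )
            )
        out[node.name] = ts
    return out


# ---------------------------------------------------------------------------
# Serialization (versioned JSON)
# ---------------------------------------------------------------------------


def stats_to_dict(
    stats: Mapping[str, TaxonStatistics], config: Config
) -> dict:
    """JSON-ready form; all column coordinates 1-based inclusive."""
    taxa = {}
    for name, ts in stats.items():
        taxa[name] = {
            "n_sequences": ts.n_sequences,
            "conservation": [round(c.conservation, 10) for c in ts.columns],
            "composition": {
                p: [round(c.composition[p], 10) for c in ts.columns]
                for p in NUCLEOTIDES
            },
            "blocks": [
                {
                    "index": bs.block.index + 1,
                    "start": bs.block.start + 1,
                    "end": bs.block.end + 1,
                    "conserved_columns": [c + 1 for c in bs.conserved_columns],
                    "mean_score": round(bs.mean_score, 10),
                    "sequence_scores": {
                        k: round(v, 10) for k, v in sorted(bs.sequence_scores.items())
                    },
                    "min_nucleotides": bs.min_nucleotides,
                    "max_nucleotides": bs.max_nucleotides,
                }
                for bs in ts.blocks
            ],
        }
    return {
        "format_version": STATS_FORMAT_VERSION,
        "config": config.to_dict(),
        "taxa": taxa,
    }


def write_stats(stats, config: Config, dest) -> None:
    data = stats_to_dict(stats, config)
    if hasattr(dest, "write"):
        json.dump(data, dest, indent=1, sort_keys=True)
    else:
        with open(dest, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
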