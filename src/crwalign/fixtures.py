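"""Deterministic toy and synthetic inputs.

Three generators cover all testing needs without external data:

* :func:`figure1_fixture` — a hand-built 10-sequence, 34-column template
  over three taxa (bacillales < bacilli < bacteria) reconstructed so that
  every worked statistic of the block-profile method comes out exactly:
  the 6/7 and 7/7 conservation cases, the {C:1/3, G:2/3} and
  {A:1/7, C:2/7, G:4/7} compositions, six blocks of (5,5,5,5,5,3)
  conserved columns, a maximum block score of 1.8, and a bacilli block-5
  average of 1.6653 (printed as 1.66).  The sequence letters themselves
  are a reconstruction, not a transcription.

* :func:`figure3_fixture` — a 7-sequence structured template over three
  nodes (one hairpin: tail, 8-bp helix, loop, tail) for the descriptor
  engine.

* :func:`synth_template` / :func:`synth_queries` — parameterized synthetic
  templates with known residue->column truth, built from repeating
  100-column structural units (conserved strand, 8-bp helix, loop with a
  variable insert region, closing strand, long connector with a second
  variable region).  Substitutions are applied per taxon and per sequence;
  indels only inside the designated variable regions, so the alignment
  grid itself is the truth.
"""

from __future__ import annotations

import numpy as np

from .core import (
    GAP,
    NUCLEOTIDES,
    AlignedSequence,
    QuerySequence,
    TaxonomyTree,
    TemplateAlignment,
)
from .descriptor import CANONICAL_PAIRS, Descriptor

# ---------------------------------------------------------------------------
# The figure1 fixture: the worked-example template (10 sequences, 3 taxa)
# ---------------------------------------------------------------------------

# Column table: one string per column, rows seq1..seq10.
# seq1-3: bacillales (genera bacillus, bacillus, listeria)
# seq4-7: additional bacilli; seq8-10: other bacteria (5'-truncated).
_F1_COLUMNS = [
    "GACUGAC---",  # 1   block 1: conserved (partials excluded -> 7/7)
    "CGUACGU---",  # 2
    "AUGCAUG---",  # 3
    "UCAGUCA---",  # 4
    "GACUGAC---",  # 5
    "AA--------",  # 6   unconserved spacer
    "AAACGUCCUG",  # 7   block 2: conserved
    "CCCAUGAAGU",  # 8
    "CGGACGGGGC",  # 9   "column 3 of block 2": bacillales C1 G2; bacilli A1 C2 G4
    "UUUGACGGAC",  # 10
    "GGGUCAUUCA",  # 11
    "UU--------",  # 12  unconserved
    "GACUGACUGA",  # 13  block 3: conserved
    "CGUACGUACG",  # 14
    "AUGCAUGCAU",  # 15
    "UCAGUCAGUC",  # 16
    "GACUGACUGA",  # 17
    "---G---G--",  # 18  unconserved
    "CCCCCCCCCC",  # 19  block 4: identical everywhere -> score 1.8
    "AAAAAAAAAA",  # 20
    "GGGGGGGGGG",  # 21
    "CCCCCCCCCC",  # 22
    "UUUUUUUUUU",  # 23
    "--U-------",  # 24  unconserved
    "GGGGGG-GGG",  # 25  block 5 col 1: bacilli 6/7 = 0.857
    "GAGAAAGAAG",  # 26  block 5 col 2: bacilli 4 A / 3 G
    "GGGGGGGGGG",  # 27
    "CCCCC-----",  # 28  conserved only within bacillales (3/3; bacilli 5/7)
    "UUUUUUUUUU",  # 29
    "CCCCCCCCCC",  # 30
    "GACUGACUGA",  # 31  block 6: three conserved columns
    "CGUACGUACG",  # 32
    "A--A------",  # 33  unconserved
    "AUGCAUGCAU",  # 34
]

FIGURE1_TAXA = {
    "seq1": "bacillus",
    "seq2": "bacillus",
    "seq3": "listeria",
    "seq4": "bacilli",
    "seq5": "bacilli",
    "seq6": "bacilli",
    "seq7": "bacilli",
    "seq8": "bacteria",
    "seq9": "bacteria",
    "seq10": "bacteria",
}

_F1_LINEAGES = [
    "bacteria;bacilli;bacillales;bacillus",
    "bacteria;bacilli;bacillales;listeria",
]

# Landmarks (0-based columns) used by tests and the acceptance script.
FIGURE1_BLOCK2_COLUMN3 = 8  # the highlighted composition column
FIGURE1_BLOCK5_COLUMN1 = 24  # bacilli conservation 6/7
FIGURE1_BLOCK5_COLUMN2 = 25  # bacilli conservation 7/7, composition 4A/3G


def figure1_fixture() -> tuple[TemplateAlignment, TaxonomyTree]:
    n = len(_F1_COLUMNS[0])
    rows = ["".join(col[i] for col in _F1_COLUMNS) for i in range(n)]
    seqs = [
        AlignedSequence(f"seq{i + 1}", FIGURE1_TAXA[f"seq{i + 1}"], rows[i])
        for i in range(n)
    ]
    return TemplateAlignment(seqs), TaxonomyTree.from_lineages(_F1_LINEAGES)


# ---------------------------------------------------------------------------
# The figure3 fixture: structured toy template (7 sequences, 3 nodes, one hairpin)
# ---------------------------------------------------------------------------

# Layout (0-based columns): tail5 0-4 | helix5' 5-12 | loop 13-19 |
# helix3' 20-27 | tail3 28-39.  Pairs (5+k, 27-k) for k in 0..7.
_F3_BASE = "GCGAU" + "GGCAGCAC" + "UUCGAAA" + "GUGCUGCC" + "ACGUACGUACGU"
_F3_PAIRS = [(5 + k, 27 - k) for k in range(8)]


def _edit(row: str, changes: dict[int, str]) -> str:
    out = list(row)
    for col, ch in changes.items():
        out[col] = ch
    return "".join(out)


def figure3_fixture() -> tuple[TemplateAlignment, TaxonomyTree]:
    rows = {
        # node 1
        "seq1": _F3_BASE,
        "seq2": _edit(_F3_BASE, {28: "G"}),
        # node 2: compensatory helix change C7->U with G25->A (U-A pair)
        "seq3": _edit(_F3_BASE, {7: "U", 25: "A", 14: "C"}),
        # seq4 adds one non-compensatory change: G9->A gives an A-C mispair
        "seq4": _edit(_F3_BASE, {7: "U", 25: "A", 14: "C", 9: "A"}),
        # node 3: loop variation; seq7 has a 1-nt shorter loop
        "seq5": _edit(_F3_BASE, {15: "G"}),
        "seq6": _edit(_F3_BASE, {15: "G", 35: "G"}),
        "seq7": _edit(_F3_BASE, {15: "G", 19: GAP}),
    }
    taxa = {
        "seq1": "node1",
        "seq2": "node1",
        "seq3": "node2",
        "seq4": "node2",
        "seq5": "node3",
        "seq6": "node3",
        "seq7": "node3",
    }
    seqs = [AlignedSequence(k, taxa[k], v) for k, v in rows.items()]
    tree = TaxonomyTree.from_lineages(
        ["root;node1", "root;node2", "root;node3"]
    )
    return TemplateAlignment(seqs, pairs=_F3_PAIRS), tree


# ---------------------------------------------------------------------------
# Synthetic templates with known truth
# ---------------------------------------------------------------------------

_CHUNK = 100
# within-chunk offsets
_H5 = (19, 26)  # helix 5' strand columns (inclusive)
_H3 = (44, 51)  # helix 3' strand
_VAR_REGIONS = ((30, 39), (65, 84))  # indel-permitted column windows

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_CANONICAL = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"),
}


def _chunk_layout(n_columns: int):
    """Per-column roles: helix pair partners, variable flags, ancestor occupancy."""
    if n_columns <= 0 or n_columns % _CHUNK:
        raise ValueError("n_columns must be a positive multiple of 100")
    pairs: list[tuple[int, int]] = []
    variable = np.zeros(n_columns, dtype=bool)
    occupied = np.ones(n_columns, dtype=bool)
    for off in range(0, n_columns, _CHUNK):
        for k in range(_H5[1] - _H5[0] + 1):
            pairs.append((off + _H5[0] + k, off + _H3[1] - k))
        for lo, hi in _VAR_REGIONS:
            for c in range(lo, hi + 1):
                variable[off + c] = True
                if (c - lo) % 3 == 2:  # every third variable column starts empty
                    occupied[off + c] = False
    return pairs, variable, occupied


def _mutate(
    row: list[str],
    rng: np.random.Generator,
    rate: float,
    pair_of: dict[int, int],
) -> None:
    """In-place substitutions at ``rate``; helix changes are compensatory
    except for a 10% fraction that leaves a mispair."""
    for c, ch in enumerate(row):
        if ch == GAP:
            continue
        if c in pair_of and pair_of[c] < c:
            continue  # 3' partner handled with its 5' mate
        if rng.random() >= rate:
            continue
        if c in pair_of:
            j = pair_of[c]
            nt = NUCLEOTIDES[rng.integers(4)]
            row[c] = nt
            if rng.random() < 0.1:  # occasional mispair
                row[j] = NUCLEOTIDES[rng.integers(4)]
            else:
                row[j] = _COMPLEMENT[nt]
        else:
            choices = [n for n in NUCLEOTIDES if n != ch]
            row[c] = choices[rng.integers(3)]


def synth_template(
    n_taxa: int = 3,
    seqs_per_taxon: int = 10,
    n_columns: int = 600,
    structure_spec: str = "default",
    substitution_rate: float = 0.05,
    indel_rate: float = 0.02,
    seed: int = 1,
) -> tuple[TemplateAlignment, TaxonomyTree, list[tuple[int, int]], dict[str, str]]:
    """A synthetic structured template with per-residue column truth.

    Returns (alignment, taxonomy, base pairs, truth) where ``truth`` maps
    sequence id to its gapped row (the generating grid *is* the alignment,
    so each residue's true column is simply its column in the row).
    """
    if not (0 <= substitution_rate < 0.5 and 0 <= indel_rate < 0.5):
        raise ValueError("rates must lie in [0, 0.5)")
    if structure_spec != "default":
        raise ValueError("only the default structure layout is built in")
    rng = np.random.default_rng(seed)
    pairs, variable, occupied = _chunk_layout(n_columns)
    pair_of = {}
    for i, j in pairs:
        pair_of[i], pair_of[j] = j, i

    # root ancestor
    root = [GAP] * n_columns
    for c in range(n_columns):
        if occupied[c] and (c not in pair_of or pair_of[c] > c):
            root[c] = NUCLEOTIDES[rng.integers(4)]
    for i, j in pairs:
        root[j] = _COMPLEMENT[root[i]]

    seqs: list[AlignedSequence] = []
    lineages = []
    for t in range(n_taxa):
        taxon = f"taxon{t + 1}"
        lineages.append(f"root;{taxon}")
        ancestor = list(root)
        _mutate(ancestor, rng, substitution_rate, pair_of)
        for s in range(seqs_per_taxon):
            row = list(ancestor)
            _mutate(row, rng, substitution_rate, pair_of)
            for c in range(n_columns):
                if not variable[c]:
                    continue
                if row[c] != GAP and rng.random() < indel_rate:
                    row[c] = GAP  # deletion
                elif row[c] == GAP and rng.random() < indel_rate:
                    row[c] = NUCLEOTIDES[rng.integers(4)]  # insertion
            seqs.append(
                AlignedSequence(f"{taxon}_s{s + 1}", taxon, "".join(row))
            )
    alignment = TemplateAlignment(seqs, pairs=pairs)
    taxonomy = TaxonomyTree.from_lineages(lineages)
    truth = {s.id: s.symbols for s in seqs}
    return alignment, taxonomy, pairs, truth


def synth_queries(
    truth: dict[str, str],
    taxon_of: dict[str, str],
    n: int,
    divergence: float = 0.0,
    completeness_fraction: float = 1.0,
    seed: int = 1,
) -> tuple[list[QuerySequence], dict[str, str]]:
    """Queries derived from template rows, with their truth rows.

    Each query is a (possibly substituted, possibly end-truncated) copy of
    a template row; its truth row carries the same residues in the same
    columns, so realignment can be scored exactly.  ``divergence`` applies
    substitutions only (indels would invalidate the column truth);
    ``completeness_fraction`` < 1 trims both ends, producing the partial
    sequences the structure engine must reject.
    """
    if not 0 <= divergence < 0.5:
        raise ValueError("divergence must lie in [0, 0.5)")
    if not 0 < completeness_fraction <= 1:
        raise ValueError("completeness_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    ids = sorted(truth)
    queries: list[QuerySequence] = []
    truth_rows: dict[str, str] = {}
    for k in range(n):
        src = ids[k % len(ids)]
        row = list(truth[src])
        for c, ch in enumerate(row):
            if ch != GAP and rng.random() < divergence:
                row[c] = [x for x in NUCLEOTIDES if x != ch][rng.integers(3)]
        residue_cols = [c for c, ch in enumerate(row) if ch != GAP]
        keep = max(1, int(round(len(residue_cols) * completeness_fraction)))
        drop = len(residue_cols) - keep
        drop5 = drop // 2
        for c in residue_cols[:drop5] + residue_cols[len(residue_cols) - (drop - drop5):]:
            row[c] = GAP
        qid = f"q{k + 1}_{src}"
        truth_rows[qid] = "".join(row)
        queries.append(
            QuerySequence(
                qid,
                "".join(ch for ch in row if ch != GAP),
                taxon_hint=taxon_of.get(src),
            )
        )
    return queries, truth_rows


# ---------------------------------------------------------------------------
# Sampling sequences from a descriptor's constraint distributions
# ---------------------------------------------------------------------------


def _draw(rng: np.random.Generator, weights: dict) -> object:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def sample_from_descriptor(
    descriptor: Descriptor,
    n: int,
    seed: int = 1,
    taxon: str = "root",
) -> list[QuerySequence]:
    """Sequences drawn from a descriptor's constraint distributions.

    Element lengths are drawn from the observed histograms — jointly
    rejection-sampled so the total log-weight clears the descriptor's
    cutoff — and residues from the per-position profiles; helix strands
    are drawn so every pair position is canonical (zero mispairs).
    Sampled sequences therefore satisfy every descriptor constraint
    without exceptions.
    """
    import math

    rng = np.random.default_rng(seed)
    section = descriptor.section(taxon)
    elements = descriptor.structure.elements
    out = []
    for k in range(n):
        # joint length vector satisfying the weight-score cutoff
        for _ in range(200):
            lengths = {}
            total = 0.0
            for el in elements:
                c = section.constraints[el.index]
                L = _draw(rng, c.length_weights)
                lengths[el.index] = L
                total += math.log2(c.length_weights[L])
                if el.kind == "helix5" and c.mispair_weights:
                    total += math.log2(
                        c.mispair_weights.get(0, max(c.mispair_weights.values()))
                    )
            if total >= section.cutoff:
                break
        frags: dict[int, str] = {}
        for el in elements:
            c = section.constraints[el.index]
            L = lengths[el.index]
            if el.kind == "helix3" and el.sister in frags:
                # pair positions are 5'-anchored here, 3'-anchored on the
                # sister strand: position t pairs with sister position t
                mate = frags[el.sister][::-1]
                res = []
                for t in range(L):
                    prof = c.profile[t] if t < len(c.profile) else {}
                    if t < len(mate):
                        joint = {
                            y: w
                            for y, w in prof.items()
                            if (mate[t], y) in CANONICAL_PAIRS
                        }
                        if joint:
                            res.append(_draw(rng, joint))
                            continue
                    res.append(_draw(rng, prof) if prof else "A")
                frags[el.index] = "".join(res)
            else:
                sis_prof = None
                if el.kind == "helix5" and el.sister is not None:
                    sis_prof = section.constraints[el.sister].profile
                res = []
                for t in range(L):
                    prof = c.profile[t] if t < len(c.profile) else {}
                    if sis_prof is not None and t < len(sis_prof):
                        # keep only residues with a canonical in-profile
                        # partner so the sister strand can pair cleanly
                        mates = sis_prof[t]
                        filtered = {
                            x: w
                            for x, w in prof.items()
                            if any((x, y) in CANONICAL_PAIRS for y in mates)
                        }
                        if filtered:
                            prof = filtered
                    res.append(_draw(rng, prof) if prof else "A")
                frag = "".join(res)
                if el.kind == "helix5":
                    frag = frag[::-1]  # profile order is 3'-anchored
                frags[el.index] = frag
        seq = "".join(frags[el.index] for el in elements)
        out.append(QuerySequence(f"sampled{k + 1}", seq))
    return out
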