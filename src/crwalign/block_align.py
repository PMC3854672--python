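"""The block-profile alignment engine.

A query is aligned into the template block by block.  At the strict stage,
blocks whose average score clears 0.9 x the maximum score (1.62 by
default) are matched with stringent criteria: every conserved column must
receive a residue, the residue's nucleotide must have been observed at
that column in the scoring taxon, and only a couple of extra residues may
sit between adjacent conserved columns.  Each block is searched at the
lowest taxonomic node where it is eligible, then at successive ancestors.
Matches commit best-first (highest score, then widest margin over the
runner-up placement), so the strongest blocks anchor their neighbours'
search windows before weaker ones are decided.

At the relaxed stage (threshold x0.8 = 1.296 by default, deletions of
conserved columns permitted) each maximal run of still-unmatched blocks
between two anchors is placed jointly by a dynamic program, and every
block whose realized score clears the relaxed threshold is committed.
Residues left over at the very end are placed greedily by per-column
composition; overflow becomes insertion annotations rather than widening
the template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .config import Config
from .core import (
    GAP,
    ConfigurationError,
    QuerySequence,
    TaxonomyTree,
)
from .stats import (
    BlockStatistics,
    ColumnStats,
    TaxonStatistics,
    subsequence_block_score,
)

# blocks with fewer conserved columns carry too little signal to anchor
# the alignment on their own; they are only placed by the joint relaxed
# pass once their neighbours pin down the search window
MIN_ANCHOR_COLUMNS = 4


@dataclass
class BlockMatch:
    block_index: int
    taxon: str
    placement: dict[int, int]  # conserved column -> query residue index
    score: float
    deletions: int
    insertions: int

    @property
    def first_position(self) -> int:
        return min(self.placement.values())

    @property
    def last_position(self) -> int:
        return max(self.placement.values())


@dataclass
class AlignmentState:
    """Mutable per-query state: residue->column assignments plus a log."""

    query: QuerySequence
    width: int
    columns: list[Optional[int]] = field(default_factory=list)
    block_matches: dict[int, BlockMatch] = field(default_factory=dict)
    taxon: str = ""
    log: list[dict] = field(default_factory=list)
    insertions: list[tuple[int, int]] = field(default_factory=list)
    # (residue index, column after which it sits), 0-based; -1 = before col 1

    def __post_init__(self) -> None:
        if not self.columns:
            self.columns = [None] * len(self.query.symbols)

    @property
    def aligned_count(self) -> int:
        return sum(1 for c in self.columns if c is not None)

    def commit(self, match: BlockMatch) -> None:
        for col, q in match.placement.items():
            if self.columns[q] is not None:
                raise ConfigurationError("residue assigned twice")
            self.columns[q] = col
        self.block_matches[match.block_index] = match

    def to_row(self) -> str:
        row = [GAP] * self.width
        for q, col in enumerate(self.columns):
            if col is not None:
                row[col] = self.query.symbols[q]
        return "".join(row)


# ---------------------------------------------------------------------------
# Candidate block matches (strict-style enumeration)
# ---------------------------------------------------------------------------


def _window(
    state: AlignmentState, start: int, end: int
) -> tuple[int, int, Optional[int], Optional[int]]:
    """Query positions available for a block spanning columns [start, end].

    Returns (wlo, whi, left anchor column, right anchor column); positions
    wlo..whi-1 lie strictly between residues already assigned to columns
    flanking the block.
    """
    wlo, whi = 0, len(state.columns)
    left_col = right_col = None
    for q, col in enumerate(state.columns):
        if col is None:
            continue
        if col < start and q >= wlo:
            wlo, left_col = q + 1, col
        if col > end and q < whi:
            whi, right_col = q, col
    return wlo, whi, left_col, right_col


def candidate_matches(
    query: QuerySequence,
    state: AlignmentState,
    block_stats: BlockStatistics,
    profile: Sequence[ColumnStats],
    threshold: float,
    allow_deletion: bool,
    max_insertions: int,
    config: Config = Config(),
    taxon: str = "",
    limit: int = 200,
) -> list[BlockMatch]:
    """Enumerate acceptable placements of query residues on a block.

    A placement maps the block's (taxon-specific) conserved columns to
    strictly increasing query positions inside the window implied by
    already-anchored neighbour blocks.  The residue run between two
    matched conserved columns may exceed the count of template columns
    between them by at most ``max_insertions``; every conserved column
    must receive a residue (with a nucleotide observed at that column in
    the taxon) unless ``allow_deletion``.  Matches scoring below
    ``threshold`` are dropped; the remainder come back sorted by score,
    then fewest indels, then leftmost position.
    """
    y = block_stats.conserved_columns
    if not y:
        return []
    n = len(y)
    w = config.composition_weight
    block = block_stats.block
    wlo, whi, left_col, right_col = _window(state, block.start, block.end)
    if whi - wlo < (1 if allow_deletion else n):
        return []
    cons = [profile[c].conservation for c in y]
    comp = [profile[c].composition for c in y]
    suffix_cons = [0.0] * (n + 1)
    for k in range(n - 1, -1, -1):
        suffix_cons[k] = suffix_cons[k + 1] + cons[k]
    span_cap = block_stats.max_nucleotides + max_insertions

    symbols = query.symbols
    results: list[BlockMatch] = []
    budget = [100_000]  # DFS node budget: search is truncated, never wrong

    def sort_results() -> None:
        results.sort(
            key=lambda m: (
                -m.score,
                m.insertions + m.deletions,
                m.first_position,
            )
        )

    def emit(placement, cons_sum, comp_sum, dels, ins):
        score = cons_sum / n + w * comp_sum / len(placement)
        if score >= threshold - 1e-12:
            results.append(
                BlockMatch(block.index, taxon, dict(placement), score, dels, ins)
            )
            if len(results) > 4 * limit:
                sort_results()
                del results[limit:]

    def dfs(k, prev_pos, prev_col, first_pos, placement, cons_sum, comp_sum,
            dels, ins):
        """Place y[k]; prev_pos/prev_col describe the last matched pair."""
        budget[0] -= 1
        if budget[0] <= 0:
            return
        if k == n:
            if placement:
                emit(placement, cons_sum, comp_sum, dels, ins)
            return
        rem = n - k
        z_now = len(placement)
        bound = (cons_sum + suffix_cons[k]) / n + w * (comp_sum + rem) / (
            z_now + rem
        )
        if bound >= threshold - 1e-12:
            if prev_pos is None:
                lo = wlo
                hi = whi
                if left_col is not None:
                    lo_cap = wlo + (y[k] - left_col - 1) + max_insertions
                    hi = min(hi, lo_cap + 1)
            else:
                capacity = y[k] - prev_col - 1 + max_insertions
                lo = prev_pos + 1
                hi = min(whi, prev_pos + 2 + capacity)
            if not allow_deletion:
                hi = min(hi, whi - (rem - 1))
            for pos in range(lo, hi):
                if first_pos is not None and pos - first_pos >= span_cap:
                    break
                if right_col is not None and (whi - 1 - pos) > (
                    right_col - y[k] - 1
                ) + max_insertions:
                    continue
                nt = symbols[pos]
                if not allow_deletion and comp[k].get(nt, 0.0) == 0.0:
                    continue  # strict stage: nucleotide never seen here
                gap_used = 0 if prev_pos is None else pos - prev_pos - 1
                natural = 0 if prev_pos is None else y[k] - prev_col - 1
                placement[y[k]] = pos
                dfs(
                    k + 1,
                    pos,
                    y[k],
                    pos if first_pos is None else first_pos,
                    placement,
                    cons_sum + cons[k],
                    comp_sum + comp[k].get(nt, 0.0),
                    dels,
                    ins + max(0, gap_used - natural),
                )
                del placement[y[k]]
            if allow_deletion:
                dfs(k + 1, prev_pos, prev_col, first_pos, placement,
                    cons_sum, comp_sum, dels + 1, ins)

    dfs(0, None, None, None, {}, 0.0, 0.0, 0, 0)
    sort_results()
    del results[limit:]
    return results


# ---------------------------------------------------------------------------
# Taxon selection
# ---------------------------------------------------------------------------


def select_taxon(
    query: QuerySequence,
    taxonomy: TaxonomyTree,
    stats: Mapping[str, TaxonStatistics],
    config: Config = Config(),
) -> str:
    """Choose the taxonomic node whose statistics will drive the alignment.

    With a name hint that matches a node of the template taxonomy, the
    lowest ancestor-or-self with statistics is used.  Otherwise a
    superficial pass (strict stage only, no taxonomy climb) is run against
    every statistics-bearing taxon at depth <= the leaf level, and the
    taxon aligning the most query residues wins; ties go to the shallower
    node, then to statistics order.
    """
    if not stats:
        raise ConfigurationError("no alignment statistics available")
    if query.taxon_hint and query.taxon_hint in taxonomy:
        for node in reversed(taxonomy.lineage(query.taxon_hint)):
            if node.name in stats:
                return node.name
    order = {name: i for i, name in enumerate(stats)}
    best = None
    best_name = None
    for name in stats:
        if taxonomy.depth(name) > config.leaf_level:
            continue
        state = align_sequence(
            query, stats, taxonomy, config, taxon=name, superficial=True
        )
        key = (-state.aligned_count, taxonomy.depth(name), order[name])
        if best is None or key < best:
            best, best_name = key, name
    if best_name is None:
        raise ConfigurationError(
            f"no statistics-bearing taxon at depth <= {config.leaf_level}"
        )
    return best_name


# ---------------------------------------------------------------------------
# Relaxed stage: joint placement of unmatched block runs
# ---------------------------------------------------------------------------


def _relaxed_pass(
    query: QuerySequence,
    state: AlignmentState,
    stats: Mapping[str, TaxonStatistics],
    path: Sequence[str],
    threshold: float,
    config: Config,
    stage_name: str,
) -> bool:
    """One joint dynamic-programming pass over runs of unmatched blocks.

    For each maximal run of unmatched blocks between two anchors, all of
    the run's conserved columns (each block taken at the lowest taxon
    where its average score clears ``threshold``) are placed together:
    the DP maximizes the summed per-column gain (C_i + w N_i) / |Y_b|,
    allowing deletions and bounded insertions, with a tiny penalty for
    drifting off the anchor-implied diagonal.  Each block's realized
    score is then evaluated with the exact formula and the block commits
    only if it clears ``threshold``.  Returns True if anything committed.
    """
    n_blocks = len(next(iter(stats.values())).blocks)
    unmatched = [b for b in range(n_blocks) if b not in state.block_matches]
    if not unmatched:
        return False
    runs: list[list[int]] = [[unmatched[0]]]
    for b in unmatched[1:]:
        if b == runs[-1][-1] + 1:
            runs[-1].append(b)
        else:
            runs.append([b])

    w8 = config.composition_weight
    max_ins = config.max_insertions_relaxed
    MAXDEL = 12  # longest tolerated run of consecutive conserved-column deletions
    LAM = 1e-4  # diagonal-drift tie-break, far below any composition signal
    committed = False

    for run in runs:
        chosen: list[tuple[int, str, BlockStatistics]] = []
        for bi in run:
            for tname in path:
                bs = stats[tname].blocks[bi]
                if bs.mean_score >= threshold and bs.conserved_columns:
                    chosen.append((bi, tname, bs))
                    break
        if not chosen:
            continue
        first_block = stats[path[0]].blocks[run[0]].block
        last_block = stats[path[0]].blocks[run[-1]].block
        wlo, whi, left_col, right_col = _window(
            state, first_block.start, last_block.end
        )
        W = whi - wlo
        if W <= 0:
            continue
        cols: list[tuple[int, float, dict, int, int]] = []
        for bi, tname, bs in chosen:
            prof = stats[tname].columns
            ylen = len(bs.conserved_columns)
            for c in bs.conserved_columns:
                cols.append(
                    (c, prof[c].conservation, prof[c].composition, bi, ylen)
                )
        cols.sort(key=lambda t: t[0])
        K = len(cols)
        NEG = float("-inf")
        anchor = left_col if left_col is not None else -1
        dp = [[NEG] * W for _ in range(K)]
        back: list[list[Optional[tuple[int, int]]]] = [
            [None] * W for _ in range(K)
        ]
        pref: list[list[tuple[float, int]]] = [
            [(NEG, -1)] * W for _ in range(K)
        ]
        for k in range(K):
            col, C, compd, bi, ylen = cols[k]
            for pos in range(W):
                nt = query.symbols[wlo + pos]
                gain = (C + w8 * compd.get(nt, 0.0)) / ylen
                pen = LAM * abs(pos - (col - anchor - 1))
                best, bp = NEG, None
                if k <= MAXDEL:
                    # y[k] is the first matched column of the whole run
                    if left_col is None or pos <= (col - anchor - 1) + max_ins:
                        best, bp = 0.0, None
                for k2 in range(k - 1, max(-1, k - 2 - MAXDEL), -1):
                    if pos == 0:
                        break
                    col2 = cols[k2][0]
                    capacity = col - col2 - 1 + max_ins
                    m, mpos = pref[k2][pos - 1]
                    if m > best:
                        if pos - 1 - mpos <= capacity and mpos >= 0:
                            best, bp = m, (k2, mpos)
                        else:
                            lo2 = max(0, pos - 1 - capacity)
                            for p2 in range(pos - 1, lo2 - 1, -1):
                                if dp[k2][p2] > best:
                                    best, bp = dp[k2][p2], (k2, p2)
                                    break
                if best > NEG:
                    dp[k][pos] = best + gain - pen
                    back[k][pos] = bp
            run_best, run_pos = NEG, -1
            row = dp[k]
            prow = pref[k]
            for pos in range(W):
                if row[pos] > run_best:
                    run_best, run_pos = row[pos], pos
                prow[pos] = (run_best, run_pos)

        # best terminal cell honouring trailing deletions and right capacity
        best_end, end_cell = NEG, None
        for k in range(max(0, K - 1 - MAXDEL), K):
            for pos in range(W):
                if dp[k][pos] == NEG:
                    continue
                if right_col is not None and (whi - 1 - pos) > (
                    right_col - cols[k][0] - 1
                ) + max_ins:
                    continue
                if dp[k][pos] > best_end:
                    best_end, end_cell = dp[k][pos], (k, pos)
        if end_cell is None:
            continue
        placement: dict[int, int] = {}
        k, pos = end_cell
        while True:
            placement[cols[k][0]] = wlo + pos
            bp = back[k][pos]
            if bp is None:
                break
            k, pos = bp

        for bi, tname, bs in chosen:
            pl = {
                c: placement[c] for c in bs.conserved_columns if c in placement
            }
            if not pl:
                continue
            nts = {c: query.symbols[p] for c, p in pl.items()}
            score = subsequence_block_score(
                nts, bs.conserved_columns, stats[tname].columns, w8
            )
            if score < threshold:
                continue
            dels = len(bs.conserved_columns) - len(pl)
            match = BlockMatch(bi, tname, pl, score, dels, 0)
            state.commit(match)
            state.log.append(
                {
                    "stage": stage_name,
                    "taxon": tname,
                    "block": bi + 1,
                    "score": round(score, 6),
                    "candidates": "joint",
                }
            )
            committed = True
    return committed


# ---------------------------------------------------------------------------
# Final fill of leftover residues
# ---------------------------------------------------------------------------


def _fill_unassigned(
    state: AlignmentState,
    profile: Sequence[ColumnStats],
    composition_weight: float = 0.8,
) -> None:
    """Place leftover residues between anchors by per-column composition.

    Each maximal run of unassigned residues is assigned, order-preserving,
    to the columns strictly between its flanking anchors so that the sum
    of per-column gains (conservation + weighted composition, with a tiny
    penalty for drifting off the anchor-implied diagonal) is maximal
    (dynamic program); residues that do not fit become insertion
    annotations.
    """
    cols = state.columns
    L = len(cols)
    q = 0
    while q < L:
        if cols[q] is not None:
            q += 1
            continue
        run_start = q
        while q < L and cols[q] is None:
            q += 1
        run_end = q  # exclusive
        left_col = cols[run_start - 1] if run_start else -1
        right_col = cols[run_end] if run_end < L else state.width
        residues = list(range(run_start, run_end))
        columns = list(range(left_col + 1, right_col))
        m, nc = len(residues), len(columns)
        if nc == 0:
            for r in residues:
                state.insertions.append((r, left_col))
            continue
        EPS = 1e-6  # prefer fewer insertion annotations on ties
        NEG = float("-inf")
        dp = [[0.0] * (nc + 1) for _ in range(m + 1)]
        back = [[0] * (nc + 1) for _ in range(m + 1)]  # 0 skip col, 1 assign, 2 skip res
        for i in range(m + 1):
            for j in range(nc + 1):
                if i == 0 and j == 0:
                    continue
                best, move = NEG, 0
                if j > 0 and dp[i][j - 1] > best:
                    best, move = dp[i][j - 1], 0
                if i > 0 and j > 0:
                    nt = state.query.symbols[residues[i - 1]]
                    cs = profile[columns[j - 1]]
                    gain = (
                        cs.conservation
                        + composition_weight * cs.composition.get(nt, 0.0)
                        - 1e-4 * abs((j - 1) - (i - 1))
                    )
                    cand = dp[i - 1][j - 1] + gain
                    if cand > best:
                        best, move = cand, 1
                if i > 0:
                    cand = dp[i - 1][j] - EPS
                    if cand > best:
                        best, move = cand, 2
                dp[i][j], back[i][j] = best, move
        i, j = m, nc
        while i > 0 or j > 0:
            move = back[i][j]
            if move == 0:
                j -= 1
            elif move == 1:
                cols[residues[i - 1]] = columns[j - 1]
                i -= 1
                j -= 1
            else:
                anchor = columns[j - 1] if j else left_col
                state.insertions.append((residues[i - 1], anchor))
                i -= 1
    state.insertions.sort()


# ---------------------------------------------------------------------------
# The iterative alignment procedure
# ---------------------------------------------------------------------------


def align_sequence(
    query: QuerySequence,
    stats: Mapping[str, TaxonStatistics],
    taxonomy: TaxonomyTree,
    config: Config = Config(),
    taxon: Optional[str] = None,
    superficial: bool = False,
) -> AlignmentState:
    """Run the full iterative block alignment for one query.

    Strict stage: each block is searched at the lowest taxon of the
    lineage where its average score clears the strict threshold, and the
    best match found anywhere (highest score, then widest margin over the
    runner-up placement, then fewest indels) commits first, one commit
    per sweep, so strong blocks anchor their neighbours' windows.  Relaxed stage(s):
    runs of leftover blocks are placed jointly at the relaxed threshold
    with deletions permitted.  Finally remaining residues are placed by
    composition.  A ``superficial`` run performs only the strict stage at
    the given taxon without climbing (used by taxon selection).
    """
    if taxon is None:
        taxon = select_taxon(query, taxonomy, stats, config)
    if taxon not in stats:
        raise ConfigurationError(f"no statistics for taxon {taxon!r}")
    some = next(iter(stats.values()))
    width = len(some.columns)
    state = AlignmentState(query=query, width=width, taxon=taxon)

    if superficial:
        path = [taxon]
    else:
        path = [
            n.name for n in reversed(taxonomy.lineage(taxon)) if n.name in stats
        ]

    # strict stage
    thr = config.strict_threshold
    cache: dict = {}
    while True:
        candidates = []
        for bi in range(len(some.blocks)):
            if bi in state.block_matches:
                continue
            for tname in path:
                bs = stats[tname].blocks[bi]
                if (
                    bs.mean_score < thr
                    or len(bs.conserved_columns) < MIN_ANCHOR_COLUMNS
                ):
                    continue
                sig = _window(state, bs.block.start, bs.block.end)
                key = (bi, tname)
                if key in cache and cache[key][0] == sig:
                    matches = cache[key][1]
                else:
                    matches = candidate_matches(
                        query,
                        state,
                        bs,
                        stats[tname].columns,
                        thr,
                        False,
                        config.max_insertions_strict,
                        config,
                        taxon=tname,
                    )
                    cache[key] = (sig, matches)
                if matches:
                    margin = (
                        matches[0].score - matches[1].score
                        if len(matches) > 1
                        else float("inf")
                    )
                    candidates.append((matches[0], margin, len(matches)))
                    break  # lowest eligible taxon wins for this block
        if not candidates:
            break
        candidates.sort(
            key=lambda t: (
                -t[0].score,
                -t[1],
                t[0].deletions + t[0].insertions,
                t[0].first_position,
                t[0].block_index,
            )
        )
        match, margin, n_found = candidates[0]
        state.commit(match)
        state.log.append(
            {
                "stage": "strict",
                "taxon": match.taxon,
                "block": match.block_index + 1,
                "score": round(match.score, 6),
                "candidates": n_found,
            }
        )

    if superficial:
        return state

    # relaxed stage(s)
    thr = config.strict_threshold
    for r in range(1 + config.extra_relaxations):
        thr *= config.relaxation_factor
        while _relaxed_pass(
            query, state, stats, path, thr, config, f"relaxed{r + 1}"
        ):
            pass

    _fill_unassigned(state, stats[path[0]].columns, config.composition_weight)
    return state


def align_batch(
    queries: Sequence[QuerySequence],
    stats: Mapping[str, TaxonStatistics],
    taxonomy: TaxonomyTree,
    config: Config = Config(),
) -> list[AlignmentState]:
    """Align queries independently (results match one-at-a-time runs)."""
    return [align_sequence(q, stats, taxonomy, config) for q in queries]
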