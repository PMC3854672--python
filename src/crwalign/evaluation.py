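"""Pairwise alignment quality metrics.

Pairwise sequence identity (PSI) of rows i and j is |B|/|E|: B the
columns where both rows carry a nucleotide, E the columns where either
does (columns gapped in both are ignored).  As written this measures
co-occupancy, not residue identity; a matched-residue variant (counting
only B-columns whose nucleotides agree) is exposed behind ``mode`` since
identity binning of rRNA pairs is only meaningful with it.  The default
is the verbatim co-occupancy form.

Accuracy of a test alignment against a reference compares "stacks": a
nucleotide of i stacks with the specific j-nucleotide (or the gap state)
sharing its column.  S counts the reference stacks reproduced exactly in
the test alignment, and accuracy = |S|/|E| with E taken from the
reference.  Identity-binned summaries aggregate pair accuracies by
reference PSI (bins left-closed, last bin closed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import CrwalignError, TemplateAlignment


class UndefinedPairError(CrwalignError):
    """Both rows are all-gap: the pair has no columns to compare."""


class IntegrityError(CrwalignError):
    """Test and reference alignments disagree on a degapped sequence."""


@dataclass
class PairwiseReport:
    i: str
    j: str
    psi: float
    accuracy: float
    n_both: int  # |B|
    n_either: int  # |E|
    n_identical: int  # |S|


def _occupancy(row: str) -> list[int]:
    """Residue ordinal per column (-1 for gap)."""
    out = []
    k = 0
    for ch in row:
        if ch == "-":
            out.append(-1)
        else:
            out.append(k)
            k += 1
    return out


def pairwise_identity(
    alignment: TemplateAlignment,
    i: str,
    j: str,
    mode: str = "co-occupancy",
) -> float:
    """PSI of rows ``i`` and ``j``; see the module docstring for ``mode``
    ("co-occupancy", the verbatim definition, or "identity")."""
    if i == j:
        raise ValueError("PSI requires two distinct sequences")
    a, b = alignment[i].symbols, alignment[j].symbols
    both = either = hits = 0
    for x, y in zip(a, b):
        xa, ya = x != "-", y != "-"
        if xa or ya:
            either += 1
        if xa and ya:
            both += 1
            if x == y:
                hits += 1
    if either == 0:
        raise UndefinedPairError(f"pair ({i}, {j}) shares no occupied columns")
    return (hits if mode == "identity" else both) / either


def _stacks(row_i: str, row_j: str) -> set[tuple[int, int]]:
    """The pair's stack set: (ordinal in i, ordinal in j) per column with a
    nucleotide in either row; gap states are encoded as -1."""
    occ_i, occ_j = _occupancy(row_i), _occupancy(row_j)
    return {
        (ki, kj)
        for ki, kj in zip(occ_i, occ_j)
        if ki != -1 or kj != -1
    }


def pairwise_accuracy(
    test: TemplateAlignment,
    reference: TemplateAlignment,
    i: str,
    j: str,
) -> PairwiseReport:
    """Stack-identity accuracy of the test alignment for one pair."""
    for seq_id in (i, j):
        ti = test[seq_id].degapped()
        ri = reference[seq_id].degapped()
        if ti != ri:
            raise IntegrityError(
                f"degapped sequence {seq_id!r} differs between alignments"
            )
    ref_stacks = _stacks(reference[i].symbols, reference[j].symbols)
    test_stacks = _stacks(test[i].symbols, test[j].symbols)
    identical = len(ref_stacks & test_stacks)
    both = sum(1 for ki, kj in ref_stacks if ki != -1 and kj != -1)
    either = len(ref_stacks)
    if either == 0:
        raise UndefinedPairError(f"pair ({i}, {j}) shares no occupied columns")
    psi = both / either
    return PairwiseReport(i, j, psi, identical / either, both, either, identical)


DEFAULT_BINS = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def accuracy_table(
    test: TemplateAlignment,
    reference: TemplateAlignment,
    bins: Sequence[float] = DEFAULT_BINS,
    ids: Sequence[str] | None = None,
    psi_mode: str = "co-occupancy",
) -> pd.DataFrame:
    """Mean pair accuracy per reference-PSI bin.

    Bins are left-closed right-open except the last, which is closed;
    pairs below the first edge are dropped.  Empty bins are absent from
    the result rather than reported as zero.
    """
    edges = sorted(bins)
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    if ids is None:
        ids = reference.ids()
    rows = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            rep = pairwise_accuracy(test, reference, ids[a], ids[b])
            psi = (
                rep.psi
                if psi_mode == "co-occupancy"
                else pairwise_identity(reference, ids[a], ids[b], mode="identity")
            )
            k = None
            for e in range(len(edges) - 1):
                last = e == len(edges) - 2
                if edges[e] <= psi < edges[e + 1] or (
                    last and psi == edges[e + 1]
                ):
                    k = e
                    break
            if k is None:
                continue
            rows.append(
                {
                    "bin": f"{edges[k]:g}-{edges[k + 1]:g}",
                    "psi": psi,
                    "accuracy": rep.accuracy,
                }
            )
    df = pd.DataFrame(rows, columns=["bin", "psi", "accuracy"])
    if df.empty:
        return pd.DataFrame(columns=["bin", "n_pairs", "mean_accuracy"])
    out = (
        df.groupby("bin", sort=True)
        .agg(n_pairs=("accuracy", "size"), mean_accuracy=("accuracy", "mean"))
        .reset_index()
    )
    return out
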