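import numpy as np
import pytest

from crwalign.core import AlignedSequence, TemplateAlignment
from crwalign.evaluation import (
    IntegrityError,
    UndefinedPairError,
    accuracy_table,
    pairwise_accuracy,
    pairwise_identity,
)


def make_alignment(rows: dict[str, str]) -> TemplateAlignment:
    return TemplateAlignment(
        [AlignedSequence(k, "t", v) for k, v in rows.items()]
    )


# --- independent oracles, straight from the definitions ------------------


def oracle_psi(a: str, b: str) -> float:
    B = {c for c in range(len(a)) if a[c] != "-" and b[c] != "-"}
    E = {c for c in range(len(a)) if a[c] != "-" or b[c] != "-"}
    return len(B) / len(E)


def oracle_accuracy(test_i, test_j, ref_i, ref_j) -> float:
    """Explicit per-nucleotide stack comparison."""

    def stack_map(row_i, row_j):
        # nucleotide ordinal of i -> ordinal of j (or None for gap), plus
        # unmatched j-nucleotides stacked against gaps of i
        ki = kj = 0
        stacks = []
        for ci, cj in zip(row_i, row_j):
            si = ki if ci != "-" else None
            sj = kj if cj != "-" else None
            if ci != "-":
                ki += 1
            if cj != "-":
                kj += 1
            if si is not None or sj is not None:
                stacks.append((si, sj))
        return stacks

    ref = stack_map(ref_i, ref_j)
    test = set(stack_map(test_i, test_j))
    S = sum(1 for st in ref if st in test)
    return S / len(ref)


def random_row(rng, length, gap_p=0.25) -> str:
    row = "".join(
        rng.choice(list("ACGU-"), p=[(1 - gap_p) / 4] * 4 + [gap_p])
        for _ in range(length)
    )
    return row if set(row) != {"-"} else "A" * length


def shuffle_gaps(rng, row) -> str:
    """Same residues, different gap placement (a realignment of the row)."""
    residues = [c for c in row if c != "-"]
    slots = sorted(rng.choice(len(row), size=len(residues), replace=False))
    out = ["-"] * len(row)
    for s, r in zip(slots, residues):
        out[s] = r
    return "".join(out)


class TestPairwiseIdentity:
    def test_identical_ungapped_rows(self):
        aln = make_alignment({"a": "ACGU", "b": "ACGU"})
        assert pairwise_identity(aln, "a", "b") == 1.0

    def test_co_occupancy_count(self):
        # 3 both-occupied columns among 5 either-occupied
        aln = make_alignment({"a": "ACG-U", "b": "A-GUU"})
        assert pairwise_identity(aln, "a", "b") == pytest.approx(3 / 5)

    def test_fully_non_overlapping_rows(self):
        aln = make_alignment({"a": "AC--", "b": "--GU"})
        assert pairwise_identity(aln, "a", "b") == 0.0

    def test_matched_residue_variant(self):
        aln = make_alignment({"a": "ACG-U", "b": "AAG-U"})
        assert pairwise_identity(aln, "a", "b") == 1.0  # co-occupancy
        assert pairwise_identity(aln, "a", "b", mode="identity") == pytest.approx(
            3 / 4
        )

    def test_all_gap_pair_is_undefined(self):
        aln = make_alignment({"a": "----", "b": "----", "c": "GGAC"})
        with pytest.raises(UndefinedPairError):
            pairwise_identity(aln, "a", "b")

    def test_symmetry_on_random_rows(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            aln = make_alignment(
                {"a": random_row(rng, 20), "b": random_row(rng, 20)}
            )
            try:
                ab = pairwise_identity(aln, "a", "b")
            except UndefinedPairError:
                continue
            assert ab == pairwise_identity(aln, "b", "a")
            assert ab == pytest.approx(
                oracle_psi(aln["a"].symbols, aln["b"].symbols)
            )


class TestPairwiseAccuracy:
    def test_test_equals_reference_gives_one(self):
        aln = make_alignment({"a": "AC-GU", "b": "A-CGU"})
        rep = pairwise_accuracy(aln, aln, "a", "b")
        assert rep.accuracy == 1.0

    def test_single_column_shift_counted_by_oracle(self):
        ref = make_alignment({"a": "ACGUACGUAC-", "b": "-ACGUACGUAC"})
        test = make_alignment({"a": "ACGUACGUAC-", "b": "ACGUACGUAC-"})
        rep = pairwise_accuracy(test, ref, "a", "b")
        expected = oracle_accuracy(
            test["a"].symbols, test["b"].symbols,
            ref["a"].symbols, ref["b"].symbols,
        )
        assert rep.accuracy == pytest.approx(expected)
        assert rep.accuracy < 1.0

    def test_relative_shift_strictly_lowers_accuracy(self):
        # sliding one row against the other changes every stack partner
        ref = make_alignment({"a": "AC-", "b": "-GU"})
        shifted = make_alignment({"a": "-AC", "b": "GU-"})
        rep = pairwise_accuracy(shifted, ref, "a", "b")
        assert rep.accuracy < 1.0

    def test_differing_degapped_sequences_rejected(self):
        ref = make_alignment({"a": "ACGU", "b": "ACGU"})
        test = make_alignment({"a": "ACGA", "b": "ACGU"})
        with pytest.raises(IntegrityError):
            pairwise_accuracy(test, ref, "a", "b")

    def test_oracle_agreement_and_symmetry_on_random_realignments(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            ref_a = random_row(rng, 24)
            ref_b = random_row(rng, 24)
            ref = make_alignment({"a": ref_a, "b": ref_b})
            test = make_alignment(
                {"a": shuffle_gaps(rng, ref_a), "b": shuffle_gaps(rng, ref_b)}
            )
            rep = pairwise_accuracy(test, ref, "a", "b")
            expected = oracle_accuracy(
                test["a"].symbols, test["b"].symbols, ref_a, ref_b
            )
            assert rep.accuracy == pytest.approx(expected)
            rep_ji = pairwise_accuracy(test, ref, "b", "a")
            assert rep_ji.accuracy == pytest.approx(rep.accuracy)


class TestAccuracyTable:
    def test_identical_alignments_fill_bins_with_ones(self):
        rows = {"a": "ACGUACGU", "b": "ACGUACG-", "c": "ACGU-CGU"}
        aln = make_alignment(rows)
        table = accuracy_table(aln, aln, bins=(0.5, 0.75, 1.0))
        assert (table["mean_accuracy"] == 1.0).all()

    def test_bin_edges_left_closed(self):
        # PSI exactly 0.6 must land in the 0.6-0.7 bin
        ref = make_alignment({"a": "ACG-U", "b": "AC-GU"})
        psi = pairwise_identity(ref, "a", "b")
        assert psi == pytest.approx(0.6)
        table = accuracy_table(ref, ref, bins=(0.5, 0.6, 0.7, 1.0))
        assert list(table["bin"]) == ["0.6-0.7"]

    def test_empty_bins_absent_not_zero(self):
        aln = make_alignment({"a": "ACGU", "b": "ACGU"})
        table = accuracy_table(aln, aln, bins=(0.0, 0.5, 0.9, 1.0))
        assert list(table["bin"]) == ["0.9-1"]
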