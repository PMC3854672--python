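import numpy as np
import pytest

from crwalign.config import Config
from crwalign.core import AlignedSequence, TaxonomyTree, TemplateAlignment
from crwalign.fixtures import (
    FIGURE1_BLOCK2_COLUMN3,
    FIGURE1_BLOCK5_COLUMN1,
    FIGURE1_BLOCK5_COLUMN2,
)
from crwalign.stats import (
    EmptyColumnError,
    UnpartitionableError,
    build_taxon_statistics,
    column_profile,
    composition_values,
    conservation_value,
    partition_blocks,
    sequence_block_placement,
    subsequence_block_score,
)


class TestConservation:
    def test_six_of_seven(self, figure1):
        aln, tree, _, _ = figure1
        bacilli = aln.taxon_sequences(tree, "bacilli")
        value = conservation_value(bacilli, FIGURE1_BLOCK5_COLUMN1)
        assert value == pytest.approx(6 / 7)
        assert round(value, 2) == 0.86

    def test_all_seven(self, figure1):
        aln, tree, _, _ = figure1
        bacilli = aln.taxon_sequences(tree, "bacilli")
        assert conservation_value(bacilli, FIGURE1_BLOCK5_COLUMN2) == 1.0

    def test_partial_sequences_do_not_affect_leading_columns(self, figure1):
        # three root sequences are 5'-truncated; the leading columns are
        # still fully conserved because partials leave the denominator
        aln, tree, _, _ = figure1
        root = aln.taxon_sequences(tree, "bacteria")
        assert conservation_value(root, 0) == 1.0

    def test_all_excluded_defined_as_zero_with_warning(self):
        seqs = [AlignedSequence("a", "t", "--AC"), AlignedSequence("b", "t", "--AC")]
        with pytest.warns(UserWarning):
            assert conservation_value(seqs, 0) == 0.0


class TestComposition:
    def test_bacillales_one_c_two_g(self, figure1):
        aln, tree, _, _ = figure1
        members = aln.taxon_sequences(tree, "bacillales")
        comp = composition_values(members, FIGURE1_BLOCK2_COLUMN3)
        assert comp == pytest.approx({"A": 0, "C": 1 / 3, "G": 2 / 3, "U": 0})

    def test_bacilli_a1_c2_g4(self, figure1):
        aln, tree, _, _ = figure1
        members = aln.taxon_sequences(tree, "bacilli")
        comp = composition_values(members, FIGURE1_BLOCK2_COLUMN3)
        assert comp == pytest.approx(
            {"A": 1 / 7, "C": 2 / 7, "G": 4 / 7, "U": 0}
        )

    def test_single_symbol_column(self):
        seqs = [AlignedSequence(f"s{i}", "t", "U") for i in range(5)]
        assert composition_values(seqs, 0) == {"A": 0, "C": 0, "G": 0, "U": 1}

    def test_empty_column_raises(self):
        seqs = [AlignedSequence("a", "t", "A-"), AlignedSequence("b", "t", "C-")]
        with pytest.raises(EmptyColumnError):
            composition_values(seqs, 1)

    def test_fractions_sum_to_one_on_random_columns(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(2, 12)
            rows = [
                "".join(rng.choice(list("ACGU-"), size=8))
                for _ in range(n)
            ]
            rows = [r if set(r) != {"-"} else "A" * 8 for r in rows]
            seqs = [AlignedSequence(f"s{i}", "t", r) for i, r in enumerate(rows)]
            for col in range(8):
                try:
                    comp = composition_values(seqs, col)
                except EmptyColumnError:
                    continue
                assert sum(comp.values()) == pytest.approx(1.0)


class TestBlocks:
    def test_figure1_partition_shape(self, figure1):
        _, _, _, stats = figure1
        sizes = [
            len(b.block.conserved_columns) for b in stats["bacteria"].blocks
        ]
        assert sizes == [5, 5, 5, 5, 5, 3]

    def test_blocks_tile_without_overlap(self, figure1):
        aln, _, _, stats = figure1
        blocks = [b.block for b in stats["bacteria"].blocks]
        covered = []
        for b in blocks:
            covered.extend(range(b.start, b.end + 1))
        assert covered == list(range(aln.width))

    def test_exact_division(self):
        seqs = [AlignedSequence(f"s{i}", "t", "ACGU" * 5) for i in range(4)]
        profile = column_profile(seqs, 20)
        blocks = partition_blocks(profile, 5, 0.8)
        assert [len(b.conserved_columns) for b in blocks] == [5, 5, 5, 5]

    def test_single_block_when_size_equals_columns(self):
        seqs = [AlignedSequence(f"s{i}", "t", "ACGUACGU") for i in range(3)]
        profile = column_profile(seqs, 8)
        blocks = partition_blocks(profile, 8, 0.8)
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (0, 7)

    def test_no_conserved_columns_is_an_error(self):
        # partial-sequence exclusion means real alignments always conserve
        # their edge columns; the error contract is exercised directly
        from crwalign.stats import ColumnStats

        profile = [
            ColumnStats(0.5, {"A": 1.0, "C": 0, "G": 0, "U": 0}, 4)
            for _ in range(6)
        ]
        with pytest.raises(UnpartitionableError):
            partition_blocks(profile, 5, 0.8)

    def test_conservation_cutoff_is_strict(self):
        # an internal gap in one of five sequences: exactly 80% occupancy
        # must NOT count as highly conserved (the cutoff is strict)
        rows = ["AAC", "AAC", "AAC", "AAC", "A-C"]
        seqs = [AlignedSequence(f"s{i}", "t", r) for i, r in enumerate(rows)]
        profile = column_profile(seqs, 3)
        blocks = partition_blocks(profile, 1, 0.8)
        conserved = [c for b in blocks for c in b.conserved_columns]
        assert conserved == [0, 2]


class TestBlockScore:
    def test_maximum_score_is_1_8(self):
        rows = ["ACGUA"] * 6
        seqs = [AlignedSequence(f"s{i}", "t", r) for i, r in enumerate(rows)]
        profile = column_profile(seqs, 5)
        y = [0, 1, 2, 3, 4]
        placement = sequence_block_placement(seqs[0], y)
        assert subsequence_block_score(placement, y, profile) == pytest.approx(1.8)

    def test_hand_evaluated_block5_member(self, figure1):
        # Y = 5 bacilli conserved columns, C = (6/7, 1, 1, 1, 1);
        # member with composition values (1, 4/7, 1, 1, 1) scores
        # 4.857/5 + 0.8 * 4.571/5 = 0.9714 + 0.7314 = 1.7029
        aln, tree, _, stats = figure1
        bacilli = stats["bacilli"]
        assert bacilli.blocks[4].sequence_scores["seq2"] == pytest.approx(
            1.7029, abs=1e-4
        )

    def test_empty_subsequence_scores_zero_with_warning(self):
        rows = ["ACG"] * 3
        seqs = [AlignedSequence(f"s{i}", "t", r) for i, r in enumerate(rows)]
        profile = column_profile(seqs, 3)
        with pytest.warns(UserWarning):
            assert subsequence_block_score({}, [0, 1, 2], profile) == 0.0

    def test_score_against_symbol_by_symbol_oracle(self):
        """Eq-by-hand recount on random alignments must agree exactly."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 200:
            n_seq = int(rng.integers(3, 10))
            width = int(rng.integers(6, 20))
            rows = []
            for _ in range(n_seq):
                row = "".join(
                    rng.choice(list("ACGU-"), size=width, p=[0.23] * 4 + [0.08])
                )
                rows.append(row if set(row) != {"-"} else "A" * width)
            seqs = [
                AlignedSequence(f"s{i}", "t", r) for i, r in enumerate(rows)
            ]
            profile = column_profile(seqs, width)
            y = sorted(
                rng.choice(width, size=int(rng.integers(1, 6)), replace=False)
            )
            target = seqs[int(rng.integers(n_seq))]
            placement = sequence_block_placement(target, y)
            if not placement:
                continue
            got = subsequence_block_score(placement, y, profile)
            # independent recount straight from the raw rows
            z = [c for c in y if target.symbols[c] in "ACGU"]
            cons = 0.0
            for c in z:
                counted = [s for s in seqs if not s.is_partial_at(c)]
                cons += sum(
                    1 for s in counted if s.symbols[c] in "ACGU"
                ) / len(counted)
            comp = 0.0
            for c in z:
                with_nt = [s for s in seqs if s.symbols[c] in "ACGU"]
                comp += sum(
                    1 for s in with_nt if s.symbols[c] == target.symbols[c]
                ) / len(with_nt)
            expected = cons / len(y) + 0.8 * comp / len(z)
            assert got == pytest.approx(expected)
            checked += 1


class TestTaxonStatistics:
    def test_figure1_taxa_with_statistics(self, figure1):
        _, _, _, stats = figure1
        assert sorted(stats) == ["bacillales", "bacilli", "bacteria"]

    def test_block5_conserved_columns_vary_between_taxa(self, figure1):
        _, _, _, stats = figure1
        assert len(stats["bacillales"].blocks[4].conserved_columns) == 6
        assert len(stats["bacilli"].blocks[4].conserved_columns) == 5

    def test_bacilli_block5_average_matches_printed_value(self, figure1):
        _, _, _, stats = figure1
        assert stats["bacilli"].blocks[4].mean_score == pytest.approx(
            1.66, abs=0.01
        )

    def test_high_min_sequences_keeps_only_root(self, figure1):
        aln, tree, config, _ = figure1
        stats = build_taxon_statistics(
            aln, tree, config.replace(min_sequences=100)
        )
        assert list(stats) == ["bacteria"]

    def test_identical_sequences_score_1_8_everywhere(self):
        rows = ["ACGUACGUAC"] * 5
        seqs = [AlignedSequence(f"s{i}", "t", r) for i, r in enumerate(rows)]
        aln = TemplateAlignment(seqs)
        tree = TaxonomyTree.from_lineages(["root;t"])
        stats = build_taxon_statistics(
            aln, tree, Config(block_size=5, min_sequences=3)
        )
        for ts in stats.values():
            for bs in ts.blocks:
                assert bs.mean_score == pytest.approx(1.8)

    def test_majority_duplicate_never_decreases_block_average(self):
        rng = np.random.default_rng(3)
        rows = [
            "".join(rng.choice(list("ACGU"), size=10)) for _ in range(6)
        ]
        seqs = [AlignedSequence(f"s{i}", "t", r) for i, r in enumerate(rows)]
        tree = TaxonomyTree.from_lineages(["root;t"])
        cfg = Config(block_size=5, min_sequences=3)
        base = build_taxon_statistics(TemplateAlignment(seqs), tree, cfg)
        majority = "".join(
            max("ACGU", key=lambda p: sum(r[c] == p for r in rows))
            for c in range(10)
        )
        seqs2 = seqs + [AlignedSequence("dup", "t", majority)]
        more = build_taxon_statistics(TemplateAlignment(seqs2), tree, cfg)
        for b0, b1 in zip(base["t"].blocks, more["t"].blocks):
            assert b1.mean_score >= b0.mean_score - 1e-12
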