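"""MSA I/O, context trimming, species pairing, shuffle null, mutual
information, JSD conservation, ablations and hydrophobicity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepdock.msatools import (
    KYTE_DOOLITTLE, Msa, MsaRow, column_mi, interchain_mi_summary,
    jsd_conservation, map_context_columns, mean_hydrophobicity, msa_depth_ok,
    pair_by_species, peptide_sequence_variants, read_msa, shuffle_pairings,
    write_fasta,
)
from .oracles import oracle_column_mi

FASTA = """\
>query OX=9606
ACDEF
>seq1 OX=10090
ACDEW
>seq2 OX=7227
AC-EF
"""

A3M = """\
>query
ACDEF
>hit1
AcgCDEF
>hit2
A-DEF
"""

STOCKHOLM = """\
# STOCKHOLM 1.0
query_HUMAN    ACDEF
seq1_MOUSE     ACDEW
seq2_DROME     AC-EF
//
"""


class TestReadMsa:
    def test_fasta_with_species_tags(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(FASTA)
        msa = read_msa(p)
        assert msa.n_cols == 5 and msa.depth == 3
        assert [r.species for r in msa.rows] == ["9606", "10090", "7227"]
        assert msa.query == "ACDEF"

    def test_a3m_insertions_removed(self, tmp_path):
        p = tmp_path / "a.a3m"
        p.write_text(A3M)
        msa = read_msa(p)
        assert msa.n_cols == 5
        assert msa.rows[1].aligned == "ACDEF"  # lowercase states stripped
        assert msa.rows[2].aligned == "A-DEF"

    def test_stockholm_matches_fasta_rows(self, tmp_path):
        sto = tmp_path / "a.sto"
        sto.write_text(STOCKHOLM)
        msa = read_msa(sto)
        assert [r.aligned for r in msa.rows] == ["ACDEF", "ACDEW", "AC-EF"]
        assert msa.rows[0].species == "HUMAN"

    def test_write_read_roundtrip(self, small_msa, tmp_path):
        p = tmp_path / "out.fasta"
        write_fasta(small_msa, p)
        back = read_msa(p)
        assert [r.aligned for r in back.rows] == [r.aligned for r in small_msa.rows]

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            Msa(rows=[MsaRow("a", "ACD"), MsaRow("b", "AC")])

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            read_msa(p)


class TestContextColumns:
    def test_whole_span_is_identity(self, small_msa):
        out = map_context_columns(small_msa, (0, small_msa.n_cols - 1))
        assert [r.aligned for r in out.rows] == [r.aligned for r in small_msa.rows]

    def test_window_selects_expected_columns(self, small_msa):
        out = map_context_columns(small_msa, (1, 3))
        assert out.n_cols == 3
        assert out.rows[0].aligned == "CDE"
        assert out.rows[3].aligned == "C-E"
        assert [r.species for r in out.rows] == [r.species for r in small_msa.rows]

    def test_out_of_range_span_rejected(self, small_msa):
        with pytest.raises(ValueError):
            map_context_columns(small_msa, (3, 9))

    def test_a3m_columns_index_query_positions(self, tmp_path):
        p = tmp_path / "a.a3m"
        p.write_text(A3M)
        msa = read_msa(p)
        # query positions 1..3 after insertion removal
        out = map_context_columns(msa, (1, 3))
        assert out.rows[0].aligned == "CDE"
        assert out.rows[1].aligned == "CDE"


def _msa(pairs, query="AAAA"):
    rows = [MsaRow("q", query, "sp_q")]
    rows += [MsaRow(f"s{i}", seq, sp) for i, (seq, sp) in enumerate(pairs)]
    return Msa(rows=rows)


class TestPairing:
    def test_only_shared_species_pair(self):
        rec = _msa([("AAAA", "A"), ("CCCC", "B")])
        pep = _msa([("GG", "B"), ("WW", "C")], query="GG")
        paired = pair_by_species(rec, pep)
        assert paired.paired_rows == 2  # query + species B
        assert paired.unpaired_receptor_rows == 1
        assert paired.unpaired_peptide_rows == 1

    def test_no_shared_species_gives_block_diagonal_only(self):
        rec = _msa([("AAAA", "A")])
        pep = _msa([("GG", "C")], query="GG")
        paired = pair_by_species(rec, pep)
        assert paired.paired_rows == 1  # just the query
        gaps_p = "-" * 2
        gaps_r = "-" * 4
        assert paired.peptide_half(paired.rows[1]) == gaps_p
        assert paired.receptor_half(paired.rows[2]) == gaps_r

    def test_within_species_rank_by_identity(self):
        # two receptor rows of species X: s0 (identity 2/4) and s1 (identity 4/4)
        rec = _msa([("AACC", "X"), ("AAAA", "X")])
        pep = _msa([("GG", "X")], query="GG")
        paired = pair_by_species(rec, pep)
        assert paired.paired_rows == 2
        assert paired.receptor_half(paired.rows[1]) == "AAAA"  # best identity pairs
        assert paired.unpaired_receptor_rows == 1

    def test_untagged_rows_go_unpaired(self):
        rec = _msa([("AAAA", None)])
        pep = _msa([("GG", None)], query="GG")
        paired = pair_by_species(rec, pep)
        assert paired.paired_rows == 1
        assert paired.unpaired_receptor_rows == 1
        assert paired.unpaired_peptide_rows == 1


class TestShuffle:
    def _paired(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        aas = list("ACDEFGHIKL")
        rec = Msa(rows=[MsaRow(f"r{i}", "".join(rng.choice(aas, 4)), f"sp{i}")
                        for i in range(n)])
        pep = Msa(rows=[MsaRow(f"p{i}", "".join(rng.choice(aas, 3)), f"sp{i}")
                        for i in range(n)])
        return pair_by_species(rec, pep)

    def test_single_paired_row_is_fixed_point(self):
        rec = _msa([])
        pep = _msa([], query="GG")
        paired = pair_by_species(rec, pep)
        out = shuffle_pairings(paired, seed=1)
        assert [r.aligned for r in out.rows] == [r.aligned for r in paired.rows]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_block_multisets_conserved(self, seed):
        paired = self._paired()
        out = shuffle_pairings(paired, seed)
        for half in ("receptor_half", "peptide_half"):
            before = sorted(getattr(paired, half)(r) for r in paired.rows)
            after = sorted(getattr(out, half)(r) for r in out.rows)
            assert before == after

    def test_query_row_never_moves(self):
        paired = self._paired()
        out = shuffle_pairings(paired, seed=5)
        assert out.rows[0].aligned == paired.rows[0].aligned


class TestMutualInformation:
    def test_perfect_two_symbol_correlation_is_one_bit(self):
        rows = [MsaRow(str(i), s) for i, s in enumerate(["AC", "AC", "GW", "GW"])]
        assert column_mi(Msa(rows=rows), 0, 1) == pytest.approx(1.0)

    def test_constant_column_gives_zero(self):
        rows = [MsaRow(str(i), s) for i, s in enumerate(["AC", "AW", "AC", "AW"])]
        assert column_mi(Msa(rows=rows), 0, 1) == pytest.approx(0.0)

    def test_eight_row_alignment_matches_enumeration_oracle(self):
        seqs = ["AC", "AD", "GC", "GD", "AC", "GD", "AD", "GC"]
        msa = Msa(rows=[MsaRow(str(i), s) for i, s in enumerate(seqs)])
        ours = column_mi(msa, 0, 1)
        oracle = oracle_column_mi([s[0] for s in seqs], [s[1] for s in seqs])
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_self_mi_equals_column_entropy(self):
        seqs = ["AA", "AA", "GG", "CC"]
        msa = Msa(rows=[MsaRow(str(i), s) for i, s in enumerate(seqs)])
        entropy = -(0.5 * math.log2(0.5) + 0.25 * math.log2(0.25) * 2)
        assert column_mi(msa, 0, 0) == pytest.approx(entropy, abs=1e-12)

    def test_mi_is_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACDG"), 2)) for _ in range(30)]
        msa = Msa(rows=[MsaRow(str(i), s) for i, s in enumerate(seqs)])
        ab = column_mi(msa, 0, 1)
        assert ab == pytest.approx(column_mi(msa, 1, 0), abs=1e-12)
        assert ab >= 0

    def test_gap_rows_excluded(self):
        rows = [MsaRow(str(i), s) for i, s in enumerate(["AC", "A-", "GC", "GW"])]
        # row 1 unusable: MI computed over the other 3
        ours = column_mi(Msa(rows=rows), 0, 1)
        oracle = oracle_column_mi(["A", "G", "G"], ["C", "C", "W"])
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_too_few_usable_rows_rejected(self):
        rows = [MsaRow("a", "A-"), MsaRow("b", "-C")]
        with pytest.raises(ValueError):
            column_mi(Msa(rows=rows), 0, 1)


class TestInterchainSummary:
    def test_constant_columns_give_zero_mean_and_max(self):
        rec = Msa(rows=[MsaRow(f"r{i}", "AA", f"sp{i}") for i in range(4)])
        pep = Msa(rows=[MsaRow(f"p{i}", "GG", f"sp{i}") for i in range(4)])
        result = interchain_mi_summary(pair_by_species(rec, pep))
        assert result.mean_interchain == 0.0 and result.max_interchain == 0.0

    def test_planted_pair_attains_the_maximum(self):
        from pepdock.synthgen import SyntheticMsaSpec, make_synthetic_msas
        rec, pep = make_synthetic_msas(
            SyntheticMsaSpec(depth=400, receptor_len=8, peptide_len=4,
                             conserved_fraction=0.0,
                             coevolving_pairs=[(2, 1, 1.5)], seed=11)
        )
        result = interchain_mi_summary(pair_by_species(rec, pep))
        top = result.per_pair.loc[result.per_pair["mi_bits"].idxmax()]
        assert (top["receptor_col"], top["peptide_col"]) == (2, 1)


class TestJsdConservation:
    def test_background_composition_scores_zero(self):
        # 20 rows, each a different amino acid -> column matches uniform background
        from pepdock.msatools import AMINO_ACIDS
        rows = [MsaRow(str(i), aa) for i, aa in enumerate(AMINO_ACIDS)]
        profile = jsd_conservation(Msa(rows=rows))
        assert profile.jsd[0] == pytest.approx(0.0, abs=1e-12)

    def test_fully_conserved_column_matches_closed_form(self):
        rows = [MsaRow(str(i), "A") for i in range(10)]
        profile = jsd_conservation(Msa(rows=rows))
        # delta vs uniform: JSD = 1/2 KL(delta||m) + 1/2 KL(u||m), m = (delta+u)/2
        p = np.zeros(20)
        p[0] = 1.0
        q = np.full(20, 0.05)
        m = (p + q) / 2
        expected = 0.5 * np.sum(p[p > 0] * np.log2(p[p > 0] / m[p > 0])) + 0.5 * np.sum(
            q * np.log2(q / m)
        )
        assert profile.jsd[0] == pytest.approx(float(expected), abs=1e-9)

    def test_gap_penalty_strictly_decreases_score(self):
        rows = [MsaRow(str(i), "A") for i in range(10)]
        with_gaps = rows + [MsaRow("g1", "-"), MsaRow("g2", "-")]
        clean = jsd_conservation(Msa(rows=rows)).jsd[0]
        gapped = jsd_conservation(Msa(rows=with_gaps)).jsd[0]
        assert gapped < clean

    def test_all_gap_column_flagged_zero(self):
        rows = [MsaRow("a", "A-"), MsaRow("b", "C-"), MsaRow("c", "G-")]
        profile = jsd_conservation(Msa(rows=rows))
        assert profile.flagged_columns == [1]
        assert profile.jsd[1] == 0.0

    def test_values_within_unit_interval(self, small_msa):
        profile = jsd_conservation(small_msa)
        assert np.all(profile.jsd >= 0) and np.all(profile.jsd <= 1)


class TestAblations:
    def test_mask_and_polyg(self):
        assert peptide_sequence_variants("ACDE", "mask") == "XXXX"
        assert peptide_sequence_variants("ACDE", "polyG") == "GGGG"

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=50, derandomize=True)
    def test_scramble_preserves_composition_and_differs(self, seed):
        seq = "AACDEFF"
        out = peptide_sequence_variants(seq, "scramble", seed)
        assert sorted(out) == sorted(seq)
        assert out != seq

    def test_scramble_of_homopolymer_is_identity(self):
        assert peptide_sequence_variants("AAAA", "scramble", 3) == "AAAA"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            peptide_sequence_variants("", "mask")


class TestHydrophobicity:
    def test_homopolymer_gives_scale_value(self):
        assert mean_hydrophobicity("III") == pytest.approx(KYTE_DOOLITTLE["I"])

    def test_two_residue_mean(self):
        expected = (KYTE_DOOLITTLE["A"] + KYTE_DOOLITTLE["R"]) / 2
        assert mean_hydrophobicity("AR") == pytest.approx(expected)

    def test_mixed_sequence_matches_lookup_oracle(self):
        seq = "ACDEFGHIKL"
        expected = sum(KYTE_DOOLITTLE[c] for c in seq) / len(seq)
        assert mean_hydrophobicity(seq) == pytest.approx(expected, abs=1e-12)

    def test_x_skipped(self):
        assert mean_hydrophobicity("AXA") == pytest.approx(KYTE_DOOLITTLE["A"])

    def test_all_unknown_rejected(self):
        with pytest.raises(ValueError):
            mean_hydrophobicity("XXX")


def test_depth_filter_boundary():
    def msa_of_depth(n):
        return Msa(rows=[MsaRow(str(i), "ACD") for i in range(n)])
    assert not msa_depth_ok(msa_of_depth(49))
    assert msa_depth_ok(msa_of_depth(50))
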