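"""Alignment handling, sequence weighting, mutual information and APC."""

import numpy as np
import pytest

from icdc import coevolution as cv
from icdc import fixtures
from icdc.coevolution import (
    Msa,
    apc_correct,
    compute_mi,
    compute_weights,
    normalize_coupling,
    read_msa,
    site_coupling,
    write_msa,
)
from icdc.enm import ResidueKey


def msa_from_rows(rows, reference_index=0):
    return Msa(
        ids=[f"s{i}" for i in range(len(rows))],
        seqs=list(rows),
        reference_index=reference_index,
        column_map=cv.build_column_map(rows[reference_index]),
    )


class TestReadMsa:
    def test_fasta_identity_column_map(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">ref\nACDE\n>s1\nACDF\n>s2\nGCDE\n")
        msa = read_msa(path, reference_id="ref")
        assert msa.n_sequences == 3 and msa.n_columns == 4
        assert msa.column_map == [ResidueKey("A", i) for i in range(1, 5)]

    def test_gapped_reference_skips_columns(self, tmp_path):
        path = tmp_path / "g.fasta"
        path.write_text(">ref\nA-CD\n>s1\nAACD\n")
        msa = read_msa(path, reference_id="ref")
        assert msa.column_map == [
            ResidueKey("A", 1), None, ResidueKey("A", 2), ResidueKey("A", 3)
        ]

    def test_unknown_reference_lists_available_ids(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">ref\nACDE\n>s1\nACDF\n")
        with pytest.raises(KeyError, match="ref, s1"):
            read_msa(path, reference_id="nope")

    def test_stockholm_roundtrip(self, tmp_path):
        fasta = tmp_path / "a.fasta"
        fasta.write_text(">ref\nAC-DE\n>s1\nACCDF\n>s2\nGC-DE\n")
        msa = read_msa(fasta, reference_id="ref")
        sto = tmp_path / "a.sto"
        write_msa(msa, sto, fmt="stockholm")
        back = read_msa(sto, fmt="stockholm", reference_id="ref")
        assert back.seqs == msa.seqs
        assert back.column_map == msa.column_map

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            msa_from_rows(["ACD", "AC"])


class TestWeights:
    def test_full_redundancy(self):
        msa = msa_from_rows(["ACDE"] * 4)
        w = compute_weights(msa, identity_threshold=0.8)
        np.testing.assert_allclose(w.weights, 0.25)
        assert w.meff == pytest.approx(1.0)

    def test_all_distinct(self):
        msa = msa_from_rows(["AAAA", "CCCC", "DDDD", "EEEE"])
        w = compute_weights(msa, identity_threshold=0.8)
        np.testing.assert_allclose(w.weights, 1.0)
        assert w.meff == pytest.approx(4.0)

    def test_matches_pairwise_counting_oracle(self):
        rows = ["ACDEFG", "ACDEFG", "ACDEYW", "KLMNPQ", "KLMNPY"]
        msa = msa_from_rows(rows)
        w = compute_weights(msa, identity_threshold=0.8)
        for i, a in enumerate(rows):
            neighbors = 0
            for b in rows:
                ident = sum(x == y for x, y in zip(a, b)) / len(a)
                neighbors += ident >= 0.8
            assert w.weights[i] == pytest.approx(1.0 / neighbors)

    def test_identity_over_shared_columns_only(self):
        msa = msa_from_rows(["AC--", "ACDE", "AC-E"], reference_index=1)
        w = compute_weights(msa, identity_threshold=0.9)
        # rows 0 and 2 are identical over their shared columns
        assert w.weights[0] < 1.0 and w.weights[2] < 1.0


class TestMutualInformation:
    def test_perfect_covariation_is_one_bit(self):
        rows = ["AA", "CC"] * 10
        msa = msa_from_rows(rows)
        cm = compute_mi(msa, pseudocount=0.0)
        assert cm.raw_mi[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_has_zero_mi(self):
        rows = ["AA", "AC", "AD", "AE", "AA", "AC"]
        msa = msa_from_rows(rows)
        cm = compute_mi(msa, pseudocount=0.0)
        assert cm.raw_mi[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_three_symbol_joint_matches_direct_sum_oracle(self):
        rows = ["AC", "AD", "CE", "CC", "AC", "CD", "AE", "CC"]
        msa = msa_from_rows(rows)
        cm = compute_mi(msa, pseudocount=0.0)
        # independent direct summation over the empirical joint table
        from collections import Counter
        joint = Counter(rows)
        total = len(rows)
        pa = Counter(r[0] for r in rows)
        pb = Counter(r[1] for r in rows)
        expected = sum(
            (c / total) * np.log2((c / total) / ((pa[k[0]] / total) * (pb[k[1]] / total)))
            for k, c in joint.items()
        )
        assert cm.raw_mi[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_gapped_rows_excluded_pairwise(self):
        rows = ["AC", "A-", "CC", "CA", "AC", "CA"]
        msa = msa_from_rows(rows, reference_index=0)
        cm = compute_mi(msa, pseudocount=0.0, min_effective=2.0)
        from collections import Counter
        used = [r for r in rows if "-" not in r]
        joint = Counter(used)
        total = len(used)
        pa = Counter(r[0] for r in used)
        pb = Counter(r[1] for r in used)
        expected = sum(
            (c / total) * np.log2((c / total) / ((pa[k[0]] / total) * (pb[k[1]] / total)))
            for k, c in joint.items()
        )
        assert cm.raw_mi[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_duplication_invariance(self):
        base = ["ACDE", "AGDE", "CCDK", "CGYK", "ACYE"]
        msa1 = msa_from_rows(base)
        msa3 = msa_from_rows(base * 3)
        # weighting cancels duplication exactly in the no-pseudocount route
        cm1 = compute_mi(msa1, compute_weights(msa1), pseudocount=0.0, min_effective=4.0)
        cm3 = compute_mi(msa3, compute_weights(msa3), pseudocount=0.0, min_effective=4.0)
        np.testing.assert_allclose(cm1.raw_mi, cm3.raw_mi, atol=1e-12)

    def test_symmetry_and_nonnegativity(self):
        msa = fixtures.make_msa(60, 8, planted_pairs=[(1, 5, 0.9)], seed=3)
        cm = normalize_coupling(apc_correct(compute_mi(msa, compute_weights(msa))))
        for m in (cm.raw_mi, cm.corrected, cm.normalized):
            np.testing.assert_allclose(m, m.T, atol=1e-12)
        assert np.nanmin(cm.raw_mi) >= -1e-12
        assert not cm.valid.diagonal().any()

    def test_all_pairs_invalid_is_hard_error(self):
        msa = msa_from_rows(["A-", "-C", "A-", "-C"])
        with pytest.raises(ValueError, match="larger MSA"):
            compute_mi(msa, min_effective=5.0)


class TestApc:
    def test_constant_mi_corrects_to_zero(self):
        L = 4
        raw = np.full((L, L), 0.7)
        np.fill_diagonal(raw, np.nan)
        valid = ~np.eye(L, dtype=bool)
        cm = cv.CouplingMatrix(raw_mi=raw, valid=valid)
        apc_correct(cm)
        np.testing.assert_allclose(cm.corrected[valid], 0.0, atol=1e-9)

    def test_single_valid_pair_corrects_to_zero(self):
        L = 3
        raw = np.full((L, L), np.nan)
        valid = np.zeros((L, L), dtype=bool)
        raw[0, 1] = raw[1, 0] = 0.4
        valid[0, 1] = valid[1, 0] = True
        cm = cv.CouplingMatrix(raw_mi=raw, valid=valid)
        apc_correct(cm)
        assert cm.corrected[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_evaluated_oracle(self):
        """APC on a 4-column matrix with one planted high-MI pair."""
        L = 4
        raw = np.full((L, L), np.nan)
        vals = {(0, 1): 1.0, (0, 2): 0.2, (0, 3): 0.1, (1, 2): 0.15, (1, 3): 0.1, (2, 3): 0.05}
        valid = np.zeros((L, L), dtype=bool)
        for (a, b), v in vals.items():
            raw[a, b] = raw[b, a] = v
            valid[a, b] = valid[b, a] = True
        cm = cv.CouplingMatrix(raw_mi=raw, valid=valid)
        apc_correct(cm)
        col_mean = [np.mean([v for (a, b), v in vals.items() if c in (a, b)]) for c in range(L)]
        mean_all = np.mean(list(vals.values()))
        for (a, b), v in vals.items():
            expected = v - col_mean[a] * col_mean[b] / mean_all
            assert cm.corrected[a, b] == pytest.approx(expected, abs=1e-12)


class TestNormalization:
    def test_rank_of_three(self):
        L = 3
        raw = np.full((L, L), np.nan)
        valid = np.zeros((L, L), dtype=bool)
        for (a, b), v in {(0, 1): 0.3, (0, 2): 0.1, (1, 2): 0.9}.items():
            raw[a, b] = raw[b, a] = v
            valid[a, b] = valid[b, a] = True
        cm = cv.CouplingMatrix(raw_mi=raw, valid=valid, corrected=raw.copy())
        normalize_coupling(cm)
        assert cm.normalized[0, 2] == pytest.approx(1 / 3)
        assert cm.normalized[0, 1] == pytest.approx(2 / 3)
        assert cm.normalized[1, 2] == pytest.approx(1.0)

    def test_ties_share_rank(self):
        L = 3
        raw = np.full((L, L), 0.5)
        np.fill_diagonal(raw, np.nan)
        valid = ~np.eye(L, dtype=bool)
        cm = cv.CouplingMatrix(raw_mi=raw, valid=valid, corrected=raw.copy())
        normalize_coupling(cm)
        vals = cm.normalized[np.triu_indices(L, k=1)]
        assert len(set(np.round(vals, 12))) == 1

    def test_planted_pair_attains_top_rank(self):
        msa = fixtures.make_msa(300, 12, planted_pairs=[(2, 9, 1.0)], seed=1)
        cm = normalize_coupling(apc_correct(compute_mi(msa, compute_weights(msa))))
        assert cm.normalized[2, 9] == pytest.approx(1.0)

    def test_site_coupling_max_and_mean(self):
        L = 4
        raw = np.full((L, L), np.nan)
        valid = np.zeros((L, L), dtype=bool)
        for (a, b), v in {(0, 2): 0.1, (0, 3): 0.9, (1, 2): 0.5, (1, 3): 0.5}.items():
            raw[a, b] = raw[b, a] = v
            valid[a, b] = valid[b, a] = True
        cm = cv.CouplingMatrix(raw_mi=raw, valid=valid, corrected=raw.copy())
        normalize_coupling(cm)
        hi = site_coupling(cm, 0, [2, 3], mode="max")
        assert hi == pytest.approx(1.0)  # (0,3) is the top-ranked pair
        assert 0 < site_coupling(cm, 0, [2, 3], mode="mean") < hi
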