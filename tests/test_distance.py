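import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribovar.alignio import CloneAlignment
from ribovar.distance import (
    POLICIES,
    DistanceMatrix,
    collapse_haplotypes,
    distance_matrix,
    diversity_summary,
    p_distance,
)
from ribovar.errors import AlignmentError, DegenerateInputError


def _aln(rows):
    ids = [f"S_#{i + 1:02d}" for i in range(len(rows))]
    return CloneAlignment("S", ids, rows)


seq_pairs = st.integers(min_value=1, max_value=40).flatmap(
    lambda m: st.tuples(
        st.text(alphabet="ACGT-", min_size=m, max_size=m),
        st.text(alphabet="ACGT-", min_size=m, max_size=m),
    )
)


class TestPDistance:
    @pytest.mark.parametrize("policy", POLICIES)
    def test_identity_is_zero(self, policy):
        assert p_distance("ACG-TACGT", "ACG-TACGT", policy) == 0.0

    def test_hand_enumerated_example(self):
        # one substitution (col 5), one single-column gap run (col 9)
        x, y = "ACGTACGTAC", "ACGTTCGT-C"
        assert p_distance(x, y, "indel-event") == pytest.approx(2 / 10)
        assert p_distance(x, y, "pairwise-deletion") == pytest.approx(1 / 9)
        assert p_distance(x, y, "gap-as-state") == pytest.approx(2 / 10)

    def test_gap_run_counts_once_regardless_of_length(self):
        x, y = "AAAAAAAAAA", "AA----AAAA"
        assert p_distance(x, y, "indel-event") == pytest.approx(1 / 10)
        assert p_distance(x, y, "gap-as-state") == pytest.approx(4 / 10)
        assert p_distance(x, y, "pairwise-deletion") == 0.0

    def test_both_gap_columns_excluded_everywhere(self):
        assert p_distance("A--T", "A--A", "indel-event") == pytest.approx(1 / 2)

    def test_identical_table_clones_at_zero(self, reconstructed):
        aln = reconstructed["W136"]
        for policy in POLICIES:
            assert p_distance(aln.row("W136_#05"), aln.row("W136_#09"), policy) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            p_distance("ACGT", "ACG")

    def test_all_excluded_pair_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            assert p_distance("--", "--") == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(pair=seq_pairs)
    def test_policy_numerator_ordering(self, pair):
        """pairwise-deletion num <= indel-event num <= gap-as-state num."""
        from ribovar.distance import _encode, _pair_stats

        x, y = (_encode(s) for s in pair)
        nums = {p: _pair_stats(x, y, p)[0] for p in POLICIES}
        assert nums["pairwise-deletion"] <= nums["indel-event"] <= nums["gap-as-state"]

    @settings(max_examples=60, derandomize=True)
    @given(
        pair=st.integers(min_value=1, max_value=40).flatmap(
            lambda m: st.tuples(
                st.text(alphabet="ACGT", min_size=m, max_size=m),
                st.text(alphabet="ACGT", min_size=m, max_size=m),
            )
        )
    )
    def test_policies_agree_on_gapless_pairs(self, pair):
        x, y = pair
        values = {p_distance(x, y, p) for p in POLICIES}
        assert len(values) == 1


class TestDistanceMatrix:
    def test_two_identical_rows(self):
        m = distance_matrix(_aln(["ACGT", "ACGT"]))
        assert np.array_equal(m.values, np.zeros((2, 2)))

    def test_three_row_toy_matches_hand_enumeration(self):
        m = distance_matrix(_aln(["AC-T", "ACGT", "ACGA"]), policy="indel-event")
        assert m.pair("S_#01", "S_#02") == pytest.approx(1 / 4)
        assert m.pair("S_#01", "S_#03") == pytest.approx(2 / 4)
        assert m.pair("S_#02", "S_#03") == pytest.approx(1 / 4)

    def test_fixture_matrix_invariants(self, reconstructed):
        m = distance_matrix(reconstructed["W136"])
        assert m.values.shape == (10, 10)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0)
        assert m.provenance == "computed"

    @settings(max_examples=40, derandomize=True)
    @given(
        rows=st.integers(min_value=2, max_value=5).flatmap(
            lambda n: st.integers(min_value=1, max_value=20).flatmap(
                lambda m: st.lists(
                    st.text(alphabet="ACGT-", min_size=m, max_size=m),
                    min_size=n,
                    max_size=n,
                )
            )
        ),
        policy=st.sampled_from(POLICIES),
    )
    def test_symmetry_zero_diagonal_range(self, rows, policy):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = distance_matrix(_aln(rows), policy=policy)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0)
        assert m.values.min() >= 0.0 and m.values.max() <= 1.0

    def test_matrix_invariant_validation(self):
        with pytest.raises(AlignmentError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.2], [0.3, 0.0]]), None)


class TestDiversitySummary:
    def test_w136_transcribed_mean(self, table2_fixtures):
        div = diversity_summary(table2_fixtures["W136"].matrix)
        assert round(div.mean_p, 4) == 0.0134

    def test_w127_max_and_argmax(self, table2_fixtures):
        div = diversity_summary(table2_fixtures["W127"].matrix)
        assert div.max_p == pytest.approx(0.0368)
        assert div.argmax_pair == ("W127_#03", "W127_#05")

    def test_all_zero_matrix(self):
        m = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)), None)
        div = diversity_summary(m)
        assert div.mean_p == div.min_p == div.max_p == 0.0
        assert div.n_haplotypes == 1
        assert div.n_pairs == 3
        assert div.n_zero_pairs == 3

    def test_single_label_rejected(self):
        with pytest.raises(DegenerateInputError):
            diversity_summary(DistanceMatrix(["a"], np.zeros((1, 1)), None))

    @settings(max_examples=30, derandomize=True)
    @given(
        k=st.integers(min_value=2, max_value=7),
        data=st.data(),
    )
    def test_mean_matches_bruteforce_over_pairs(self, k, data):
        tri = data.draw(
            st.lists(
                st.floats(min_value=0, max_value=1, allow_nan=False),
                min_size=k * (k - 1) // 2,
                max_size=k * (k - 1) // 2,
            )
        )
        m = np.zeros((k, k))
        it = iter(tri)
        for i in range(k):
            for j in range(i + 1, k):
                m[i, j] = m[j, i] = next(it)
        dm = DistanceMatrix([f"t{i}" for i in range(k)], m, None)
        div = diversity_summary(dm)
        brute = [m[i, j] for i, j in itertools.combinations(range(k), 2)]
        assert div.mean_p == pytest.approx(sum(brute) / len(brute), abs=1e-12)
        assert div.n_pairs == len(brute)

    def test_haplotypes_by_transitive_closure(self):
        # a-b and b-c at zero, a-c nonzero: still one haplotype group
        m = np.array(
            [[0.0, 0.0, 0.01], [0.0, 0.0, 0.0], [0.01, 0.0, 0.0]]
        )
        m = (m + m.T) / 2
        div = diversity_summary(DistanceMatrix(["a", "b", "c"], m, None))
        assert div.n_haplotypes == 1


class TestCollapseHaplotypes:
    def test_w136_groups(self, reconstructed):
        groups = collapse_haplotypes(reconstructed["W136"])
        multi = [g for g in groups if len(g) > 1]
        assert ["W136_#04", "W136_#10"] in multi
        assert ["W136_#05", "W136_#09"] in multi
        assert len(groups) == 8

    def test_all_distinct(self):
        assert collapse_haplotypes(_aln(["ACGT", "ACGA", "ACTT"])) == [
            ["S_#01"], ["S_#02"], ["S_#03"],
        ]

    def test_all_identical(self):
        assert collapse_haplotypes(_aln(["ACGT"] * 3)) == [
            ["S_#01", "S_#02", "S_#03"]
        ]


class TestExports:
    def test_tsv_lower_triangle_and_phylip(self, table2_fixtures):
        m = table2_fixtures["Z704"].matrix
        tsv = m.to_tsv_lower()
        lines = tsv.strip().split("\n")
        assert len(lines) == 11
        assert lines[1].split("\t")[1] == "-"
        assert "0.0182" in tsv
        phy = m.to_phylip()
        assert phy.startswith("10\n")
        assert len(phy.strip().split("\n")) == 11
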