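"""Gene concatenation, site classification and K2P distances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strepdelim.mlsa import (
    AlignmentError,
    FrameError,
    GeneAlignmentSet,
    MembershipError,
    NoOverlapError,
    SaturationError,
    SiteComparison,
    classify_sites,
    concatenate,
    k2p_distance,
    k2p_from_proportions,
    load_gene_fastas,
    mlsa_distance_matrix,
    read_distance_matrix,
    write_distance_matrix,
    write_phylip_lower,
)


class TestLoading:
    def test_valid_set_loads(self, gene_fastas):
        aln = load_gene_fastas(gene_fastas)
        assert aln.strains == ["s1", "s2", "s3"]
        assert aln.gene_length("rpoB") == 60

    def test_length_mismatch_names_gene(self, gene_fastas, tmp_path):
        bad = tmp_path / "atpD_bad.fna"
        bad.write_text(">s1\n" + "A" * 30 + "\n>s2\n" + "A" * 27 + "\n>s3\n" + "A" * 30 + "\n")
        paths = dict(gene_fastas, atpD=bad)
        with pytest.raises(AlignmentError, match="atpD"):
            load_gene_fastas(paths)

    def test_out_of_frame_length_rejected(self, gene_fastas, tmp_path):
        bad = tmp_path / "trpB_bad.fna"
        seq = "A" * 31
        bad.write_text(f">s1\n{seq}\n>s2\n{seq}\n>s3\n{seq}\n")
        with pytest.raises(FrameError, match="trpB"):
            load_gene_fastas(dict(gene_fastas, trpB=bad))

    def test_inconsistent_strain_sets_rejected(self, gene_fastas, tmp_path):
        bad = tmp_path / "recA_bad.fna"
        bad.write_text(">s1\n" + "A" * 30 + "\n>s2\n" + "A" * 30 + "\n")
        with pytest.raises(MembershipError, match="recA"):
            load_gene_fastas(dict(gene_fastas, recA=bad))

    def test_wrong_gene_names_rejected(self, gene_fastas):
        paths = dict(gene_fastas)
        paths["wrongGene"] = paths.pop("atpD")
        with pytest.raises(MembershipError):
            load_gene_fastas(paths)


class TestConcatenate:
    def test_length_is_sum_of_gene_lengths(self, gene_fastas):
        aln = load_gene_fastas(gene_fastas)
        total = sum(aln.gene_length(g) for g in aln.gene_order)
        assert len(concatenate(aln, "s1")) == total == 195

    def test_fixed_gene_order_prefix(self, gene_fastas):
        aln = load_gene_fastas(gene_fastas)
        cat = concatenate(aln, "s2")
        n_atpD = aln.gene_length("atpD")
        assert cat[:n_atpD] == aln.genes["atpD"]["s2"]
        assert cat[n_atpD : n_atpD + aln.gene_length("gyrB")] == aln.genes["gyrB"]["s2"]

    def test_unknown_strain_raises(self, gene_fastas):
        aln = load_gene_fastas(gene_fastas)
        with pytest.raises(KeyError):
            concatenate(aln, "missing")


class TestClassifySites:
    def test_identical_sequences(self):
        s = "ACGT" * 25
        c = classify_sites(s, s)
        assert (c.compared, c.transitions, c.transversions, c.excluded) == (100, 0, 0, 0)

    def test_counts_transitions_and_transversions(self):
        a = list("A" * 100)
        b = list("A" * 100)
        for i in range(4):
            b[i] = "G"  # A<->G transitions
        for i in range(4, 6):
            b[i] = "T"  # A<->T transversions
        c = classify_sites("".join(a), "".join(b))
        assert (c.transitions, c.transversions, c.compared) == (4, 2, 100)

    def test_pairwise_deletion_of_gaps_and_ambiguity(self):
        a = "-ACGTACGTA"
        b = "AACGTACGTG"  # gap col excluded; last col A<->G transition
        c = classify_sites(a, b)
        assert (c.compared, c.excluded, c.transitions, c.transversions) == (9, 1, 1, 0)
        n = classify_sites("NACGT", "AACGT")
        assert (n.compared, n.excluded) == (4, 1)

    def test_u_is_treated_as_t(self):
        c = classify_sites("ACGU", "ACGT")
        assert (c.compared, c.transitions, c.transversions) == (4, 0, 0)

    def test_case_insensitive(self):
        c = classify_sites("acgt", "ACGT")
        assert c.compared == 4 and c.transitions == 0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            classify_sites("ACGT", "ACG")


class TestK2PDistance:
    def test_zero_distance_for_identical(self):
        assert k2p_distance(SiteComparison(100, 0, 0, 0)) == 0.0

    def test_hand_computed_case_p004_q002(self):
        # -1/2 ln(0.90 * sqrt(0.96)) evaluated independently
        d = k2p_distance(SiteComparison(100, 4, 2, 0))
        assert d == pytest.approx(0.06289, abs=5e-6)

    def test_hand_computed_case_one_transition_in_nine(self):
        # -1/2 ln(7/9) evaluated independently
        d = k2p_distance(SiteComparison(9, 1, 0, 0))
        assert d == pytest.approx(0.12566, abs=5e-6)

    def test_no_overlap_raises(self):
        with pytest.raises(NoOverlapError):
            k2p_distance(SiteComparison(0, 0, 0, 10))

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance(SiteComparison(10, 5, 0, 0))  # 1-2P-Q = 0
        with pytest.raises(SaturationError):
            k2p_from_proportions(0.2, 0.5)

    @given(
        p=st.floats(0, 0.35),
        q=st.floats(0, 0.25),
    )
    @settings(deadline=None, max_examples=200)
    def test_correction_never_shrinks_raw_divergence(self, p, q):
        """K2P distance >= P + Q: the multiple-hit correction only inflates."""
        if 2 * p + q >= 0.999 or 2 * q >= 0.999:
            return
        assert k2p_from_proportions(p, q) >= p + q - 1e-12


class TestDistanceMatrix:
    def test_identical_strains_zero_matrix(self, tmp_path):
        seq = "ACGTAA"
        genes = {g: {"x": seq, "y": seq} for g in
                 ("atpD", "gyrB", "recA", "rpoB", "trpB")}
        m = mlsa_distance_matrix(GeneAlignmentSet(genes=genes))
        assert np.allclose(m.values, 0.0)

    def test_matrix_matches_per_pair_recomputation(self, gene_fastas):
        aln = load_gene_fastas(gene_fastas)
        m = mlsa_distance_matrix(aln)
        # oracle: recompute each cell independently
        for i, si in enumerate(m.ids):
            for j, sj in enumerate(m.ids):
                if i == j:
                    assert m.values[i, j] == 0.0
                    continue
                d = k2p_distance(
                    classify_sites(concatenate(aln, si), concatenate(aln, sj))
                )
                assert m.values[i, j] == pytest.approx(d, rel=1e-12)
        assert np.allclose(m.values, m.values.T)

    def test_pooled_gene_counts_equal_concatenated_distance(self, gene_fastas):
        """Summing per-gene site counts gives the concatenation's distance."""
        aln = load_gene_fastas(gene_fastas)
        pooled = SiteComparison(0, 0, 0, 0)
        for g in aln.gene_order:
            pooled = pooled + classify_sites(aln.genes[g]["s1"], aln.genes[g]["s3"])
        d_pooled = k2p_distance(pooled)
        d_concat = k2p_distance(
            classify_sites(concatenate(aln, "s1"), concatenate(aln, "s3"))
        )
        assert d_pooled == pytest.approx(d_concat, rel=1e-15)

    def test_round_trip_to_six_dp(self, gene_fastas, tmp_path):
        aln = load_gene_fastas(gene_fastas)
        m = mlsa_distance_matrix(aln)
        path = write_distance_matrix(m, tmp_path / "d.tsv")
        again = read_distance_matrix(path)
        assert again.ids == m.ids
        assert np.allclose(again.values, m.values, atol=5e-7)

    def test_saturated_pair_flagged_not_dropped(self):
        # maximally diverged pair: all transitions => 1-2P-Q <= 0
        genes = {g: {"x": "AAA", "y": "GGG"} for g in
                 ("atpD", "gyrB", "recA", "rpoB", "trpB")}
        m = mlsa_distance_matrix(GeneAlignmentSet(genes=genes))
        assert ("x", "y") in m.failures
        assert math.isnan(m.values[0, 1])

    def test_phylip_output_shape(self, gene_fastas, tmp_path):
        aln = load_gene_fastas(gene_fastas)
        m = mlsa_distance_matrix(aln)
        path = write_phylip_lower(m, tmp_path / "d.phy")
        lines = path.read_text().splitlines()
        assert lines[0].strip() == "3"
        assert len(lines) == 4
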