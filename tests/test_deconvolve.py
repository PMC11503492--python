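"""Codon decoding, bead calling, k class, FDR matrix, enrichment, heat map."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson

from delscreen import (
    CONTROL_ID,
    AmpliconLayout,
    Codebook,
    DecodedRead,
    DecodeStatus,
    KClassTable,
    LibraryMember,
    bb_enrichment,
    call_bead,
    compute_kclass,
    decode_read,
    estimate_fdr,
    export_heatmap,
)


class TestDecodeRead:
    def test_error_free_round_trip(self, toy_codebook, toy_library):
        m = toy_library[0]
        seq = toy_codebook.amplicon(
            toy_codebook.cycle1_codons[m.starter_id], toy_codebook.cycle2_codons[m.acid_id]
        )
        d = decode_read(seq, toy_codebook)
        assert d.status is DecodeStatus.EXACT
        assert (d.codon1_id, d.codon2_id) == (m.starter_id, m.acid_id)

    def test_single_substitution_corrected(self, toy_codebook, toy_library):
        m = toy_library[0]
        c1 = toy_codebook.cycle1_codons[m.starter_id]
        mutated = ("T" if c1[0] != "T" else "A") + c1[1:]
        seq = toy_codebook.amplicon(mutated, toy_codebook.cycle2_codons[m.acid_id])
        d = decode_read(seq, toy_codebook, max_mismatch=1)
        assert d.status is DecodeStatus.CORRECTED
        assert d.codon1_id == m.starter_id

    def test_equidistant_codons_ambiguous(self):
        # d_min = 2 codebook built by hand: "AA" and "AC" are both at
        # Hamming distance 1 from the observed "AG"
        cb = Codebook(
            codon_length=2,
            cycle1_codons={"s1": "AA", "s2": "AC"},
            cycle2_codons={"a1": "GG"},
            reserved_control_codon="TT",
            layout=AmpliconLayout(const5="", spacer="", const3=""),
        )
        d = decode_read("AG" + "GG", cb, max_mismatch=1)
        assert d.status is DecodeStatus.AMBIGUOUS

    def test_control_codon_flagged(self, toy_codebook):
        seq = toy_codebook.amplicon(
            toy_codebook.reserved_control_codon, toy_codebook.reserved_control_codon
        )
        d = decode_read(seq, toy_codebook)
        assert d.is_control
        assert d.status is DecodeStatus.EXACT

    def test_length_mismatch_fails_not_raises(self, toy_codebook):
        d = decode_read("ACGT", toy_codebook)
        assert d.status is DecodeStatus.FAIL

    def test_unrecognizable_codon_fails(self, toy_codebook, toy_library):
        m = toy_library[0]
        # three substitutions exceed max_mismatch=1 on a d_min=3 codebook
        c1 = toy_codebook.cycle1_codons[m.starter_id]
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        mutated = "".join(flip[b] for b in c1[:3]) + c1[3:]
        seq = toy_codebook.amplicon(mutated, toy_codebook.cycle2_codons[m.acid_id])
        d = decode_read(seq, toy_codebook, max_mismatch=1)
        assert d.status in (DecodeStatus.FAIL, DecodeStatus.AMBIGUOUS)


def _read(c1, c2, status=DecodeStatus.EXACT, control=False):
    return DecodedRead(c1, c2, status, is_control=control)


class TestCallBead:
    def test_unanimous(self):
        assert call_bead([_read("S1", "A1")] * 20) == "S1-A1"

    def test_majority_above_min_support(self):
        reads = [_read("S1", "A1")] * 12 + [_read("S2", "A2")] * 8
        assert call_bead(reads) == "S1-A1"  # support 0.6 >= 0.5

    def test_exact_tie_is_no_call(self):
        reads = [_read("S1", "A1")] * 10 + [_read("S2", "A2")] * 10
        assert call_bead(reads) is None

    def test_below_min_support_is_no_call(self):
        reads = (
            [_read("S1", "A1")] * 4 + [_read("S2", "A2")] * 3 + [_read("S3", "A3")] * 3
        )
        assert call_bead(reads, min_support=0.5) is None

    def test_zero_usable_reads(self):
        assert call_bead([]) is None
        assert call_bead([_read(None, None, DecodeStatus.FAIL)] * 5) is None

    def test_ambiguous_reads_dilute_support(self):
        reads = [_read("S1", "A1")] * 5 + [_read(None, None, DecodeStatus.AMBIGUOUS)] * 6
        assert call_bead(reads, min_support=0.5) is None

    def test_control_bead(self):
        reads = [_read(None, None, control=True)] * 10
        assert call_bead(reads) == CONTROL_ID


class TestKClass:
    def test_distinct_bead_counting(self):
        calls = pd.DataFrame(
            {
                "bead_id": ["b1", "b2", "b3"],
                "screen_id": ["s"] * 3,
                "structure_id": ["A", "A", "B"],
            }
        )
        t = compute_kclass(calls)
        k = t.rows.set_index("structure_id")["k"]
        assert k["A"] == 2 and k["B"] == 1

    def test_summed_across_screens(self):
        calls = pd.DataFrame(
            {
                "bead_id": ["b1", "b2", "b3", "c1", "c2"],
                "screen_id": ["s1"] * 3 + ["s2"] * 2,
                "structure_id": ["A"] * 5,
            }
        )
        t = compute_kclass(calls)
        assert t.summed()["A"] == 5

    def test_conservation(self):
        rng = np.random.default_rng(0)
        n = 1500
        calls = pd.DataFrame(
            {
                "bead_id": [f"b{i}" for i in range(n)],
                "screen_id": ["s"] * n,
                "structure_id": rng.integers(0, 200, n).astype(str),
            }
        )
        assert compute_kclass(calls).total_beads() == n

    def test_duplicate_bead_raises(self):
        calls = pd.DataFrame(
            {"bead_id": ["b1", "b1"], "screen_id": ["s", "s"], "structure_id": ["A", "A"]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            compute_kclass(calls)

    def test_no_calls_dropped(self):
        calls = pd.DataFrame(
            {"bead_id": ["b1", "b2"], "screen_id": ["s", "s"], "structure_id": ["A", None]}
        )
        t = compute_kclass(calls)
        assert t.total_beads() == 1


class TestFDR:
    def test_fdr_at_1_is_always_1(self):
        fdr = estimate_fdr(500, sample_size=100, n_samples=5, seed=3)
        assert fdr.fdr(1) == 1.0

    def test_monotone_nonincreasing(self):
        fdr = estimate_fdr(5348, sample_size=1500, n_samples=3, seed=4)
        vals = fdr.table["fdr_mean"].to_numpy()
        assert (np.diff(vals) <= 1e-12).all()

    @given(n_structures=st.integers(2, 2000), sample_size=st.integers(1, 3000),
           seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40)
    def test_monotonicity_property(self, n_structures, sample_size, seed):
        fdr = estimate_fdr(n_structures, sample_size=sample_size, n_samples=2,
                           k_max=6, seed=seed)
        vals = fdr.table["fdr_mean"].to_numpy()
        assert vals[0] == 1.0
        assert (np.diff(vals) <= 1e-12).all()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_matches_poisson_closed_form(self):
        """Null fraction at >= k tracks P(X>=k)/P(X>=1), X ~ Poisson(n/N)."""
        n_structures, sample_size = 5348, 1500
        lam = sample_size / n_structures
        fdr = estimate_fdr(n_structures, sample_size=sample_size, n_samples=40, seed=5)
        for k in (2, 3):
            expected = poisson.sf(k - 1, lam) / poisson.sf(0, lam)
            # binomial SE over ~observed structures, averaged over replicates
            n_obs = n_structures * poisson.sf(0, lam)
            se = np.sqrt(expected * (1 - expected) / n_obs / 40)
            assert abs(fdr.fdr(k) - expected) < 3 * se

    def test_degenerate_single_bead_sample(self):
        fdr = estimate_fdr(100, sample_size=1, n_samples=3, k_max=4, seed=6)
        assert fdr.fdr(1) == 1.0
        assert fdr.fdr(2) == 0.0
        assert bool(fdr.table.loc[fdr.table["k"] == 2, "degenerate"].iloc[0])

    def test_reproducible_given_seed(self):
        a = estimate_fdr(1000, 500, 3, seed=7).table
        b = estimate_fdr(1000, 500, 3, seed=7).table
        pd.testing.assert_frame_equal(a, b)


class TestEnrichment:
    def test_toy_exact_hypergeometric(self, toy_library):
        """All 4 members of starter S1 as hits: p = 1/C(12,4) = 1/495."""
        hits = [m.member_id for m in toy_library if m.starter_id == "S1"]
        rows = bb_enrichment(hits, toy_library).set_index("bb_id")
        assert rows.loc["S1", "p"] == pytest.approx(1 / 495)
        assert rows.loc["S1", "n_hits_containing"] == 4

    def test_whole_library_as_hits_gives_p_one(self, toy_library):
        rows = bb_enrichment([m.member_id for m in toy_library], toy_library)
        assert np.allclose(rows["p"], 1.0)

    def test_absent_bb_not_enriched(self, toy_library):
        hits = [m.member_id for m in toy_library if m.starter_id != "S3"]
        rows = bb_enrichment(hits, toy_library).set_index("bb_id")
        assert rows.loc["S3", "p"] == pytest.approx(1.0)
        assert rows.loc["S3", "n_hits_containing"] == 0

    def test_bonferroni_adjustment(self, toy_library):
        hits = [m.member_id for m in toy_library if m.starter_id == "S1"]
        rows = bb_enrichment(hits, toy_library)
        n_tests = len(rows)  # 3 starters + 4 acids
        assert n_tests == 7
        s1 = rows.set_index("bb_id").loc["S1"]
        assert s1["p_adjusted"] == pytest.approx(min(1.0, s1["p"] * 7))

    def test_pvalues_in_unit_interval_and_counts_consistent(self, toy_library):
        rng = np.random.default_rng(8)
        hits = [m.member_id for m in rng.choice(toy_library, size=6, replace=False)]
        rows = bb_enrichment(hits, toy_library)
        assert ((rows["p"] >= 0) & (rows["p"] <= 1)).all()
        assert (
            rows["n_hits_containing"]
            <= np.minimum(rows["n_hits_total"], rows["n_lib_containing"])
        ).all()

    def test_uniform_hits_give_calibrated_p(self, fullscale_library):
        """Random hit draws from the library give roughly uniform p-values."""
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(30):
            hits = [m.member_id for m in rng.choice(fullscale_library, 50, replace=False)]
            rows = bb_enrichment(hits, fullscale_library)
            pvals.extend(rows.loc[rows["cycle"] == 1, "p"])
        pvals = np.asarray(pvals)
        # conservative calibration check on a discrete statistic: the null
        # p-value CDF never exceeds the uniform line
        for alpha in (0.05, 0.1, 0.25):
            assert (pvals <= alpha).mean() < alpha + 3 * np.sqrt(alpha / len(pvals))

    def test_empty_hit_set_warns(self, toy_library):
        with pytest.warns(UserWarning):
            rows = bb_enrichment([], toy_library)
        assert rows.empty

    def test_unknown_structure_raises(self, toy_library):
        with pytest.raises(ValueError, match="not in library"):
            bb_enrichment(["X1-Y1"], toy_library)


class TestHeatmap:
    def _table(self, rows):
        return KClassTable(pd.DataFrame(rows, columns=["structure_id", "screen_id", "k"]))

    def test_single_structure(self):
        t = self._table([("S1-A2", "s", 5)])
        mat = export_heatmap(t, ["S1", "S2"], ["A1", "A2"])
        assert mat.loc["S1", "A2"] == 5
        assert mat.to_numpy().sum() == 5

    def test_row_sums_are_per_starter_totals(self, toy_library):
        rows = [("S1-A1", "s1", 3), ("S1-A2", "s1", 2), ("S2-A1", "s2", 4)]
        mat = export_heatmap(self._table(rows), ["S1", "S2", "S3"], ["A1", "A2", "A3", "A4"])
        assert mat.sum(axis=1).tolist() == [5, 4, 0]

    def test_hand_entered_toy_matrix(self):
        rows = [("S1-A1", "s", 1), ("S2-A3", "s", 7), ("S3-A4", "s", 2), ("S3-A1", "s", 3)]
        mat = export_heatmap(self._table(rows), ["S1", "S2", "S3"], ["A1", "A2", "A3", "A4"])
        expected = np.array([[1, 0, 0, 0], [0, 0, 7, 0], [3, 0, 0, 2]])
        assert (mat.to_numpy() == expected).all()

    def test_unknown_structure_raises(self):
        t = self._table([("S9-A1", "s", 1)])
        with pytest.raises(ValueError):
            export_heatmap(t, ["S1"], ["A1"])
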