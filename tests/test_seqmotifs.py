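import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hlhkit import synthetic
from hlhkit.seqmotifs import (
    conservation_map,
    hydropathy_profile,
    identity_matrix,
    net_charge,
    physchem,
    ptm_meta_score,
    scan_dbd,
    scan_nes,
    scan_nls,
)


class TestNlsScan:
    def test_core_pattern_found(self):
        hits = scan_nls("AAKKRKAA")
        assert [(h.start, h.end) for h in hits] == [(3, 6)]
        assert hits[0].sequence == "KKRK"

    def test_no_lysine_no_hits(self):
        assert scan_nls("AAAGGGTTTSSS") == []

    def test_bipartite_extension_spans_second_cluster(self):
        seq = "A" * 81 + "KKAR" + "A" * 7 + "KKRR" + "A" * 4
        hits = [h for h in scan_nls(seq) if h.bipartite]
        assert [(h.start, h.end) for h in hits] == [(82, 96)]
        assert hits[0].end - hits[0].start + 1 == 15


class TestNesScan:
    def test_literal_pattern_single_hit(self):
        hits = scan_nes("LAAALAALAL")
        assert [(h.start, h.end) for h in hits] == [(1, 10)]
        assert hits[0].score == 1.0

    def test_wrong_spacing_rejected(self):
        assert scan_nes("LLLLAAAAAA") == []

    def test_planted_position_recovered(self):
        seq = synthetic.embed_motifs(60, [("LAAALAALAL", 29)], seed=0)
        assert [h.start for h in scan_nes(seq)] == [29]

    def test_extended_anchor_option(self):
        seq = "IAAALAALAL"
        assert scan_nes(seq) == []
        hits = scan_nes(seq, extended_anchors=True)
        assert len(hits) == 1 and hits[0].score == pytest.approx(0.75)


class TestDbdScan:
    @pytest.mark.parametrize("motif", ["RKGRTKR", "KKRGARR"])
    def test_published_cores_score_six_sevenths(self, motif):
        hits = scan_dbd(motif)
        assert len(hits) == 1
        assert hits[0].score == pytest.approx(6 / 7)

    def test_poly_alanine_clean(self):
        assert scan_dbd("A" * 50) == []

    def test_bipartite_pairing_of_two_cores(self):
        seq = synthetic.embed_motifs(120, [("RKGRTKR", 20), ("KKRGARR", 50)], seed=1)
        hits = scan_dbd(seq)
        cores = [h for h in hits if h.motif_id == "dbd_core"]
        pairs = [h for h in hits if h.motif_id == "dbd_bipartite"]
        assert [h.start for h in cores] == [20, 50]
        assert [(h.start, h.end) for h in pairs] == [(20, 56)]

    def test_hit_subsequence_reslices_from_input(self):
        seq = synthetic.embed_motifs(100, [("RKGRTKR", 40)], seed=2)
        for h in scan_dbd(seq):
            assert seq[h.start - 1 : h.end] == h.sequence


class TestHydropathy:
    def test_poly_isoleucine_equals_scale_entry(self):
        profile = hydropathy_profile("I" * 15, window=9)
        np.testing.assert_allclose(profile, 4.5)

    def test_alternating_extremes_average(self):
        profile = hydropathy_profile("IR" * 10, window=4 + 5)
        # I = 4.5, R = -4.5; window of 9 holds 5 of one and 4 of the other
        assert np.abs(profile).max() <= 0.5

    def test_profile_length(self):
        assert len(hydropathy_profile("ACDEFGHIKL", window=9)) == 2

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            hydropathy_profile("ACDEFGHIKL", window=8)


class TestPhyschem:
    def test_glycine_molecular_weight(self):
        mw, _ = physchem("G")
        assert mw == pytest.approx(75.07, abs=0.01)

    def test_net_charge_vanishes_at_pi(self):
        for seq in ("ACDKRH", "GGDDEE", "KKKRRR"):
            _, pi = physchem(seq)
            assert abs(net_charge(seq, pi)) < 1e-3

    def test_charge_function_bounds(self):
        assert physchem("K" * 10)[1] > 10.0
        assert physchem("D" * 10)[1] < 4.0

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError):
            physchem("ACDEX")


class TestIdentityMatrix:
    def test_identical_pair_is_hundred(self):
        m = identity_matrix(["AAAA", "AAAA"])
        assert m.iloc[0, 1] == 100.0

    def test_half_identity(self):
        m = identity_matrix(["AAAA", "AATT"])
        assert m.iloc[0, 1] == 50.0

    def test_gap_gap_columns_excluded(self):
        m = identity_matrix(["A-A", "A-T"])
        assert m.iloc[0, 1] == 50.0

    def test_symmetric_with_diagonal_hundred(self):
        m = identity_matrix(["ACDE", "ACDF", "ACFF"])
        np.testing.assert_array_equal(m.values, m.values.T)
        np.testing.assert_array_equal(np.diag(m.values), 100.0)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            identity_matrix(["AAA", "AAAA"])


class TestConservation:
    def test_fully_conserved_column(self):
        out = conservation_map(["LAAA", "LTTT", "LCCC", "LGGG"])
        assert out.loc[0, "conservation_pct"] == 100.0
        assert out.loc[0, "grade"] == 9

    def test_half_conserved_column(self):
        out = conservation_map(["AL", "AL", "AV", "AV"])
        assert out.loc[1, "conservation_pct"] == 50.0

    def test_all_distinct_column(self):
        out = conservation_map(["A", "C", "D", "E"])
        assert out.loc[0, "conservation_pct"] == 25.0

    def test_projection_mismatch_reports_offset(self, hlh_structure):
        with pytest.raises(ValueError, match="mismatch"):
            conservation_map(["AAAA"], structure=hlh_structure)

    def test_projection_onto_structure(self):
        st = synthetic.build_ideal_helix("ACDE", [])
        out = conservation_map(["ACDE", "ACDA"], structure=st)
        assert list(out["residue_number"]) == [1, 2, 3, 4]


class TestPtmMetaScore:
    @staticmethod
    def _table(n_above: int, n_total: int = 30):
        rows = []
        for i in range(n_total):
            score = 0.9 if i < n_above else 0.1
            rows.append((12, "K", "acetyl", f"prog{i}", score, 0.5))
        return pd.DataFrame(rows, columns=["site", "residue", "class",
                                           "program", "score", "cutoff"])

    @pytest.mark.parametrize("n_above, expected", [(30, 1.0), (0, 0.0), (15, 0.5)])
    def test_fraction_of_predicting_programs(self, n_above, expected):
        out = ptm_meta_score(self._table(n_above), include_zero=True)
        assert out["score"].iloc[0] == pytest.approx(expected)

    def test_zero_sites_omitted_by_default(self):
        assert len(ptm_meta_score(self._table(0))) == 0

    def test_strictly_above_cutoff(self):
        table = self._table(0)
        table.loc[0, "score"] = 0.5  # exactly at the cutoff: not predicted
        out = ptm_meta_score(table, include_zero=True)
        assert out["score"].iloc[0] == 0.0

    def test_missing_cutoff_rejected(self):
        table = self._table(5)
        table.loc[3, "cutoff"] = np.nan
        with pytest.raises(ValueError, match="cutoff"):
            ptm_meta_score(table)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(flips=st.integers(min_value=0, max_value=30))
    def test_monotone_in_predicting_programs(self, flips):
        low = ptm_meta_score(self._table(flips), include_zero=True)["score"].iloc[0]
        high = ptm_meta_score(self._table(min(flips + 1, 30)),
                              include_zero=True)["score"].iloc[0]
        assert high >= low
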