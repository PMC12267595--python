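import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from il2kit import descriptors as dsc
from il2kit.io import AMINO_ACIDS, PeptideDataset, PeptideRecord

peptides = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=25)


class TestAAC:
    def test_examples(self):
        assert dsc.compute_aac("AAAA")[0] == 100.0
        assert np.allclose(dsc.compute_aac(AMINO_ACIDS), 5.0)
        aac = dsc.compute_aac("AC")
        assert aac[0] == 50.0 and aac[1] == 50.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            dsc.compute_aac("")

    @settings(max_examples=60, derandomize=True)
    @given(peptides)
    def test_sums_to_100(self, seq):
        assert dsc.compute_aac(seq).sum() == pytest.approx(100.0, abs=1e-9)


class TestDPC:
    def test_examples(self):
        v = dsc.compute_dpc("AAAA")
        assert v[0] == 100.0 and v.sum() == pytest.approx(100.0)
        v = dsc.compute_dpc("ACAC")
        names = dict(zip(dsc._DIPEPTIDES, v))
        assert names["AC"] == pytest.approx(200.0 / 3)
        assert names["CA"] == pytest.approx(100.0 / 3)

    def test_append_length(self):
        v = dsc.compute_dpc("ACAC", append_length=True)
        assert len(v) == 401 and v[-1] == 4.0

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            dsc.compute_dpc("A")

    @settings(max_examples=60, derandomize=True)
    @given(peptides)
    def test_sums_to_100(self, seq):
        assert dsc.compute_dpc(seq).sum() == pytest.approx(100.0, abs=1e-9)

    def test_repeat_converges_to_analytic_frequencies(self):
        # "XY" repeated k times: of 2k-1 adjacent pairs, k are XY, k-1 are YX
        seq = "WY" * 50
        names = dict(zip(dsc._DIPEPTIDES, dsc.compute_dpc(seq)))
        assert names["WY"] == pytest.approx(100.0 * 50 / 99)
        assert names["YW"] == pytest.approx(100.0 * 49 / 99)


class TestCTD:
    def test_homopolymer(self):
        v = dsc.compute_ctd("AAAA")
        groups = dsc.ctd_property_groups()
        names = dsc.ctd_column_names()
        vals = dict(zip(names, v))
        for prop, gs in groups.items():
            comp = [vals[f"CTD_{prop}_C_{g}"] for g, _ in gs]
            # A's group takes 100%, every transition is 0
            assert sorted(comp) == [0.0, 0.0, 100.0]
            a_group = next(g for g, members in gs if "A" in members)
            assert vals[f"CTD_{prop}_C_{a_group}"] == 100.0
            transitions = [x for n, x in vals.items() if n.startswith(f"CTD_{prop}_T_")]
            assert transitions == [0.0, 0.0, 0.0]
        assert len(v) == 147

    def test_charge_transition_single_crossing(self):
        # KKDD: pairs KK, KD, DK -> exactly one positive/negative crossing
        v = dict(zip(dsc.ctd_column_names(), dsc.compute_ctd("KKDD")))
        assert v["CTD_charge_T_positive_negative"] == pytest.approx(100.0 / 3)
        assert v["CTD_charge_T_positive_neutral"] == 0.0
        assert v["CTD_charge_T_neutral_negative"] == 0.0

    @settings(max_examples=40, derandomize=True)
    @given(peptides)
    def test_composition_normalises_and_distribution_monotone(self, seq):
        v = dict(zip(dsc.ctd_column_names(), dsc.compute_ctd(seq)))
        groups = dsc.ctd_property_groups()
        for prop, gs in groups.items():
            comp = sum(v[f"CTD_{prop}_C_{g}"] for g, _ in gs)
            assert comp == pytest.approx(100.0, abs=1e-9)
            for g, _ in gs:
                dist = [v[f"CTD_{prop}_D_{g}_{p}"] for p in (0, 25, 50, 75, 100)]
                assert all(0.0 <= d <= 100.0 for d in dist)
                assert dist == sorted(dist)


class TestRunAndGapDescriptors:
    def test_rri_run_length_formula(self):
        v = dsc.compute_rri("AAAB" .replace("B", "C"))  # AAAC: run A^3, run C^1
        assert v[0] == pytest.approx(9.0 / 4)
        assert v[1] == pytest.approx(1.0 / 4)

    def test_ddr_gap_sum(self):
        # A at 0 and 4: summed gap 4, length 5
        v = dsc.compute_ddr("ACDCA")
        assert v[0] == pytest.approx(100.0 * 4 / 5)
        assert v[1] == pytest.approx(100.0 * 2 / 5)  # C at 1 and 3
        assert v[2] == 0.0  # single occurrence

    def test_pcp_membership(self):
        v = dict(zip([f"PCP_{c}" for c, _ in dsc._PCP_CLASSES], dsc.compute_pcp("KR")))
        assert v["PCP_positively_charged"] == 100.0
        assert v["PCP_negatively_charged"] == 0.0


class TestTerminalBinary:
    def test_full_length_sets_16_bits(self):
        v = dsc.compute_terminal_binary("A" * 8 + "C" * 8)
        assert v.sum() == 16
        names = dsc.aab_column_names()
        on = {n for n, x in zip(names, v) if x == 1}
        assert on == {f"AAB_N{i}_A" for i in range(1, 9)} | {
            f"AAB_C{j}_C" for j in range(1, 9)
        }

    def test_overlapping_windows_for_10mer(self):
        v = dsc.compute_terminal_binary("ACDEFGHIKL")
        assert v.sum() == 16

    def test_short_peptide_unfilled_positions(self):
        v = dsc.compute_terminal_binary("ACDEF")
        assert v.sum() == 10  # 5 N slots + 5 C slots


class TestFeatureSetDispatch:
    @pytest.mark.parametrize(
        "tag,ncols",
        [("AAC", 20), ("DPC", 400), ("DPC_LEN", 401), ("CTD", 147),
         ("AAB", 320), ("PCP", 29), ("DDR", 20), ("RRI", 20)],
    )
    def test_shapes(self, tiny_labeled, tag, ncols):
        fm = dsc.compute_feature_set(tiny_labeled, tag)
        assert fm.frame.shape == (6, ncols)
        assert fm.row_ids == [r.id for r in tiny_labeled]
        assert not fm.frame.isna().any().any()

    def test_unknown_tag_errors(self, tiny_labeled):
        with pytest.raises(ValueError, match="unknown feature set"):
            dsc.compute_feature_set(tiny_labeled, "NOPE")

    def test_row_permutation_permutes_rows(self, tiny_labeled):
        fm = dsc.compute_feature_set(tiny_labeled, "AAC")
        rev = PeptideDataset(list(reversed(tiny_labeled.records)))
        fm_rev = dsc.compute_feature_set(rev, "AAC")
        assert (fm.frame.iloc[::-1].to_numpy() == fm_rev.frame.to_numpy()).all()

    def test_csv_round_trip(self, tiny_labeled, tmp_path):
        fm = dsc.compute_feature_set(tiny_labeled, "AAC")
        p = tmp_path / "aac.csv"
        fm.to_csv(p)
        back = dsc.FeatureMatrix.from_csv(p, "AAC")
        assert np.allclose(back.frame.to_numpy(), fm.frame.to_numpy())
        assert back.column_names == fm.column_names
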