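import math

import numpy as np
import pandas as pd
import pytest

from cytoreg.nanostring import (
    background_threshold,
    nanostring_log2fc,
    normalize_panel,
    positive_control_scale,
    read_panel,
    reference_gene_scale,
    subtract_background,
    write_normalized_tsv,
    write_qc_tsv,
)
from cytoreg import synth

from conftest import make_panel


class TestBackground:
    def test_mean_plus_two_sample_sd(self):
        panel = make_panel(
            {
                "geneA": [100] * 4,
                "POS_A": [800] * 4,
                "NEG_A": [4] * 4, "NEG_B": [6] * 4, "NEG_C": [5] * 4,
                "NEG_D": [5] * 4, "NEG_E": [5] * 4, "NEG_F": [5] * 4,
                "REF_1": [500] * 4,
            }
        )
        B = background_threshold(panel, "T1")
        assert B == pytest.approx(5 + 2 * math.sqrt(0.4))

    def test_all_zero_negatives_give_zero_threshold(self):
        panel = make_panel(
            {"geneA": [10] * 4, "POS_A": [800] * 4,
             "NEG_A": [0] * 4, "NEG_B": [0] * 4, "REF_1": [500] * 4}
        )
        assert background_threshold(panel, "C1") == 0.0

    def test_single_negative_probe_rejected_at_construction(self):
        with pytest.raises(ValueError, match="negative"):
            make_panel({"geneA": [10] * 4, "POS_A": [800] * 4,
                        "NEG_A": [5] * 4, "REF_1": [500] * 4})

    def test_subtraction_and_detection_flags(self):
        panel = make_panel(
            {
                "high": [10] * 4, "low": [6] * 4, "zero": [0] * 4,
                "POS_A": [800] * 4,
                "NEG_A": [4] * 4, "NEG_B": [6] * 4, "NEG_C": [5] * 4,
                "NEG_D": [5] * 4, "NEG_E": [5] * 4, "NEG_F": [5] * 4,
                "REF_1": [500] * 4,
            }
        )
        corrected, detected, B = subtract_background(panel)
        assert corrected.at["high", "T1"] == pytest.approx(10 - (5 + 2 * math.sqrt(0.4)))
        assert not detected.at["low", "T1"]       # 6 <= 6.265 -> nd
        assert pd.isna(corrected.at["low", "T1"])
        assert not detected.at["zero", "T1"]


class TestScaleFactors:
    def test_flat_panel_gives_unit_scales(self, flat_panel):
        s_pos = positive_control_scale(flat_panel)
        np.testing.assert_allclose(s_pos, 1.0)
        corrected, _, _ = subtract_background(flat_panel)
        s_ref = reference_gene_scale(corrected, s_pos, flat_panel)
        np.testing.assert_allclose(s_ref, 1.0)

    def test_geometric_mean_construction(self):
        panel = make_panel(
            {"geneA": [50] * 4,
             "POS_A": [100, 200, 100, 100], "POS_B": [200, 400, 200, 200],
             "POS_C": [400, 800, 400, 400],
             "NEG_A": [0] * 4, "NEG_B": [0] * 4, "REF_1": [500] * 4}
        )
        s_pos = positive_control_scale(panel)
        # lane T1 geomean = (100*200*400)^(1/3) = 200; lane T2 doubled
        assert s_pos["T2"] == pytest.approx(s_pos["T1"] / 2)
        # product (scale * geomean) equal across lanes
        gm = panel.counts.loc[["POS_A", "POS_B", "POS_C"]].apply(
            lambda c: np.exp(np.log(c).mean()))
        np.testing.assert_allclose((s_pos * gm).to_numpy(),
                                   (s_pos * gm).iloc[0])

    def test_zero_positive_count_rejected(self):
        panel = make_panel(
            {"geneA": [50] * 4, "POS_A": [0, 100, 100, 100],
             "NEG_A": [0] * 4, "NEG_B": [0] * 4, "REF_1": [500] * 4}
        )
        with pytest.raises(ValueError, match="positive"):
            positive_control_scale(panel)

    def test_reference_lane_at_4x_gets_quarter_scale(self):
        panel = make_panel(
            {"geneA": [50] * 4, "POS_A": [800] * 4,
             "NEG_A": [0] * 4, "NEG_B": [0] * 4,
             "REF_1": [2000, 500, 500, 500]}
        )
        corrected, _, _ = subtract_background(panel)
        s_ref = reference_gene_scale(corrected, positive_control_scale(panel),
                                     panel)
        assert s_ref["T1"] == pytest.approx(s_ref["T2"] / 4)

    def test_undetected_reference_names_lane_and_probe(self):
        panel = make_panel(
            {"geneA": [50] * 4, "POS_A": [800] * 4,
             "NEG_A": [4] * 4, "NEG_B": [6] * 4,
             "REF_1": [3, 500, 500, 500]}
        )
        corrected, _, _ = subtract_background(panel)
        with pytest.raises(ValueError, match="REF_1"):
            reference_gene_scale(corrected, positive_control_scale(panel),
                                 panel)


class TestLog2FC:
    def build_normalized(self, values, neg=0):
        panel = make_panel(
            {**values, "POS_A": [800] * 4,
             "NEG_A": [neg] * 4, "NEG_B": [neg] * 4, "REF_1": [500] * 4}
        )
        return normalize_panel(panel)

    def test_ratio_of_condition_means(self):
        norm = self.build_normalized({"geneA": [108, 108, 27, 27]})
        fc = nanostring_log2fc(norm)
        assert fc.at["geneA", "log2fc"] == pytest.approx(2.0)
        assert fc.at["geneA", "code"] == "ok"

    def test_equal_means_give_zero(self):
        norm = self.build_normalized({"geneA": [50, 50, 50, 50]})
        assert nanostring_log2fc(norm).at["geneA", "log2fc"] == pytest.approx(0.0)

    def test_nd_codes(self):
        norm = self.build_normalized(
            {"ndT": [3, 3, 50, 50], "ndC": [50, 50, 3, 3], "ndBoth": [3, 3, 3, 3]},
            neg=4,
        )
        fc = nanostring_log2fc(norm)
        assert fc.at["ndT", "code"] == "nd-treated"
        assert fc.at["ndC", "code"] == "nd-control"
        assert fc.at["ndBoth", "code"] == "ND"

    def test_mean_of_ratios_flag(self):
        norm = self.build_normalized({"geneA": [40, 160, 20, 20]})
        default = nanostring_log2fc(norm).at["geneA", "log2fc"]
        alt = nanostring_log2fc(norm, mean_of_ratios=True).at["geneA", "log2fc"]
        assert default == pytest.approx(np.log2(100 / 20))
        assert alt == pytest.approx(0.5 * (np.log2(2) + np.log2(8)))

    def test_missing_condition_rejected(self):
        norm = self.build_normalized({"geneA": [50] * 4})
        with pytest.raises(ValueError):
            nanostring_log2fc(norm, treated_lanes=[], control_lanes=["C1"])


class TestChainProperties:
    def test_single_lane_rescaling_preserves_fold_changes(self):
        panel, _ = synth.simulate_nanostring_panel(
            n_endogenous=8, sigma=0.05, seed=21)
        scaled_counts = panel.counts.copy()
        scaled_counts["T2"] = (scaled_counts["T2"] * 3).round().astype(int)
        scaled = synth.simulate_nanostring_panel(n_endogenous=8, sigma=0.05,
                                                 seed=21)[0]
        scaled.counts = scaled_counts

        base_norm = normalize_panel(panel)
        scaled_norm = normalize_panel(scaled)
        # detection flags are lane-local, hence unchanged
        pd.testing.assert_frame_equal(base_norm.detected, scaled_norm.detected)
        # values agree up to one shared unit (the cross-lane anchor moves);
        # all fold changes are therefore unchanged
        ratio = (scaled_norm.values / base_norm.values).stack()
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)
        fc_a = nanostring_log2fc(base_norm)["log2fc"].dropna()
        fc_b = nanostring_log2fc(scaled_norm)["log2fc"].dropna()
        np.testing.assert_allclose(fc_a, fc_b, atol=1e-9)

    def test_raising_one_count_never_decreases_its_value(self):
        panel, _ = synth.simulate_nanostring_panel(
            n_endogenous=5, sigma=0.0, seed=2)
        bumped = synth.simulate_nanostring_panel(
            n_endogenous=5, sigma=0.0, seed=2)[0]
        bumped.counts.at["gene001", "T1"] += 50
        a = normalize_panel(panel).values.at["gene001", "T1"]
        b = normalize_panel(bumped).values.at["gene001", "T1"]
        assert b >= a


class TestSimulationRecovery:
    def test_noiseless_unit_lanes_recover_exact_ratios(self):
        truth = np.array([2.0, 1.0, 0.0, -1.0, -2.0])
        panel, _ = synth.simulate_nanostring_panel(
            n_endogenous=5, true_log2fc=truth, lane_factors=np.ones(6),
            sigma=0.0, baseline_range=(512.0, 512.0), seed=1)
        fc = nanostring_log2fc(normalize_panel(panel))
        np.testing.assert_allclose(fc["log2fc"].to_numpy(), truth, atol=1e-12)

    def test_lane_factors_recovered_within_five_percent(self):
        # averaged over replicate panels: one panel pins the combined lane
        # scale only to ~sigma/sqrt(3) (three reference probes)
        lf = np.array([1.0, 2.0, 0.8, 1.1, 0.9, 1.3])
        log_recs = []
        for seed in range(8):
            panel, _ = synth.simulate_nanostring_panel(
                lane_factors=lf, sigma=0.1, seed=seed)
            norm = normalize_panel(panel)
            rec = 1.0 / (norm.s_pos * norm.s_ref)
            log_recs.append(np.log(rec / np.exp(np.log(rec).mean())))
        recovered = np.exp(np.mean(log_recs, axis=0))
        target = lf / np.exp(np.log(lf).mean())
        np.testing.assert_allclose(recovered, target, rtol=0.05)

    def test_standard_curve_qc_reported(self):
        # additive background flattens the low end of the ladder, so the
        # log-log slope sits slightly below 1 even at low noise
        panel, _ = synth.simulate_nanostring_panel(sigma=0.05, seed=3)
        norm = normalize_panel(panel)
        assert ((norm.qc["slope"] > 0.85) & (norm.qc["slope"] < 1.05)).all()
        assert (norm.qc["r_squared"] > 0.97).all()


def test_panel_tsv_round_trip(tmp_path):
    panel, _ = synth.simulate_nanostring_panel(n_endogenous=4, seed=5)
    panel.counts.rename_axis("probe_id").to_csv(tmp_path / "counts.tsv", sep="\t")
    meta = pd.DataFrame({"class": panel.probe_class,
                         "known_conc": panel.positive_conc})
    meta.rename_axis("probe_id").to_csv(tmp_path / "probes.tsv", sep="\t")
    lanes = pd.DataFrame({"condition": pd.Series(panel.lane_condition),
                          "replicate": pd.Series(panel.lane_replicate)})
    lanes.rename_axis("lane_id").to_csv(tmp_path / "lanes.tsv", sep="\t")

    again = read_panel(tmp_path / "counts.tsv", tmp_path / "probes.tsv",
                       tmp_path / "lanes.tsv")
    pd.testing.assert_frame_equal(again.counts, panel.counts,
                                  check_names=False)
    assert again.lane_condition == panel.lane_condition

    norm = normalize_panel(again)
    write_normalized_tsv(norm, tmp_path / "norm.tsv")
    write_qc_tsv(norm, tmp_path / "qc.tsv")
    text = (tmp_path / "norm.tsv").read_text()
    assert text.startswith("probe_id\t")
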