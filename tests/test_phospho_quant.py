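import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import incitepipe as ip
from incitepipe.phospho_quant import STATE_DOUBLE, STATE_UNPHOS
from tests.conftest import annotations_from_truth


def _small_setup(iso_counts_by_cell, phospho_counts):
    """One culture/condition group, panel1 cells; returns (adt, annotations, design)."""
    design = ip.default_design()
    n = len(iso_counts_by_cell)
    barcodes = [f"b{i}" for i in range(n)]
    features = ["p-STAT3", "p-p65", "p-ERK1/2", "p-FOS", "isotype"]
    dense = np.zeros((n, 5), dtype=int)
    dense[:, 4] = iso_counts_by_cell
    dense[:, 0] = phospho_counts
    adt = ip.CellByFeatureCounts(barcodes, features, sp.csr_matrix(dense), "adt")
    ann = pd.DataFrame(
        {
            "sample_id": "A_stimulated_panel1",
            "condition": "stimulated",
            "culture": "A",
            "panel": "panel1",
            "group": "A_stimulated",
            "status": "singlet",
            "pass_qc": True,
            "contaminant": False,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    return adt, ann, design


class TestIsotypeMedians:
    def test_odd_group_median(self):
        adt, ann, design = _small_setup([3, 4, 5], [0, 0, 0])
        med = ip.compute_isotype_medians(adt, ann, design)
        assert med[("A", "stimulated")] == 4.0

    def test_even_group_mean_of_middle(self):
        adt, ann, design = _small_setup([3, 5], [0, 0])
        med = ip.compute_isotype_medians(adt, ann, design)
        assert med[("A", "stimulated")] == 4.0

    def test_one_median_per_culture_condition(self, tiny_dataset, tiny_annotations):
        _, adt, _, truth = tiny_dataset
        med = ip.compute_isotype_medians(adt, tiny_annotations, truth.config.design)
        assert len(med) == 6  # 3 cultures x 2 conditions
        assert all(3.0 <= m <= 5.0 for m in med.values())

    def test_group_without_isotype_cells_errors(self):
        adt, ann, design = _small_setup([3, 4], [0, 0])
        ann["panel"] = "panel2"  # no isotype-bearing cells left in the group
        ann["sample_id"] = "A_stimulated_panel2"
        with pytest.raises(ip.DegenerateDataError, match="stimulated"):
            ip.compute_isotype_medians(adt, ann, design)


class TestCorrectAndCall:
    def test_correction_arithmetic(self):
        adt, ann, design = _small_setup([4, 4, 4], [6, 2, 0])
        quant = ip.correct_and_call(adt, {("A", "stimulated"): 4.0}, design, ann)
        sub = quant.table[quant.table["target"] == "p-STAT3"].set_index("barcode")
        assert sub.loc["b0", "corrected"] == pytest.approx(math.log(3), abs=1e-12)
        assert bool(sub.loc["b0", "positive"])
        assert sub.loc["b1", "corrected"] == 0.0 and not sub.loc["b1", "positive"]
        assert sub.loc["b2", "corrected"] == 0.0 and not sub.loc["b2", "positive"]

    def test_isotype_channel_excluded(self):
        adt, ann, design = _small_setup([4], [1])
        quant = ip.correct_and_call(adt, {("A", "stimulated"): 4.0}, design, ann)
        assert "isotype" not in set(quant.table["target"])

    def test_positive_iff_raw_exceeds_median_brute_force(self):
        """Algebraic equivalence of the three-step recipe, on random matrices."""
        rng = np.random.default_rng(77)
        for _ in range(200):
            raw = rng.integers(0, 12, size=8)
            m = float(rng.integers(0, 8)) + (0.5 if rng.random() < 0.3 else 0.0)
            v = np.log1p(np.clip(raw - m, 0, None))
            assert ((v > 0) == (raw > m)).all()

    def test_raising_median_never_raises_level(self):
        adt, ann, design = _small_setup([4] * 5, [0, 2, 5, 8, 20])
        q1 = ip.correct_and_call(adt, {("A", "stimulated"): 2.0}, design, ann)
        q2 = ip.correct_and_call(adt, {("A", "stimulated"): 6.0}, design, ann)
        v1 = q1.table.sort_values(["target", "barcode"])["corrected"].to_numpy()
        v2 = q2.table.sort_values(["target", "barcode"])["corrected"].to_numpy()
        assert (v2 <= v1).all()


class TestPhosphoStates:
    def _states(self, stat3, p65):
        adt, ann, design = _small_setup([4, 4], [0, 0])
        dense = adt.to_dense()
        dense[:, 0] = stat3
        dense[:, 1] = p65
        adt2 = ip.CellByFeatureCounts(adt.cell_barcodes, adt.feature_ids, sp.csr_matrix(dense), "adt")
        quant = ip.correct_and_call(adt2, {("A", "stimulated"): 4.0}, design, ann)
        return ip.annotate_phospho_states(quant, design)

    def test_double_single_and_unphosphorylated(self):
        st = self._states([10, 0], [10, 0])
        assert st.loc["b0", "state"] == STATE_DOUBLE
        assert st.loc["b1", "state"] == STATE_UNPHOS
        st2 = self._states([10, 0], [0, 10])
        assert st2.loc["b0", "state"] == "single:p-STAT3"
        assert st2.loc["b1", "state"] == "single:p-p65"

    def test_panel_with_wrong_target_count_rejected(self):
        design = ip.SampleDesign(
            condition_hashes={"H1": "stim"},
            identity_hashes={"H2": ("A", "p1")},
            panels={"p1": ip.PanelSpec(("t1", "t2", "t3"), "iso")},
        )
        quant = ip.AdtQuant(table=pd.DataFrame(columns=["barcode", "target", "positive", "panel"]))
        with pytest.raises(ip.ConfigError, match="pairs"):
            ip.annotate_phospho_states(quant, design)


class TestSampleSummary:
    def test_direct_fraction(self):
        adt, ann, design = _small_setup([4] * 10, [10] * 4 + [0] * 6)
        quant = ip.correct_and_call(adt, {("A", "stimulated"): 4.0}, design, ann)
        s = ip.summarize_per_sample(quant)
        row = s[s["target"] == "p-STAT3"].iloc[0]
        assert row["percent_positive"] == pytest.approx(40.0)
        assert row["n_cells"] == 10

    def test_all_positive_is_hundred(self):
        adt, ann, design = _small_setup([4] * 3, [10, 20, 30])
        quant = ip.correct_and_call(adt, {("A", "stimulated"): 4.0}, design, ann)
        s = ip.summarize_per_sample(quant)
        assert s[s["target"] == "p-STAT3"]["percent_positive"].iloc[0] == 100.0

    def test_recovers_truth_positivity(self, tiny_dataset, tiny_annotations):
        """Measured percent positivity matches truth per (group, target) within 2 points."""
        _, adt, _, truth = tiny_dataset
        design = truth.config.design
        med = ip.compute_isotype_medians(adt, tiny_annotations, design)
        quant = ip.correct_and_call(adt, med, design, tiny_annotations)
        s = ip.summarize_per_sample(quant)
        ts = ip.truth_summary(truth)
        merged = s.merge(ts, on=["group", "target"], suffixes=("_m", "_t"))
        assert len(merged) == 24  # 6 groups x 4 targets
        # ~45 cells per (group, target): one miscalled cell moves a row ~2.2 points
        assert (merged["percent_positive_m"] - merged["percent_positive_t"]).abs().max() < 3.0


class TestOrderingInvariance:
    def test_percent_invariant_to_cell_order(self, tiny_dataset, tiny_annotations):
        _, adt, _, truth = tiny_dataset
        design = truth.config.design
        med = ip.compute_isotype_medians(adt, tiny_annotations, design)
        s1 = ip.summarize_per_sample(ip.correct_and_call(adt, med, design, tiny_annotations))
        perm = np.random.default_rng(3).permutation(adt.n_cells)
        adt2 = ip.CellByFeatureCounts(
            [adt.cell_barcodes[i] for i in perm], adt.feature_ids, adt.counts[perm], "adt"
        )
        s2 = ip.summarize_per_sample(ip.correct_and_call(adt2, med, design, tiny_annotations))
        pd.testing.assert_frame_equal(s1, s2)
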