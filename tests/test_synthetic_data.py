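import numpy as np
import pandas as pd
import pytest
from scipy import stats

import incitepipe as ip
from incitepipe.synthetic_data import STREAM_STRUCTURE, substream


class TestValidation:
    def test_zero_samples_rejected(self):
        design = ip.SampleDesign(condition_hashes={"H1": "stim"}, identity_hashes={}, panels={})
        with pytest.raises(ip.ConfigError, match="zero samples"):
            ip.generate_dataset(ip.GeneratorConfig(design=design, positive_fraction={}))

    def test_incompatible_program_overlap_rejected(self):
        progs = {
            "a": ip.GeneProgram("a", ("g1",), 1.0, "resting"),
            "b": ip.GeneProgram("b", ("g1",), 2.0, "activation"),
        }
        with pytest.raises(ip.ConfigError, match="incompatible"):
            ip.GeneratorConfig(gene_programs=progs)

    def test_compatible_overlap_allowed(self):
        progs = {
            "a": ip.GeneProgram("a", ("g1",), 1.0, "resting"),
            "b": ip.GeneProgram("b", ("g1",), 1.0, "activation"),
        }
        ip.GeneratorConfig(gene_programs=progs)  # no error

    def test_out_of_range_fractions_rejected(self):
        with pytest.raises(ip.ConfigError):
            ip.GeneratorConfig(doublet_rate=1.5)


class TestEdgeCases:
    def test_zero_cells_gives_empty_dataset(self):
        rna, adt, hto, truth = ip.generate_dataset(ip.GeneratorConfig(n_cells_per_sample=0))
        assert rna.n_cells == adt.n_cells == hto.n_cells == 0
        assert len(truth) == 0
        assert rna.n_features > 0

    def test_zero_doublet_rate(self):
        cfg = ip.GeneratorConfig(
            n_cells_per_sample=20, n_genes=300, mean_genes_per_cell=100,
            mean_counts_per_cell=300, doublet_rate=0.0, seed=2,
        )
        truth = ip.generate_dataset(cfg)[3]
        assert truth.cells["is_doublet"].sum() == 0


class TestDeterminismAndStructure:
    def test_identical_config_bit_identical_output(self, tiny_config, tiny_dataset):
        rna2, adt2, hto2, truth2 = ip.generate_dataset(tiny_config)
        rna, adt, hto, truth = tiny_dataset
        assert rna.equals(rna2) and adt.equals(adt2) and hto.equals(hto2)
        pd.testing.assert_frame_equal(truth.cells, truth2.cells)

    def test_shared_barcode_axis_and_uniqueness(self, tiny_dataset):
        rna, adt, hto, truth = tiny_dataset
        assert rna.cell_barcodes == adt.cell_barcodes == hto.cell_barcodes
        assert len(set(rna.cell_barcodes)) == rna.n_cells
        assert list(truth.cells.index) == rna.cell_barcodes

    def test_doublet_flags_replay_bernoulli_substream(self, tiny_config, tiny_dataset):
        """Doublet flags are exactly the first Bernoulli draws of the structure stream."""
        truth = tiny_dataset[3]
        rng = substream(tiny_config.seed, STREAM_STRUCTURE)
        expected = rng.random(len(truth)) < tiny_config.doublet_rate
        assert (truth.cells["is_doublet"].to_numpy() == expected).all()

    def test_doublets_are_sums_of_recorded_constituents(self):
        cfg = ip.GeneratorConfig(
            n_cells_per_sample=25, n_genes=400, mean_genes_per_cell=150,
            mean_counts_per_cell=500, doublet_rate=0.15, seed=6,
        )
        rna, adt, hto, truth, comp = ip.generate_dataset(cfg, _return_components=True)
        doublets = truth.cells["is_doublet"].to_numpy()
        for modality, mat in zip(("gene", "adt", "hashtag"), (rna, adt, hto)):
            primary, partner = comp[modality]
            assert ((primary + partner) != mat.counts).nnz == 0
            partner_rows = np.asarray(partner.sum(axis=1)).ravel()
            assert (partner_rows[~doublets] == 0).all()
            if modality in ("gene", "hashtag"):  # ADT rows can draw all-zero
                assert (partner_rows[doublets] > 0).all()
        # constituents come from distinct samples
        d = truth.cells[doublets]
        assert (d["partner_sample"] != d["sample_id"]).all()

    def test_truth_fractions_match_config_within_binomial_ci(self):
        cfg = ip.GeneratorConfig(
            n_cells_per_sample=1000, n_genes=60, mean_genes_per_cell=20,
            mean_counts_per_cell=80, doublet_rate=0.0, contaminant_fraction=0.0, seed=8,
        )
        truth = ip.generate_dataset(cfg)[3]
        t = truth.cells
        for (sid, target), frac in cfg.positive_fraction.items():
            sub = t[t["sample_id"] == sid]
            n = len(sub)
            observed = sub[f"pos_{target}"].mean()
            half = stats.norm.ppf(0.995) * np.sqrt(max(frac * (1 - frac), 1e-9) / n)
            assert abs(observed - frac) <= half + 1e-9, (sid, target)

    def test_counts_nonnegative_integers(self, tiny_dataset):
        for m in tiny_dataset[:3]:
            assert (m.counts.data >= 0).all()
            assert m.counts.dtype == np.int64


class TestReportedScaleDefaults:
    def test_detected_genes_per_cell_near_reported_mean(self):
        """Stimulated singlets average ~3,000 detected genes at default depth."""
        cfg = ip.GeneratorConfig(n_cells_per_sample=25, seed=4)  # default 10k genes
        rna, _, _, truth = ip.generate_dataset(cfg)
        qc = ip.compute_qc_metrics(rna)
        sel = ((truth.cells["condition"] == "stimulated") & ~truth.cells["is_doublet"]).to_numpy()
        mean_genes = qc.loc[sel, "genes_detected"].mean()
        assert mean_genes == pytest.approx(3026, rel=0.10)

    def test_isotype_medians_in_reported_range(self, tiny_dataset, tiny_annotations):
        _, adt, _, truth = tiny_dataset
        med = ip.compute_isotype_medians(adt, tiny_annotations, truth.config.design)
        assert all(3.0 <= v <= 5.0 for v in med.values())


class TestFlowTable:
    def test_zero_noise_is_exact_truth(self, tiny_dataset):
        truth = tiny_dataset[3]
        flow = ip.generate_flow_table(truth, noise_sd=0.0, seed=1)
        ts = ip.truth_summary(truth)
        merged = flow.table.merge(
            ts, left_on=["sample_id", "target_id"], right_on=["group", "target"]
        )
        assert np.allclose(merged["percent_positive_x"], merged["percent_positive_y"])

    def test_zero_noise_concordance_r2_is_one(self, tiny_dataset):
        truth = tiny_dataset[3]
        flow = ip.generate_flow_table(truth, noise_sd=0.0, seed=1)
        fits = ip.compare_modalities(ip.truth_summary(truth), flow)
        informative = [f for f in fits if f.axis == "percent_positive"]
        assert len(informative) == 4
        assert all(f.r_squared == pytest.approx(1.0, abs=1e-9) for f in fits)

    def test_stim_pfos_fraction_yields_864_percent(self):
        cfg = ip.GeneratorConfig(
            n_cells_per_sample=400, n_genes=60, mean_genes_per_cell=20,
            mean_counts_per_cell=80, doublet_rate=0.0, contaminant_fraction=0.0, seed=10,
        )
        truth = ip.generate_dataset(cfg)[3]
        flow = ip.generate_flow_table(truth, noise_sd=0.0, seed=0)
        row = flow.table[
            (flow.table["sample_id"] == "A_stimulated") & (flow.table["target_id"] == "p-FOS")
        ]
        assert row["percent_positive"].iloc[0] == pytest.approx(86.4, abs=2.5)

    def test_empty_truth_rejected(self):
        truth = ip.generate_dataset(ip.GeneratorConfig(n_cells_per_sample=0))[3]
        with pytest.raises(ip.DegenerateDataError):
            ip.generate_flow_table(truth, noise_sd=0.0, seed=0)


class TestWriteDataset:
    def test_round_trip_through_disk(self, tmp_path):
        cfg = ip.GeneratorConfig(
            n_cells_per_sample=10, n_genes=200, mean_genes_per_cell=80,
            mean_counts_per_cell=200, seed=12,
        )
        rna, adt, hto, truth = ip.generate_dataset(cfg)
        ip.write_dataset(rna, adt, hto, truth, tmp_path)
        assert ip.read_counts_dir(tmp_path / "rna", "gene").equals(rna)
        assert ip.read_counts_dir(tmp_path / "adt", "adt").equals(adt)
        assert ip.read_counts_dir(tmp_path / "hto", "hashtag").equals(hto)
        assert (tmp_path / "truth.tsv").exists() and (tmp_path / "generator_config.json").exists()
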