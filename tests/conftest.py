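import numpy as np
import pandas as pd
import pytest

import incitepipe as ip


@pytest.fixture(scope="session")
def tiny_config() -> ip.GeneratorConfig:
    """Small but fully structured dataset: 12 samples x 50 cells, 800 genes."""
    return ip.GeneratorConfig(
        n_cells_per_sample=50,
        n_genes=800,
        mean_genes_per_cell=400.0,
        mean_counts_per_cell=1200.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return ip.generate_dataset(tiny_config)


def annotations_from_truth(truth: ip.SyntheticTruth) -> pd.DataFrame:
    """Oracle-side cell annotations built directly from generator ground truth."""
    t = truth.cells
    ann = t[["sample_id", "condition", "culture", "panel", "group"]].copy()
    ann["status"] = np.where(t["is_doublet"], "doublet", "singlet")
    ann["pass_qc"] = True
    ann["contaminant"] = t["is_contaminant"].to_numpy()
    return ann


@pytest.fixture(scope="session")
def tiny_annotations(tiny_dataset):
    return annotations_from_truth(tiny_dataset[3])
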