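import numpy as np
import pytest

import chromaccess as ca


@pytest.fixture(scope="session")
def noise_free_well():
    """One rendered well of 50 separated nuclei with exact ground truth."""
    cells = ca.sample_population(ca.PopulationParams(n_cells=50, seed=2))
    rp = ca.RenderParams(seed=3, noise_model="none")
    img, labels, truth = ca.render_well(cells, ca.DyeModel(), rp)
    return img, labels, truth


@pytest.fixture(scope="session")
def demo_plate(tmp_path_factory):
    """Two-condition plate (accessible fraction 0.30 vs 0.45), EdU labelled."""
    out = tmp_path_factory.mktemp("plate")
    conds = [
        ca.ConditionSpec(
            "control",
            ca.PopulationParams(n_cells=50, accessible_fraction=0.30, edu_label_s_phase=True),
            ca.DyeModel(),
            n_wells=4,
            edu_channel=True,
        ),
        ca.ConditionSpec(
            "treated",
            ca.PopulationParams(n_cells=50, accessible_fraction=0.45, edu_label_s_phase=True),
            ca.DyeModel(),
            n_wells=4,
            edu_channel=True,
        ),
    ]
    layout, truth = ca.generate_plate(
        conds, ca.RenderParams(noise_model="gaussian"), out, seed=42
    )
    return out, layout, truth


def match_to_truth(segs: np.ndarray, truth_labels: np.ndarray, truth_row):
    """Segmentation label that overlaps a given ground-truth nucleus most."""
    true_mask = truth_labels == (truth_row.cell_id + 1)
    ids = segs[true_mask]
    ids = ids[ids > 0]
    if ids.size == 0:
        return None
    return int(np.bincount(ids).argmax())
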