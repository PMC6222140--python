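import numpy as np
import pytest

import redoxhcs as rx


@pytest.fixture(scope="session")
def cal() -> rx.ProbeCalibration:
    return rx.ProbeCalibration()


@pytest.fixture(scope="session")
def sparse_field(cal):
    """Ten well-separated cells: both segmentation modes resolve them all."""
    scene = rx.SceneSpec(n_cells=10, field_shape=(192, 192), min_spacing_px=40.0)
    return rx.generate_field(scene, cal, rx.NoiseSpec(), seed=11)


@pytest.fixture(scope="session")
def crowded_field(cal):
    """A tight monolayer patch where halos of neighbouring cells touch."""
    scene = rx.crowded_scene(n_cells=40, field_shape=(192, 192))
    return rx.generate_field(scene, cal, rx.NoiseSpec(), seed=12)


@pytest.fixture(scope="session")
def graded_oxidation_fields(cal):
    """Fields whose cells span the whole oxidation range, with ground truth."""
    out = []
    for seed in range(4):
        scene = rx.SceneSpec(
            n_cells=30,
            min_spacing_px=26.0,
            oxidized_fraction=lambda rng, n: rng.uniform(0.0, 1.0, n),
        )
        out.append(rx.generate_field(scene, cal, rx.NoiseSpec(), seed=20 + seed))
    return out


def matched_measurements(fimg, truth, mode="nuclear-ring"):
    """Measure a field and join each record to its ground-truth cell by
    nucleus IoU matching. Returns (records, true_ratio, true_f) aligned."""
    from redoxhcs.quantify import analyze_field
    from redoxhcs.segment import match_to_ground_truth, segment_nuclei, \
        subtract_background

    recs = analyze_field(fimg, mode=mode)
    nuc = segment_nuclei(subtract_background(np.asarray(fimg.channels["nuclear"],
                                                        dtype=float)))
    m = match_to_ground_truth(nuc, truth.nucleus_labels, 0.5)
    lut = dict(zip(m.pairs.pred_label, m.pairs.truth_label))
    rows = []
    for r in recs:
        if r.ratio is None or r.cell_label not in lut:
            continue
        tl = int(lut[r.cell_label])
        rows.append(
            (r, truth.true_ratio[tl - 1], truth.true_oxidized_fraction[tl - 1])
        )
    return rows
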