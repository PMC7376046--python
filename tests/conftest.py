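import numpy as np
import pytest

from ctcscope import dataset, segment, synthgen
from ctcscope.synthgen import CTC, WBC


@pytest.fixture(scope="session")
def nontouching_config():
    return synthgen.GeneratorConfig(touching_fraction=0.0)


@pytest.fixture(scope="session")
def small_pair(nontouching_config):
    """One 480x640 frame with 20 WBC + 4 CTC, non-touching."""
    return synthgen.generate_pair(20, 4, nontouching_config, seed=42,
                                  frame_id="fixture0")


@pytest.fixture(scope="session")
def segmented_pair(small_pair):
    label_map, regions = segment.segment_frame(small_pair.bright)
    return small_pair, label_map, regions


def match_to_truth(cells, regions, max_dist=3.0):
    """Greedy nearest matching of region centroids to ground-truth centers.

    Returns (matched pairs [(cell_idx, region_idx)], unmatched cells,
    false regions).
    """
    centers = np.array([c.center_rc for c in cells]).reshape(-1, 2)
    cents = np.array([r.centroid_rc for r in regions]).reshape(-1, 2)
    if len(centers) == 0 or len(cents) == 0:
        return [], list(range(len(cells))), list(range(len(regions)))
    d = np.linalg.norm(centers[:, None, :] - cents[None, :, :], axis=2)
    pairs = []
    used_c, used_r = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for ci, ri in order:
        if d[ci, ri] > max_dist:
            break
        if ci in used_c or ri in used_r:
            continue
        pairs.append((int(ci), int(ri)))
        used_c.add(int(ci))
        used_r.add(int(ri))
    unmatched = [i for i in range(len(cells)) if i not in used_c]
    false = [i for i in range(len(regions)) if i not in used_r]
    return pairs, unmatched, false


def make_toy_crops(n_per_class=12, side=30, seed=0, sep=2.0, prefix="toy"):
    """Trivially separable crops: class-dependent blob contrast + noise.

    The patches survive normalization (mean 0 / sd 1) with the class signal
    intact because the classes differ in *pattern*, not offset: WBC-like
    crops carry a centered bright blob, CTC-like crops a bright ring.
    """
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:side, 0:side] - (side - 1) / 2.0
    rad = np.hypot(rr, cc)
    blob = np.exp(-(rad / 5.0) ** 2)
    ring = np.exp(-((rad - 9.0) / 2.5) ** 2)
    crops = []
    for i in range(n_per_class):
        for label, pattern in ((WBC, blob), (CTC, ring)):
            px = sep * pattern + 0.1 * rng.standard_normal((side, side))
            px = (px - px.mean()) / px.std()
            crops.append(dataset.CellCrop(
                pixels=px, crop_id=f"{prefix}-{label}-{i}",
                source_frame="toy", centroid_rc=(float(side), float(side)),
                label=label))
    return crops
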