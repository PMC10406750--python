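import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

import gistgrf as g


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small generated cohort with panel, shared across tests."""
    cfg = g.CohortConfig(
        n_cases=12, image_height=128, image_width=128, effect_size=1.5,
        n_readers=25, seed=11,
    )
    cases = g.generate_cohort(cfg)
    reports = g.simulate_reader_panel(cases, cfg)
    return cfg, cases, reports


@pytest.fixture(scope="session")
def oriented_cropped(tiny_cohort):
    """One preprocessed image: oriented, masked, cropped, with regions."""
    _, cases, _ = tiny_cohort
    image = cases[0].images[("CC", "L")]
    oriented = g.orient_left(image)
    mask = g.make_mask(oriented)
    cropped, cmask, _ = g.crop_to_breast(oriented, mask)
    grid = g.lattice_blocks(cmask.mask, block_size=32, coverage_min=0.9)
    square = g.largest_inscribed_square(cmask.mask)
    return cropped, cmask, grid, square


def make_noise_feature_table(n_cases, view="CC", seed=0, informative=None):
    """Image-level feature table (2 rows/case) with 34 noise columns.

    ``informative``: optional dict {column_index: effect} shifting difficult
    cases' values.
    """
    rng = np.random.default_rng(seed)
    names = g.feature_names()
    labels = {}
    rows = []
    for i in range(n_cases):
        cid = f"c{i:03d}"
        label = "difficult" if i < n_cases // 2 else "easy"
        labels[cid] = label
        for lat in "LR":
            vals = rng.normal(size=34)
            if informative:
                for idx, eff in informative.items():
                    if label == "difficult":
                        vals[idx] += eff
            rows.append(
                {"case_id": cid, "view": view, "laterality": lat,
                 **dict(zip(names, vals))}
            )
    return pd.DataFrame(rows), pd.Series(labels)
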