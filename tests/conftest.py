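"""Shared fixtures: small phantoms, digital test solids and one trained net.

Everything is generated at test time; the trained-network fixture is session
scoped because slice-wise training is the most expensive step in the suite.
"""

import numpy as np
import pytest

from osteoseg.io import LabelVolume
from osteoseg.model import NetConfig, build_model, train
from osteoseg.phantom import PhantomSpec, generate_cohort, generate_phantom
from osteoseg.preprocess import (
    binarize_bone,
    build_slice_dataset,
    clean_labels,
    normalize_cohort,
    split_cases,
)


def digital_ball(radius_vox: float, shape=None, spacing=(1.0, 1.0, 1.0), radius_mm=None):
    """Binary ball rasterised at the grid centre; radius in voxels or mm."""
    spacing = np.asarray(spacing, dtype=float)
    r_mm = radius_mm if radius_mm is not None else radius_vox * spacing.max()
    if shape is None:
        half = np.ceil(r_mm / spacing).astype(int) + 4
        shape = tuple(2 * half + 1)
    idx = np.indices(shape).astype(float)
    centre = (np.array(shape) - 1) / 2 * spacing
    d2 = sum((idx[a] * spacing[a] - centre[a]) ** 2 for a in range(3))
    mask = (d2 <= r_mm**2).astype(np.int32)
    return LabelVolume(mask, spacing_mm=spacing, label_codes={"background": 0, "bone": 1})


@pytest.fixture(scope="session")
def femur_mask():
    """Noise-free phantom femur mask on the default anisotropic grid."""
    spec = PhantomSpec(grid_shape=(64, 160, 160), noise_sd=0.0, boundary_blur_sigma_mm=0.0)
    _, labels = generate_phantom(spec)
    return binarize_bone(labels, "femur")


SMOKE_NET = NetConfig(
    depth=3,
    base_filters=8,
    epochs=12,
    batch_size=8,
    seed=0,
    optimizer="adam",
    learning_rate=1e-3,
    loss="bce+dice",
)


def make_training_setup(noise_sd: float, n_cases: int = 8, seed: int = 7):
    """Phantom cohort -> normalised slice datasets for the smoke benchmark."""
    spec = PhantomSpec(grid_shape=(32, 64, 64), noise_sd=noise_sd, boundary_blur_sigma_mm=0.8)
    cohort = generate_cohort(n_cases, spec, seed=seed)
    ids = [c[0] for c in cohort]
    train_ids, val_ids = split_cases(ids, 0.7, seed=seed)
    normed = dict(zip(ids, normalize_cohort([c[1] for c in cohort])))
    masks = {cid: clean_labels(binarize_bone(lab, "femur")) for cid, _, lab in cohort}
    train_ds = build_slice_dataset(
        [normed[c] for c in train_ids], [masks[c] for c in train_ids], case_ids=train_ids
    )
    val_ds = build_slice_dataset(
        [normed[c] for c in val_ids], [masks[c] for c in val_ids], case_ids=val_ids
    )
    return {
        "train_ds": train_ds,
        "val_ds": val_ds,
        "normed": normed,
        "masks": masks,
        "train_ids": train_ids,
        "val_ids": val_ids,
    }


@pytest.fixture(scope="session")
def smoke_run():
    """One trained tiny U-Net on the 8-phantom benchmark, reused across tests."""
    setup = make_training_setup(noise_sd=8.0)
    net = build_model(SMOKE_NET)
    records = train(net, setup["train_ds"], setup["val_ds"], SMOKE_NET)
    return {"net": net, "records": records, "config": SMOKE_NET, **setup}
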