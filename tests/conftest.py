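"""Shared fixtures: small synthetic stacks and hand-built domains."""

from __future__ import annotations

import numpy as np
import pytest

from chromodomain3d.domain_detection import ChromatinDomain
from chromodomain3d.pipeline import synthetic_pipeline_config
from chromodomain3d.synthetic_data import SyntheticSpec, generate_cell

ISO_SPACING = (1.0, 1.0, 1.0)


def small_spec(**overrides) -> SyntheticSpec:
    """Fast 96x96x8 field with a fitting nucleus; ~0.1 s to generate."""
    params = dict(
        seed=7,
        shape_zyx=(8, 96, 96),
        nucleus_semiaxes_um=(0.5, 2.2, 2.2),
        n_domains=5,
        open_fraction=0.0,
        open_length_um=(0.7, 1.1),
        channel_shift=(1, -2),
    )
    params.update(overrides)
    return SyntheticSpec(**params)


@pytest.fixture(scope="session")
def small_cell():
    return generate_cell(small_spec())


@pytest.fixture(scope="session")
def small_config():
    return synthetic_pipeline_config(min_nucleus_pixels=1200, max_shift=6)


def make_domain(
    voxels: np.ndarray,
    intensities: dict[str, np.ndarray] | None = None,
    spacing: tuple[float, float, float] = ISO_SPACING,
    domain_id: int = 1,
) -> ChromatinDomain:
    """Build a ChromatinDomain directly from voxel coordinates."""
    voxels = np.asarray(voxels, dtype=np.int64).reshape(-1, 3)
    intensities = intensities or {}
    sp = np.asarray(spacing)
    return ChromatinDomain(
        id=domain_id,
        voxels=voxels,
        volume_vox=len(voxels),
        centroid_um=tuple((voxels.mean(axis=0) * sp).tolist()),
        mean_intensity={k: float(np.mean(v)) for k, v in intensities.items()},
        intensity_vectors={k: np.asarray(v, float) for k, v in intensities.items()},
        spacing=tuple(spacing),
    )


def ball_voxels(radius: int, center=None) -> np.ndarray:
    """Voxel coordinates of a digitized sphere of the given voxel radius."""
    c = center if center is not None else (radius + 2,) * 3
    rng = np.arange(0, 2 * (radius + 2) + 1)
    zz, yy, xx = np.meshgrid(rng, rng, rng, indexing="ij")
    keep = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= radius**2
    return np.argwhere(keep)
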