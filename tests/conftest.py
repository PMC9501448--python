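"""Shared fixtures: small, fast digital phantoms with full ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from natendon.datamodel import LabelMap, Role, StudyConfig
from natendon.phantom import (
    Phantom,
    PhantomSpec,
    default_compartments,
    regional_tendon_compartments,
)

SMALL_FOV = (64.0, 64.0, 120.0)


def small_spec(**kw) -> PhantomSpec:
    """Study-like phantom on a reduced field of view (fast to render).

    Geometry is the default layout scaled into a 64 x 64 x 120 mm box; the
    tendon tube and its segment boundaries stay aligned with the coarse grid.
    """
    comp_kw = {}
    for key in ("tendon_concentration_mM", "tendon_relaxation", "include_skin"):
        if key in kw:
            comp_kw[key] = kw.pop(key)
    regional = kw.pop("regional", False)
    if "compartments" not in kw:
        kw["compartments"] = (
            regional_tendon_compartments(fov_mm=SMALL_FOV, **comp_kw)
            if regional
            else default_compartments(fov_mm=SMALL_FOV, **comp_kw)
        )
    kw.setdefault("fov_mm", SMALL_FOV)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def noise_free_phantom() -> Phantom:
    """Rasterized noise-free small phantom (uniform sensitivity)."""
    return Phantom(small_spec(), StudyConfig())


@pytest.fixture(scope="session")
def snr_phantom() -> Phantom:
    """Small phantom with the noise level set from a whole-tendon SNR of 11.7."""
    return Phantom(small_spec(target_snr=11.7), StudyConfig())


def tube_mask(
    shape=(20, 20, 100),
    voxel_mm=1.0,
    center=(10.0, 10.0),
    radius=6.0,
    z_first=2,
    z_last=96,
    code=Role.TENDON,
) -> LabelMap:
    """Simple single-code tendon tube on its own grid."""
    nx, ny, nz = shape
    x = (np.arange(nx) + 0.5)[:, None, None] * voxel_mm
    y = (np.arange(ny) + 0.5)[None, :, None] * voxel_mm
    z = np.arange(nz)[None, None, :]
    inside = (
        ((x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius**2)
        & (z >= z_first)
        & (z <= z_last)
    )
    labels = np.where(inside, int(code), 0).astype(np.int32)
    return LabelMap(labels, np.full(3, float(voxel_mm)), np.zeros(3), {int(code): Role(code).name})
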