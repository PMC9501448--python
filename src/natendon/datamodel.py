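"""Core data containers for the sodium-MRI tendon pipeline.

Conventions used throughout the package:

* 0-based voxel indices; the world position of a voxel is
  ``origin_mm + index * voxel_size_mm`` and its centre is offset by half a
  voxel.  Axis 2 is the slice axis and runs along the tendon's long axis,
  increasing from the calcaneal insertion (distal) towards proximal.
* Signal is in arbitrary units (a.u.), concentrations in mM, lengths in mm
  and times in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Nucleus",
    "Role",
    "Volume3D",
    "LabelMap",
    "RelaxationParams",
    "StudyConfig",
    "TENDON_RELAXATION",
    "PHANTOM_RELAXATION",
    "same_grid",
]


class Nucleus(str, Enum):
    """Imaged nucleus of a volume."""

    H1 = "1H"
    NA23 = "23Na"


class Role(IntEnum):
    """Integer label codes of the region maps.

    INS/MID/MTJ are the three 3-cm tendon segments (insertion, mid-portion,
    myotendinous junction) counted from the calcaneal end.  TENDON marks the
    undivided tendon mask before segmentation.  VIAL_* are the agarose
    reference phantoms, NOISE the signal-free region used as noise reference.
    """

    BACKGROUND = 0
    INS = 1
    MID = 2
    MTJ = 3
    SKIN = 4
    TENDON = 5
    VIAL_50 = 10
    VIAL_75 = 11
    VIAL_100 = 12
    VIAL_125 = 13
    NOISE = 99


#: The three tendon segments in distal -> proximal order.
SEGMENT_ROLES = (Role.INS, Role.MID, Role.MTJ)
#: Reference vial codes in ascending concentration order.
VIAL_ROLES = (Role.VIAL_50, Role.VIAL_75, Role.VIAL_100, Role.VIAL_125)


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3:
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    return v


def same_grid(a, b, tol_mm: float = 1e-6) -> bool:
    """True when two volumes/label maps share shape, voxel size and origin."""
    return (
        a.shape == b.shape
        and np.allclose(a.voxel_size_mm, b.voxel_size_mm, atol=tol_mm)
        and np.allclose(a.origin_mm, b.origin_mm, atol=tol_mm)
    )


@dataclass
class Volume3D:
    """A 3-D scalar image with grid geometry and acquisition timing.

    Parameters
    ----------
    data:
        3-D array of signal values (a.u.).  Must be finite.
    voxel_size_mm, origin_mm:
        Grid geometry; all voxel sizes strictly positive.
    nucleus:
        Imaged nucleus.
    tr_ms, te_ms:
        Repetition / echo time of the acquisition, when applicable.
    """

    data: np.ndarray
    voxel_size_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    nucleus: Nucleus = Nucleus.NA23
    tr_ms: float | None = None
    te_ms: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 + 1:
            raise ValueError(f"not a 3-D volume: data has {self.data.ndim} dimensions")
        if min(self.data.shape) < 1:
            raise ValueError("volume must have at least one voxel per axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.voxel_size_mm = _as_vec3(self.voxel_size_mm, "voxel_size_mm")
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel sizes must be positive")
        self.origin_mm = _as_vec3(self.origin_mm, "origin_mm")
        self.nucleus = Nucleus(self.nucleus)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy_with(self, data: np.ndarray, **meta) -> "Volume3D":
        """New volume on the same grid with replaced data (and metadata)."""
        kw = dict(
            voxel_size_mm=self.voxel_size_mm.copy(),
            origin_mm=self.origin_mm.copy(),
            nucleus=self.nucleus,
            tr_ms=self.tr_ms,
            te_ms=self.te_ms,
        )
        kw.update(meta)
        return Volume3D(np.asarray(data, dtype=float), **kw)


@dataclass
class LabelMap:
    """Integer region map on a named grid.

    Every nonzero code present in ``labels`` must appear in ``legend``,
    mapping the code to its :class:`Role` name.
    """

    labels: np.ndarray
    voxel_size_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    legend: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"not a 3-D label map: {labels.ndim} dimensions")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(labels == np.round(labels)):
                raise ValueError("label map contains non-integer values")
            labels = labels.astype(np.int32)
        self.labels = labels
        self.voxel_size_mm = _as_vec3(self.voxel_size_mm, "voxel_size_mm")
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel sizes must be positive")
        self.origin_mm = _as_vec3(self.origin_mm, "origin_mm")
        self.legend = {int(k): str(v) for k, v in dict(self.legend).items()}
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"label codes without legend entry: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, code: int) -> np.ndarray:
        """Boolean mask of one label code."""
        code = int(code)
        if code != 0 and code not in self.legend:
            raise KeyError(f"label code {code} not present in legend")
        return self.labels == code

    def count(self, code: int) -> int:
        return int(self.mask(code).sum())


@dataclass(frozen=True)
class RelaxationParams:
    """The sodium relaxation quadruple (T1, T2s*, T2l*, ps) of a compartment.

    ``ps`` is the amplitude fraction of the short transverse component;
    for a single pool of spin-3/2 nuclei it is theoretically 3/5 (the two
    satellite transitions of the 3:4:3 multiplet relax fast).
    """

    t1_ms: float
    t2s_ms: float
    t2l_ms: float
    ps: float

    def __post_init__(self):
        if not (self.t1_ms > 0 and self.t2s_ms > 0 and self.t2l_ms > 0):
            raise ValueError("relaxation times must be positive")
        if self.t2s_ms > self.t2l_ms:
            raise ValueError("t2s_ms must not exceed t2l_ms")
        if not 0 < self.ps < 1:
            raise ValueError("ps must lie strictly in (0, 1)")


#: Whole-tendon in-vivo reference relaxation values at 3 T (ROI-mean fits
#: pooled over healthy controls), used as the generator/tissue default.
TENDON_RELAXATION: Mapping[str, RelaxationParams] = {
    "INS": RelaxationParams(18.4, 1.4, 14.5, 0.304),
    "MID": RelaxationParams(19.2, 1.4, 14.2, 0.326),
    "MTJ": RelaxationParams(23.3, 1.5, 14.6, 0.318),
    "Total": RelaxationParams(20.4, 1.4, 13.9, 0.316),
}

#: Mean relaxation of the 4% agarose reference vials pooled over
#: concentrations, used for the relaxation-weighting correction.
PHANTOM_RELAXATION = RelaxationParams(38.5, 6.0, 13.0, 0.602)


def _strictly_increasing(xs: Sequence[float]) -> bool:
    return all(b > a for a, b in zip(xs, xs[1:]))


@dataclass
class StudyConfig:
    """Acquisition protocol of a study.

    Defaults reproduce the surface-coil protocol of the study this package
    models: five saturation-recovery TRs, twelve echo times acquired as three
    interleaved four-echo trains at TR = 30 ms, one concentration-weighted
    acquisition at TR = 15 / TE = 0.1 ms, a four-echo proton scan, and four
    reference vials at 50-125 mM.
    """

    tr_list_ms: tuple = (8.0, 9.0, 10.0, 15.0, 25.0)
    te_list_ms: tuple = (0.1, 1.5, 3.0, 6.2, 7.6, 9.1, 12.3, 13.7, 15.2, 18.4, 19.8, 21.3)
    t2star_tr_ms: float = 30.0
    t1_te_ms: float = 0.1
    quant_tr_ms: float = 15.0
    quant_te_ms: float = 0.1
    h1_te_list_ms: tuple = (0.1, 3.0, 6.0, 9.0)
    h1_tr_ms: float = 12.0
    sensitivity_tr_ms: float = 15.0
    sensitivity_te_ms: float = 0.3
    vial_concentrations_mM: tuple = (50.0, 75.0, 100.0, 125.0)
    segment_length_mm: float = 30.0

    def __post_init__(self):
        self.tr_list_ms = tuple(float(x) for x in self.tr_list_ms)
        self.te_list_ms = tuple(float(x) for x in self.te_list_ms)
        self.h1_te_list_ms = tuple(float(x) for x in self.h1_te_list_ms)
        self.vial_concentrations_mM = tuple(float(x) for x in self.vial_concentrations_mM)
        for name in ("tr_list_ms", "te_list_ms", "h1_te_list_ms"):
            if not _strictly_increasing(getattr(self, name)):
                raise ValueError(f"{name} must be strictly increasing")
        if not _strictly_increasing(self.vial_concentrations_mM):
            raise ValueError("vial concentrations must be strictly increasing")
        if min(self.vial_concentrations_mM) <= 0:
            raise ValueError("vial concentrations must be positive")
        if self.segment_length_mm <= 0:
            raise ValueError("segment_length_mm must be positive")
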