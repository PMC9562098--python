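"""Volumetric OCT containers, I/O, projections, and axial-scale conversions.

A swept-source OCT volume is a stack of B-scans: the array is indexed
``(slow, axial, fast)``, where *slow* selects a B-scan, *axial* runs down an
A-scan (row 0 is the vitreous side, i.e. the top of a displayed B-scan), and
*fast* indexes A-scans within a B-scan. Volumes are stored on disk as
multi-page TIFF stacks (one page per B-scan) with a JSON metadata sidecar
carrying the pixel spacing and exam identity.

The axial pixel spacing of a swept-source engine is set by its imaging range:
a range quoted in air divides by the group refractive index of tissue to give
the in-tissue depth range, which divided by the number of axial samples gives
micrometres per pixel. For the device emulated here, 6 mm in air at a group
index of 1.333 gives 4.5 mm in tissue, i.e. 4.4 um per pixel over 1024
samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

#: Group refractive index of retinal tissue used for air-to-tissue depth
#: conversion when none is given.
DEFAULT_GROUP_INDEX = 1.333


@dataclass
class OCTVolume:
    """A 3-D OCT intensity volume with physical spacing and exam identity.

    Parameters
    ----------
    intensities
        Non-negative array of shape ``(n_slow, n_axial, n_fast)`` in linear
        intensity scale.
    axial_pixel_um
        Axial sampling in micrometres per pixel.
    lateral_pixel_um
        Lateral (en face) sampling in micrometres per pixel, assumed
        isotropic in fast and slow.
    metadata
        Free-form exam identity: ``patient_id``, ``eye``, ``session_id``,
        ``fov`` ("105" or "140"), ``seed`` ...
    """

    intensities: np.ndarray
    axial_pixel_um: float
    lateral_pixel_um: float = 15.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float32)
        if arr.ndim != 3:
            raise ValueError(f"volume must be 3-D (slow, axial, fast); got shape {arr.shape}")
        if min(arr.shape) < 1:
            raise ValueError(f"all volume dimensions must be >= 1; got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume intensities must be finite")
        if arr.min() < 0:
            raise ValueError("volume intensities must be non-negative")
        if not self.axial_pixel_um > 0:
            raise ValueError(f"axial_pixel_um must be > 0; got {self.axial_pixel_um}")
        if not self.lateral_pixel_um > 0:
            raise ValueError(f"lateral_pixel_um must be > 0; got {self.lateral_pixel_um}")
        self.intensities = arr

    @property
    def n_slow(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_axial(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_fast(self) -> int:
        return self.intensities.shape[2]

    @property
    def enface_shape(self) -> tuple[int, int]:
        """(slow, fast) shape of any en face projection of this volume."""
        return (self.n_slow, self.n_fast)


@dataclass
class EnFaceImage:
    """A 2-D fundus-like view formed by projecting a volume along depth."""

    pixels: np.ndarray  # (slow, fast)
    projection_kind: str  # "mean" | "max"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("en face image must be 2-D")
        if self.projection_kind not in ("mean", "max"):
            raise ValueError(f"unknown projection kind {self.projection_kind!r}")


# ---------------------------------------------------------------------------
# axial-scale conversions
# ---------------------------------------------------------------------------

def air_to_tissue_depth(range_mm_air: float, group_index: float = DEFAULT_GROUP_INDEX) -> float:
    """Convert an imaging depth range quoted in air to its in-tissue range.

    Optical path length scales with the group refractive index, so a range of
    ``range_mm_air`` millimetres in air spans ``range_mm_air / group_index``
    millimetres inside tissue.
    """
    if not range_mm_air > 0:
        raise ValueError(f"range_mm_air must be > 0; got {range_mm_air}")
    if not group_index > 0:
        raise ValueError(f"group_index must be > 0; got {group_index}")
    return range_mm_air / group_index


def axial_pixel_size_um(range_tissue_mm: float, n_axial: int) -> float:
    """Micrometres per axial pixel given the in-tissue depth range and sample count."""
    if not range_tissue_mm > 0:
        raise ValueError(f"range_tissue_mm must be > 0; got {range_tissue_mm}")
    if not (isinstance(n_axial, (int, np.integer)) and n_axial >= 1):
        raise ValueError(f"n_axial must be a positive integer; got {n_axial}")
    return 1000.0 * range_tissue_mm / n_axial


# ---------------------------------------------------------------------------
# projections and B-scan averaging
# ---------------------------------------------------------------------------

def enface_projection(volume: OCTVolume, kind: str = "mean") -> EnFaceImage:
    """Project a volume along the axial axis into an en face image.

    ``kind="mean"`` averages each A-scan; ``kind="max"`` takes its brightest
    voxel. Projection is over the full depth of the volume.
    """
    if kind == "mean":
        pixels = volume.intensities.mean(axis=1)
    elif kind == "max":
        pixels = volume.intensities.max(axis=1)
    else:
        raise ValueError(f"unknown projection kind {kind!r}; expected 'mean' or 'max'")
    return EnFaceImage(pixels=pixels, projection_kind=kind)


def average_adjacent_bscans(volume: OCTVolume, k: int) -> OCTVolume:
    """Replace each B-scan by the mean of its k nearest slow-axis neighbours.

    The window is truncated at the volume edges (no reflection or padding), so
    boundary scans average fewer neighbours. ``k=1`` is the identity.
    Registration prior to averaging is not performed; phantom volumes are
    already aligned.
    """
    if not isinstance(k, (int, np.integer)):
        raise ValueError(f"k must be an integer; got {k!r}")
    if k % 2 == 0:
        raise ValueError(f"k must be odd; got {k}")
    if not 1 <= k <= volume.n_slow:
        raise ValueError(f"k must be in [1, n_slow={volume.n_slow}]; got {k}")
    if k == 1:
        return OCTVolume(
            intensities=volume.intensities.copy(),
            axial_pixel_um=volume.axial_pixel_um,
            lateral_pixel_um=volume.lateral_pixel_um,
            metadata=dict(volume.metadata),
        )
    half = k // 2
    arr = volume.intensities
    # cumulative sum along slow axis -> truncated-window mean with true counts
    csum = np.cumsum(arr, axis=0, dtype=np.float64)
    csum = np.concatenate([np.zeros_like(csum[:1]), csum], axis=0)
    n = volume.n_slow
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    sums = csum[hi] - csum[lo]
    counts = (hi - lo).astype(np.float64)[:, None, None]
    out = (sums / counts).astype(np.float32)
    return OCTVolume(
        intensities=out,
        axial_pixel_um=volume.axial_pixel_um,
        lateral_pixel_um=volume.lateral_pixel_um,
        metadata=dict(volume.metadata),
    )


def rescale_contrast(image: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0) -> np.ndarray:
    """Percentile contrast stretch to [0, 1] for display. Never feeds measurement."""
    arr = np.asarray(image, dtype=np.float64)
    lo, hi = np.percentile(arr, [low_pct, high_pct])
    if hi <= lo:
        return np.zeros_like(arr)
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0)


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF + JSON sidecar
# ---------------------------------------------------------------------------

_SIDECAR_REQUIRED = ("axial_pixel_um", "lateral_pixel_um", "n_slow", "n_axial", "n_fast")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_volume(volume: OCTVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF (one page per B-scan) plus JSON sidecar.

    Returns the sidecar path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.intensities, photometric="minisblack")  # pages along slow axis
    sidecar = {
        "axial_pixel_um": volume.axial_pixel_um,
        "lateral_pixel_um": volume.lateral_pixel_um,
        "n_slow": volume.n_slow,
        "n_axial": volume.n_axial,
        "n_fast": volume.n_fast,
        "metadata": volume.metadata,
    }
    sc_path = _sidecar_path(path)
    sc_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return sc_path


def read_volume(path: str | Path) -> OCTVolume:
    """Read a TIFF-stack volume and its JSON sidecar, validating consistency."""
    path = Path(path)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sc_path} for volume {path}")
    sidecar = json.loads(sc_path.read_text())
    for key in _SIDECAR_REQUIRED:
        if key not in sidecar:
            raise ValueError(f"sidecar {sc_path} missing required field {key!r}")
    if not sidecar["axial_pixel_um"] > 0 or not sidecar["lateral_pixel_um"] > 0:
        raise ValueError(f"sidecar {sc_path} declares non-positive pixel spacing")
    arr = tifffile.imread(path)
    if arr.ndim == 2:  # single-page stack
        arr = arr[None, ...]
    declared = (sidecar["n_slow"], sidecar["n_axial"], sidecar["n_fast"])
    if tuple(arr.shape) != declared:
        raise ValueError(
            f"stack shape {tuple(arr.shape)} does not match sidecar-declared {declared}"
        )
    return OCTVolume(
        intensities=arr,
        axial_pixel_um=float(sidecar["axial_pixel_um"]),
        lateral_pixel_um=float(sidecar["lateral_pixel_um"]),
        metadata=dict(sidecar.get("metadata", {})),
    )
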