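"""First-order descriptors of 3-D intensity volumes.

Structural MR volumes (typically ~256 x 256 x 170 voxels) are summarised
into one feature row per scan so that tabular rule extraction can run on
imaging studies.  The descriptor set, computed on a Gaussian-smoothed copy
of the volume:

* global sum, mean and maximum of all voxel values;
* sum, mean and maximum of the middle slice along each of the three axes
  (middle index = ``floor(dim / 2)``);
* the most frequent intensity from a histogram, with the background value
  0 optionally excluded;
* ``max_slab_sum`` — collapse the two inner axes by summation to one value
  per outer-axis index, then take the maximum over those slab sums;
* per-tissue sums over an integer label volume (1 = CSF, 2 = gray matter,
  3 = white matter), plus each tissue's masked ``max_slab_sum``.

Tissue segmentation itself is out of scope; a precomputed label volume
(e.g. from a Markov-random-field segmenter) is accepted as input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Volume",
    "load_volume",
    "smooth",
    "first_order",
    "histogram_mode",
    "max_slab_sum",
    "tissue_sums",
    "volume_features",
    "TISSUE_LABELS",
]

TISSUE_LABELS = {1: "csf", 2: "gray_matter", 3: "white_matter"}


@dataclass(frozen=True)
class Volume:
    """A 3-D intensity array with optional voxel-size metadata (mm)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] | None = None

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError(f"volume must be 3-D with positive extents, got shape {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValueError("volume contains non-finite voxel values")
        object.__setattr__(self, "data", arr)


def _as_array(volume) -> np.ndarray:
    arr = volume.data if isinstance(volume, Volume) else np.asarray(volume, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {arr.shape}")
    return arr


def load_volume(path) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or .npy volume from disk."""
    p = str(path)
    if p.endswith(".npy"):
        return Volume(np.load(p))
    import nibabel as nib

    img = nib.load(p)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(img.get_fdata(), dtype=float), zooms)


def smooth(volume, sigma: float = 1.0) -> np.ndarray:
    """Gaussian-filter the volume along its three axes; ``sigma`` is in
    voxels and 0 is the identity.

    Boundaries are handled by reflection and the kernel is truncated at 4
    standard deviations (and renormalised), so a constant volume passes
    through unchanged and an interior impulse conserves its mass.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    arr = _as_array(volume)
    if sigma == 0:
        return arr.copy()
    return gaussian_filter(arr, sigma=sigma, mode="reflect")


def first_order(volume) -> dict[str, float]:
    """The 12 first-order descriptors: global {sum, mean, max} and, per
    axis, the middle slice's {sum, mean, max}."""
    arr = _as_array(volume)
    feats = {"sum": float(arr.sum()), "mean": float(arr.mean()), "max": float(arr.max())}
    for axis in range(3):
        mid = arr.shape[axis] // 2
        sl = np.take(arr, mid, axis=axis)
        feats[f"mid{axis}_sum"] = float(sl.sum())
        feats[f"mid{axis}_mean"] = float(sl.mean())
        feats[f"mid{axis}_max"] = float(sl.max())
    return feats


def histogram_mode(volume, exclude_background: bool = True, bins: int = 256) -> float:
    """Most frequent discretised intensity.

    Intensities are binned into ``bins`` equal-width bins over the range of
    the considered voxels and the center of the fullest bin is returned
    (ties: the lowest bin).  With ``exclude_background`` the value 0 —
    image background — is left out of the histogram.
    """
    arr = _as_array(volume).ravel()
    if exclude_background:
        arr = arr[arr != 0]
        if arr.size == 0:
            raise ValueError("volume has no nonzero voxels; cannot exclude background")
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(arr, bins=bins, range=(lo, hi))
    i = int(np.argmax(counts))
    return float((edges[i] + edges[i + 1]) / 2)


def max_slab_sum(volume, axis: int = 0) -> float:
    """Collapse the two other axes by summation, then take the maximum of
    the resulting per-slab sums."""
    arr = _as_array(volume)
    other = tuple(a for a in range(3) if a != axis)
    return float(arr.sum(axis=other).max())


def tissue_sums(volume, labels, axis: int = 0) -> dict[str, float]:
    """Per-tissue intensity sums and masked slab maxima.

    ``labels`` is an integer volume of the same shape: 0 background, 1-3
    the tissue classes.  For each tissue the total of its voxel values and
    the :func:`max_slab_sum` of the tissue-masked volume are returned.
    """
    arr = _as_array(volume)
    lab = np.asarray(labels)
    if lab.shape != arr.shape:
        raise ValueError(f"label volume shape {lab.shape} != intensity shape {arr.shape}")
    feats: dict[str, float] = {}
    for value, name in TISSUE_LABELS.items():
        masked = np.where(lab == value, arr, 0.0)
        feats[f"{name}_sum"] = float(masked.sum())
        feats[f"{name}_max_slab_sum"] = max_slab_sum(masked, axis=axis)
    return feats


def volume_features(volume, sigma: float = 1.0, labels=None, axis: int = 0,
                    bins: int = 256) -> dict[str, float]:
    """One feature row per volume: smooth, then first-order + histogram
    mode + slab maximum (+ per-tissue descriptors when a label volume is
    supplied).  All descriptors are computed on the smoothed volume."""
    sm = smooth(volume, sigma)
    feats = first_order(sm)
    feats["histogram_mode"] = histogram_mode(sm, exclude_background=True, bins=bins)
    feats["max_slab_sum"] = max_slab_sum(sm, axis=axis)
    if labels is not None:
        feats.update(tissue_sums(sm, labels, axis=axis))
    return feats
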