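"""Nucleus segmentation, volumetry, and distance–volume statistics.

The chromatin-marker channel is smoothed, thresholded with Otsu's method,
hole-filled, and reduced to its largest connected component; the nuclear
volume is the voxel count times the voxel volume. Nuclei whose mask leans
on the stack border beyond a tolerated fraction are flagged clipped and
excluded from volume statistics. Volumes are related to inter-allelic
distances by Pearson correlation and compared between conditions by
Welch's t-test (Mann-Whitney optional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import label

from .stack import NUCLEUS, ImageStack


class SegmentationError(RuntimeError):
    """No nucleus-like foreground found in the stack."""


@dataclass
class NucleusMeasurement:
    """Volume and position of one segmented nucleus, plus condition metadata."""

    nucleus_id: str
    volume_um3: float
    centroid_um: tuple[float, ...]
    clipped: bool = False
    zone: str = ""
    dose_gy: float = 0.0
    time_h: float = 0.0
    genotype: str = ""
    distance_um: float = float("nan")
    paired: bool | None = None

    def __post_init__(self) -> None:
        if self.volume_um3 <= 0:
            raise ValueError("volume must be positive")


def segment_nucleus(
    stack: ImageStack,
    smooth_sigma_um: float = 0.2,
    border_tolerance: float = 0.02,
    nucleus_id: str = "nucleus",
) -> tuple[np.ndarray, NucleusMeasurement]:
    """Segment the single nucleus in the chromatin channel.

    Pipeline: Gaussian smoothing (``smooth_sigma_um`` converted to voxel
    units per axis), Otsu threshold, fill holes, keep the largest
    connected component. The measurement is flagged ``clipped`` when more
    than ``border_tolerance`` of the mask voxels lie on the stack border.

    Raises :class:`SegmentationError` on background-only stacks (no
    bimodal structure: Otsu splits noise and the "foreground" is either
    empty or most of the field).
    """
    volume = stack.channel(NUCLEUS)
    if volume.ndim != 3:
        raise ValueError("segment_nucleus needs a 3D stack")
    voxel = np.asarray(stack.voxel_size)
    sigma_vox = smooth_sigma_um / voxel
    smoothed = ndimage.gaussian_filter(volume.astype(float), sigma=sigma_vox)

    spread = smoothed.max() - smoothed.min()
    if spread <= 0:
        raise SegmentationError("constant image: nothing to segment")
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    frac = mask.mean()
    if frac == 0 or frac > 0.9:
        raise SegmentationError("no nucleus-like foreground (threshold degenerate)")
    # reject pure-noise splits: foreground must stand clear of background
    fg, bg = smoothed[mask], smoothed[~mask]
    if fg.mean() - bg.mean() < 3.0 * bg.std():
        raise SegmentationError("foreground not separable from background noise")

    mask = ndimage.binary_fill_holes(mask)
    labels = label(mask)
    if labels.max() == 0:
        raise SegmentationError("empty mask")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest

    border = np.zeros_like(mask)
    for ax in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[ax] = edge
            border[tuple(sl)] = True
    clipped = float(np.sum(mask & border)) / float(np.sum(mask)) > border_tolerance

    voxel_volume = float(np.prod(voxel))
    n_vox = int(np.sum(mask))
    centroid_vox = np.array(ndimage.center_of_mass(mask))
    measurement = NucleusMeasurement(
        nucleus_id=nucleus_id,
        volume_um3=n_vox * voxel_volume,
        centroid_um=tuple(float(c) for c in centroid_vox * voxel),
        clipped=clipped,
    )
    return mask, measurement


def correlate_distance_volume(measurements: list[NucleusMeasurement]) -> dict:
    """Pearson correlation between inter-allelic distance and nuclear volume.

    Only measurements carrying a non-paired, finite distance enter the
    sample. Raises on n < 3 or zero variance in either variable.
    """
    rows = [
        m for m in measurements
        if np.isfinite(m.distance_um) and not m.paired and not m.clipped
    ]
    if len(rows) < 3:
        raise ValueError("need at least 3 nuclei with measurable distances")
    d = np.array([m.distance_um for m in rows])
    v = np.array([m.volume_um3 for m in rows])
    if d.std() == 0 or v.std() == 0:
        raise ValueError("zero variance in distance or volume")
    r, p = stats.pearsonr(d, v)
    return {"r": float(r), "p": float(p), "n": len(rows)}


def compare_volumes(
    groups: dict[str, np.ndarray], test: str = "welch"
) -> dict:
    """Two-sided two-sample test of volumes between two conditions.

    ``test`` is ``"welch"`` (unequal-variance t-test, default) or
    ``"mannwhitney"``. Two identical constant groups are degenerate and
    reported with p = 1 by convention.
    """
    if len(groups) != 2:
        raise ValueError("compare_volumes expects exactly two groups")
    (name_a, a), (name_b, b) = [(k, np.asarray(v, dtype=float)) for k, v in groups.items()]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        stat, p = 0.0, 1.0
    elif test == "welch":
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mannwhitney":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "test": test,
        "statistic": float(stat),
        "p": float(p),
        "groups": {name_a: {"n": int(a.size), "mean": float(a.mean())},
                   name_b: {"n": int(b.size), "mean": float(b.mean())}},
    }
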