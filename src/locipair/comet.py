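"""Neutral comet-assay quantification: tail DNA %, tail length, Olive moment.

A comet image shows a bright head (undamaged DNA) and, when double-strand
breaks are present, a tail of fragmented DNA that migrated along the
electrophoresis axis (+x by convention; rotate real images accordingly).
The image is background-subtracted with a rolling-percentile filter,
thresholded at ``k`` robust SDs (MAD) above zero, the head is fit as a
disc around the intensity mode, and everything beyond the head edge along
+x is tail. Reported per comet:

* tail DNA % = 100 x tail intensity / (head + tail intensity)
* tail length = distance along the migration axis from the head centre to
  the farthest above-threshold tail pixel (px, and μm when the pixel size
  is known)
* Olive tail moment = tail DNA % x head-to-tail centroid distance (percent px)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .stack import ImageStack


class CometSegmentationError(RuntimeError):
    """No comet signal above background."""


@dataclass
class CometMeasurement:
    head_center_px: tuple[float, float]
    head_radius_px: float
    tail_length_px: float
    tail_length_um: float | None
    tail_dna_percent: float
    olive_tail_moment: float
    condition: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.tail_dna_percent <= 100:
            raise ValueError("tail DNA percent must be in [0, 100]")
        if self.olive_tail_moment < 0 or self.tail_length_px < 0:
            raise ValueError("tail moment and length must be >= 0")


def _comet_plane(image: ImageStack | np.ndarray) -> tuple[np.ndarray, float | None]:
    if isinstance(image, ImageStack):
        plane = image.data[0]
        if plane.ndim != 2:
            raise ValueError("comet analysis needs a single-channel 2D image")
        return plane.astype(float), float(image.voxel_size[-1])
    plane = np.asarray(image, dtype=float)
    if plane.ndim != 2:
        raise ValueError("comet analysis needs a 2D image")
    return plane, None


def subtract_background(plane: np.ndarray, window_px: int = 51, percentile: float = 10.0) -> np.ndarray:
    """Rolling-percentile background subtraction, clipped at zero.

    The percentile surface is computed on a 4x-subsampled grid and
    bilinearly upsampled; the background varies on scales much larger
    than 4 px, so this changes nothing but the run time.
    """
    sub = 4
    coarse = plane[::sub, ::sub]
    size = max(window_px // sub, 3)
    bg_coarse = ndimage.percentile_filter(coarse, percentile, size=size)
    zoom = (plane.shape[0] / bg_coarse.shape[0], plane.shape[1] / bg_coarse.shape[1])
    bg = ndimage.zoom(bg_coarse, zoom, order=1, grid_mode=True, mode="nearest")
    bg = bg[: plane.shape[0], : plane.shape[1]]
    return np.clip(plane - bg, 0.0, None)


def segment_comet(
    image: ImageStack | np.ndarray,
    threshold_k: float = 3.0,
    background_window_px: int = 51,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a single-comet image into a head mask and a tail mask.

    The threshold is ``threshold_k`` MAD-derived SDs above zero on the
    background-subtracted image. The head is the disc, centred on the
    intensity mode, that covers the bright core (pixels above half the
    peak); the tail is every above-threshold pixel beyond the head edge
    along +x. Raises :class:`CometSegmentationError` when nothing clears
    the threshold.
    """
    plane, _ = _comet_plane(image)
    corrected = subtract_background(plane, background_window_px)
    # normalise so every later cut is relative: tail percentages must not
    # depend on multiplying the image by a positive constant
    if corrected.max() > 0:
        corrected = corrected / corrected.max()
    mad = float(np.median(np.abs(corrected - np.median(corrected))))
    threshold = float(np.median(corrected)) + threshold_k * 1.4826 * mad
    if threshold <= 0:
        # noise-free image: keep the cut relative so tail percentages stay
        # invariant to rescaling the whole image
        threshold = 1e-6 * float(corrected.max())
    signal = corrected > threshold
    # drop isolated noise specks: keep connected regions of >= 8 px
    labels, n_labels = ndimage.label(signal)
    if n_labels:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        signal = sizes[labels] >= 8
    if not np.any(signal) or corrected.max() <= threshold:
        raise CometSegmentationError("no comet signal above background")

    # head: a disc centred on the leftmost substantial local maximum of
    # the x-profile — the head always leads the tail, which migrates
    # along +x, so even a tail brighter than the head cannot capture the
    # mode. The radius is read off the -x side of the head, which the
    # tail never contaminates; the +x half of the disc follows by symmetry.
    xprof = ndimage.gaussian_filter1d(corrected.sum(axis=0), 2.0)
    floor = 0.2 * float(xprof.max())
    is_peak = np.zeros_like(xprof, dtype=bool)
    is_peak[1:-1] = (xprof[1:-1] >= xprof[:-2]) & (xprof[1:-1] >= xprof[2:]) & (
        xprof[1:-1] >= floor
    )
    peak_cols = np.nonzero(is_peak)[0]
    px = int(peak_cols[0]) if peak_cols.size else int(np.argmax(xprof))
    col_band = corrected[:, max(px - 2, 0) : px + 3]
    weights = col_band.sum(axis=1)
    cy = float(np.average(np.arange(plane.shape[0]), weights=weights)) if weights.sum() > 0 else plane.shape[0] / 2.0
    cx = float(px)
    yy, xx = np.nonzero(signal)
    band = (np.abs(yy - cy) <= 2) & (xx <= cx)
    x_left = float(np.min(xx[band])) if np.any(band) else cx - 1.0
    radius = max(cx - x_left, 1.0)
    gy, gx = np.mgrid[0 : plane.shape[0], 0 : plane.shape[1]]
    head_mask = (gy - cy) ** 2 + (gx - cx) ** 2 <= radius**2

    tail_mask = signal & (gx > cx + radius) & ~head_mask
    return head_mask, tail_mask


def tail_metrics(
    image: ImageStack | np.ndarray,
    head_mask: np.ndarray,
    tail_mask: np.ndarray,
    background_window_px: int = 51,
    condition: str = "",
) -> CometMeasurement:
    """Compute tail DNA %, tail length and Olive tail moment from the masks."""
    if np.any(head_mask & tail_mask):
        raise ValueError("head and tail masks must be disjoint")
    plane, pixel_um = _comet_plane(image)
    corrected = subtract_background(plane, background_window_px)
    head_sum = float(corrected[head_mask].sum())
    tail_sum = float(corrected[tail_mask].sum())
    total = head_sum + tail_sum
    if total <= 0:
        raise ValueError("zero total intensity in head + tail")
    tail_percent = 100.0 * tail_sum / total

    gy, gx = np.mgrid[0 : plane.shape[0], 0 : plane.shape[1]]
    w_head = corrected[head_mask]
    cy = float(np.average(gy[head_mask], weights=w_head)) if w_head.sum() > 0 else float(gy[head_mask].mean())
    cx = float(np.average(gx[head_mask], weights=w_head)) if w_head.sum() > 0 else float(gx[head_mask].mean())
    yy, xx = np.nonzero(head_mask)
    radius = float(np.max(np.hypot(yy - cy, xx - cx)))

    if tail_sum > 0 and np.any(tail_mask):
        tx = gx[tail_mask]
        ty = gy[tail_mask]
        w = corrected[tail_mask]
        # length along the migration axis: head centre to farthest tail column
        tail_length = float(np.max(tx) - cx)
        if w.sum() > 0:
            tcx = float(np.average(tx, weights=w))
            tcy = float(np.average(ty, weights=w))
            centroid_sep = float(np.hypot(tcx - cx, tcy - cy))
        else:
            centroid_sep = 0.0
    else:
        tail_length = 0.0
        centroid_sep = 0.0
    olive = tail_percent * centroid_sep

    return CometMeasurement(
        head_center_px=(cy, cx),
        head_radius_px=radius,
        tail_length_px=tail_length,
        tail_length_um=tail_length * pixel_um if pixel_um else None,
        tail_dna_percent=tail_percent,
        olive_tail_moment=olive,
        condition=condition,
    )


def measure_comet(image: ImageStack | np.ndarray, condition: str = "", **kwargs) -> CometMeasurement:
    """Segment and measure one comet in a single call."""
    head, tail = segment_comet(image, **kwargs)
    return tail_metrics(image, head, tail, condition=condition)


def recovery_verdict(induced: bool, residual: bool) -> str:
    """Map the two test outcomes to a verdict string.

    ``induced``: the acute (0 h) group is significantly above control;
    ``residual``: the late (24 h) group is significantly above control.
    """
    if not induced:
        return "no induction"
    return "not recovered" if residual else "recovered"


def dsb_timecourse(
    groups: dict[str, list[CometMeasurement]],
    control_key: str = "control",
    alpha: float = 0.05,
    acute_key: str = "0h",
    late_key: str = "24h",
) -> dict:
    """Per-group tail-DNA summaries with recovery logic against a control.

    Each non-control group is compared with the control group by a
    one-sided Welch t-test (greater). The verdict combines the acute and
    late outcomes via :func:`recovery_verdict`.
    """
    if control_key not in groups:
        raise ValueError(f"missing control group {control_key!r}")
    summaries: dict[str, dict] = {}
    control = np.array([m.tail_dna_percent for m in groups[control_key]])
    for name, measurements in groups.items():
        vals = np.array([m.tail_dna_percent for m in measurements])
        entry = {
            "n": int(vals.size),
            "mean_tail_percent": float(vals.mean()),
            "sd_tail_percent": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        }
        if name != control_key:
            if np.allclose(vals, control.mean()) and np.allclose(control, control.mean()):
                p = 1.0
            else:
                _, p = stats.ttest_ind(vals, control, equal_var=False, alternative="greater")
            entry["p_vs_control"] = float(p)
            entry["significant"] = bool(p < alpha)
        summaries[name] = entry

    verdict = None
    if acute_key in summaries and late_key in summaries:
        verdict = recovery_verdict(
            summaries[acute_key]["significant"], summaries[late_key]["significant"]
        )
    return {"groups": summaries, "alpha": alpha, "verdict": verdict}
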