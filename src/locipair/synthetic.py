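"""Synthetic microscopy data with known ground truth.

Generates the kinds of data the analysis modules consume:

* two-channel 3D stacks of a single root nucleus — channel ``foci`` holds
  two PSF-blurred sub-resolution point sources (the lacO/LacI-EGFP tagged
  homologous loci), channel ``nucleus`` holds a filled ellipsoid (the
  chromatin marker);
* time series of such stacks with a rigid random-walk nucleus drift and a
  constant true separation;
* dose-response panels in which the true inter-allelic separation shortens
  with γ-ray dose and relaxes back over time while the nucleus volume
  stays dose-independent;
* 2D comet-assay images with a controlled tail DNA fraction.

Every generated image travels with a :class:`SyntheticTruth` record
carrying the exact coordinates, separation and volume used, so detection
and measurement code can be scored against ground truth.

Coordinate convention: physical positions are voxel-centre coordinates,
``position_um = index * voxel_size``, axis order (z, y, x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .stack import COMET, FOCI, NUCLEUS, ImageStack


class SeparationInfeasibleError(RuntimeError):
    """Requested inter-allelic separation cannot be placed in the nucleoplasm."""


class DriftOutOfBoundsError(RuntimeError):
    """Nucleus random walk left the stack and enlargement was disabled."""


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleusModel:
    """Geometry and imaging parameters of one nucleus population.

    ``semi_axes_um`` is the nucleus ellipsoid (z, y, x) in μm; the
    nucleolus is a concentric sphere of ``nucleolus_radius_um``. The true
    inter-allelic separation is drawn from a normal distribution truncated
    at zero with the stated mean and SD. ``size_jitter_sd`` is the SD of a
    per-nucleus lognormal scale factor applied to all nuclear lengths;
    the separation mean scales with it, which induces the positive
    distance–volume relationship seen across growing nuclei.
    """

    zone: str = "meristematic"
    semi_axes_um: tuple[float, float, float] = (2.3, 2.3, 2.3)
    nucleolus_radius_um: float = 1.17
    separation_mean_um: float = 3.5
    separation_sd_um: float = 1.0
    focus_amplitude: float = 2000.0  # integrated photons per focus
    background: float = 10.0  # photons per voxel
    psf_sigma_xy_um: float = 0.125
    psf_sigma_z_um: float = 0.3
    voxel_size_um: tuple[float, float, float] = (0.5, 0.1, 0.1)
    nucleus_intensity: float = 100.0  # photons per voxel inside the ellipsoid
    size_jitter_sd: float = 0.12
    read_noise_sd: float = 2.0
    noise: bool = True
    margin_um: float = 1.0

    def __post_init__(self) -> None:
        if min(self.semi_axes_um) <= 0 or self.nucleolus_radius_um <= 0:
            raise ValueError("all lengths must be positive")
        if self.nucleolus_radius_um >= min(self.semi_axes_um):
            raise ValueError("nucleolus must fit strictly inside the nucleus")
        if self.separation_mean_um < 0:
            raise ValueError("separation mean must be >= 0")
        if min(self.voxel_size_um) <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.psf_sigma_xy_um <= 0 or self.psf_sigma_z_um <= 0:
            raise ValueError("PSF sigmas must be positive")

    @property
    def volume_um3(self) -> float:
        """Nominal (unjittered) ellipsoid volume, μm³."""
        a, b, c = self.semi_axes_um
        return 4.0 / 3.0 * math.pi * a * b * c


def meristematic_model(**overrides) -> NucleusModel:
    """Default small-diploid-nucleus population (root meristematic zone)."""
    return replace(NucleusModel(), **overrides) if overrides else NucleusModel()


def elongation_model(**overrides) -> NucleusModel:
    """Default endoreplicated population (root elongation zone): ~4x the
    meristematic volume, longer separations."""
    base = NucleusModel(
        zone="elongation",
        semi_axes_um=(2.9, 3.7, 4.6),
        nucleolus_radius_um=1.8,
        separation_mean_um=4.5,
        separation_sd_um=1.2,
    )
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class DoseResponseModel:
    """Dose- and time-dependence of the true inter-allelic separation.

    The mean separation shortens with γ-ray dose as a saturating
    exponential and relaxes back to baseline exponentially in time:

        mean(D, t) = baseline - amplitude * (1 - exp(-D / D50)) * exp(-t / tau)

    A fraction of nuclei undergo full pairing (separation collapses to ~0)
    with a probability that rises with dose on the same saturation curve
    from a small baseline rate. Set ``shortening_um = 0`` and
    ``pairing_boost = 0`` for repair-deficient phenotypes in which
    irradiation moves neither quantity.
    """

    baseline_um: float = 3.5
    shortening_um: float = 1.2
    half_saturation_gy: float = 50.0
    recovery_tau_h: float = 5.0
    pairing_baseline: float = 0.02
    pairing_boost: float = 0.20

    def __post_init__(self) -> None:
        if self.baseline_um <= 0 or self.half_saturation_gy <= 0 or self.recovery_tau_h <= 0:
            raise ValueError("baseline, half-saturation dose and recovery tau must be positive")
        if self.shortening_um < 0 or self.shortening_um > self.baseline_um:
            raise ValueError("shortening amplitude must be in [0, baseline]")
        if not (0 <= self.pairing_baseline <= 1 and 0 <= self.pairing_boost <= 1):
            raise ValueError("pairing probabilities must be in [0, 1]")

    def _dose_factor(self, dose_gy: float) -> float:
        return 1.0 - math.exp(-dose_gy / self.half_saturation_gy)

    def predicted_mean_um(self, dose_gy: float, time_h: float = 0.0) -> float:
        """Predicted mean separation at a given dose and time post-irradiation."""
        if dose_gy < 0 or time_h < 0:
            raise ValueError("dose and time must be >= 0")
        return self.baseline_um - self.shortening_um * self._dose_factor(dose_gy) * math.exp(
            -time_h / self.recovery_tau_h
        )

    def pairing_probability(self, dose_gy: float, time_h: float = 0.0) -> float:
        """Probability that the two loci are fully paired (one merged dot)."""
        if dose_gy < 0 or time_h < 0:
            raise ValueError("dose and time must be >= 0")
        p = self.pairing_baseline + self.pairing_boost * self._dose_factor(dose_gy) * math.exp(
            -time_h / self.recovery_tau_h
        )
        return min(p, 1.0)


@dataclass(frozen=True)
class CometModel:
    """Single synthetic comet: a bright head disc plus an exponential tail.

    ``tail_length_px`` is measured from the head centre along +x (the
    migration axis); the rendered tail occupies the strip between the head
    edge and that endpoint. ``tail_fraction`` of the total signal is
    placed in the tail, the rest in the head, exactly, before noise.
    """

    shape: tuple[int, int] = (96, 192)
    head_center: tuple[float, float] = (48.0, 48.0)  # (y, x) px
    head_radius_px: float = 12.0
    tail_length_px: float = 90.0
    tail_fraction: float = 0.2
    intensity: float = 200_000.0  # total signal photons
    background: float = 5.0
    noise: bool = True
    read_noise_sd: float = 1.0
    pixel_size_um: float | None = 0.32

    def __post_init__(self) -> None:
        if not 0 <= self.tail_fraction <= 1:
            raise ValueError("tail_fraction must be in [0, 1]")
        if self.head_radius_px <= 0:
            raise ValueError("head radius must be positive")
        if self.tail_length_px <= self.head_radius_px:
            raise ValueError("tail_length_px is measured from the head centre "
                             "and must exceed the head radius")
        cy, cx = self.head_center
        ny, nx = self.shape
        if not (self.head_radius_px <= cy <= ny - self.head_radius_px):
            raise ValueError("head does not fit in the image vertically")
        if not (self.head_radius_px <= cx and cx + self.tail_length_px < nx):
            raise ValueError("head plus tail does not fit in the image horizontally")


@dataclass
class SyntheticTruth:
    """Ground truth for one generated image."""

    coordinates_um: np.ndarray  # (2, 3) focus positions, stack frame (z, y, x)
    separation_um: float
    volume_um3: float
    zone: str
    dose_gy: float = 0.0
    time_h: float = 0.0
    genotype: str = "wild-type"
    nucleus_center_um: np.ndarray | None = None
    semi_axes_um: tuple[float, float, float] | None = None
    nucleolus_radius_um: float | None = None
    paired: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates_um = np.asarray(self.coordinates_um, dtype=float)
        if self.coordinates_um.shape != (2, 3):
            raise ValueError("coordinates must have shape (2, 3)")
        d = float(np.linalg.norm(self.coordinates_um[0] - self.coordinates_um[1]))
        if not math.isclose(d, self.separation_um, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("separation must equal the distance between the coordinates")
        if not (self.zone and self.genotype):
            raise ValueError("metadata fields must be non-empty")

    def to_dict(self) -> dict:
        return {
            "coordinates_um": self.coordinates_um.tolist(),
            "separation_um": self.separation_um,
            "volume_um3": self.volume_um3,
            "zone": self.zone,
            "dose_gy": self.dose_gy,
            "time_h": self.time_h,
            "genotype": self.genotype,
            "paired": self.paired,
        }


# ---------------------------------------------------------------------------
# Geometry sampling
# ---------------------------------------------------------------------------

def _in_nucleoplasm(points: np.ndarray, semi_axes: np.ndarray, nucleolus_r: float) -> np.ndarray:
    """Points (n, 3) relative to the nucleus centre: inside ellipsoid, outside nucleolus."""
    inside = np.sum((points / semi_axes) ** 2, axis=1) <= 1.0
    outside_nucleolus = np.linalg.norm(points, axis=1) > nucleolus_r
    return inside & outside_nucleolus


def sample_pair_coordinates(
    semi_axes_um: Sequence[float],
    nucleolus_radius_um: float,
    separation_um: float,
    rng: np.random.Generator,
    max_attempts: int = 20000,
) -> np.ndarray:
    """Place two points the given distance apart, both in the nucleoplasm.

    Rejection sampling: the first point is uniform in the nucleoplasm, the
    second sits at the requested separation in a uniform random direction;
    the pair is accepted when the second point also lands in the
    nucleoplasm. Coordinates are relative to the nucleus centre, (z, y, x).
    """
    semi_axes = np.asarray(semi_axes_um, dtype=float)
    batch = 256
    attempts = 0
    while attempts < max_attempts:
        attempts += batch
        # uniform in the ellipsoid via uniform ball + anisotropic scaling
        raw = rng.normal(size=(batch, 3))
        raw /= np.linalg.norm(raw, axis=1, keepdims=True)
        radius = np.cbrt(rng.random(batch))
        p1 = raw * radius[:, None] * semi_axes
        ok1 = np.linalg.norm(p1, axis=1) > nucleolus_radius_um
        direction = rng.normal(size=(batch, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        p2 = p1 + separation_um * direction
        ok = ok1 & _in_nucleoplasm(p2, semi_axes, nucleolus_radius_um)
        if np.any(ok):
            i = int(np.argmax(ok))
            return np.stack([p1[i], p2[i]])
    raise SeparationInfeasibleError(
        f"could not place a pair at separation {separation_um:.3g} μm inside the "
        f"nucleoplasm (semi-axes {tuple(semi_axes)}, nucleolus {nucleolus_radius_um}) "
        f"after {max_attempts} attempts"
    )


def draw_separation(
    mean_um: float, sd_um: float, rng: np.random.Generator, max_um: float | None = None
) -> float:
    """Draw a true separation from a normal truncated to [0, max_um]."""
    for _ in range(10000):
        s = rng.normal(mean_um, sd_um) if sd_um > 0 else mean_um
        if s >= 0 and (max_um is None or s <= max_um):
            return float(s)
    raise SeparationInfeasibleError("truncated-normal separation draw failed")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _axis_coords(n: int, voxel: float) -> np.ndarray:
    return np.arange(n) * voxel


def _render_foci(
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
    positions_um: np.ndarray,
    amplitudes: Sequence[float],
    sigma_um: tuple[float, float, float],
) -> np.ndarray:
    """Sum of integrated-Gaussian point sources sampled at voxel centres.

    Each source contributes ``A * prod_ax N(c_ax; p_ax, sigma_ax) * voxel_ax``
    so its voxel sum approximates the integrated amplitude ``A``.
    """
    img = np.zeros(shape, dtype=float)
    for pos, amp in zip(positions_um, amplitudes):
        factors = []
        for ax in range(3):
            c = _axis_coords(shape[ax], voxel[ax])
            s = sigma_um[ax]
            g = np.exp(-0.5 * ((c - pos[ax]) / s) ** 2) / (s * math.sqrt(2 * math.pi))
            factors.append(g * voxel[ax])
        img += amp * np.einsum("i,j,k->ijk", *factors)
    return img


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
    center_um: np.ndarray,
    semi_axes_um: np.ndarray,
) -> np.ndarray:
    grids = np.meshgrid(
        *[( _axis_coords(n, v) - c) / a
          for n, v, c, a in zip(shape, voxel, center_um, semi_axes_um)],
        indexing="ij",
    )
    return grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2 <= 1.0


def _apply_noise(clean: np.ndarray, read_noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    noisy = rng.poisson(clean).astype(float)
    if read_noise_sd > 0:
        noisy += rng.normal(0.0, read_noise_sd, size=clean.shape)
    return np.clip(noisy, 0.0, None)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_nucleus_stack(
    model: NucleusModel,
    separation_override: float | None = None,
    seed: int | np.random.Generator | None = None,
    dose_gy: float = 0.0,
    time_h: float = 0.0,
    genotype: str = "wild-type",
    force_paired: bool = False,
    center_offset_um: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
) -> tuple[ImageStack, SyntheticTruth]:
    """Render one two-channel nucleus stack and its ground truth.

    The per-nucleus size jitter rescales all nuclear lengths by a common
    lognormal factor and scales the separation mean with it (unless an
    explicit ``separation_override`` is given, which is honoured exactly).
    ``force_paired`` collapses the separation to zero, emulating fully
    overlapped homologous loci.
    """
    if separation_override is not None and separation_override < 0:
        raise ValueError("separation must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    voxel = model.voxel_size_um

    # Joint (size jitter, pair placement) rejection: a fixed requested
    # separation may not fit in an unusually small jittered nucleus, in
    # which case a fresh jitter is drawn rather than failing outright.
    rel = None
    for _ in range(20):
        jitter = (
            float(np.exp(rng.normal(0.0, model.size_jitter_sd)))
            if model.size_jitter_sd > 0 else 1.0
        )
        semi_axes = np.asarray(model.semi_axes_um) * jitter
        nucleolus_r = model.nucleolus_radius_um * jitter
        if force_paired:
            separation = 0.0
        elif separation_override is not None:
            separation = float(separation_override)
        else:
            separation = draw_separation(
                model.separation_mean_um * jitter, model.separation_sd_um, rng,
                max_um=1.9 * float(semi_axes.max()),
            )
        try:
            rel = sample_pair_coordinates(semi_axes, nucleolus_r, separation, rng,
                                          max_attempts=8192)
        except SeparationInfeasibleError:
            continue
        if separation == 0.0:
            rel[1] = rel[0]
        break
    if rel is None:
        raise SeparationInfeasibleError(
            f"separation {separation_override} μm does not fit in the nucleoplasm "
            f"of this model (semi-axes {model.semi_axes_um})"
        )

    if shape is None:
        shape = tuple(
            int(math.ceil(2 * (a + model.margin_um) / v)) + 1
            for a, v in zip(semi_axes, voxel)
        )
    extent = np.array([(n - 1) * v for n, v in zip(shape, voxel)])
    center = extent / 2.0
    if center_offset_um is not None:
        center = center + np.asarray(center_offset_um, dtype=float)
    lo = center - semi_axes
    hi = extent - (center + semi_axes)
    if lo.min() < -1e-9 or hi.min() < -1e-9:
        raise ValueError("stack too small to contain the nucleus")
    coords = rel + center

    sigma = (model.psf_sigma_z_um, model.psf_sigma_xy_um, model.psf_sigma_xy_um)
    foci = model.background + _render_foci(
        shape, voxel, coords, [model.focus_amplitude] * 2, sigma
    )
    nuc_mask = _ellipsoid_mask(shape, voxel, center, semi_axes)
    nucleus = model.background + model.nucleus_intensity * nuc_mask

    if model.noise:
        foci = _apply_noise(foci, model.read_noise_sd, rng)
        nucleus = _apply_noise(nucleus, model.read_noise_sd, rng)

    stack = ImageStack(
        data=np.stack([foci, nucleus]), voxel_size=voxel, channels=(FOCI, NUCLEUS)
    )
    truth = SyntheticTruth(
        coordinates_um=coords,
        separation_um=separation,
        volume_um3=4.0 / 3.0 * math.pi * float(np.prod(semi_axes)),
        zone=model.zone,
        dose_gy=dose_gy,
        time_h=time_h,
        genotype=genotype,
        nucleus_center_um=center,
        semi_axes_um=tuple(semi_axes),
        nucleolus_radius_um=nucleolus_r,
        paired=separation == 0.0,
        extra={"size_jitter": jitter},
    )
    return stack, truth


def generate_time_series(
    model: NucleusModel,
    n_timepoints: int,
    interval_min: float = 10.0,
    drift_um_per_step: float = 0.0,
    seed: int | None = None,
    expand_stack: bool = True,
    separation_override: float | None = None,
) -> list[tuple[ImageStack, SyntheticTruth]]:
    """Time series with rigid nucleus drift and a constant true separation.

    The nucleus centroid performs a 3D random walk with steps of the
    stated magnitude; the locus pair translates rigidly with it, so the
    true separation is identical at every timepoint by construction. If
    the walk would leave the default field of view the stack is enlarged
    to fit (``expand_stack=True``) or :class:`DriftOutOfBoundsError` is
    raised.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    rng = np.random.default_rng(seed)
    jitter_rng = np.random.default_rng(rng.integers(2**31))

    # fix one nucleus geometry and pair for the whole series
    base = replace(model, size_jitter_sd=0.0, noise=model.noise)
    jitter = float(np.exp(jitter_rng.normal(0.0, model.size_jitter_sd))) if model.size_jitter_sd > 0 else 1.0
    semi_axes = np.asarray(model.semi_axes_um) * jitter
    scaled = replace(
        base,
        semi_axes_um=tuple(semi_axes),
        nucleolus_radius_um=model.nucleolus_radius_um * jitter,
        separation_mean_um=model.separation_mean_um * jitter,
    )
    if separation_override is not None:
        separation = float(separation_override)
    else:
        separation = draw_separation(
            scaled.separation_mean_um, model.separation_sd_um, rng,
            max_um=1.9 * float(semi_axes.max()),
        )
    rel = sample_pair_coordinates(semi_axes, scaled.nucleolus_radius_um, separation, rng)
    if separation == 0.0:
        rel[1] = rel[0]

    steps = np.zeros((n_timepoints, 3))
    if drift_um_per_step > 0:
        directions = rng.normal(size=(n_timepoints - 1, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        steps[1:] = directions * drift_um_per_step
    offsets = np.cumsum(steps, axis=0)

    # size the common stack to contain the nucleus across the whole walk
    voxel = np.asarray(model.voxel_size_um)
    span_lo = offsets.min(axis=0)
    span_hi = offsets.max(axis=0)
    half = semi_axes + model.margin_um + np.maximum(span_hi, -span_lo)
    shape = tuple(int(math.ceil(2 * h / v)) + 1 for h, v in zip(half, voxel))
    if not expand_stack:
        default_shape = tuple(
            int(math.ceil(2 * (a + model.margin_um) / v)) for a, v in zip(semi_axes, voxel)
        )
        if any(s > d + 1 for s, d in zip(shape, default_shape)):
            raise DriftOutOfBoundsError("nucleus walks outside the default stack")

    series: list[tuple[ImageStack, SyntheticTruth]] = []
    extent = np.array([(n - 1) * v for n, v in zip(shape, voxel)])
    walk_center = (span_lo + span_hi) / 2.0
    for t in range(n_timepoints):
        center = extent / 2.0 - walk_center + offsets[t]
        coords = rel + center
        sigma = (model.psf_sigma_z_um, model.psf_sigma_xy_um, model.psf_sigma_xy_um)
        foci = model.background + _render_foci(
            shape, tuple(voxel), coords, [model.focus_amplitude] * 2, sigma
        )
        nuc_mask = _ellipsoid_mask(shape, tuple(voxel), center, semi_axes)
        nucleus = model.background + model.nucleus_intensity * nuc_mask
        if model.noise:
            foci = _apply_noise(foci, model.read_noise_sd, rng)
            nucleus = _apply_noise(nucleus, model.read_noise_sd, rng)
        stack = ImageStack(
            data=np.stack([foci, nucleus]), voxel_size=tuple(voxel), channels=(FOCI, NUCLEUS)
        )
        truth = SyntheticTruth(
            coordinates_um=coords,
            separation_um=separation,
            volume_um3=4.0 / 3.0 * math.pi * float(np.prod(semi_axes)),
            zone=model.zone,
            time_h=t * interval_min / 60.0,
            nucleus_center_um=center,
            semi_axes_um=tuple(semi_axes),
            nucleolus_radius_um=scaled.nucleolus_radius_um,
            paired=separation == 0.0,
            extra={"timepoint": t, "time_min": t * interval_min},
        )
        series.append((stack, truth))
    return series


def generate_dose_panel(
    model: NucleusModel,
    dose_response: DoseResponseModel,
    doses_gy: Sequence[float],
    n_per_dose: int,
    time_h: float = 0.0,
    seed: int | None = None,
    genotype: str = "wild-type",
) -> list[tuple[ImageStack, SyntheticTruth]]:
    """Panel of nuclei across γ-ray doses at one time post-irradiation.

    Per-nucleus true separations are drawn around the dose-response
    model's predicted mean; a dose-dependent fraction of nuclei is fully
    paired. The nucleus size distribution is identical across doses —
    irradiation never changes the volume in this generator.
    """
    if n_per_dose < 1:
        raise ValueError("n_per_dose must be >= 1")
    if any(d < 0 for d in doses_gy):
        raise ValueError("doses must be >= 0")
    children = np.random.SeedSequence(seed).spawn(len(doses_gy) * n_per_dose)
    out: list[tuple[ImageStack, SyntheticTruth]] = []
    k = 0
    for dose in doses_gy:
        mean = dose_response.predicted_mean_um(dose, time_h)
        p_pair = dose_response.pairing_probability(dose, time_h)
        dosed = replace(model, separation_mean_um=mean)
        for _ in range(n_per_dose):
            rng = np.random.default_rng(children[k])
            k += 1
            paired = bool(rng.random() < p_pair)
            stack, truth = generate_nucleus_stack(
                dosed, seed=rng, dose_gy=dose, time_h=time_h,
                genotype=genotype, force_paired=paired,
            )
            out.append((stack, truth))
    return out


def generate_comet_image(
    model: CometModel, seed: int | None = None
) -> tuple[ImageStack, SyntheticTruth]:
    """Render one 2D comet: hard-edged head disc + truncated exponential tail.

    Pre-noise, exactly ``tail_fraction`` of the total signal lies beyond
    the head edge along +x (the electrophoresis direction) and the rest
    inside the head disc, so pixel sums against the truth masks recover
    the requested fraction exactly.
    """
    rng = np.random.default_rng(seed)
    ny, nx = model.shape
    cy, cx = model.head_center
    yy, xx = np.mgrid[0:ny, 0:nx]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    head_mask = r2 <= model.head_radius_px**2

    img = np.zeros((ny, nx), dtype=float)
    head_total = model.intensity * (1.0 - model.tail_fraction)
    if head_total > 0:
        # centrally peaked profile inside the disc, zero outside
        profile = np.where(head_mask, np.exp(-0.5 * r2 / (model.head_radius_px / 1.5) ** 2), 0.0)
        img += head_total * profile / profile.sum()

    tail_total = model.intensity * model.tail_fraction
    if tail_total > 0:
        start = cx + model.head_radius_px
        end = cx + model.tail_length_px
        in_tail_x = (xx > start) & (xx <= end)
        lam = max((model.tail_length_px - model.head_radius_px) / 4.0, 1.0)
        sigma_lat = model.head_radius_px / 2.0
        profile = np.where(
            in_tail_x,
            np.exp(-(xx - start) / lam) * np.exp(-0.5 * ((yy - cy) / sigma_lat) ** 2),
            0.0,
        )
        img += tail_total * profile / profile.sum()

    clean = img + model.background
    data = _apply_noise(clean, model.read_noise_sd, rng) if model.noise else clean
    pix = model.pixel_size_um or 1.0
    stack = ImageStack(data=data[None], voxel_size=(pix, pix), channels=(COMET,))
    center3 = np.array([0.0, cy * pix, cx * pix])
    truth = SyntheticTruth(
        coordinates_um=np.stack([center3, center3]),
        separation_um=0.0,
        volume_um3=float(np.pi * model.head_radius_px**2 * pix**2),  # head area proxy
        zone="comet",
        extra={
            "tail_fraction": model.tail_fraction,
            "tail_length_px": model.tail_length_px,
            "head_center_px": (cy, cx),
            "head_radius_px": model.head_radius_px,
        },
    )
    return stack, truth
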