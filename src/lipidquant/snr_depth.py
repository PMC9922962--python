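"""SNR-versus-depth profiling of the liver region.

The liver ROI is tiled from its shallowest pixel downward into horizontal
slabs of fixed thickness (default 5 mm).  For each slab — and for the SAT
region as an additional depth-labelled segment — the SNR is the mean pixel
intensity of the segment divided by the noise standard deviation, estimated
from the coupling-medium region above the skin line.  SNR is reported both on
the linear scale and in dB (20*log10, amplitude convention, since
reconstructed optoacoustic images are amplitude-like).

Depth of a row is (row - skin_row) * pixel_pitch_cm; a slab's depth label is
the centroid (mean depth) of its masked pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, ValidationError
from .phantom import ROI_LIVER, ROI_SAT, MultispectralStack, ROISet


@dataclass(frozen=True)
class DepthSlab:
    """One horizontal band of the liver mask."""

    top_depth_cm: float
    bottom_depth_cm: float
    centroid_depth_cm: float
    mask: np.ndarray


@dataclass(frozen=True)
class SNRSegment:
    label: str
    centroid_depth_cm: float
    snr_linear: float
    snr_db: float
    n_pixels: int


@dataclass(frozen=True)
class SNRProfile:
    """Depth-ordered SNR segments for one subject at one wavelength."""

    subject_id: str
    wavelength_nm: float
    noise_sd: float
    segments: tuple[SNRSegment, ...]

    def liver_segments(self) -> list[SNRSegment]:
        return [s for s in self.segments if s.label.startswith(ROI_LIVER)]

    def sat_segment(self) -> SNRSegment | None:
        for s in self.segments:
            if s.label == ROI_SAT:
                return s
        return None


def estimate_noise(
    stack_or_pixels, skin_row: int, wavelength_nm: float | None = None
) -> float:
    """Noise sd from the coupling-medium rows above the skin line.

    Accepts either a :class:`MultispectralStack` plus a wavelength, or a bare
    2-D image.  Population standard deviation (ddof=0) of all pixels in rows
    strictly above ``skin_row``.
    """
    if isinstance(stack_or_pixels, MultispectralStack):
        if wavelength_nm is None:
            raise ValidationError("wavelength required with a stack input")
        image = stack_or_pixels.plane(wavelength_nm)
    else:
        image = np.asarray(stack_or_pixels, dtype=float)
    standoff = image[:skin_row]
    if standoff.size < 50:
        raise ValidationError(
            f"only {standoff.size} standoff pixels above the skin line; need >= 50"
        )
    return float(standoff.std(ddof=0))


def partition_liver(
    roiset: ROISet, pixel_pitch_cm: float, slab_thickness_cm: float = 0.5
) -> list[DepthSlab]:
    """Tile the liver mask into contiguous depth slabs.

    Bands start at the depth of the shallowest liver pixel; the last band may
    be thinner; empty bands are dropped.  The slab masks partition the liver
    mask exactly.
    """
    if slab_thickness_cm <= 0:
        raise ValidationError("slab thickness must be positive")
    liver = roiset.mask(ROI_LIVER)
    if not liver.any():
        raise ValidationError("liver mask is empty")
    rows = np.arange(liver.shape[0])
    depth = (rows - roiset.skin_row) * pixel_pitch_cm
    masked_rows = np.flatnonzero(liver.any(axis=1))
    d0 = depth[masked_rows[0]]
    d_max = depth[masked_rows[-1]]
    slabs: list[DepthSlab] = []
    m = 0
    while d0 + m * slab_thickness_cm <= d_max + 1e-12:
        top = d0 + m * slab_thickness_cm
        bottom = top + slab_thickness_cm
        in_band = (depth >= top - 1e-12) & (depth < bottom - 1e-12)
        mask = liver & in_band[:, None]
        m += 1
        if not mask.any():
            continue
        pix_depth = depth[np.nonzero(mask)[0]]
        slabs.append(
            DepthSlab(
                top_depth_cm=top,
                bottom_depth_cm=min(bottom, d_max),  # last slab may be thinner
                centroid_depth_cm=float(pix_depth.mean()),
                mask=mask,
            )
        )
    return slabs


def snr_profile(
    stack: MultispectralStack,
    roiset: ROISet,
    wavelength_nm: float,
    slab_thickness_cm: float = 0.5,
    include_sat: bool = True,
) -> SNRProfile:
    """Per-slab SNR (linear and dB) at one wavelength."""
    noise_sd = estimate_noise(stack, roiset.skin_row, wavelength_nm)
    if noise_sd == 0:
        raise DegenerateDataError("noise sd is zero; SNR undefined")
    image = stack.plane(wavelength_nm)
    segments: list[SNRSegment] = []

    if include_sat and ROI_SAT in roiset.masks:
        sat = roiset.mask(ROI_SAT)
        if sat.any():
            pix_rows = np.nonzero(sat)[0]
            centroid = float(
                ((pix_rows - roiset.skin_row) * stack.pixel_pitch_cm).mean()
            )
            segments.append(_segment(ROI_SAT, image, sat, centroid, noise_sd))

    for i, slab in enumerate(
        partition_liver(roiset, stack.pixel_pitch_cm, slab_thickness_cm)
    ):
        segments.append(
            _segment(f"{ROI_LIVER}-{i}", image, slab.mask,
                     slab.centroid_depth_cm, noise_sd)
        )
    return SNRProfile(
        subject_id=stack.subject_id,
        wavelength_nm=wavelength_nm,
        noise_sd=noise_sd,
        segments=tuple(segments),
    )


def _segment(label, image, mask, centroid, noise_sd) -> SNRSegment:
    snr = float(image[mask].mean()) / noise_sd
    snr_db = 20 * math.log10(snr) if snr > 0 else -math.inf
    return SNRSegment(
        label=label,
        centroid_depth_cm=centroid,
        snr_linear=snr,
        snr_db=snr_db,
        n_pixels=int(mask.sum()),
    )


def percent_decrease(profile: SNRProfile) -> dict:
    """Percent SNR decrease per slab step and per centimetre of depth.

    Step decrease between consecutive liver slabs k, k+1 is
    100*(1 - snr_{k+1}/snr_k) on the linear scale.  The per-cm figure uses
    geometric (exponential) interpolation of the step ratio:
    100*(1 - (snr_{k+1}/snr_k)^(1 cm / delta_depth)).  Steps with a zero
    numerator SNR are flagged and excluded from the means.  If a SAT segment
    is present, the SAT-to-first-liver-slab drop is reported as well.
    """
    liver = profile.liver_segments()
    if len(liver) < 2:
        raise ValidationError("need at least 2 liver slabs for decrease summaries")
    steps, per_cm, flagged = [], [], []
    for k in range(len(liver) - 1):
        s0, s1 = liver[k], liver[k + 1]
        if s0.snr_linear == 0:
            flagged.append(k)
            continue
        ratio = s1.snr_linear / s0.snr_linear
        steps.append(100.0 * (1.0 - ratio))
        dd = s1.centroid_depth_cm - s0.centroid_depth_cm
        if dd > 0 and ratio > 0:
            per_cm.append(100.0 * (1.0 - ratio ** (1.0 / dd)))
        elif ratio == 0:
            per_cm.append(100.0)
    out = {
        "step_decreases_pct": steps,
        "mean_step_decrease_pct": float(np.mean(steps)) if steps else float("nan"),
        "per_cm_decreases_pct": per_cm,
        "mean_per_cm_decrease_pct": float(np.mean(per_cm)) if per_cm else float("nan"),
        "undefined_steps": flagged,
    }
    sat = profile.sat_segment()
    if sat is not None and sat.snr_linear > 0:
        out["sat_to_first_liver_decrease_pct"] = 100.0 * (
            1.0 - liver[0].snr_linear / sat.snr_linear
        )
    return out
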