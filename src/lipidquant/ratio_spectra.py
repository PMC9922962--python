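"""Normalized ROI/background ratio spectra.

For each subject and region of interest, the mean pixel intensity inside the
ROI is divided by the mean intensity of the background region (the entire
imaged tissue, which contains both SAT and liver) at every wavelength.  The
resulting ratio curve is then normalized by its own maximum across
wavelengths, yielding a per-subject "normalized ratio spectrum" in [0, 1].

Because ROI and background scale together with laser pulse energy, the raw
ratio is invariant to global and per-wavelength multiplicative fluctuations;
normalizing by the spectral maximum additionally removes subject-dependent
scale so spectra are comparable across subjects.  The value at 930 nm — the
lipid absorption peak — is the per-subject lipid score.

Normalization is per ROI, per stack: each ROI's curve is divided by its own
spectral maximum.  Ties in the maximum resolve to the shortest wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AlignmentError, SpectralDivisionError, ValidationError
from .phantom import ROI_BGR, MultispectralStack, ROISet


@dataclass(frozen=True)
class RatioSpectrum:
    """Per-subject ROI/BGR ratio curve, raw and max-normalized."""

    subject_id: str
    roi_name: str
    wavelengths_nm: np.ndarray
    raw_ratio: np.ndarray
    normalized_ratio: np.ndarray

    def value_at(self, wavelength_nm: float) -> float:
        """Normalized ratio at an on-grid wavelength (exact lookup)."""
        hits = np.flatnonzero(
            np.isclose(self.wavelengths_nm, wavelength_nm, rtol=0, atol=1e-6)
        )
        if hits.size != 1:
            raise ValidationError(
                f"{wavelength_nm} nm is not on this spectrum's grid"
            )
        return float(self.normalized_ratio[hits[0]])


@dataclass(frozen=True)
class GroupSpectrum:
    """Per-wavelength mean and SEM of normalized ratios over subjects."""

    roi_name: str
    cohort: str
    wavelengths_nm: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int


def roi_mean(stack: MultispectralStack, mask: np.ndarray, wavelength_nm: float) -> float:
    """Arithmetic mean pixel intensity under ``mask`` at one wavelength."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask is empty")
    return float(stack.plane(wavelength_nm)[mask].mean())


def _roi_means_all(stack: MultispectralStack, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask is empty")
    return stack.pixels[mask].mean(axis=0)  # (n_wavelengths,)


def ratio_spectrum(
    stack: MultispectralStack, roiset: ROISet, roi_name: str
) -> RatioSpectrum:
    """ROI/BGR ratio at every wavelength, normalized by its spectral maximum."""
    roi_means = _roi_means_all(stack, roiset.mask(roi_name))
    bgr_means = _roi_means_all(stack, roiset.mask(ROI_BGR))
    zero = bgr_means == 0
    if zero.any():
        raise SpectralDivisionError(stack.grid.wavelengths()[zero])
    raw = roi_means / bgr_means
    peak = raw[np.argmax(raw)]  # argmax: first (shortest-wavelength) maximum
    normalized = raw / peak if peak > 0 else raw.copy()
    return RatioSpectrum(
        subject_id=stack.subject_id,
        roi_name=roi_name,
        wavelengths_nm=stack.grid.wavelengths(),
        raw_ratio=raw,
        normalized_ratio=normalized,
    )


def value_at(spectrum: RatioSpectrum, wavelength_nm: float) -> float:
    """Module-level alias of :meth:`RatioSpectrum.value_at`."""
    return spectrum.value_at(wavelength_nm)


def group_spectrum(
    spectra: Sequence[RatioSpectrum], cohort: str = ""
) -> GroupSpectrum:
    """Mean +/- SEM of normalized ratio spectra over subjects."""
    if len(spectra) < 2:
        raise ValidationError("need at least 2 spectra for a group spectrum")
    roi_names = {s.roi_name for s in spectra}
    if len(roi_names) != 1:
        raise ValidationError(f"mixed ROI names in group: {sorted(roi_names)}")
    wl0 = spectra[0].wavelengths_nm
    for s in spectra[1:]:
        if s.wavelengths_nm.shape != wl0.shape or not np.array_equal(
            s.wavelengths_nm, wl0
        ):
            raise AlignmentError("spectra are on different wavelength grids")
    values = np.vstack([s.normalized_ratio for s in spectra])
    n = values.shape[0]
    return GroupSpectrum(
        roi_name=roi_names.pop(),
        cohort=cohort,
        wavelengths_nm=wl0,
        mean=values.mean(axis=0),
        sem=values.std(axis=0, ddof=1) / np.sqrt(n),
        n=n,
    )
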