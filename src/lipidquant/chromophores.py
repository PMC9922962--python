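"""Near-infrared chromophore absorption spectra and tissue mixing.

The four chromophores that dominate soft-tissue absorption between 680 and
970 nm are oxyhemoglobin, deoxyhemoglobin, lipid and water.  Lipid carries a
characteristic absorption peak near 930 nm — the spectral feature the whole
pipeline quantifies — while hemoglobin dominates below ~900 nm and water
rises toward its 970 nm peak.

Tabulated reference spectra ship as package data (``data/*.tsv``, two
columns: wavelength in nm, mu_a in 1/cm at the stated reference
concentration).  Tissue absorption is modelled as a linear Beer–Lambert
mixture of the reference spectra weighted by volume fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from .errors import AlignmentError, ValidationError

CHROMOPHORE_NAMES = ("oxyhemoglobin", "deoxyhemoglobin", "lipid", "water")

#: Wavelength range (nm) covered by the shipped tables.
TABULATED_RANGE_NM = (650.0, 1000.0)


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid, inclusive of both endpoints."""

    start_nm: float
    stop_nm: float
    step_nm: float

    def __post_init__(self) -> None:
        if not self.start_nm < self.stop_nm:
            raise ValidationError("start_nm must be < stop_nm")
        if self.step_nm <= 0:
            raise ValidationError("step_nm must be positive")
        span = self.stop_nm - self.start_nm
        n_steps = span / self.step_nm
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValidationError(
                f"grid span {span} nm is not a multiple of step {self.step_nm} nm"
            )

    def count(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.count())

    def index_of(self, wavelength_nm: float) -> int:
        """Exact-lookup index of a wavelength; off-grid values are an error."""
        wl = self.wavelengths()
        hits = np.flatnonzero(np.isclose(wl, wavelength_nm, rtol=0, atol=1e-6))
        if hits.size != 1:
            raise ValidationError(
                f"{wavelength_nm} nm is not on the grid "
                f"({self.start_nm}-{self.stop_nm} step {self.step_nm})"
            )
        return int(hits[0])


#: Clinical hand-held preset: 28 wavelengths, 700-970 nm in 10 nm steps.
CLINICAL_GRID = WavelengthGrid(700.0, 970.0, 10.0)
#: Small-animal preset: 29 wavelengths, 680-960 nm in 10 nm steps.
MOUSE_GRID = WavelengthGrid(680.0, 960.0, 10.0)


@dataclass(frozen=True)
class ChromophoreSpectrum:
    """Absorption spectrum of one chromophore at a reference concentration."""

    name: str
    wavelengths_nm: np.ndarray
    mu_a: np.ndarray  # 1/cm

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        mu = np.asarray(self.mu_a, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "mu_a", mu)
        if wl.shape != mu.shape or wl.ndim != 1:
            raise ValidationError("wavelengths and mu_a must be 1-D and aligned")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if np.any(mu < 0):
            raise ValidationError("mu_a must be non-negative")

    def resample(self, grid: WavelengthGrid) -> "ChromophoreSpectrum":
        """Linear interpolation onto ``grid`` (must lie within the table)."""
        target = grid.wavelengths()
        if target[0] < self.wavelengths_nm[0] or target[-1] > self.wavelengths_nm[-1]:
            raise ValidationError(
                f"grid {grid.start_nm}-{grid.stop_nm} nm outside tabulated range "
                f"{self.wavelengths_nm[0]}-{self.wavelengths_nm[-1]} nm"
            )
        return ChromophoreSpectrum(
            self.name, target, np.interp(target, self.wavelengths_nm, self.mu_a)
        )


@dataclass(frozen=True)
class TissueComposition:
    """Volume fractions of the reference chromophores plus optoacoustic efficiency.

    ``grueneisen`` is the dimensionless conversion efficiency from absorbed
    optical energy to initial acoustic pressure; it scales the whole spectrum.
    """

    fractions: Mapping[str, float] = field(default_factory=dict)
    grueneisen: float = 1.0

    def __post_init__(self) -> None:
        for name, f in self.fractions.items():
            if name not in CHROMOPHORE_NAMES:
                raise ValidationError(f"unknown chromophore {name!r}")
            if f < 0:
                raise ValidationError(f"negative volume fraction for {name}")
        if sum(self.fractions.values()) > 1 + 1e-9:
            raise ValidationError("volume fractions sum to more than 1")
        if self.grueneisen <= 0:
            raise ValidationError("grueneisen must be positive")

    def scaled(self, factors: Mapping[str, float]) -> "TissueComposition":
        """New composition with each fraction multiplied by ``factors[name]``.

        If the scaled fractions would sum above 1 they are renormalized to
        sum exactly 1, keeping the mixture physical.
        """
        new = {n: f * factors.get(n, 1.0) for n, f in self.fractions.items()}
        total = sum(new.values())
        if total > 1:
            new = {n: f / total for n, f in new.items()}
        return TissueComposition(new, self.grueneisen)


def _read_table(name: str) -> ChromophoreSpectrum:
    text = resources.files("lipidquant.data").joinpath(f"{name}.tsv").read_text()
    rows = [
        line.split("\t")
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    wl = np.array([float(r[0]) for r in rows])
    mu = np.array([float(r[1]) for r in rows])
    return ChromophoreSpectrum(name, wl, mu)


def load_raw_spectra() -> dict[str, ChromophoreSpectrum]:
    """Shipped tables at their native (10 nm, 650-1000 nm) sampling."""
    return {name: _read_table(name) for name in CHROMOPHORE_NAMES}


def load_builtin_spectra(grid: WavelengthGrid) -> dict[str, ChromophoreSpectrum]:
    """All four reference spectra resampled onto ``grid``.

    Raises :class:`ValidationError` if the grid extends beyond the tabulated
    650-1000 nm range.
    """
    return {name: spec.resample(grid) for name, spec in load_raw_spectra().items()}


def mix_absorption(
    comp: TissueComposition, spectra: Mapping[str, ChromophoreSpectrum]
) -> np.ndarray:
    """Linear mixture mu_a(lambda) = sum_c fraction_c * mu_a_c(lambda), in 1/cm.

    All spectra must share one wavelength grid.  The Grueneisen factor is
    deliberately NOT applied here: it belongs to the optoacoustic forward
    model, not to optical absorption.
    """
    grids = [s.wavelengths_nm for s in spectra.values()]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.array_equal(g, grids[0]):
            raise AlignmentError("chromophore spectra are on different grids")
    mu = np.zeros_like(grids[0], dtype=float)
    for name, f in comp.fractions.items():
        if name not in spectra:
            raise ValidationError(f"no spectrum supplied for {name!r}")
        mu += f * spectra[name].mu_a
    return mu
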