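"""Exception hierarchy for the lipidquant pipeline."""


class LipidquantError(Exception):
    """Base class for all lipidquant errors."""


class ValidationError(LipidquantError):
    """Input violates a documented contract (shapes, masks, ranges)."""


class FormatError(LipidquantError):
    """A file is structurally inconsistent with its declared metadata."""


class AlignmentError(LipidquantError):
    """Spectra or stacks do not share a common wavelength grid."""


class DegenerateDataError(LipidquantError):
    """Statistic undefined on this input (constant sample, zero variance)."""


class SpectralDivisionError(LipidquantError):
    """Background mean is zero at one or more wavelengths."""

    def __init__(self, wavelengths_nm):
        self.wavelengths_nm = list(wavelengths_nm)
        super().__init__(
            f"background ROI mean is zero at wavelengths {self.wavelengths_nm} nm"
        )


class NoIntersectionError(LipidquantError):
    """Density curves do not cross between their modes."""
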