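"""Synthetic multispectral optoacoustic phantoms.

Generates layered 2-D tissue phantoms (coupling-medium standoff, skin,
subcutaneous adipose tissue, an unanalysed muscle/fascia spacer, liver) and
renders a multispectral image stack per subject with the forward model

    pixel(z, lambda) = Gamma * mu_a(lambda) * exp(-mu_eff * z) * j(lambda) + eps

where z is depth below the skin line, ``j`` is a per-wavelength laser-energy
jitter factor (mean 1), and ``eps`` is additive Gaussian noise.  Pixels are
truncated at zero by default, mirroring the non-negativity constraint of
tomographic reconstruction.  Standoff rows above the skin line carry noise
only, so a noise estimator that uses the coupling-medium region is exercised
faithfully.

Two cohorts are supported for each species preset: ``healthy`` and
``steatosis``.  Steatosis raises the liver lipid volume fraction and thickens
the SAT layer; SAT composition itself is identical between cohorts, which is
what makes the SAT contrast a true null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .chromophores import (
    CLINICAL_GRID,
    MOUSE_GRID,
    TissueComposition,
    WavelengthGrid,
    load_builtin_spectra,
    mix_absorption,
)
from .errors import FormatError, ValidationError

COHORTS = ("healthy", "steatosis")

# ROI names used throughout the pipeline.
ROI_SAT = "SAT"
ROI_LIVER = "liver"
ROI_BGR = "BGR"


@dataclass(frozen=True)
class LayerSpec:
    """One horizontal tissue layer, top to bottom."""

    name: str
    thickness_cm: float
    composition: TissueComposition

    def __post_init__(self) -> None:
        if self.thickness_cm <= 0:
            raise ValidationError(f"layer {self.name!r} has non-positive thickness")
        if self.name == "standoff" and sum(self.composition.fractions.values()) > 0:
            raise ValidationError("standoff layer must have zero chromophore content")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic subject scan."""

    grid: WavelengthGrid
    layers: tuple[LayerSpec, ...]
    pixel_pitch_cm: float
    image_height_px: int
    image_width_px: int
    mu_eff_per_cm: float = 0.3
    noise_sd: float = 0.002
    pulse_jitter_cv: float = 0.02
    seed: int = 0
    truncate: bool = True

    def __post_init__(self) -> None:
        if not self.layers or self.layers[0].name != "standoff":
            raise ValidationError("layers must begin with a standoff layer")
        if self.mu_eff_per_cm < 0 or self.noise_sd < 0 or self.pulse_jitter_cv < 0:
            raise ValidationError("mu_eff, noise_sd and jitter CV must be >= 0")
        if self.pixel_pitch_cm <= 0:
            raise ValidationError("pixel_pitch_cm must be positive")
        total = sum(l.thickness_cm for l in self.layers)
        if total > self.image_height_px * self.pixel_pitch_cm + 1e-9:
            raise ValidationError("layers exceed the image extent")

    @property
    def skin_row(self) -> int:
        return int(round(self.layers[0].thickness_cm / self.pixel_pitch_cm))


@dataclass(frozen=True)
class MultispectralStack:
    """Co-registered single-wavelength images for one subject.

    ``pixels`` is indexed (row, column, wavelength); row 0 is the probe side
    and depth of a row is ``(row - skin_row) * pixel_pitch_cm``.
    """

    pixels: np.ndarray
    grid: WavelengthGrid
    pixel_pitch_cm: float
    skin_row: int
    subject_id: str = "S0"
    cohort: str = "healthy"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 3:
            raise ValidationError("pixels must be (row, column, wavelength)")
        if px.shape[2] != self.grid.count():
            raise FormatError(
                f"stack has {px.shape[2]} planes but grid declares {self.grid.count()}"
            )
        if np.any(px < 0):
            raise ValidationError("pixels must be non-negative")

    def plane(self, wavelength_nm: float) -> np.ndarray:
        return self.pixels[:, :, self.grid.index_of(wavelength_nm)]

    def depth_of_row(self, row) -> np.ndarray:
        return (np.asarray(row) - self.skin_row) * self.pixel_pitch_cm


@dataclass(frozen=True)
class ROISet:
    """SAT/liver/background boolean masks plus the skin-line row."""

    masks: dict[str, np.ndarray]
    skin_row: int

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            self.masks[name] = m
            if m.ndim != 2:
                raise ValidationError(f"mask {name!r} must be 2-D")
            if m[: self.skin_row].any():
                raise ValidationError(f"mask {name!r} extends above the skin line")
        sat = self.masks.get(ROI_SAT)
        liver = self.masks.get(ROI_LIVER)
        bgr = self.masks.get(ROI_BGR)
        if sat is not None and liver is not None and (sat & liver).any():
            raise ValidationError("SAT and liver masks overlap")
        if bgr is not None:
            for name in (ROI_SAT, ROI_LIVER):
                if name in self.masks and (self.masks[name] & ~bgr).any():
                    raise ValidationError(f"BGR does not contain the {name} mask")

    def mask(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise ValidationError(f"no mask named {name!r}")
        return self.masks[name]


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _skin() -> TissueComposition:
    return TissueComposition(
        {"oxyhemoglobin": 0.01, "deoxyhemoglobin": 0.01, "water": 0.50, "lipid": 0.10}
    )


def _sat() -> TissueComposition:
    return TissueComposition(
        {"oxyhemoglobin": 0.005, "deoxyhemoglobin": 0.005, "water": 0.15, "lipid": 0.15}
    )


def _muscle() -> TissueComposition:
    return TissueComposition(
        {"oxyhemoglobin": 0.02, "deoxyhemoglobin": 0.05, "water": 0.70, "lipid": 0.05}
    )


def _liver(lipid_fraction: float) -> TissueComposition:
    # Liver blood is predominantly portal-venous, hence deoxy-weighted.
    return TissueComposition(
        {
            "oxyhemoglobin": 0.02,
            "deoxyhemoglobin": 0.06,
            "water": 0.20,
            "lipid": lipid_fraction,
        }
    )


#: Liver lipid volume fraction per cohort (same for both species presets).
#: Effective values: they fold in the spectral fluence filtering the
#: single-exponential attenuation model does not represent, and are chosen
#: so the background region keeps a blood-dominated shape while the
#: steatotic liver gains a clear 930 nm excess.
LIVER_LIPID_FRACTION = {"healthy": 0.02, "steatosis": 0.40}
#: Human SAT thickness per cohort (cm); the steatosis cohort carries a
#: visibly thicker subcutaneous fat layer.
HUMAN_SAT_THICKNESS = {"healthy": 0.8, "steatosis": 1.6}
MOUSE_SAT_THICKNESS = {"healthy": 0.15, "steatosis": 0.40}


def human_preset(
    cohort: str = "healthy", seed: int = 0, reduced: bool = False
) -> PhantomSpec:
    """Hand-held clinical geometry: 700-970 nm grid, liver a few cm deep.

    ``reduced`` coarsens the pixel pitch and narrows the image so that large
    replicate studies stay cheap; the layered geometry in cm is unchanged.
    """
    _check_cohort(cohort)
    sat = HUMAN_SAT_THICKNESS[cohort]
    layers = (
        LayerSpec("standoff", 0.3, TissueComposition({})),
        LayerSpec("skin", 0.1, _skin()),
        LayerSpec(ROI_SAT, sat, _sat()),
        LayerSpec("muscle", 1.3, _muscle()),
        # liver fills the remaining depth
        LayerSpec(ROI_LIVER, 1.5, _liver(LIVER_LIPID_FRACTION[cohort])),
    )
    pitch = 0.025 if reduced else 0.01
    height_cm = 0.3 + 0.1 + sat + 1.3 + 1.5
    return PhantomSpec(
        grid=CLINICAL_GRID,
        layers=layers,
        pixel_pitch_cm=pitch,
        image_height_px=int(round(height_cm / pitch)),
        image_width_px=40 if reduced else 200,
        seed=seed,
    )


def mouse_preset(
    cohort: str = "healthy", seed: int = 0, reduced: bool = False
) -> PhantomSpec:
    """Small-animal geometry: 680-960 nm grid, shallow liver."""
    _check_cohort(cohort)
    sat = MOUSE_SAT_THICKNESS[cohort]
    layers = (
        LayerSpec("standoff", 0.2, TissueComposition({})),
        LayerSpec("skin", 0.05, _skin()),
        LayerSpec(ROI_SAT, sat, _sat()),
        LayerSpec("muscle", 0.2, _muscle()),
        LayerSpec(ROI_LIVER, 0.8, _liver(LIVER_LIPID_FRACTION[cohort])),
    )
    pitch = 0.0125 if reduced else 0.005
    height_cm = 0.2 + 0.05 + sat + 0.2 + 0.8
    return PhantomSpec(
        grid=MOUSE_GRID,
        layers=layers,
        pixel_pitch_cm=pitch,
        image_height_px=int(round(height_cm / pitch)),
        image_width_px=40 if reduced else 200,
        seed=seed,
    )


PRESETS: dict[str, Callable[..., PhantomSpec]] = {
    "human": human_preset,
    "mouse": mouse_preset,
}


def _check_cohort(cohort: str) -> None:
    if cohort not in COHORTS:
        raise ValidationError(f"cohort must be one of {COHORTS}, got {cohort!r}")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _layer_rows(spec: PhantomSpec) -> list[tuple[LayerSpec, int, int]]:
    """(layer, first_row, last_row_exclusive) for every layer incl. standoff."""
    out = []
    row = 0
    for layer in spec.layers:
        n_rows = int(round(layer.thickness_cm / spec.pixel_pitch_cm))
        stop = min(row + n_rows, spec.image_height_px)
        out.append((layer, row, stop))
        row = stop
    return out


def _render_field(spec: PhantomSpec) -> np.ndarray:
    """Raw (un-truncated) forward-model field, deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    spectra = load_builtin_spectra(spec.grid)
    n_l = spec.grid.count()
    h, w = spec.image_height_px, spec.image_width_px

    # Per-wavelength laser-energy jitter, shared by every pixel of a plane.
    if spec.pulse_jitter_cv > 0:
        jitter = np.clip(rng.normal(1.0, spec.pulse_jitter_cv, size=n_l), 0.0, None)
    else:
        jitter = np.ones(n_l)

    signal = np.zeros((h, w, n_l))
    depth = (np.arange(h) - spec.skin_row) * spec.pixel_pitch_cm
    atten = np.exp(-spec.mu_eff_per_cm * np.clip(depth, 0.0, None))
    for layer, r0, r1 in _layer_rows(spec):
        if layer.name == "standoff" or r1 <= r0:
            continue
        mu = mix_absorption(layer.composition, spectra)  # (n_l,)
        amp = layer.composition.grueneisen * mu * jitter
        signal[r0:r1] = atten[r0:r1, None, None] * amp[None, None, :]

    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
    return signal


def generate_raw_noise_stack(spec: PhantomSpec) -> np.ndarray:
    """Un-truncated pixel array for noise-calibration studies.

    Same forward model and seed behaviour as :func:`generate_stack` but the
    zero-truncation is skipped, so the standoff region carries the raw
    Gaussian noise.  Returned as a bare array because the stack container
    enforces non-negativity.
    """
    return _render_field(spec)


def generate_stack(
    spec: PhantomSpec, cohort: str = "healthy", subject_id: str = "S0"
) -> tuple[MultispectralStack, ROISet]:
    """Render one subject from ``spec`` and return the stack with its masks.

    Deterministic in ``spec.seed``: identical specs give bit-identical output.
    Pixels are truncated at zero, mirroring reconstruction non-negativity.
    """
    _check_cohort(cohort)
    stack = MultispectralStack(
        pixels=np.clip(_render_field(spec), 0.0, None),
        grid=spec.grid,
        pixel_pitch_cm=spec.pixel_pitch_cm,
        skin_row=spec.skin_row,
        subject_id=subject_id,
        cohort=cohort,
    )

    h, w = spec.image_height_px, spec.image_width_px
    masks: dict[str, np.ndarray] = {}
    tissue = np.zeros((h, w), dtype=bool)
    for layer, r0, r1 in _layer_rows(spec):
        if layer.name == "standoff":
            continue
        band = np.zeros((h, w), dtype=bool)
        band[r0:r1] = True
        tissue |= band
        if layer.name in (ROI_SAT, ROI_LIVER):
            masks[layer.name] = band
    masks[ROI_BGR] = tissue
    return stack, ROISet(masks=masks, skin_row=spec.skin_row)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Bounded inter-subject variability: layer thicknesses and chromophore
#: fractions are each multiplied by 1 + Uniform(-jitter, +jitter).
DEFAULT_THICKNESS_JITTER = 0.15
DEFAULT_COMPOSITION_JITTER = 0.15


def _perturb_spec(spec: PhantomSpec, rng: np.random.Generator,
                  thickness_jitter: float, composition_jitter: float) -> PhantomSpec:
    """Bounded per-subject variability.

    Thicknesses and chromophore fractions of every tissue layer are scaled by
    independent 1 + Uniform(-jitter, +jitter) factors; the deepest layer
    (liver) then fills whatever depth remains, so the image extent is
    preserved and a thicker SAT pushes the liver deeper — as in real scans.
    """
    layers = []
    extent = spec.image_height_px * spec.pixel_pitch_cm
    for i, layer in enumerate(spec.layers):
        if layer.name == "standoff":
            layers.append(layer)
            continue
        factors = {
            n: 1 + rng.uniform(-composition_jitter, composition_jitter)
            for n in layer.composition.fractions
        }
        comp = layer.composition.scaled(factors)
        if i == len(spec.layers) - 1:
            t = extent - sum(l.thickness_cm for l in layers)
            if t <= 0:
                raise ValidationError("perturbed layers exceed the image extent")
        else:
            t = layer.thickness_cm * (
                1 + rng.uniform(-thickness_jitter, thickness_jitter)
            )
        layers.append(LayerSpec(layer.name, t, comp))
    return replace(spec, layers=tuple(layers))


def generate_cohort(
    preset: str | Callable[..., PhantomSpec] = "human",
    n_per_group: int = 5,
    base_seed: int = 0,
    cohorts: Sequence[str] = COHORTS,
    reduced: bool = False,
    thickness_jitter: float = DEFAULT_THICKNESS_JITTER,
    composition_jitter: float = DEFAULT_COMPOSITION_JITTER,
) -> dict[str, list[tuple[MultispectralStack, ROISet]]]:
    """Simulate ``n_per_group`` subjects per cohort with deterministic seeds.

    Per-subject seeds are spawned from ``base_seed`` via
    ``numpy.random.SeedSequence`` so subjects are independent yet fully
    reproducible.  Inter-subject variability perturbs layer thicknesses and
    compositions within the documented bounded ranges.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    factory = PRESETS[preset] if isinstance(preset, str) else preset
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(len(cohorts) * n_per_group)
    out: dict[str, list[tuple[MultispectralStack, ROISet]]] = {}
    k = 0
    for j, cohort in enumerate(cohorts):
        # duplicate labels (e.g. healthy-vs-healthy null runs) get a suffix
        key = cohort if cohort not in out else f"{cohort}_{j + 1}"
        subjects = []
        for i in range(n_per_group):
            child = children[k]
            k += 1
            rng = np.random.default_rng(child)
            stack_seed = int(rng.integers(0, 2**31 - 1))
            spec = factory(cohort=cohort, seed=stack_seed, reduced=reduced)
            spec = _perturb_spec(spec, rng, thickness_jitter, composition_jitter)
            subjects.append(
                generate_stack(spec, cohort=cohort, subject_id=f"{key}-{i}")
            )
        out[key] = subjects
    return out
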