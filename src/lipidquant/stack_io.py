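"""Reading and writing multispectral stacks, ROI masks, and configs.

HDF5 is the canonical container (datasets ``pixels`` and ``wavelengths_nm``,
attributes ``pixel_pitch_cm``, ``skin_row``, ``cohort``, ``subject_id``).  A
multi-page TIFF with a JSON sidecar is supported for interoperability; both
dialects round-trip pixels bit-exactly.  Readers validate shape/metadata
consistency and reject corrupt inputs instead of coercing them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .chromophores import WavelengthGrid
from .errors import FormatError, ValidationError
from .phantom import ROI_BGR, MultispectralStack, ROISet

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Tunable settings of the analysis chain.

    ``target_wavelength_nm`` defaults to 930 nm, the NIR lipid absorption
    peak; ``slab_thickness_cm`` to 0.5 cm (5 mm depth segments).
    """

    target_wavelength_nm: float = 930.0
    slab_thickness_cm: float = 0.5
    normalization: str = "per_roi_max"
    density_method: str = "kde"
    density_grid_points: int = 512
    density_bins: int = 64
    proportions_method: str = "pooled"
    gate_alpha: float = 0.05
    welch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slab_thickness_cm <= 0:
            raise ValidationError("slab_thickness_cm must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _grid_from_wavelengths(wl: np.ndarray) -> WavelengthGrid:
    wl = np.asarray(wl, dtype=float)
    if wl.size < 2:
        raise FormatError("need at least two wavelengths")
    steps = np.diff(wl)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
        raise FormatError("wavelengths are not a uniform increasing grid")
    return WavelengthGrid(float(wl[0]), float(wl[-1]), float(steps[0]))


# ---------------------------------------------------------------------------
# Stacks
# ---------------------------------------------------------------------------

def write_stack(stack: MultispectralStack, path: str | Path) -> None:
    """Write a stack as HDF5 (`.h5`/`.hdf5`) or TIFF+JSON sidecar (`.tif`)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("pixels", data=stack.pixels)
            f.create_dataset("wavelengths_nm", data=stack.grid.wavelengths())
            f.attrs["pixel_pitch_cm"] = stack.pixel_pitch_cm
            f.attrs["skin_row"] = stack.skin_row
            f.attrs["cohort"] = stack.cohort
            f.attrs["subject_id"] = stack.subject_id
    elif path.suffix in (".tif", ".tiff"):
        # pages along the wavelength axis
        tifffile.imwrite(path, np.moveaxis(stack.pixels, 2, 0))
        sidecar = {
            "wavelengths_nm": stack.grid.wavelengths().tolist(),
            "pixel_pitch_cm": stack.pixel_pitch_cm,
            "skin_row": stack.skin_row,
            "cohort": stack.cohort,
            "subject_id": stack.subject_id,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )
    else:
        raise FormatError(f"unsupported stack format {path.suffix!r}")


def read_stack(path: str | Path) -> MultispectralStack:
    """Read a stack written by :func:`write_stack`; validates metadata."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "wavelengths_nm" not in f:
                raise FormatError("stack file lacks wavelength metadata")
            pixels = f["pixels"][()]
            wl = f["wavelengths_nm"][()]
            meta = dict(f.attrs)
    elif path.suffix in (".tif", ".tiff"):
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if not sidecar_path.exists():
            raise FormatError(f"missing JSON sidecar {sidecar_path}")
        meta = json.loads(sidecar_path.read_text())
        if "wavelengths_nm" not in meta:
            raise FormatError("sidecar lacks wavelength metadata")
        wl = np.asarray(meta["wavelengths_nm"], dtype=float)
        pixels = np.moveaxis(tifffile.imread(path), 0, 2)
    else:
        raise FormatError(f"unsupported stack format {path.suffix!r}")

    grid = _grid_from_wavelengths(np.asarray(wl))
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 3 or pixels.shape[2] != grid.count():
        raise FormatError(
            f"stack has {pixels.shape[-1] if pixels.ndim == 3 else '?'} planes "
            f"but grid declares {grid.count()}"
        )
    if np.any(pixels < 0):
        raise ValidationError("stack contains negative pixels")
    return MultispectralStack(
        pixels=pixels,
        grid=grid,
        pixel_pitch_cm=float(meta["pixel_pitch_cm"]),
        skin_row=int(meta["skin_row"]),
        subject_id=str(meta.get("subject_id", "S0")),
        cohort=str(meta.get("cohort", "healthy")),
    )


# ---------------------------------------------------------------------------
# ROI sets
# ---------------------------------------------------------------------------

def write_roiset(roiset: ROISet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix not in (".h5", ".hdf5"):
        raise FormatError("ROI sets are stored as HDF5")
    with h5py.File(path, "w") as f:
        for name, mask in roiset.masks.items():
            f.create_dataset(name, data=mask.astype(bool))
        f.attrs["skin_row"] = roiset.skin_row


def read_roiset(path: str | Path, stack: MultispectralStack) -> ROISet:
    """Read masks and validate them against ``stack``.

    If no background mask is stored, BGR is auto-completed as the union of
    all stored tissue masks (SAT, liver, and any declared other tissue), with
    a logged notice.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        masks = {name: f[name][()].astype(bool) for name in f.keys()}
        skin_row = int(f.attrs["skin_row"])

    expected = stack.pixels.shape[:2]
    for name, mask in masks.items():
        if mask.shape != expected:
            raise FormatError(
                f"mask {name!r} shape {mask.shape} != image shape {expected}"
            )
    if skin_row != stack.skin_row:
        raise FormatError(
            f"ROI skin_row {skin_row} != stack skin_row {stack.skin_row}"
        )
    if ROI_BGR not in masks:
        union = np.zeros(expected, dtype=bool)
        for mask in masks.values():
            union |= mask
        masks[ROI_BGR] = union
        logger.info("no BGR mask in %s; auto-completed as union of %s",
                    path.name, sorted(set(masks) - {ROI_BGR}))
    return ROISet(masks=masks, skin_row=skin_row)


def write_cohort(cohort_data, outdir: str | Path, fmt: str = "h5") -> list[Path]:
    """Write every (stack, roiset) of a generated cohort dict under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for label, subjects in cohort_data.items():
        for stack, roiset in subjects:
            base = outdir / f"{stack.subject_id}"
            write_stack(stack, base.with_suffix(f".{fmt}"))
            write_roiset(roiset, Path(str(base) + "_rois.h5"))
            written.append(base.with_suffix(f".{fmt}"))
    return written


def read_cohort(indir: str | Path) -> dict[str, list[tuple[MultispectralStack, ROISet]]]:
    """Read every stack+ROI pair under ``indir``, grouped by cohort label."""
    indir = Path(indir)
    out: dict[str, list[tuple[MultispectralStack, ROISet]]] = {}
    stack_files = sorted(
        p for p in indir.iterdir()
        if p.suffix in (".h5", ".hdf5", ".tif", ".tiff")
        and not p.stem.endswith("_rois")
    )
    if not stack_files:
        raise FormatError(f"no stack files found in {indir}")
    for sf in stack_files:
        stack = read_stack(sf)
        roiset = read_roiset(indir / f"{sf.stem}_rois.h5", stack)
        out.setdefault(stack.cohort, []).append((stack, roiset))
    return out
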