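"""Pooled pixel-level classification at the target wavelength.

All liver-ROI pixels of each group's subjects are pooled and their intensity
distribution estimated (Gaussian KDE with Silverman bandwidth by default, or
a histogram).  The classification threshold is the intensity where the two
group densities intersect between their modes; the proportion of liver pixels
above that threshold is then computed per subject and compared between groups
with a two-sample proportions z-test on the pooled counts.

Pooling pixels across subjects ignores within-subject correlation, so a
cluster-aware alternative — an unpaired t-test on the subject-level
proportions — is provided and is the statistically safer choice; the pooled
z-test remains the default for comparability with pooled-pixel reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .errors import NoIntersectionError, ValidationError
from .group_stats import compare_groups
from .phantom import ROI_LIVER, MultispectralStack, ROISet

logger = logging.getLogger(__name__)

GroupData = Sequence[tuple[MultispectralStack, ROISet]]


@dataclass(frozen=True)
class DensityCurve:
    """Estimated intensity density of one group's pooled liver pixels."""

    grid: np.ndarray
    density: np.ndarray
    label: str
    bandwidth: float

    def mode(self) -> float:
        return float(self.grid[np.argmax(self.density)])


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    candidates: tuple[float, ...]
    proportions: dict[str, list[float]]  # per-subject, per group
    counts: dict[str, tuple[int, int]]  # (above, total) pooled per group
    statistic: float
    p_value: float
    method: str


def _pool_pixels(group: GroupData, wavelength_nm: float) -> np.ndarray:
    pools = []
    for stack, roiset in group:
        mask = roiset.mask(ROI_LIVER)
        if not mask.any():
            logger.warning("subject %s has an empty liver mask; skipped",
                           stack.subject_id)
            continue
        pools.append(stack.plane(wavelength_nm)[mask])
    if not pools:
        raise ValidationError("no liver pixels pooled for this group")
    return np.concatenate(pools)


def pooled_density(
    groups: dict[str, GroupData],
    wavelength_nm: float,
    n_grid: int = 512,
    method: str = "kde",
    bins: int = 64,
) -> dict[str, DensityCurve]:
    """Density curve per group on one shared evaluation grid.

    ``method`` is "kde" (Gaussian kernel, Silverman bandwidth) or "histogram"
    (``bins`` equal-width bins over the shared range, density-normalized).
    """
    pools = {label: _pool_pixels(g, wavelength_nm) for label, g in groups.items()}
    all_px = np.concatenate(list(pools.values()))
    curves: dict[str, DensityCurve] = {}
    if method == "kde":
        kdes = {}
        bw = 0.0
        for label, px in pools.items():
            if np.ptp(px) == 0:
                raise ValidationError(
                    f"group {label!r} pixel pool is constant; KDE undefined"
                )
            kde = stats.gaussian_kde(px, bw_method="silverman")
            kdes[label] = kde
            bw = max(bw, float(kde.factor * px.std(ddof=1)))
        lo, hi = all_px.min() - 4 * bw, all_px.max() + 4 * bw
        grid = np.linspace(lo, hi, n_grid)
        for label, kde in kdes.items():
            curves[label] = DensityCurve(
                grid=grid,
                density=kde(grid),
                label=label,
                bandwidth=float(kde.factor * pools[label].std(ddof=1)),
            )
    elif method == "histogram":
        lo, hi = all_px.min(), all_px.max()
        edges = np.linspace(lo, hi, bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        for label, px in pools.items():
            dens, _ = np.histogram(px, bins=edges, density=True)
            curves[label] = DensityCurve(
                grid=centers,
                density=dens.astype(float),
                label=label,
                bandwidth=float(edges[1] - edges[0]),
            )
    else:
        raise ValidationError(f"unknown density method {method!r}")
    return curves


def find_threshold(curve_a: DensityCurve, curve_b: DensityCurve) -> tuple[float, tuple[float, ...]]:
    """Intensity where the two density curves cross between their modes.

    Sign changes of the density difference are located on the shared grid and
    refined by linear interpolation.  When several crossings fall between the
    modes the one closest to the mode midpoint is chosen; all candidates are
    returned.
    """
    if curve_a.grid.shape != curve_b.grid.shape or not np.allclose(
        curve_a.grid, curve_b.grid
    ):
        raise ValidationError("density curves are on different grids")
    grid = curve_a.grid
    mode_a, mode_b = curve_a.mode(), curve_b.mode()
    if mode_a == mode_b:
        raise NoIntersectionError("group modes coincide; no between-mode interval")
    lo, hi = sorted((mode_a, mode_b))
    diff = curve_a.density - curve_b.density
    sel = (grid >= lo) & (grid <= hi)
    idx = np.flatnonzero(sel)
    candidates = []
    for i in idx[:-1]:
        d0, d1 = diff[i], diff[i + 1]
        if d0 == 0:
            candidates.append(float(grid[i]))
        elif d0 * d1 < 0:
            # linear refinement between bracketing grid points
            frac = d0 / (d0 - d1)
            candidates.append(float(grid[i] + frac * (grid[i + 1] - grid[i])))
    if not candidates:
        raise NoIntersectionError(
            f"no density crossing between modes {lo:.4g} and {hi:.4g} "
            f"(min |diff| = {np.abs(diff[sel]).min():.3g})"
        )
    mid = 0.5 * (lo + hi)
    threshold = min(candidates, key=lambda c: abs(c - mid))
    return threshold, tuple(candidates)


def two_proportion_ztest(count_a: int, n_a: int, count_b: int, n_b: int) -> tuple[float, float]:
    """Two-sided pooled two-sample proportion z-test on counts."""
    if min(n_a, n_b) == 0:
        raise ValidationError("empty group in proportions test")
    pooled = (count_a + count_b) / (n_a + n_b)
    if pooled in (0.0, 1.0):
        logger.warning("degenerate proportions (all %s threshold); p = 1",
                       "above" if pooled == 1.0 else "below")
        return 0.0, 1.0
    z, p = proportions_ztest([count_a, count_b], [n_a, n_b], alternative="two-sided")
    return float(z), float(p)


def proportions_above(
    groups: dict[str, GroupData],
    wavelength_nm: float,
    threshold: float,
    candidates: tuple[float, ...] = (),
    method: str = "pooled",
) -> ThresholdResult:
    """Per-subject proportion of liver pixels above ``threshold`` plus group test.

    ``method="pooled"`` runs the two-sample z-test on pooled pixel counts;
    ``method="per_subject"`` runs an unpaired t-test on the subject-level
    proportions (cluster-aware alternative).
    """
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    proportions: dict[str, list[float]] = {}
    counts: dict[str, tuple[int, int]] = {}
    for label, group in groups.items():
        per_subject = []
        above_total, n_total = 0, 0
        for stack, roiset in group:
            mask = roiset.mask(ROI_LIVER)
            if not mask.any():
                logger.warning("subject %s has an empty liver mask; skipped",
                               stack.subject_id)
                continue
            px = stack.plane(wavelength_nm)[mask]
            above = int((px > threshold).sum())
            per_subject.append(above / px.size)
            above_total += above
            n_total += px.size
        proportions[label] = per_subject
        counts[label] = (above_total, n_total)

    labels = list(groups)
    if len(labels) != 2:
        raise ValidationError("proportions test needs exactly two groups")
    (a_above, a_n), (b_above, b_n) = counts[labels[0]], counts[labels[1]]
    if method == "pooled":
        stat, p = two_proportion_ztest(a_above, a_n, b_above, b_n)
    elif method == "per_subject":
        cmp = compare_groups(proportions[labels[0]], proportions[labels[1]])
        stat, p = cmp.t_statistic, cmp.p_two_sided
    else:
        raise ValidationError(f"unknown proportions test method {method!r}")
    return ThresholdResult(
        threshold=float(threshold),
        candidates=tuple(candidates),
        proportions=proportions,
        counts=counts,
        statistic=stat,
        p_value=p,
        method=method,
    )
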