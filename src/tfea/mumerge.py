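"""Consensus-ROI inference from multi-sample interval calls.

Each sample region is modelled as a Gaussian positional density for the
hypothetical underlying locus; replicate densities are multiplied within a
condition, summed across conditions, and the local maxima of the joint
function become the consensus ROI centers.  Widths follow from an
inverse-distance weighted average of the contributing half-widths, and
overlapping ROIs within a group are shrunk symmetrically until disjoint.

The joint function is used only through its relative values (its maxima);
it is not a normalized probability density.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .intervals import GenomicRegion, RegionGroup, SampleRegion, group_overlapping

__all__ = [
    "PositionalDensity",
    "ROI",
    "region_density",
    "joint_density",
    "find_maxima",
    "roi_width",
    "resolve_overlaps",
    "mumerge",
    "write_bed",
]

# floor for a per-replicate factor in the log-product; keeps the product
# finite for large replicate counts without moving any maximum
_FACTOR_FLOOR = 1e-300


@dataclass
class PositionalDensity:
    """A nonnegative function sampled on a regular grid of base positions."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have equal length")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("density values must be finite and >= 0")


@dataclass
class ROI:
    """A consensus region of interest: inferred center, half-width, interval."""

    mu_hat: float
    sigma_hat: float
    region: GenomicRegion
    group_id: str
    joint_value: float


def _group_grid(
    group: RegionGroup, rho: float, step: float = 1.0
) -> np.ndarray:
    """Integer-spaced evaluation grid over the group span, padded by
    3*max(rho*sigma) per side so edge maxima are not clipped."""
    pad = math.ceil(3 * rho * max(r.sigma for r in group.regions))
    return np.arange(group.start - pad, group.stop + pad + step / 2, step)


def region_density(
    r: SampleRegion,
    rho: float = 1.0,
    grid: np.ndarray | None = None,
    group: RegionGroup | None = None,
) -> PositionalDensity:
    """Gaussian positional density of one sample region.

    The region ``(mu, sigma)`` maps to the standard-normal shape
    ``phi((x - mu) / (rho * sigma))``, where the width ratio ``rho``
    (default 1) is the ratio of the region half-width to the standard
    deviation of its Gaussian representation.
    """
    if rho <= 0:
        raise ValueError(f"width ratio rho must be > 0, got {rho}")
    if r.sigma <= 0:
        raise ValueError(f"region half-width must be > 0, got {r.sigma}")
    if grid is None:
        if group is None:
            group = RegionGroup([r], {r.condition_id: [r.sample_id]})
        grid = _group_grid(group, rho)
    values = norm.pdf((grid - r.mu) / (rho * r.sigma))
    return PositionalDensity(grid, values)


def joint_density(
    group: RegionGroup, rho: float = 1.0, step: float = 1.0
) -> PositionalDensity:
    """Joint positional function for a group of overlapping sample regions.

    Within each condition, every replicate contributes the sum of its
    region densities (or the uniform value 1/Delta if it has no region in
    the group); replicate terms are multiplied, and the per-condition
    products are summed.  The replicate product is evaluated as
    exp(sum(log .)) with a per-factor floor, which preserves the positions
    of all maxima; the condition sum is taken in linear space.
    """
    grid = _group_grid(group, rho, step)
    uniform = 1.0 / max(group.span, 1.0)
    log_products = []
    for cond, sample_ids in group.design.items():
        log_product = np.zeros_like(grid)
        for sample_id in sample_ids:
            regs = group.regions_of(sample_id)
            if regs:
                inner = np.zeros_like(grid)
                for r in regs:
                    inner += norm.pdf((grid - r.mu) / (rho * r.sigma))
            else:
                inner = np.full_like(grid, uniform)
            log_product += np.log(np.maximum(inner, _FACTOR_FLOOR))
        log_products.append(log_product)
    # one GLOBAL rescale before exponentiation: a per-condition rescale
    # would distort the condition sum and move its maxima
    peak = max(lp.max() for lp in log_products)
    total = np.zeros_like(grid)
    for lp in log_products:
        total += np.exp(lp - peak)
    return PositionalDensity(grid, total)


def _local_maxima(values: np.ndarray) -> list[tuple[int, float]]:
    """Indices of strict local maxima; plateaus contribute their midpoint."""
    n = len(values)
    if n == 1:
        return [(0, float(values[0]))]
    maxima: list[tuple[int, float]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        left_ok = i == 0 or values[i - 1] < values[i]
        right_ok = j == n - 1 or values[j + 1] < values[i]
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            maxima.append(((i + j) // 2, float(values[i])))
        i = j + 1
    return maxima


def median_regions_per_sample(group: RegionGroup) -> float:
    """Median region count per sample, counting design samples with zero
    regions in the group."""
    counts = [
        len(group.regions_of(s))
        for samples in group.design.values()
        for s in samples
    ]
    return statistics.median(counts)


def find_maxima(
    density: PositionalDensity,
    group: RegionGroup,
    max_per_group: int | None = None,
) -> list[tuple[float, float]]:
    """Candidate ROI centers: local maxima of the joint function, ranked
    descending by value and truncated to the top M+1, M the median region
    count per sample.

    Returns ``(position, joint_value)`` pairs.  A completely flat density
    (no strict maximum) degenerates to the span midpoint.
    """
    maxima = _local_maxima(density.values)
    if not maxima:
        mid_idx = len(density.grid) // 2
        maxima = [(mid_idx, float(density.values[mid_idx]))]
    if max_per_group is None:
        max_per_group = max(1, int(median_regions_per_sample(group)) + 1)
    # stable rank: value descending, then position ascending
    maxima.sort(key=lambda m: (-m[1], density.grid[m[0]]))
    return [
        (float(density.grid[idx]), val)
        for idx, val in maxima[:max_per_group]
    ]


def roi_width(mu_hat: float, group: RegionGroup) -> float:
    """Inverse-distance weighted half-width for a candidate center.

    sigma_hat = sum_i sigma_i/(|mu_hat - mu_i| + 1) / sum_i 1/(|mu_hat - mu_i| + 1)
    over all sample regions in the group (uniform-only samples contribute
    no term).  Lies between min and max of the contributing half-widths.
    """
    if not group.regions:
        raise ValueError("group has no sample regions")
    weights = [1.0 / (abs(mu_hat - r.mu) + 1.0) for r in group.regions]
    num = sum(w * r.sigma for w, r in zip(weights, group.regions))
    return num / sum(weights)


def resolve_overlaps(rois: list[ROI]) -> list[ROI]:
    """Shrink overlapping ROIs symmetrically about their centers until
    disjoint.

    ROIs are processed in center order; centers never move.  Two ROIs with
    identical centers cannot be separated by symmetric shrinking, so the
    one with the larger joint value survives.  An ROI whose half-width is
    driven to zero or below is dropped.
    """
    if len(rois) <= 1:
        return list(rois)
    rois = sorted(rois, key=lambda r: (r.mu_hat, -r.joint_value))
    # identical-center ties: keep highest joint value
    deduped: list[ROI] = []
    for roi in rois:
        if deduped and roi.mu_hat == deduped[-1].mu_hat:
            continue
        deduped.append(roi)

    halves = [r.sigma_hat for r in deduped]
    for a in range(len(deduped) - 1):
        b = a + 1
        overlap = (deduped[a].mu_hat + halves[a]) - (
            deduped[b].mu_hat - halves[b]
        )
        if overlap > 0:
            halves[a] -= overlap / 2
            halves[b] -= overlap / 2

    out: list[ROI] = []
    for roi, half in zip(deduped, halves):
        if half <= 0:
            continue
        if half == roi.sigma_hat:
            out.append(roi)
        else:
            start = max(0, int(round(roi.mu_hat - half)))
            stop = int(round(roi.mu_hat + half))
            if stop <= start:
                continue
            out.append(
                ROI(
                    roi.mu_hat,
                    half,
                    GenomicRegion(roi.region.chrom, start, stop),
                    roi.group_id,
                    roi.joint_value,
                )
            )
    return out


def _process_group(
    group: RegionGroup,
    group_id: str,
    rho: float,
    max_per_group: int | None,
    step: float,
) -> list[ROI]:
    density = joint_density(group, rho, step)
    candidates = find_maxima(density, group, max_per_group)
    rois = []
    for mu_hat, joint_value in candidates:
        sigma_hat = roi_width(mu_hat, group)
        start = max(0, int(round(mu_hat - sigma_hat)))
        stop = int(round(mu_hat + sigma_hat))
        if stop <= start:
            continue
        rois.append(
            ROI(
                mu_hat,
                sigma_hat,
                GenomicRegion(group.chrom, start, stop),
                group_id,
                joint_value,
            )
        )
    return resolve_overlaps(rois)


def mumerge(
    samples: Mapping[str, Sequence[SampleRegion]],
    design: Mapping[str, Sequence[str]] | None = None,
    rho: float = 1.0,
    max_per_group: int | None = None,
    step: float = 1.0,
) -> list[ROI]:
    """Infer consensus ROIs from per-sample region calls.

    Deterministic: groups overlapping regions, evaluates the joint
    positional function per group, keeps its ranked maxima, assigns widths
    and resolves intra-group overlaps.  Output is sorted by (chrom, start).
    """
    groups = group_overlapping(samples, design)
    if not groups:
        raise ValueError("no sample regions provided")
    rois: list[ROI] = []
    for g_idx, group in enumerate(groups):
        group_id = f"{group.chrom}:{group.start}-{group.stop}"
        rois.extend(_process_group(group, group_id, rho, max_per_group, step))
    rois.sort(key=lambda r: (r.region.chrom, r.region.start))
    return rois


def write_bed(rois: Sequence[ROI], path: str | Path) -> None:
    """Write ROIs as BED4+score (name = group_id:rank, score = joint value)."""
    rank_in_group: dict[str, int] = {}
    with open(path, "w") as fh:
        for roi in rois:
            rank = rank_in_group.get(roi.group_id, 0)
            rank_in_group[roi.group_id] = rank + 1
            fh.write(
                f"{roi.region.chrom}\t{roi.region.start}\t{roi.region.stop}"
                f"\t{roi.group_id}:{rank}\t{roi.joint_value:.6g}\n"
            )
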