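"""Genomic-interval data model, BED I/O and overlap grouping.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, stop)``.  "Overlap" means an intersection of positive length, so
abutting intervals (``stop == start``) do *not* overlap.  Strand is ignored:
regions of interest mark bidirectional initiation zones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GenomicRegion",
    "SampleRegion",
    "RegionGroup",
    "BedParseError",
    "read_bed",
    "read_design",
    "group_overlapping",
]


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval ``[start, stop)`` on one chromosome."""

    chrom: str
    start: int
    stop: int
    annotation: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.stop <= self.start:
            raise ValueError(
                f"stop must be > start, got [{self.start}, {self.stop})"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.stop) / 2

    @property
    def half_width(self) -> float:
        return (self.stop - self.start) / 2

    def overlaps(self, other: "GenomicRegion") -> bool:
        """Positive-length intersection on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.stop
            and other.start < self.stop
        )


@dataclass(frozen=True)
class SampleRegion:
    """One interval called in one sample, as a (midpoint, half-width) pair.

    The midpoint ``mu`` and half-width ``sigma`` are kept as floats:
    odd-length regions have fractional centers and the downstream density
    model operates on continuous positions.
    """

    region: GenomicRegion
    sample_id: str
    condition_id: str

    @property
    def mu(self) -> float:
        return self.region.midpoint

    @property
    def sigma(self) -> float:
        return self.region.half_width


@dataclass
class RegionGroup:
    """A transitively connected set of overlapping sample regions.

    ``design`` maps condition_id -> sample_ids and includes samples that
    contribute no region to this group; those samples enter the joint
    density as a uniform term over the group span.
    """

    regions: list[SampleRegion]
    design: dict[str, list[str]]
    chrom: str = field(init=False)
    start: int = field(init=False)
    stop: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("RegionGroup requires at least one region")
        chroms = {r.region.chrom for r in self.regions}
        if len(chroms) != 1:
            raise ValueError(f"regions span multiple chromosomes: {chroms}")
        self.chrom = chroms.pop()
        self.start = min(r.region.start for r in self.regions)
        self.stop = max(r.region.stop for r in self.regions)

    @property
    def span(self) -> float:
        """Full range Delta encompassed by the grouped regions (bp)."""
        return float(self.stop - self.start)

    def regions_of(self, sample_id: str) -> list[SampleRegion]:
        return [r for r in self.regions if r.sample_id == sample_id]


def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Read a BED3+ file, preserving order and extra columns.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped.
    Malformed data lines raise :class:`BedParseError` naming the 1-based
    line number.
    """
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 columns, got {len(fields)}"
                )
            try:
                start, stop = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from exc
            try:
                region = GenomicRegion(
                    fields[0], start, stop, annotation=tuple(fields[3:])
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            regions.append(region)
    return regions


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a design table (TSV: sample_id, condition_id, bed_path)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample_id", "condition_id", "bed_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in design table")
    return df


def design_mapping(design: pd.DataFrame) -> dict[str, list[str]]:
    """condition_id -> list of sample_ids, in table order."""
    return {
        cond: list(sub["sample_id"])
        for cond, sub in design.groupby("condition_id", sort=False)
    }


def load_samples(design: pd.DataFrame) -> dict[str, list[SampleRegion]]:
    """Read each sample's BED file and label regions with the design."""
    samples: dict[str, list[SampleRegion]] = {}
    for row in design.itertuples(index=False):
        regions = read_bed(row.bed_path)
        samples[row.sample_id] = [
            SampleRegion(r, row.sample_id, row.condition_id) for r in regions
        ]
    return samples


def group_overlapping(
    samples: Mapping[str, Sequence[SampleRegion]],
    design: Mapping[str, Sequence[str]] | None = None,
) -> list[RegionGroup]:
    """Partition sample regions into transitively overlapping groups.

    A sweep over start-sorted intervals per chromosome yields exactly the
    connected components of the pairwise-overlap graph.  Groups are returned
    sorted by (chrom, start); the result is invariant to input order.
    """
    all_regions = [r for regs in samples.values() for r in regs]
    if not all_regions:
        return []
    if design is None:
        design = _design_from(samples)
    design_dict = {c: list(s) for c, s in design.items()}

    by_chrom: dict[str, list[SampleRegion]] = {}
    for r in all_regions:
        by_chrom.setdefault(r.region.chrom, []).append(r)

    groups: list[RegionGroup] = []
    for chrom in sorted(by_chrom):
        regs = sorted(
            by_chrom[chrom], key=lambda r: (r.region.start, r.region.stop)
        )
        current: list[SampleRegion] = [regs[0]]
        reach = regs[0].region.stop
        for r in regs[1:]:
            if r.region.start < reach:  # strict: touching does not group
                current.append(r)
                reach = max(reach, r.region.stop)
            else:
                groups.append(RegionGroup(current, design_dict))
                current = [r]
                reach = r.region.stop
        groups.append(RegionGroup(current, design_dict))
    return groups


def _design_from(
    samples: Mapping[str, Sequence[SampleRegion]],
) -> dict[str, list[str]]:
    design: dict[str, list[str]] = {}
    for sample_id, regs in samples.items():
        conds = {r.condition_id for r in regs}
        if len(conds) > 1:
            raise ValueError(
                f"sample {sample_id!r} carries multiple conditions: {conds}"
            )
        cond = conds.pop() if conds else "condition"
        design.setdefault(cond, []).append(sample_id)
    return design
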