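"""Ranking ROIs by differential signal.

The enrichment statistic only consumes an ordering, so this module either
ingests a DESeq2-style results table (the recommended route) or computes a
clearly labeled fallback statistic from raw counts.  The default ranking
runs from the most significant positive fold-change to the most
significant negative fold-change: positive-LFC records by p ascending,
then zero-LFC records, then negative-LFC records by p descending.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DifferentialRecord",
    "rank_rois",
    "read_differential_table",
    "count_reads",
    "fallback_differential",
]

_MIN_P = sys.float_info.min


@dataclass(frozen=True)
class DifferentialRecord:
    """Per-ROI differential signal: p-value and signed log2 fold change."""

    roi_id: str
    p_value: float
    log_fold_change: float
    base_mean: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError(
                f"{self.roi_id}: p_value must be in (0, 1], got {self.p_value}"
            )


def rank_rois(
    records: Sequence[DifferentialRecord], mode: str = "pvalue"
) -> list[DifferentialRecord]:
    """Order records most-significant-positive first.

    ``pvalue`` mode: positive LFC by p ascending, zero LFC at the
    boundary, negative LFC by p descending.  ``fold_change`` mode: by
    descending signed LFC.  Ties break lexicographically on roi_id.
    """
    if not records:
        raise ValueError("no records to rank")
    ids = [r.roi_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate roi_id in differential records")
    if mode == "pvalue":

        def key(r: DifferentialRecord):
            if r.log_fold_change > 0:
                return (0, r.p_value, r.roi_id)
            if r.log_fold_change == 0:
                return (1, 0.0, r.roi_id)
            return (2, -r.p_value, r.roi_id)

    elif mode == "fold_change":

        def key(r: DifferentialRecord):
            return (-r.log_fold_change, r.roi_id)

    else:
        raise ValueError(f"unknown ranking mode {mode!r}")
    return sorted(records, key=key)


def read_differential_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> list[DifferentialRecord]:
    """Read a DESeq2-style results TSV.

    ``columns`` remaps the expected names {id, pvalue, log2FoldChange,
    baseMean} to the file's actual headers (e.g. pvalue -> padj to rank on
    adjusted p).  Zero p-values (underflow in the upstream fit) are
    clamped to the smallest positive float.
    """
    colmap = {
        "id": "id",
        "pvalue": "pvalue",
        "log2FoldChange": "log2FoldChange",
        "baseMean": "baseMean",
    }
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t")
    for want in ("id", "pvalue", "log2FoldChange"):
        if colmap[want] not in df.columns:
            raise ValueError(
                f"{path}: missing column {colmap[want]!r} (for {want})"
            )
    has_mean = colmap["baseMean"] in df.columns
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        p = float(d[colmap["pvalue"]])
        if np.isnan(p):
            continue  # DESeq2 reports NA for filtered/outlier rows
        records.append(
            DifferentialRecord(
                str(d[colmap["id"]]),
                max(p, _MIN_P),
                float(d[colmap["log2FoldChange"]]),
                float(d[colmap["baseMean"]]) if has_mean else None,
            )
        )
    return records


def count_reads(
    rois: Sequence[tuple[str, int, int]],
    bam_paths: Sequence[str | Path],
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read counts per ROI per alignment file (overlap >= 1 bp).

    ``rois`` are (chrom, start, stop) triples; alignment files must be
    coordinate-sorted and indexed.  Returns a DataFrame indexed by
    "chrom:start-stop" with one column per sample.
    """
    import pysam

    if sample_ids is None:
        sample_ids = [Path(p).stem for p in bam_paths]
    index = [f"{c}:{s}-{e}" for c, s, e in rois]
    data: dict[str, list[int]] = {}
    for sample, path in zip(sample_ids, bam_paths):
        with pysam.AlignmentFile(str(path)) as bam:
            if not bam.has_index():
                raise ValueError(f"{path}: missing index (.bai/.csi)")
            data[sample] = [
                bam.count(chrom, start, stop) for chrom, start, stop in rois
            ]
    return pd.DataFrame(data, index=index)


def fallback_differential(
    counts: pd.DataFrame, design: Mapping[str, Sequence[str]]
) -> list[DifferentialRecord]:
    """Simple two-condition differential statistic from raw counts.

    NOT a DESeq fit: counts are library-size normalized (to the mean
    library size), LFC = log2((mean_B + 0.5) / (mean_A + 0.5)), and the
    p-value is a two-sided Welch t-test on log2(normalized + 0.5) when
    both conditions have >= 2 replicates (1.0 otherwise, leaving only the
    LFC ordering).  Condition order follows the design mapping: the first
    key is the reference (A).
    """
    conditions = list(design)
    if len(conditions) != 2:
        raise ValueError(
            f"fallback statistic needs exactly 2 conditions, got {len(conditions)}"
        )
    cond_a, cond_b = conditions
    cols_a, cols_b = list(design[cond_a]), list(design[cond_b])
    missing = (set(cols_a) | set(cols_b)) - set(counts.columns)
    if missing:
        raise ValueError(f"samples missing from counts table: {sorted(missing)}")

    lib = counts.sum(axis=0).astype(float)
    norm = counts / lib * lib.mean()
    mean_a = norm[cols_a].mean(axis=1)
    mean_b = norm[cols_b].mean(axis=1)
    lfc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    base_mean = norm[cols_a + cols_b].mean(axis=1)

    can_test = len(cols_a) >= 2 and len(cols_b) >= 2
    if can_test:
        log_a = np.log2(norm[cols_a] + 0.5)
        log_b = np.log2(norm[cols_b] + 0.5)
        pvals = stats.ttest_ind(
            log_b, log_a, axis=1, equal_var=False
        ).pvalue
        pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    else:
        pvals = np.ones(len(counts))

    return [
        DifferentialRecord(
            str(roi_id), max(float(p), _MIN_P), float(l), float(bm)
        )
        for roi_id, p, l, bm in zip(counts.index, pvals, lfc, base_mean)
    ]
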