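"""RNA-seq sample exclusion from precomputed QC metrics.

This module does not compute raw-read metrics; it ingests a metrics table
(one row per sample, any upstream QC tool) and applies the exclusion
logic: a minimum transcriptome capture efficiency (fraction of reads
uniquely mapped to the transcriptome, default 0.70, inclusive) and a
maximum absolute difference in duplication rate between R1 and R2 of a
paired-end sample, plus pass-through boolean flags for adapter
contamination, coverage uniformity and insert-size anomalies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .annotation_db import DataError


@dataclass
class SampleMetrics:
    sample_id: str
    mean_base_quality: float
    gc_percent: float
    adapter_flag: bool
    dup_rate_r1: float
    dup_rate_r2: float
    uniquely_mapped_fraction: float
    coverage_uniformity_flag: bool = False
    insert_size_flag: bool = False

    def __post_init__(self) -> None:
        for name in ("dup_rate_r1", "dup_rate_r2", "uniquely_mapped_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(
                    f"sample {self.sample_id}: {name}={v} outside [0, 1]"
                )


@dataclass
class QcThresholds:
    """Exclusion thresholds.

    The R1/R2 duplication-difference cutoff is not a published constant;
    0.10 absolute is the package default and is configurable.
    """

    min_capture_efficiency: float = 0.70
    max_r1_r2_dup_diff: float = 0.10

    def __post_init__(self) -> None:
        for name in ("min_capture_efficiency", "max_r1_r2_dup_diff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name}={v} outside [0, 1]")


def evaluate_sample(m: SampleMetrics,
                    t: QcThresholds | None = None) -> tuple[bool, list[str]]:
    """Evaluate one sample; returns (passed, reasons for every violated rule)."""
    t = t or QcThresholds()
    reasons = []
    if m.uniquely_mapped_fraction < t.min_capture_efficiency:
        reasons.append("capture_efficiency")
    if abs(m.dup_rate_r1 - m.dup_rate_r2) > t.max_r1_r2_dup_diff:
        reasons.append("r1_r2_dup_difference")
    if m.adapter_flag:
        reasons.append("adapter_contamination")
    if m.coverage_uniformity_flag:
        reasons.append("coverage_uniformity")
    if m.insert_size_flag:
        reasons.append("insert_size")
    return (not reasons, reasons)


def filter_samples(metrics: Iterable[SampleMetrics],
                   t: QcThresholds | None = None
                   ) -> tuple[list[SampleMetrics], list[tuple[SampleMetrics, list[str]]]]:
    """Partition samples into (kept, excluded-with-reasons)."""
    t = t or QcThresholds()
    metrics = list(metrics)
    seen = set()
    for m in metrics:
        if m.sample_id in seen:
            raise DataError(f"duplicate sample_id {m.sample_id!r}")
        seen.add(m.sample_id)
    kept, excluded = [], []
    for m in metrics:
        ok, reasons = evaluate_sample(m, t)
        if ok:
            kept.append(m)
        else:
            excluded.append((m, reasons))
    return kept, excluded


METRICS_COLUMNS = [
    "sample_id", "mean_base_quality", "gc_percent", "adapter_flag",
    "dup_rate_r1", "dup_rate_r2", "uniquely_mapped_fraction",
    "coverage_uniformity_flag", "insert_size_flag",
]


def read_metrics(path: str | Path) -> list[SampleMetrics]:
    """Read the documented metrics TSV schema (one row per sample)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(METRICS_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing metrics columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(SampleMetrics(
            sample_id=str(row["sample_id"]),
            mean_base_quality=float(row["mean_base_quality"]),
            gc_percent=float(row["gc_percent"]),
            adapter_flag=bool(row["adapter_flag"]),
            dup_rate_r1=float(row["dup_rate_r1"]),
            dup_rate_r2=float(row["dup_rate_r2"]),
            uniquely_mapped_fraction=float(row["uniquely_mapped_fraction"]),
            coverage_uniformity_flag=bool(row["coverage_uniformity_flag"]),
            insert_size_flag=bool(row["insert_size_flag"]),
        ))
    return out


def write_report(kept, excluded, path: str | Path) -> None:
    rows = [{"sample_id": m.sample_id, "status": "kept", "reasons": ""}
            for m in kept]
    rows += [{"sample_id": m.sample_id, "status": "excluded",
              "reasons": ";".join(r)} for m, r in excluded]
    pd.DataFrame(rows).sort_values("sample_id").to_csv(path, sep="\t", index=False)
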