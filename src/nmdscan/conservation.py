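"""Exon conservation partitioning and per-base score averaging.

Partitions exons into three mutually exclusive sets -- (1) exons whose
inclusion triggers NMD (poison exons), (2) alternatively spliced exons
that do not trigger NMD, and (3) the remaining protein-coding
(constitutive) exons -- then averages a per-base conservation score
(phastCons-style, values in [0, 1]) over each exon and summarizes the
fraction of exons whose mean meets a conservation threshold
(default 0.8, inclusive).

The score track is read from bedGraph or fixed-step wiggle text; bases
without data are distinguished from score 0 and excluded from means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .annotation_db import (
    DataError,
    GenomicInterval,
    TranscriptDatabase,
)
from .event_catalog import ASEvent

DEFAULT_CONSERVED_THRESHOLD = 0.8


@dataclass
class ConservationConfig:
    conserved_threshold: float = DEFAULT_CONSERVED_THRESHOLD


class ConservationTrack:
    """Per-chromosome sorted, non-overlapping runs of per-base scores."""

    def __init__(self) -> None:
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_runs(cls, runs: Iterable[tuple[str, int, int, float]]
                  ) -> "ConservationTrack":
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, score in runs:
            if end <= start:
                raise DataError(f"empty run {chrom}:{start}-{end}")
            if not 0.0 <= score <= 1.0:
                raise DataError(
                    f"score {score} at {chrom}:{start}-{end} outside [0, 1]"
                )
            per_chrom.setdefault(chrom, []).append((start, end, score))
        track = cls()
        for chrom, items in per_chrom.items():
            items.sort()
            prev_end = -1
            for s, e, _ in items:
                if s < prev_end:
                    raise DataError(f"overlapping score runs on {chrom} at {s}")
                prev_end = e
            starts = np.array([s for s, _, _ in items], dtype=np.int64)
            ends = np.array([e for _, e, _ in items], dtype=np.int64)
            scores = np.array([v for _, _, v in items], dtype=np.float64)
            track._runs[chrom] = (starts, ends, scores)
        return track

    def scores(self, interval: GenomicInterval) -> np.ndarray:
        """Per-base scores over the interval; NaN where the track has no data."""
        out = np.full(len(interval), np.nan)
        runs = self._runs.get(interval.chrom)
        if runs is None:
            return out
        starts, ends, scores = runs
        i = max(0, int(np.searchsorted(ends, interval.start, side="right")))
        while i < len(starts) and starts[i] < interval.end:
            lo = max(starts[i], interval.start)
            hi = min(ends[i], interval.end)
            if lo < hi:
                out[lo - interval.start:hi - interval.start] = scores[i]
            i += 1
        return out


def load_score_track(path: str | Path,
                     dialect: str = "bedgraph") -> ConservationTrack:
    """Load a score track from bedGraph (half-open) or fixed-step wiggle."""
    runs: list[tuple[str, int, int, float]] = []
    if dialect == "bedgraph":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split()
                if len(fields) != 4:
                    raise DataError(
                        f"{path} line {lineno}: bedGraph needs 4 columns"
                    )
                runs.append((fields[0], int(fields[1]), int(fields[2]),
                             float(fields[3])))
    elif dialect == "fixed_wig":
        chrom, pos, step, span = None, 0, 1, 1
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                if line.startswith("fixedStep"):
                    kv = dict(tok.split("=") for tok in line.split()[1:])
                    chrom = kv["chrom"]
                    pos = int(kv["start"]) - 1  # wiggle is 1-based
                    step = int(kv.get("step", 1))
                    span = int(kv.get("span", 1))
                    continue
                if chrom is None:
                    raise DataError(
                        f"{path} line {lineno}: value before fixedStep header"
                    )
                runs.append((chrom, pos, pos + span, float(line)))
                pos += step
    else:
        raise DataError(f"unknown track dialect {dialect!r}")
    return ConservationTrack.from_runs(runs)


# ---------------------------------------------------------------------------
# exon set partition
# ---------------------------------------------------------------------------

@dataclass
class ExonSetPartition:
    """Three mutually exclusive exon sets (deduplicated coordinates)."""

    set1: set[GenomicInterval]  # NMD-inclusion (poison) exons
    set2: set[GenomicInterval]  # non-NMD alternatively spliced exons
    set3: set[GenomicInterval]  # remaining protein-coding exons


def partition_exon_sets(db: TranscriptDatabase,
                        labeled_events: Iterable[tuple[ASEvent, str]]
                        ) -> ExonSetPartition:
    """Build the three mutually exclusive exon sets.

    set1 collects the alternative exons of EI_NMD events; set2 the
    alternative exons of non-NMD cassette events (NMD membership wins
    when an exon appears in both); set3 is every exon of every
    protein-coding transcript minus set1 and set2.  Exons are
    deduplicated by (chrom, start, end, strand).
    """
    set1: set[GenomicInterval] = set()
    set2: set[GenomicInterval] = set()
    for ev, label in labeled_events:
        if ev.event_type != "SE":
            continue
        if label == "EI_NMD":
            set1.add(ev.alt_region)
        elif label == "cassette_exon":
            set2.add(ev.alt_region)
    set2 -= set1
    set3: set[GenomicInterval] = set()
    for tx in db:
        if tx.biotype == "protein_coding":
            set3.update(tx.exons)
    set3 -= set1
    set3 -= set2
    return ExonSetPartition(set1, set2, set3)


# ---------------------------------------------------------------------------
# averaging and summaries
# ---------------------------------------------------------------------------

def mean_conservation(interval: GenomicInterval, track: ConservationTrack,
                      flank: int = 0) -> tuple[Optional[float], float]:
    """Mean score over the spliced region (exon body, optionally +- flank).

    Returns (mean over bases with data, fraction of bases without data);
    the mean is None when no base has data.
    """
    region = interval
    if flank:
        region = GenomicInterval(
            interval.chrom, max(0, interval.start - flank),
            interval.end + flank, interval.strand,
        )
    vals = track.scores(region)
    nodata = float(np.isnan(vals).mean())
    if nodata == 1.0:
        return None, nodata
    return float(np.nanmean(vals)), nodata


def conserved_fraction(exons: Iterable[GenomicInterval],
                       track: ConservationTrack,
                       cfg: ConservationConfig | None = None,
                       flank: int = 0
                       ) -> tuple[Optional[float], list[float]]:
    """Fraction of exons with defined mean score >= threshold.

    Returns (fraction, per-exon means for density plotting); fraction is
    None when no exon has a defined mean.
    """
    cfg = cfg or ConservationConfig()
    means = []
    for exon in sorted(exons):
        m, _ = mean_conservation(exon, track, flank=flank)
        if m is not None:
            means.append(m)
    if not means:
        return None, means
    n_conserved = sum(1 for m in means if m >= cfg.conserved_threshold)
    return n_conserved / len(means), means


def write_bed(exons: Iterable[GenomicInterval], path: str | Path,
              name: str = ".") -> None:
    lines = [
        f"{e.chrom}\t{e.start}\t{e.end}\t{name}\t0\t{e.strand}"
        for e in sorted(exons)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
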