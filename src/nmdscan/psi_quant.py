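"""Percent-spliced-in (PSI) quantification of NMD-inducing events.

Reads STAR ``SJ.out.tab`` splice-junction count tables, aggregates counts
per event with role-aware pooling, computes the event-type-specific PSI
estimators, applies the abundance filters (minimum uniquely-mapped read
pairs on the NMD-supporting junctions and minimum non-productive PSI),
and summarizes a unique-gene catalog.

Estimators
----------
Cassette (SE) events::

    psi = sj_inc / (sj_inc + 2 * sj_skip)

where ``sj_inc`` sums both inclusion junctions; the factor 2 compensates
for each isoform copy contributing reads to two inclusion junctions but
only one skipping junction.  For NMD-inducing skipping, the reported
value is ``1 - psi``.  Alternative splice sites::

    psi = sj_nmd / (sj_nmd + sj_coding)

Alternative introns (exitrons), with exon expression estimated from the
host exon's flanking junctions::

    expr = (sj_3p + sj_5p) / 2
    psi  = min(sj_ai, expr) / expr
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .annotation_db import DataError, JunctionKey
from .event_catalog import ASEvent

logger = logging.getLogger(__name__)

UNDEFINED = None

#: labels quantified downstream; dropped_complex and non-NMD labels are not.
QUANTIFIED_LABELS = ("EI_NMD", "ES_NMD", "A3_NMD", "A5_NMD", "AI_NMD")

_STRAND_CODES = {0: ".", 1: "+", 2: "-"}


class CountTableError(ValueError):
    """Malformed junction-count input."""


@dataclass
class FilterConfig:
    """Event reporting thresholds.

    ``min_junction_reads``: minimum summed uniquely-mapped read pairs on
    the NMD-supporting junction role(s); default 3.  ``min_psi``: minimum
    non-productive PSI; default 0.03.  Both thresholds are inclusive.
    ``min_reads_scope`` selects whether the read filter applies to the
    NMD-supporting role only (default) or to every junction role.
    """

    min_junction_reads: int = 3
    min_psi: float = 0.03
    min_reads_scope: str = "nmd_role"

    def __post_init__(self) -> None:
        if self.min_junction_reads < 0:
            raise DataError("min_junction_reads must be >= 0")
        if not 0.0 <= self.min_psi <= 1.0:
            raise DataError("min_psi must be in [0, 1]")
        if self.min_reads_scope not in ("nmd_role", "all_roles"):
            raise DataError(f"unknown min_reads_scope {self.min_reads_scope!r}")


class JunctionCountTable:
    """Per-sample uniquely-mapped read counts keyed by junction."""

    def __init__(self, sample_id: str,
                 counts: dict[JunctionKey, int] | None = None,
                 allow_undefined_strand: bool = False) -> None:
        self.sample_id = sample_id
        self.counts: dict[JunctionKey, int] = dict(counts or {})
        self.allow_undefined_strand = allow_undefined_strand

    def __len__(self) -> int:
        return len(self.counts)

    def get(self, jk: JunctionKey) -> int:
        """Count for a junction; absent junctions contribute 0.

        Rows with undefined strand (STAR code 0) match a stranded query
        only when ``allow_undefined_strand`` is set.
        """
        if jk in self.counts:
            return self.counts[jk]
        if self.allow_undefined_strand and jk.strand != ".":
            return self.counts.get(
                JunctionKey(jk.chrom, jk.start, jk.end, "."), 0
            )
        return 0


def read_star_sj(path: str | Path, sample_id: str,
                 allow_undefined_strand: bool = False) -> JunctionCountTable:
    """Read a STAR ``SJ.out.tab`` file.

    Columns: chrom, intron first base (1-based), intron last base
    (1-based), strand code {0: undefined, 1: +, 2: -}, intron motif code,
    annotated flag, uniquely-mapped reads, multi-mapped reads, maximum
    spliced overhang.  Counts are taken from the unique-reads column.
    """
    counts: dict[JunctionKey, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise CountTableError(
                    f"{path} line {lineno}: expected 9 columns, got {len(fields)}"
                )
            try:
                first, last = int(fields[1]), int(fields[2])
                strand = _STRAND_CODES[int(fields[3])]
                unique = int(fields[6])
            except (ValueError, KeyError) as exc:
                raise CountTableError(
                    f"{path} line {lineno}: malformed field: {exc}"
                ) from exc
            if unique < 0:
                raise CountTableError(
                    f"{path} line {lineno}: negative unique-read count"
                )
            jk = JunctionKey(fields[0], first - 1, last, strand)
            counts[jk] = counts.get(jk, 0) + unique
    return JunctionCountTable(sample_id, counts, allow_undefined_strand)


# ---------------------------------------------------------------------------
# PSI estimators
# ---------------------------------------------------------------------------

def psi_cassette(sj_inc: int, sj_skip: int, orientation: str = "EI") -> Optional[float]:
    """Cassette-exon PSI; ``orientation`` 'EI' for inclusion, 'ES' for 1-psi."""
    if sj_inc < 0 or sj_skip < 0:
        raise DataError("junction counts must be non-negative")
    if orientation not in ("EI", "ES"):
        raise DataError(f"orientation must be 'EI' or 'ES', got {orientation!r}")
    if sj_inc + sj_skip == 0:
        return UNDEFINED
    psi = sj_inc / (sj_inc + 2 * sj_skip)
    return psi if orientation == "EI" else 1.0 - psi


def psi_alt_ss(sj_nmd: int, sj_coding: int) -> Optional[float]:
    """Alternative 3'/5' splice-site PSI (NMD junction over both)."""
    if sj_nmd < 0 or sj_coding < 0:
        raise DataError("junction counts must be non-negative")
    if sj_nmd + sj_coding == 0:
        return UNDEFINED
    return sj_nmd / (sj_nmd + sj_coding)


def psi_alt_intron(sj_ai: int, sj_3p: int, sj_5p: int) -> Optional[float]:
    """Alternative-intron (exitron) PSI, clipped by exon expression."""
    if min(sj_ai, sj_3p, sj_5p) < 0:
        raise DataError("junction counts must be non-negative")
    expr = (sj_3p + sj_5p) / 2.0
    if expr == 0:
        return UNDEFINED
    return min(sj_ai, expr) / expr


# ---------------------------------------------------------------------------
# per-event aggregation
# ---------------------------------------------------------------------------

@dataclass
class PsiRecord:
    """Per-event, per-sample counts, PSI and filter status."""

    event_id: str
    sample_id: str
    gene_id: str
    label: str
    counts: dict[str, int] = field(default_factory=dict)
    psi: Optional[float] = None
    nmd_role_count: int = 0
    passed_filters: bool = False
    fail_reasons: list[str] = field(default_factory=list)


@dataclass
class _EventGroup:
    """Merged events sharing the same alternatively spliced region and label."""

    event_id: str        # lexicographically first member id
    gene_id: str
    label: str
    inc_junctions: set = field(default_factory=set)   # SE
    skip_junctions: set = field(default_factory=set)  # SE
    nmd_junctions: set = field(default_factory=set)   # A3/A5
    coding_junctions: set = field(default_factory=set)
    ai_junction: Optional[JunctionKey] = None          # RI
    flank_3p: set = field(default_factory=set)
    flank_5p: set = field(default_factory=set)


def group_events(events_with_labels: Iterable[tuple[ASEvent, str]],
                 labels=None) -> list[_EventGroup]:
    """Merge classified events for counting.

    SE events sharing the same alternatively spliced exon (and label) are
    pooled, and RI events sharing the same alternative-intron junction
    pool the flanking junctions of all parent exons.  ``dropped_complex``
    and non-NMD events never enter a group.
    """
    groups: dict[tuple, _EventGroup] = {}
    for ev, label in events_with_labels:
        if label not in QUANTIFIED_LABELS:
            continue
        if ev.event_type == "SE":
            key = ("SE", ev.chrom, ev.strand, ev.alt_region.start,
                   ev.alt_region.end, label)
        elif ev.event_type == "RI":
            j = ev.junctions["ai_junction"]
            key = ("RI", ev.chrom, ev.strand, j.start, j.end, label)
        else:
            key = (ev.event_type,) + ev.dedup_key[1:] + (label,)
        g = groups.get(key)
        if g is None:
            g = groups[key] = _EventGroup(ev.event_id, ev.gene_id, label)
        elif ev.event_id < g.event_id:
            g.event_id = ev.event_id
        j = ev.junctions
        if ev.event_type == "SE":
            g.inc_junctions.update((j["inclusion_upstream"], j["inclusion_downstream"]))
            g.skip_junctions.add(j["skipping"])
        elif ev.event_type in ("A3", "A5"):
            if labels is None:
                raise DataError("label table required to orient A3/A5 junctions")
            for role in ("long_junction", "short_junction"):
                (g.nmd_junctions if labels.is_nmd(j[role]) else
                 g.coding_junctions).add(j[role])
        else:
            g.ai_junction = j["ai_junction"]
            g.flank_3p.update(j["flanking_3p"])
            g.flank_5p.update(j["flanking_5p"])
    return sorted(groups.values(), key=lambda g: g.event_id)


def quantify_sample(events_with_labels: Iterable[tuple[ASEvent, str]],
                    counts: JunctionCountTable,
                    cfg: FilterConfig | None = None,
                    labels=None) -> list[PsiRecord]:
    """Compute per-event PSI records for one sample and apply filters."""
    cfg = cfg or FilterConfig()
    records = []
    for g in group_events(events_with_labels, labels=labels):
        rec = PsiRecord(g.event_id, counts.sample_id, g.gene_id, g.label)
        if g.label in ("EI_NMD", "ES_NMD"):
            sj_inc = sum(counts.get(j) for j in sorted(g.inc_junctions))
            sj_skip = sum(counts.get(j) for j in sorted(g.skip_junctions))
            rec.counts = {"sj_inc": sj_inc, "sj_skip": sj_skip}
            orientation = "EI" if g.label == "EI_NMD" else "ES"
            rec.psi = psi_cassette(sj_inc, sj_skip, orientation)
            rec.nmd_role_count = sj_inc if g.label == "EI_NMD" else sj_skip
        elif g.label in ("A3_NMD", "A5_NMD"):
            sj_nmd = sum(counts.get(j) for j in sorted(g.nmd_junctions))
            sj_coding = sum(counts.get(j) for j in sorted(g.coding_junctions))
            rec.counts = {"sj_nmd": sj_nmd, "sj_coding": sj_coding}
            rec.psi = psi_alt_ss(sj_nmd, sj_coding)
            rec.nmd_role_count = sj_nmd
        else:  # AI_NMD
            sj_ai = counts.get(g.ai_junction)
            sj_3p = sum(counts.get(j) for j in sorted(g.flank_3p))
            sj_5p = sum(counts.get(j) for j in sorted(g.flank_5p))
            rec.counts = {"sj_ai": sj_ai, "sj_3p": sj_3p, "sj_5p": sj_5p}
            rec.psi = psi_alt_intron(sj_ai, sj_3p, sj_5p)
            rec.nmd_role_count = sj_ai
        records.append(rec)
    return apply_filters(records, cfg)


def apply_filters(records: list[PsiRecord],
                  cfg: FilterConfig | None = None) -> list[PsiRecord]:
    """Mark each record pass/fail; failing records are kept with reasons."""
    cfg = cfg or FilterConfig()
    for rec in records:
        reasons = []
        if rec.psi is None:
            reasons.append("zero_denominator")
        elif rec.psi < cfg.min_psi:
            reasons.append("min_psi")
        read_pool = (
            rec.nmd_role_count
            if cfg.min_reads_scope == "nmd_role"
            else min(rec.counts.values())
        )
        if read_pool < cfg.min_junction_reads:
            reasons.append("min_reads")
        rec.fail_reasons = reasons
        rec.passed_filters = not reasons
    return records


# ---------------------------------------------------------------------------
# multi-sample catalog
# ---------------------------------------------------------------------------

def records_to_frame(records: Iterable[PsiRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "event_id": r.event_id,
            "sample_id": r.sample_id,
            "gene_id": r.gene_id,
            "label": r.label,
            "psi": float("nan") if r.psi is None else r.psi,
            "nmd_role_count": r.nmd_role_count,
            "passed_filters": r.passed_filters,
            "fail_reasons": ";".join(r.fail_reasons),
            **{k: v for k, v in r.counts.items()},
        })
    cols = ["event_id", "sample_id", "gene_id", "label", "psi",
            "nmd_role_count", "passed_filters", "fail_reasons",
            "sj_inc", "sj_skip", "sj_nmd", "sj_coding",
            "sj_ai", "sj_3p", "sj_5p"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = float("nan")
    return df[cols] if len(df) else pd.DataFrame(columns=cols)


def summarize_gene_catalog(psi: pd.DataFrame,
                           disease_flags: dict[str, bool] | None = None
                           ) -> tuple[pd.DataFrame, dict]:
    """Build the gene-level catalog from per-sample PSI records.

    An event is catalogued if it passes the filters in at least one
    sample; its reported PSI is the maximum across passing samples.  The
    headline counters count each gene once even when it carries several
    event types, while the per-type tallies allow a gene in several
    types.
    """
    passed = psi[psi["passed_filters"].astype(bool)]
    if len(passed) == 0:
        catalog = pd.DataFrame(
            columns=["gene_id", "event_id", "label", "max_psi", "n_passing_samples"]
        )
    else:
        catalog = (
            passed.groupby(["gene_id", "event_id", "label"], as_index=False)
            .agg(max_psi=("psi", "max"), n_passing_samples=("sample_id", "nunique"))
            .sort_values(["gene_id", "event_id"])
            .reset_index(drop=True)
        )
    if disease_flags is not None:
        catalog["disease_associated"] = [
            bool(disease_flags.get(g, False)) for g in catalog["gene_id"]
        ]
    unique_genes = catalog["gene_id"].nunique()
    per_type = {
        label: catalog.loc[catalog["label"] == label, "gene_id"].nunique()
        for label in QUANTIFIED_LABELS
    }
    summary = {
        "unique_genes": int(unique_genes),
        "genes_per_event_type": per_type,
        "n_events": int(len(catalog)),
    }
    if disease_flags is not None:
        flagged = catalog.loc[catalog["disease_associated"], "gene_id"].nunique()
        summary["unique_disease_genes"] = int(flagged)
        summary["disease_genes_per_event_type"] = {
            label: catalog.loc[
                (catalog["label"] == label) & catalog["disease_associated"],
                "gene_id",
            ].nunique()
            for label in QUANTIFIED_LABELS
        }
    return catalog, summary


def pool_count_tables(tables: Iterable[JunctionCountTable],
                      sample_id: str = "pooled") -> JunctionCountTable:
    """Sum junction counts across samples (pooled-counts mode)."""
    pooled: dict[JunctionKey, int] = {}
    allow = False
    for t in tables:
        allow = allow or t.allow_undefined_strand
        for jk, c in t.counts.items():
            pooled[jk] = pooled.get(jk, 0) + c
    return JunctionCountTable(sample_id, pooled, allow)


def read_sample_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest TSV with columns sample_id, path, condition."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "path"}
    if not required.issubset(df.columns):
        raise CountTableError(
            f"{path}: manifest must have columns {sorted(required)}"
        )
    if "condition" not in df.columns:
        df["condition"] = "unknown"
    if df["sample_id"].duplicated().any():
        raise CountTableError(f"{path}: duplicate sample_ids in manifest")
    return df
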