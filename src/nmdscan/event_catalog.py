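"""Alternative-splicing event enumeration and NMD classification.

Enumerates skipped-exon (SE), alternative 3'/5' splice-site (A3/A5) and
retained-intron / alternative-intron (RI) events from a transcript
database using SUPPA2-compatible semantics, reads SUPPA2 ``.ioe`` files as
an alternative event source, and classifies each event's NMD status from
the junction label table.

Event identifiers follow the SUPPA2 grammar with 1-based splice-site
coordinates, where each junction span ``a-b`` gives ``a`` = last exonic
base of the upstream exon and ``b`` = first exonic base of the downstream
exon::

    GENE;SE:chrom:a1-b1:a2-b2:strand      (upstream then downstream
                                           inclusion junction)
    GENE;A3:chrom:a-b1:a-b2:strand        (long then short junction)
    GENE;A5:chrom:a1-b:a2-b:strand        (long then short junction)
    GENE;RI:chrom:s:a-b:e:strand          (host exon s..e retaining
                                           intron a+1..b-1)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .annotation_db import (
    DataError,
    GenomicInterval,
    JunctionKey,
    JunctionLabelTable,
    TranscriptDatabase,
)

logger = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "A3", "A5", "RI")

#: NMD classification labels for events.
NMD_EVENT_LABELS = (
    "EI_NMD",
    "ES_NMD",
    "cassette_exon",
    "A3_NMD",
    "A5_NMD",
    "AI_NMD",
    "non_NMD",
    "dropped_complex",
)


class EventError(ValueError):
    """Malformed or inconsistent event data."""


@dataclass
class ASEvent:
    """One alternative-splicing event with role-tagged junctions.

    Role slots by type:

    * SE -- ``inclusion_upstream``, ``inclusion_downstream``, ``skipping``
    * A3/A5 -- ``long_junction``, ``short_junction``
    * RI -- ``ai_junction``, plus ``flanking_3p`` / ``flanking_5p``
      junction sets of the host exon, and ``host_exon``
    """

    event_id: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    junctions: dict = field(default_factory=dict)
    alt_region: Optional[GenomicInterval] = None
    host_exon: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise EventError(f"unknown event type {self.event_type!r}")
        required = {
            "SE": {"inclusion_upstream", "inclusion_downstream", "skipping"},
            "A3": {"long_junction", "short_junction"},
            "A5": {"long_junction", "short_junction"},
            "RI": {"ai_junction", "flanking_3p", "flanking_5p"},
        }[self.event_type]
        missing = required - set(self.junctions)
        if missing:
            raise EventError(f"{self.event_id}: missing junction roles {missing}")

    @property
    def dedup_key(self) -> tuple:
        return (self.event_type, self.chrom, self.strand, self._coords())

    def _coords(self) -> tuple:
        j = self.junctions
        if self.event_type == "SE":
            return (
                j["inclusion_upstream"].start,
                j["inclusion_upstream"].end,
                j["inclusion_downstream"].start,
                j["inclusion_downstream"].end,
            )
        if self.event_type in ("A3", "A5"):
            return (
                j["long_junction"].start,
                j["long_junction"].end,
                j["short_junction"].start,
                j["short_junction"].end,
            )
        return (
            self.host_exon.start,
            j["ai_junction"].start,
            j["ai_junction"].end,
            self.host_exon.end,
        )


# ---------------------------------------------------------------------------
# event-id grammar
# ---------------------------------------------------------------------------

def _span(jk: JunctionKey) -> str:
    # 1-based exonic boundary coordinates flanking the intron
    return f"{jk.start}-{jk.end + 1}"


def _parse_span(chrom: str, span: str, strand: str) -> JunctionKey:
    a, b = span.split("-")
    return JunctionKey(chrom, int(a), int(b) - 1, strand)


def format_event_id(event_type: str, gene_id: str, chrom: str, strand: str,
                    junctions: dict, host_exon: Optional[GenomicInterval]) -> str:
    if event_type == "SE":
        body = f"{_span(junctions['inclusion_upstream'])}:{_span(junctions['inclusion_downstream'])}"
    elif event_type in ("A3", "A5"):
        body = f"{_span(junctions['long_junction'])}:{_span(junctions['short_junction'])}"
    else:
        body = f"{host_exon.start + 1}:{_span(junctions['ai_junction'])}:{host_exon.end}"
    return f"{gene_id};{event_type}:{chrom}:{body}:{strand}"


def parse_event_id(event_id: str) -> ASEvent:
    """Reconstruct an :class:`ASEvent` from its identifier string.

    RI flanking junction sets are not encoded in the id and come back
    empty; they are repopulated against a database where needed.
    """
    try:
        gene_id, rest = event_id.split(";", 1)
        parts = rest.split(":")
        event_type, chrom, strand = parts[0], parts[1], parts[-1]
        body = parts[2:-1]
        if event_type == "SE":
            j1 = _parse_span(chrom, body[0], strand)
            j2 = _parse_span(chrom, body[1], strand)
            junctions = {
                "inclusion_upstream": j1,
                "inclusion_downstream": j2,
                "skipping": JunctionKey(chrom, j1.start, j2.end, strand),
            }
            alt = GenomicInterval(chrom, j1.end, j2.start, strand)
            return ASEvent(event_id, "SE", gene_id, chrom, strand, junctions, alt)
        if event_type in ("A3", "A5"):
            jl = _parse_span(chrom, body[0], strand)
            js = _parse_span(chrom, body[1], strand)
            if jl.length < js.length:
                raise EventError("long junction is shorter than short junction")
            junctions = {"long_junction": jl, "short_junction": js}
            alt = _alt_ss_region(jl, js)
            return ASEvent(event_id, event_type, gene_id, chrom, strand, junctions, alt)
        if event_type == "RI":
            s = int(body[0]) - 1
            jk = _parse_span(chrom, body[1], strand)
            e = int(body[2])
            junctions = {
                "ai_junction": jk,
                "flanking_3p": frozenset(),
                "flanking_5p": frozenset(),
            }
            host = GenomicInterval(chrom, s, e, strand)
            alt = GenomicInterval(chrom, jk.start, jk.end, strand)
            return ASEvent(event_id, "RI", gene_id, chrom, strand, junctions, alt, host)
    except (EventError, DataError):
        raise
    except Exception as exc:
        raise EventError(f"malformed event id {event_id!r}: {exc}") from exc
    raise EventError(f"unsupported event type in id {event_id!r}")


def _alt_ss_region(jl: JunctionKey, js: JunctionKey) -> GenomicInterval:
    """The segment exonic in the short form and intronic in the long form."""
    if jl.start == js.start:  # acceptors differ
        lo, hi = sorted((jl.end, js.end))
    else:  # donors differ
        lo, hi = sorted((jl.start, js.start))
    return GenomicInterval(jl.chrom, lo, hi, jl.strand)


# ---------------------------------------------------------------------------
# native enumeration
# ---------------------------------------------------------------------------

def _make_event(event_type, gene_id, chrom, strand, junctions, alt, host=None):
    eid = format_event_id(event_type, gene_id, chrom, strand, junctions, host)
    return ASEvent(eid, event_type, gene_id, chrom, strand, junctions, alt, host)


def enumerate_events(db: TranscriptDatabase) -> list[ASEvent]:
    """Enumerate SE, A3, A5 and RI events gene by gene.

    * SE: one transcript includes an internal exon with flanking junctions
      whose outer boundaries are joined by a skipping junction present in
      another transcript of the gene.
    * A3/A5: two junctions of the gene share one splice site, differ at
      the other, and the exons at the differing side share their far
      boundary (SUPPA semantics).
    * RI: a junction of the gene lies strictly inside a single exon of
      another transcript (exitron geometry included); one event per
      (intron, host exon) pair.

    Events are deduplicated by (type, coordinates, strand).
    """
    events: dict[tuple, ASEvent] = {}
    for gene_id in db.gene_ids:
        txs = db.gene_transcripts(gene_id)
        if len(txs) < 2:
            continue
        gene_junctions: set[JunctionKey] = set()
        # (junction, upstream exon, downstream exon) in genomic orientation
        flanked: set[tuple] = set()
        for tx in txs:
            exons = tx.exons
            for a, b in zip(exons, exons[1:]):
                jk = JunctionKey(tx.chrom, a.end, b.start, tx.strand)
                gene_junctions.add(jk)
                flanked.add((jk, a, b))
        chrom = txs[0].chrom
        strand = txs[0].strand

        # SE
        for tx in txs:
            exons = tx.exons
            for i in range(1, len(exons) - 1):
                up = JunctionKey(chrom, exons[i - 1].end, exons[i].start, strand)
                down = JunctionKey(chrom, exons[i].end, exons[i + 1].start, strand)
                skip = JunctionKey(chrom, up.start, down.end, strand)
                if skip in gene_junctions:
                    ev = _make_event(
                        "SE", gene_id, chrom, strand,
                        {"inclusion_upstream": up, "inclusion_downstream": down,
                         "skipping": skip},
                        exons[i],
                    )
                    events.setdefault(ev.dedup_key, ev)

        # A3 / A5: group junctions by the shared splice site, require the
        # variable-side exon to share its far boundary
        by_start: dict[int, set[tuple]] = {}
        by_end: dict[int, set[tuple]] = {}
        for jk, up, down in flanked:
            by_start.setdefault(jk.start, set()).add((jk, down.end))
            by_end.setdefault(jk.end, set()).add((jk, up.start))
        for group, varies_at in ((by_start, "end"), (by_end, "start")):
            for entries in group.values():
                entries = sorted(entries)
                for i in range(len(entries)):
                    for k in range(i + 1, len(entries)):
                        (j1, far1), (j2, far2) = entries[i], entries[k]
                        if j1 == j2 or far1 != far2:
                            continue
                        if getattr(j1, varies_at) == getattr(j2, varies_at):
                            continue
                        long_j, short_j = (
                            (j1, j2) if j1.length > j2.length else (j2, j1)
                        )
                        # acceptor is the strand-3' intron boundary
                        if varies_at == "end":
                            etype = "A3" if strand == "+" else "A5"
                        else:
                            etype = "A5" if strand == "+" else "A3"
                        ev = _make_event(
                            etype, gene_id, chrom, strand,
                            {"long_junction": long_j, "short_junction": short_j},
                            _alt_ss_region(long_j, short_j),
                        )
                        events.setdefault(ev.dedup_key, ev)

        # RI
        for tx in txs:
            for exon in tx.exons:
                for jk in gene_junctions:
                    if exon.start < jk.start and jk.end < exon.end:
                        ev = _make_event(
                            "RI", gene_id, chrom, strand,
                            {
                                "ai_junction": jk,
                                "flanking_3p": _flank_set(gene_junctions, exon, strand, "3p"),
                                "flanking_5p": _flank_set(gene_junctions, exon, strand, "5p"),
                            },
                            GenomicInterval(chrom, jk.start, jk.end, strand),
                            host=exon,
                        )
                        events.setdefault(ev.dedup_key, ev)

    return sorted(events.values(), key=lambda e: e.event_id)


def _flank_set(gene_junctions: set[JunctionKey], exon: GenomicInterval,
               strand: str, side: str) -> frozenset[JunctionKey]:
    """Junctions using the host exon's 3' or 5' splice site.

    On '+' the exon's 3' splice site (acceptor) is its start and the 5'
    splice site (donor) its end; reversed on '-'.
    """
    at_start = frozenset(j for j in gene_junctions if j.end == exon.start)
    at_end = frozenset(j for j in gene_junctions if j.start == exon.end)
    if (side == "3p") == (strand == "+"):
        return at_start
    return at_end


# ---------------------------------------------------------------------------
# .ioe ingest / export
# ---------------------------------------------------------------------------

IOE_HEADER = "seqname\tgene_id\tevent_id\talternative_transcripts\ttotal_transcripts"


def read_ioe(path: str | Path) -> list[ASEvent]:
    """Parse a SUPPA2 ``.ioe`` event file into :class:`ASEvent` records.

    Event types outside {SE, A3, A5, RI} (e.g. MX, AF, AL) are skipped
    with a warning.
    """
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or lineno == 1 and line.startswith("seqname"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EventError(
                    f"{path} line {lineno}: expected >= 3 tab-separated columns"
                )
            event_id = fields[2]
            etype = event_id.split(";", 1)[-1].split(":", 1)[0]
            if etype not in EVENT_TYPES:
                warnings.warn(
                    f"{path} line {lineno}: skipping unsupported event type {etype}"
                )
                continue
            try:
                events.append(parse_event_id(event_id))
            except (EventError, DataError) as exc:
                raise EventError(f"{path} line {lineno}: {exc}") from exc
    return events


def write_ioe(events: Iterable[ASEvent], path: str | Path,
              db: TranscriptDatabase | None = None) -> None:
    """Write events as a SUPPA2-style ``.ioe`` file.

    Transcript columns are filled from ``db`` when available, else left
    as ``.`` placeholders (the event geometry lives in the id).
    """
    lines = [IOE_HEADER]
    for ev in events:
        alt, total = ".", "."
        if db is not None:
            gene_txs = db.gene_transcripts(ev.gene_id)
            total = ",".join(sorted(t.transcript_id for t in gene_txs)) or "."
        lines.append(f"{ev.chrom}\t{ev.gene_id}\t{ev.event_id}\t{alt}\t{total}")
    Path(path).write_text("\n".join(lines) + "\n")


def restore_ri_flanks(events: Iterable[ASEvent], db: TranscriptDatabase) -> None:
    """Fill RI flanking-junction sets (absent from .ioe ids) from ``db``."""
    gene_j: dict[str, set[JunctionKey]] = {}
    for ev in events:
        if ev.event_type != "RI":
            continue
        if ev.gene_id not in gene_j:
            js: set[JunctionKey] = set()
            for tx in db.gene_transcripts(ev.gene_id):
                js.update(tx.junctions())
            gene_j[ev.gene_id] = js
        junctions = gene_j[ev.gene_id]
        ev.junctions["flanking_3p"] = _flank_set(
            junctions, ev.host_exon, ev.strand, "3p"
        )
        ev.junctions["flanking_5p"] = _flank_set(
            junctions, ev.host_exon, ev.strand, "5p"
        )


# ---------------------------------------------------------------------------
# NMD classification
# ---------------------------------------------------------------------------

def classify_event_nmd(event: ASEvent, labels: JunctionLabelTable) -> str:
    """Classify one event's NMD status from junction labels.

    SE: the skipping junction is tested first (NMD -> ``ES_NMD``), then
    the inclusion junctions (either NMD -> ``EI_NMD``), else
    ``cassette_exon``.  A3/A5: exactly one NMD junction gives
    ``A3_NMD``/``A5_NMD``; both NMD means likely complex splicing and the
    event is dropped (``dropped_complex``); neither gives ``non_NMD``.
    RI: NMD on the alternative-intron junction gives ``AI_NMD``.
    """
    def lab(jk: JunctionKey) -> bool:
        if jk not in labels:
            raise EventError(
                f"event {event.event_id}: junction "
                f"{jk.chrom}:{jk.start}-{jk.end}({jk.strand}) absent from label table"
            )
        return labels.is_nmd(jk)

    j = event.junctions
    if event.event_type == "SE":
        if lab(j["skipping"]):
            return "ES_NMD"
        if lab(j["inclusion_upstream"]) or lab(j["inclusion_downstream"]):
            return "EI_NMD"
        return "cassette_exon"
    if event.event_type in ("A3", "A5"):
        nmd_long, nmd_short = lab(j["long_junction"]), lab(j["short_junction"])
        if nmd_long and nmd_short:
            return "dropped_complex"
        if nmd_long or nmd_short:
            return f"{event.event_type}_NMD"
        return "non_NMD"
    # RI
    return "AI_NMD" if lab(j["ai_junction"]) else "non_NMD"


def classify_events(
    events: Iterable[ASEvent], labels: JunctionLabelTable
) -> list[tuple[ASEvent, str]]:
    """Classify a batch of events; returns (event, label) pairs."""
    return [(ev, classify_event_nmd(ev, labels)) for ev in events]
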