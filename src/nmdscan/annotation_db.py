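"""Transcript database construction and NMD junction labeling.

Builds a transcript/gene database from GTF (GENCODE dialect) and genePred
(UCSC/RefSeq dialect) annotation files, extracts every exon-exon junction,
labels each junction ``coding`` or ``NMD`` by the exclusivity rule (a
junction is NMD if and only if every transcript containing it is itself an
NMD-sensitive or non-coding isoform), and evaluates the 50-nt premature
termination codon (PTC) rule on individual transcript models.

Coordinate convention
---------------------
All internal coordinates are 0-based half-open.  GTF (1-based inclusive)
and genePred (already 0-based half-open) are converted at the I/O boundary.
A junction ``JunctionKey(chrom, start, end, strand)`` describes the intron
as the half-open interval ``[start, end)``; equivalently ``start`` is the
1-based coordinate of the last exonic base of the upstream exon and
``end + 1`` is the 1-based coordinate of the first exonic base of the
downstream exon.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

logger = logging.getLogger(__name__)

#: biotypes that make a transcript eligible to mark a junction as NMD.
NMD_ELIGIBLE_BIOTYPES = frozenset({"nmd", "noncoding"})

#: recognised transcript biotypes.
BIOTYPES = ("protein_coding", "nmd", "noncoding", "other")

DEFAULT_MIN_INTRON_LENGTH = 20


class AnnotationError(ValueError):
    """Malformed annotation input (bad coordinates, unknown dialect...)."""


class DataError(ValueError):
    """Structurally valid input carrying inconsistent data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a given strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DataError(
                f"interval start must precede end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise DataError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class JunctionKey:
    """An intron (donor-acceptor pair) as a half-open interval ``[start, end)``.

    Identity is by all four fields: identical coordinates on opposite
    strands are distinct keys because donor and acceptor roles swap.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError(
                f"intron must have positive length: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise DataError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One isoform: ordered exons, optional stop-codon position, biotype.

    ``exons`` are stored sorted by genomic start; :meth:`exons_tx_order`
    yields them 5'->3' in transcript orientation.  ``cds_end`` is the
    0-based genomic coordinate of the *last base of the stop codon* (the
    strand-3'-most base on '+', the strand-3'-most i.e. genomically lowest
    base on '-').
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    exons: list[GenomicInterval]
    cds_end: Optional[int] = None
    biotype: str = "other"
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise DataError(f"unknown biotype {self.biotype!r}")
        if not self.exons:
            raise DataError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for e in self.exons:
            if e.chrom != self.chrom or e.strand != self.strand:
                raise DataError(
                    f"transcript {self.transcript_id}: exons on mixed chrom/strand"
                )
            if prev_end is not None and e.start < prev_end:
                raise DataError(
                    f"transcript {self.transcript_id}: overlapping/unordered exons"
                )
            prev_end = e.end
        if self.cds_end is not None and not any(
            e.start <= self.cds_end < e.end for e in self.exons
        ):
            raise DataError(
                f"transcript {self.transcript_id}: cds_end {self.cds_end} "
                "outside exon bounds"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.transcript_id)

    def exons_tx_order(self) -> list[GenomicInterval]:
        """Exons 5'->3' in transcript orientation."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def junctions(self) -> list[JunctionKey]:
        """All exon-exon junctions (introns) of this transcript."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(JunctionKey(self.chrom, a.end, b.start, self.strand))
        return out

    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def spliced_position(self, genomic_pos: int) -> int:
        """Map a genomic base to its 0-based spliced-transcript coordinate."""
        offset = 0
        for e in self.exons_tx_order():
            if e.start <= genomic_pos < e.end:
                within = (
                    genomic_pos - e.start if self.strand == "+" else e.end - 1 - genomic_pos
                )
                return offset + within
            offset += len(e)
        raise DataError(
            f"position {genomic_pos} is not exonic in transcript {self.transcript_id}"
        )


@dataclass
class NmdRuleConfig:
    """Parameters of the 50-nt PTC rule.

    ``min_ptc_distance_nt``: minimum number of spliced nucleotides between
    the stop codon's last base and the 3'-most exon-exon junction for the
    transcript to be predicted NMD-sensitive.  The comparison is inclusive
    ("at least 50 nucleotides").
    """

    min_ptc_distance_nt: int = 50

    def __post_init__(self) -> None:
        if self.min_ptc_distance_nt < 0:
            raise DataError("min_ptc_distance_nt must be >= 0")


@dataclass
class JunctionLabelTable:
    """Junction -> {coding, NMD} labels with supporting transcript ids."""

    labels: dict[JunctionKey, str] = field(default_factory=dict)
    support: dict[JunctionKey, frozenset[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, jk: JunctionKey) -> bool:
        return jk in self.labels

    def __getitem__(self, jk: JunctionKey) -> str:
        return self.labels[jk]

    def is_nmd(self, jk: JunctionKey) -> bool:
        return self.labels[jk] == "NMD"


# ---------------------------------------------------------------------------
# transcript database
# ---------------------------------------------------------------------------

class TranscriptDatabase:
    """Merged, multi-source collection of transcript models."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self._by_key: dict[tuple[str, str], TranscriptModel] = {}
        self._genes: dict[str, list[tuple[str, str]]] = {}
        for tx in transcripts:
            self.add(tx)

    def add(self, tx: TranscriptModel) -> None:
        if tx.key in self._by_key:
            raise DataError(f"duplicate transcript {tx.key}")
        self._by_key[tx.key] = tx
        self._genes.setdefault(tx.gene_id, []).append(tx.key)

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[TranscriptModel]:
        # deterministic order
        for key in sorted(self._by_key):
            yield self._by_key[key]

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self._genes)

    def gene_transcripts(self, gene_id: str) -> list[TranscriptModel]:
        return [self._by_key[k] for k in sorted(self._genes.get(gene_id, []))]

    def to_jsonl(self) -> str:
        lines = []
        for tx in self:
            rec = {
                "transcript_id": tx.transcript_id,
                "gene_id": tx.gene_id,
                "gene_symbol": tx.gene_symbol,
                "chrom": tx.chrom,
                "strand": tx.strand,
                "exons": [[e.start, e.end] for e in tx.exons],
                "cds_end": tx.cds_end,
                "biotype": tx.biotype,
                "source": tx.source,
            }
            lines.append(json.dumps(rec, sort_keys=True))
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_jsonl(cls, text: str) -> "TranscriptDatabase":
        db = cls()
        for line in text.splitlines():
            if not line.strip():
                continue
            rec = json.loads(line)
            db.add(
                TranscriptModel(
                    transcript_id=rec["transcript_id"],
                    gene_id=rec["gene_id"],
                    gene_symbol=rec["gene_symbol"],
                    exons=[
                        GenomicInterval(rec["chrom"], s, e, rec["strand"])
                        for s, e in rec["exons"]
                    ],
                    cds_end=rec["cds_end"],
                    biotype=rec["biotype"],
                    source=rec["source"],
                )
            )
        return db

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_jsonl())

    @classmethod
    def load(cls, path: str | Path) -> "TranscriptDatabase":
        return cls.from_jsonl(Path(path).read_text())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _gencode_biotype(raw: str) -> str:
    if raw == "nonsense_mediated_decay":
        return "nmd"
    if raw == "protein_coding":
        return "protein_coding"
    # unrecognised biotype strings are conservative non-NMD
    return "other"


def _genepred_biotype(accession: str) -> str:
    if accession.startswith("NR_"):
        return "noncoding"
    if accession.startswith("NM_"):
        return "protein_coding"
    return "other"


def _read_gtf(path: str | Path, min_intron_length: int) -> list[TranscriptModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises a grab-bag of exception types
        raise AnnotationError(f"failed to parse GTF {path}: {exc}") from exc

    exons: dict[str, list] = {}
    stops: dict[str, list] = {}
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        attrs = feat.attributes
        try:
            tid = attrs["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"{path}: {feat.featuretype} feature without transcript_id"
            ) from exc
        if tid not in meta:
            biotype_raw = (
                attrs.get("transcript_type") or attrs.get("transcript_biotype") or [""]
            )[0]
            meta[tid] = {
                "gene_id": attrs.get("gene_id", [tid])[0],
                "gene_symbol": attrs.get("gene_name", attrs.get("gene_id", [tid]))[0],
                "biotype": _gencode_biotype(biotype_raw),
            }
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(feat)
        elif feat.featuretype == "stop_codon":
            stops.setdefault(tid, []).append(feat)

    out = []
    for tid in sorted(meta):
        feats = exons.get(tid, [])
        if not feats:
            warnings.warn(f"{path}: transcript {tid} has no exon rows; rejected")
            continue
        strand = feats[0].strand
        chrom = feats[0].seqid
        try:
            intervals = [
                GenomicInterval(chrom, f.start - 1, f.end, strand) for f in feats
            ]
        except DataError as exc:
            raise AnnotationError(f"{path}: transcript {tid}: {exc}") from exc
        cds_end = None
        if tid in stops:
            if strand == "+":
                cds_end = max(f.end for f in stops[tid]) - 1
            else:
                cds_end = min(f.start for f in stops[tid]) - 1
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=meta[tid]["gene_id"],
            gene_symbol=meta[tid]["gene_symbol"],
            exons=intervals,
            cds_end=cds_end,
            biotype=meta[tid]["biotype"],
            source="gencode",
        )
        if _short_intron(tx, min_intron_length):
            warnings.warn(
                f"{path}: transcript {tid} has an intron shorter than "
                f"{min_intron_length} nt; rejected"
            )
            continue
        out.append(tx)
    return out


GENEPRED_COLUMNS = (
    "name chrom strand txStart txEnd cdsStart cdsEnd exonCount "
    "exonStarts exonEnds name2"
).split()


def _read_genepred(path: str | Path, min_intron_length: int) -> list[TranscriptModel]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(GENEPRED_COLUMNS):
                raise AnnotationError(
                    f"{path} line {lineno}: expected >= {len(GENEPRED_COLUMNS)} "
                    f"tab-separated fields, got {len(fields)}"
                )
            row = dict(zip(GENEPRED_COLUMNS, fields))
            try:
                starts = [int(x) for x in row["exonStarts"].rstrip(",").split(",")]
                ends = [int(x) for x in row["exonEnds"].rstrip(",").split(",")]
                cds_start, cds_stop = int(row["cdsStart"]), int(row["cdsEnd"])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path} line {lineno}: malformed coordinate field: {exc}"
                ) from exc
            if len(starts) != len(ends) or len(starts) != int(row["exonCount"]):
                raise AnnotationError(
                    f"{path} line {lineno}: exonCount disagrees with exon lists"
                )
            strand = row["strand"]
            cds_end = None
            if cds_stop > cds_start:
                cds_end = cds_stop - 1 if strand == "+" else cds_start
            try:
                tx = TranscriptModel(
                    transcript_id=row["name"],
                    gene_id=row["name2"] or row["name"],
                    gene_symbol=row["name2"] or row["name"],
                    exons=[
                        GenomicInterval(row["chrom"], s, e, strand)
                        for s, e in zip(starts, ends)
                    ],
                    cds_end=cds_end,
                    biotype=_genepred_biotype(row["name"]),
                    source="refseq",
                )
            except DataError as exc:
                raise AnnotationError(f"{path} line {lineno}: {exc}") from exc
            if _short_intron(tx, min_intron_length):
                warnings.warn(
                    f"{path} line {lineno}: intron shorter than "
                    f"{min_intron_length} nt; transcript rejected"
                )
                continue
            out.append(tx)
    return out


def _short_intron(tx: TranscriptModel, min_len: int) -> bool:
    return any(j.length < min_len for j in tx.junctions())


def load_annotations(
    paths: Iterable[tuple[str | Path, str]],
    min_intron_length: int = DEFAULT_MIN_INTRON_LENGTH,
) -> TranscriptDatabase:
    """Load and merge annotation files into a transcript database.

    Parameters
    ----------
    paths:
        Iterable of ``(path, dialect)`` pairs; dialect is ``"gtf"`` or
        ``"genepred"``.
    min_intron_length:
        Transcripts containing an intron shorter than this are rejected
        with a warning (guards degenerate inputs).

    GENCODE transcripts typed ``nonsense_mediated_decay`` map to biotype
    ``nmd``; genePred accessions beginning ``NR_`` map to ``noncoding`` and
    ``NM_`` to ``protein_coding``.  Transcripts from different sources with
    the same id are kept distinct by ``(source, transcript_id)``.
    """
    db = TranscriptDatabase()
    paths = list(paths)
    for path, dialect in paths:
        if dialect == "gtf":
            txs = _read_gtf(path, min_intron_length)
        elif dialect == "genepred":
            txs = _read_genepred(path, min_intron_length)
        else:
            raise AnnotationError(f"unknown annotation dialect {dialect!r}")
        for tx in txs:
            db.add(tx)
    logger.info("loaded %d transcripts from %d file(s)", len(db), len(paths))
    return db


# ---------------------------------------------------------------------------
# junction labeling and the 50-nt rule
# ---------------------------------------------------------------------------

def extract_junction_labels(db: TranscriptDatabase) -> JunctionLabelTable:
    """Label every exon-exon junction in the database coding vs NMD.

    A junction is NMD if and only if *every* transcript containing it has
    biotype in {nmd, noncoding}; a single protein-coding (or unrecognised)
    transcript sharing the junction forces the coding label.
    """
    members: dict[JunctionKey, set[str]] = {}
    all_nmd: dict[JunctionKey, bool] = {}
    for tx in db:
        eligible = tx.biotype in NMD_ELIGIBLE_BIOTYPES
        for jk in tx.junctions():
            members.setdefault(jk, set()).add(tx.transcript_id)
            all_nmd[jk] = all_nmd.get(jk, True) and eligible
    table = JunctionLabelTable()
    for jk in members:
        table.labels[jk] = "NMD" if all_nmd[jk] else "coding"
        table.support[jk] = frozenset(members[jk])
    return table


def evaluate_ptc_rule(
    tx: TranscriptModel, cfg: NmdRuleConfig | None = None
) -> str:
    """Apply the 50-nt PTC rule to one transcript model.

    Returns ``"nmd_predicted"`` if the stop codon lies at least
    ``cfg.min_ptc_distance_nt`` spliced nucleotides upstream of the
    3'-most exon-exon junction, ``"not_nmd"`` if it lies closer or in the
    last exon, and ``"not_applicable"`` for single-exon transcripts or
    transcripts without an annotated stop.

    The distance is the number of spliced nucleotides strictly between the
    stop codon's last base and the junction.
    """
    cfg = cfg or NmdRuleConfig()
    if len(tx.exons) < 2 or tx.cds_end is None:
        return "not_applicable"
    stop_pos = tx.spliced_position(tx.cds_end)  # raises DataError if not exonic
    last_junction_pos = tx.spliced_length() - len(tx.exons_tx_order()[-1])
    if stop_pos >= last_junction_pos:  # stop codon in the 3'-most exon
        return "not_nmd"
    distance = last_junction_pos - 1 - stop_pos
    return "nmd_predicted" if distance >= cfg.min_ptc_distance_nt else "not_nmd"
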