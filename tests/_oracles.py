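"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results by direct enumeration (per-junction
transcript scans, exhaustive pairwise transcript comparison, per-base
loops) without calling the code paths they validate.
"""

from __future__ import annotations

import numpy as np

from nmdscan.annotation_db import (
    GenomicInterval,
    TranscriptDatabase,
    TranscriptModel,
)

NMD_ELIGIBLE = {"nmd", "noncoding"}


def brute_force_junction_labels(db: TranscriptDatabase) -> dict[tuple, str]:
    """For each junction, scan every transcript of the database and apply
    the exclusivity rule directly."""
    transcripts = list(db)
    junctions = set()
    for tx in transcripts:
        for jk in tx.junctions():
            junctions.add((jk.chrom, jk.start, jk.end, jk.strand))
    out = {}
    for key in junctions:
        carriers = [
            tx for tx in transcripts
            if any((j.chrom, j.start, j.end, j.strand) == key
                   for j in tx.junctions())
        ]
        exclusive = all(tx.biotype in NMD_ELIGIBLE for tx in carriers)
        out[key] = "NMD" if exclusive else "coding"
    return out


def pairwise_event_oracle(db: TranscriptDatabase) -> set[tuple]:
    """Exhaustive pairwise transcript comparison; returns dedup keys
    (event_type, chrom, strand, coords) matching ``ASEvent.dedup_key``."""
    found: set[tuple] = set()
    for gene_id in db.gene_ids:
        txs = db.gene_transcripts(gene_id)
        for a in txs:
            for b in txs:
                if a.transcript_id == b.transcript_id:
                    continue
                found |= _compare_pair(a, b)
    return found


def _compare_pair(a: TranscriptModel, b: TranscriptModel) -> set[tuple]:
    chrom, strand = a.chrom, a.strand
    out: set[tuple] = set()
    b_junctions = {(j.start, j.end) for j in b.junctions()}

    # SE: internal exon of a skipped by a junction of b
    ex = a.exons
    for i in range(1, len(ex) - 1):
        up = (ex[i - 1].end, ex[i].start)
        down = (ex[i].end, ex[i + 1].start)
        if (up[0], down[1]) in b_junctions:
            out.add(("SE", chrom, strand, (up[0], up[1], down[0], down[1])))

    # A3/A5: junctions sharing one boundary whose variable-side exons
    # share their far boundary
    def flanked(tx):
        return [
            ((e1.end, e2.start), e1, e2)
            for e1, e2 in zip(tx.exons, tx.exons[1:])
        ]

    for ja, ua, da in flanked(a):
        for jb, ub, db_ in flanked(b):
            if ja == jb:
                continue
            if ja[0] == jb[0] and ja[1] != jb[1] and da.end == db_.end:
                etype = "A3" if strand == "+" else "A5"
                long_j, short_j = sorted((ja, jb), key=lambda j: j[0] - j[1])
                out.add((etype, chrom, strand, (*long_j, *short_j)))
            if ja[1] == jb[1] and ja[0] != jb[0] and ua.start == ub.start:
                etype = "A5" if strand == "+" else "A3"
                long_j, short_j = sorted((ja, jb), key=lambda j: j[0] - j[1])
                out.add((etype, chrom, strand, (*long_j, *short_j)))

    # RI: junction of b strictly inside an exon of a
    for exon in a.exons:
        for js, je in b_junctions:
            if exon.start < js and je < exon.end:
                out.add(("RI", chrom, strand, (exon.start, js, je, exon.end)))
    return out


def per_base_mean(interval: GenomicInterval, runs: list[tuple]) -> tuple:
    """Per-base loop over (chrom, start, end, score) runs."""
    vals = []
    n_nodata = 0
    for pos in range(interval.start, interval.end):
        hit = None
        for chrom, s, e, score in runs:
            if chrom == interval.chrom and s <= pos < e:
                hit = score
                break
        if hit is None:
            n_nodata += 1
        else:
            vals.append(hit)
    mean = float(np.mean(vals)) if vals else None
    return mean, n_nodata / len(interval)


def random_gene(rng: np.random.Generator, gene_id: str,
                with_biotypes: bool = True) -> list[TranscriptModel]:
    """A random multi-isoform gene exercising skipping, alternative
    splice-site and intron-retention geometry on shared splice sites."""
    chrom = "chrT"
    strand = "+" if rng.random() < 0.5 else "-"
    n_slots = int(rng.integers(3, 7))
    cursor = 1000
    slots = []
    for _ in range(n_slots):
        length = int(rng.integers(80, 200))
        slots.append((cursor, cursor + length))
        cursor += length + int(rng.integers(260, 800))
    alt_starts = {
        i: slots[i][0] - int(rng.integers(30, 100))
        for i in range(1, n_slots) if rng.random() < 0.3
    }
    alt_ends = {
        i: slots[i][1] + int(rng.integers(30, 100))
        for i in range(n_slots - 1) if rng.random() < 0.3
    }
    n_tx = int(rng.integers(2, 7))
    transcripts = []
    for t in range(n_tx):
        exons = []
        i = 0
        while i < n_slots:
            if 0 < i < n_slots - 1 and rng.random() < 0.2:
                i += 1  # skip this exon
                continue
            s, e = slots[i]
            if i in alt_starts and rng.random() < 0.5:
                s = alt_starts[i]
            if i < n_slots - 1 and rng.random() < 0.15:
                # retain the next intron: merge with the following slot
                e = slots[i + 1][1]
                exons.append((s, e))
                i += 2
                continue
            if i in alt_ends and rng.random() < 0.5:
                e = alt_ends[i]
            exons.append((s, e))
            i += 1
        if len(exons) < 2:
            exons = list(slots[:2])
        biotype = (
            str(rng.choice(["protein_coding", "nmd", "noncoding", "other"]))
            if with_biotypes else "protein_coding"
        )
        transcripts.append(TranscriptModel(
            transcript_id=f"{gene_id}.t{t}",
            gene_id=gene_id,
            gene_symbol=gene_id,
            exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
            biotype=biotype,
            source="synthetic",
        ))
    return transcripts
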