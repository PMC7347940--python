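"""Synthetic AS-NMD fixtures with known ground truth.

Generates gene models carrying planted non-productive (NMD-inducing)
alternative-splicing events of each type (poison-exon inclusion EI,
NMD-inducing skipping ES, alternative 3'/5' splice sites, exitron AI),
simulates splice-junction read counts under an explicit degradation
model, and emits conservation, QC and disease tables with planted truth.

Degradation model
-----------------
Each gene transcribes a fraction ``psi`` of non-productive and ``1-psi``
of productive isoforms.  NMD degrades non-productive transcripts with
per-gene efficiency ``d`` (survival ``s = 1 - d``); cycloheximide (CHX)
treatment blocks NMD, forcing ``s = 1``.  The observed non-productive
abundance is therefore::

    f(psi, d) = psi * (1 - d) / (psi * (1 - d) + 1 - psi)

and the CHX/DMSO fold increase of the non-productive fraction is
``psi / f(psi, d)``.  By default ``d`` is drawn per gene from a uniform
fold-increase band (1.1x-9x), and ``psi`` from the uniform range
0.186-0.89, matching the post-NMD-inhibition abundances observed for
validated events.

Count model
-----------
``depth`` is the expected number of uniquely-mapped read pairs per
junction per unit of isoform abundance: every junction of an isoform
draws independently ``Poisson(depth * isoform_fraction)``.  An isoform
copy therefore contributes reads to *both* inclusion junctions of an
included exon but to only *one* skipping junction, which is exactly the
asymmetry the cassette PSI estimator's factor of 2 corrects for.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .annotation_db import (
    DataError,
    GenomicInterval,
    JunctionKey,
    NmdRuleConfig,
    TranscriptDatabase,
    TranscriptModel,
    evaluate_ptc_rule,
)
from .psi_quant import JunctionCountTable

NMD_TYPES = ("EI", "ES", "A3", "A5", "AI")
EXPECTED_LABEL = {
    "EI": "EI_NMD", "ES": "ES_NMD", "A3": "A3_NMD",
    "A5": "A5_NMD", "AI": "AI_NMD",
}

#: default event-type mix: cassette-exon events dominate, as in genome-wide
#: catalogs of AS-NMD; at n_genes=60 this yields 40 NMD-event genes.
DEFAULT_EVENT_MIX = {
    "EI": 15 / 60, "ES": 9 / 60, "A3": 6 / 60, "A5": 6 / 60,
    "AI": 4 / 60, "none": 20 / 60,
}

_GENE_BLOCK = 20_000
_GENE_SPACING = 30_000


class GenerationError(RuntimeError):
    """Requested geometry or parameters cannot be realized."""


@dataclass
class SimConfig:
    """Generative model parameters.

    ``psi_range`` is the uniform support of the per-gene true
    non-productive splicing fraction (default 0.186-0.89, the observed
    post-NMD-inhibition abundance band); ``psi_fixed`` overrides it with
    a single value.  ``nmd_efficiency`` fixes the degradation efficiency
    ``d`` for every gene; when None, ``d`` is derived per gene from a
    CHX fold-increase draw in ``fold_range``.  ``chx=True`` simulates
    translation-inhibited samples (``d`` forced to 0).  ``depth`` is the
    expected junction reads per unit isoform abundance.
    """

    n_genes: int = 60
    event_type_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_MIX)
    )
    psi_range: tuple[float, float] = (0.186, 0.89)
    psi_fixed: Optional[float] = None
    fold_range: tuple[float, float] = (1.1, 9.0)
    nmd_efficiency: Optional[float] = None
    chx: bool = False
    depth: float = 1000.0
    seed: int = 0
    minus_strand_fraction: float = 0.3
    genepred_fraction: float = 0.2
    # conservation planting: per-set exceedance fraction at the threshold
    conserved_threshold: float = 0.8
    set_exceedance: dict[str, float] = field(
        default_factory=lambda: {"set1": 0.16, "set2": 0.08, "set3": 0.60}
    )
    # QC table planting
    n_qc_samples: int = 10
    n_qc_fail_capture: int = 2
    n_qc_fail_dup: int = 1
    # disease table planting
    disease_fraction: float = 0.3
    samples: tuple[tuple[str, str], ...] = (("DMSO_1", "dmso"), ("CHX_1", "chx"))

    def __post_init__(self) -> None:
        total = sum(self.event_type_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"event_type_mix proportions sum to {total}, not 1")
        if self.psi_fixed is not None and not 0.0 < self.psi_fixed < 1.0:
            raise DataError("psi_fixed must be in (0, 1)")
        if self.nmd_efficiency is not None and not 0.0 <= self.nmd_efficiency <= 1.0:
            raise DataError("nmd_efficiency must be in [0, 1]")
        if self.depth <= 0:
            raise DataError("depth must be positive")


def observed_fraction(psi: float, d: float) -> float:
    """Closed-form observed non-productive fraction after degradation."""
    surv = psi * (1.0 - d)
    return surv / (surv + (1.0 - psi))


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    event_type: str                    # EI/ES/A3/A5/AI/none
    psi_true: Optional[float]
    nmd_efficiency: Optional[float]
    fold_expected: Optional[float]
    expected_label: Optional[str]
    alt_region: Optional[tuple[int, int]]
    # transcript_id -> list of junctions; role 'np'/'p' or a numeric fraction
    isoform_junctions: dict[str, list[tuple[str, int, int, str]]]
    isoform_role: dict[str, object]

    def expected_observed_psi(self, chx: bool) -> Optional[float]:
        if self.psi_true is None:
            return None
        d = 0.0 if chx else (self.nmd_efficiency or 0.0)
        return observed_fraction(self.psi_true, d)


@dataclass
class SyntheticTruth:
    config: dict
    genes: list[GeneTruth]
    # conservation: (set_name, chrom, start, end, strand, conserved, mean)
    conservation: list[tuple] = field(default_factory=list)
    # qc: (sample_id, intended_pass, reasons)
    qc: list[tuple] = field(default_factory=list)
    disease_genes: list[str] = field(default_factory=list)
    alias_only_gene: Optional[str] = None

    def nmd_gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes if g.event_type in NMD_TYPES]

    def genes_per_label(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.genes:
            if g.expected_label:
                out[g.expected_label] = out.get(g.expected_label, 0) + 1
        return out

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "genes": [asdict(g) for g in self.genes],
            "conservation": self.conservation,
            "qc": self.qc,
            "disease_genes": self.disease_genes,
            "alias_only_gene": self.alias_only_gene,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        raw = json.loads(text)
        genes = [GeneTruth(**g) for g in raw["genes"]]
        for g in genes:
            g.alt_region = tuple(g.alt_region) if g.alt_region else None
            g.isoform_junctions = {
                k: [tuple(j) for j in v] for k, v in g.isoform_junctions.items()
            }
        return cls(
            config=raw["config"],
            genes=genes,
            conservation=[tuple(c) for c in raw["conservation"]],
            qc=[tuple(q) for q in raw["qc"]],
            disease_genes=raw["disease_genes"],
            alias_only_gene=raw["alias_only_gene"],
        )


def _jk_tuple(jk: JunctionKey) -> tuple[str, int, int, str]:
    return (jk.chrom, jk.start, jk.end, jk.strand)


# ---------------------------------------------------------------------------
# gene geometry
# ---------------------------------------------------------------------------

def _assign_types(cfg: SimConfig, rng: np.random.Generator) -> list[str]:
    """Deterministic largest-remainder apportionment of the type mix."""
    keys = sorted(cfg.event_type_mix)
    exact = {k: cfg.event_type_mix[k] * cfg.n_genes for k in keys}
    counts = {k: int(math.floor(exact[k])) for k in keys}
    short = cfg.n_genes - sum(counts.values())
    for k in sorted(keys, key=lambda k: (-(exact[k] - counts[k]), k))[:short]:
        counts[k] += 1
    types = [k for k in keys for _ in range(counts[k])]
    return [types[i] for i in rng.permutation(len(types))]


def _reflect(iv: tuple[int, int], lo: int, hi: int) -> tuple[int, int]:
    return (lo + hi - iv[1], lo + hi - iv[0])


def _build_gene(rng: np.random.Generator, gene_id: str, event_type: str,
                block_start: int, strand: str,
                psi: Optional[float], d: Optional[float]):
    """Construct one gene's transcript models on a virtual '+' layout,
    then reflect for '-' genes.  Returns (transcripts, GeneTruth)."""
    chrom = "chr1"
    n_ex = 6
    lens = rng.integers(120, 300, size=n_ex)
    if event_type == "AI":
        lens[2] = 400  # long host exon for the exitron
    introns = rng.integers(300, 1500, size=n_ex - 1)

    exons: list[tuple[int, int]] = []
    cursor = block_start + 200
    for i in range(n_ex):
        exons.append((cursor, cursor + int(lens[i])))
        cursor += int(lens[i]) + (int(introns[i]) if i < n_ex - 1 else 0)
    if cursor - block_start > _GENE_BLOCK - 200:
        raise GenerationError(f"{gene_id}: gene exceeds its coordinate block")

    cds_end_prod = exons[-1][0] + 30
    prod_exons = list(exons)
    alt_region = None
    iso2 = None  # (exons, cds_end) of the second isoform
    frac2: object = None

    if event_type == "EI":
        gap_lo, gap_hi = exons[2][1], exons[3][0]
        x_len = 120
        x_start = gap_lo + (gap_hi - gap_lo - x_len) // 2
        if x_start - gap_lo < 20 or gap_hi - (x_start + x_len) < 20:
            raise GenerationError(f"{gene_id}: intron too short for poison exon")
        poison = (x_start, x_start + x_len)
        iso2 = (exons[:3] + [poison] + exons[3:], poison[0] + 60)
        alt_region = poison
        frac2 = "np"
    elif event_type == "ES":
        iso2 = (exons[:2] + exons[3:], exons[3][0] + 30)
        alt_region = exons[2]
        frac2 = "np"
    elif event_type == "A3":
        ext = 176
        if exons[3][0] - ext - exons[2][1] < 20:
            raise GenerationError(f"{gene_id}: intron too short for 3'ss extension")
        e3x = (exons[3][0] - ext, exons[3][1])
        iso2 = (exons[:3] + [e3x] + exons[4:], exons[3][0] + 30)
        alt_region = (e3x[0], exons[3][0])
        frac2 = "np"
    elif event_type == "A5":
        ext = 80
        if exons[3][0] - (exons[2][1] + ext) < 20:
            raise GenerationError(f"{gene_id}: intron too short for 5'ss extension")
        e2x = (exons[2][0], exons[2][1] + ext)
        iso2 = (exons[:2] + [e2x] + exons[3:], exons[3][0] + 30)
        alt_region = (exons[2][1], e2x[1])
        frac2 = "np"
    elif event_type == "AI":
        dstart = exons[2][0] + 150
        dend = dstart + 80
        iso2 = (
            exons[:2] + [(exons[2][0], dstart), (dend, exons[2][1])] + exons[3:],
            exons[3][0] + 30,
        )
        alt_region = (dstart, dend)
        frac2 = "np"
    elif event_type == "none":
        if rng.random() < 0.5:
            iso2 = (exons[:2] + exons[3:], exons[-1][0] + 30)
            alt_region = exons[2]
            frac2 = float(rng.uniform(0.3, 0.7))  # skipping-isoform fraction
    else:
        raise GenerationError(f"unknown event type {event_type!r}")

    def finalize(exon_list, cds_end):
        if strand == "-":
            lo, hi = block_start, block_start + _GENE_BLOCK
            exon_list = sorted(_reflect(e, lo, hi) for e in exon_list)
            cds_end = lo + hi - 1 - cds_end
        return exon_list, cds_end

    prod_exons_f, cds_prod_f = finalize(prod_exons, cds_end_prod)
    tx_prod = TranscriptModel(
        transcript_id=f"{gene_id}.p", gene_id=gene_id, gene_symbol=gene_id,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in prod_exons_f],
        cds_end=cds_prod_f, biotype="other", source="synthetic",
    )
    transcripts = [tx_prod]
    if iso2 is not None:
        iso2_exons_f, cds_iso2_f = finalize(*iso2)
        transcripts.append(TranscriptModel(
            transcript_id=f"{gene_id}.n" if frac2 == "np" else f"{gene_id}.q",
            gene_id=gene_id, gene_symbol=gene_id,
            exons=[GenomicInterval(chrom, s, e, strand) for s, e in iso2_exons_f],
            cds_end=cds_iso2_f, biotype="other", source="synthetic",
        ))
    if alt_region is not None and strand == "-":
        alt_region = _reflect(alt_region, block_start, block_start + _GENE_BLOCK)

    # biotypes are assigned BY the 50-nt rule, never by fiat
    rule = NmdRuleConfig()
    for tx in transcripts:
        verdict = evaluate_ptc_rule(tx, rule)
        tx.biotype = "nmd" if verdict == "nmd_predicted" else "protein_coding"
    if tx_prod.biotype != "protein_coding":
        raise GenerationError(f"{gene_id}: productive isoform predicted NMD")
    if frac2 == "np" and transcripts[1].biotype != "nmd":
        raise GenerationError(f"{gene_id}: NMD isoform not predicted NMD")
    if event_type == "none" and len(transcripts) == 2 \
            and transcripts[1].biotype != "protein_coding":
        raise GenerationError(f"{gene_id}: control isoform predicted NMD")

    iso_junctions = {
        tx.transcript_id: [_jk_tuple(j) for j in tx.junctions()]
        for tx in transcripts
    }
    iso_role: dict[str, object] = {tx_prod.transcript_id: "p"}
    if iso2 is not None:
        iso_role[transcripts[1].transcript_id] = frac2
    truth = GeneTruth(
        gene_id=gene_id, chrom=chrom, strand=strand, event_type=event_type,
        psi_true=psi if event_type in NMD_TYPES else None,
        nmd_efficiency=d if event_type in NMD_TYPES else None,
        fold_expected=(
            None if event_type not in NMD_TYPES or psi is None or d is None
            else psi / observed_fraction(psi, d)
        ),
        expected_label=EXPECTED_LABEL.get(event_type),
        alt_region=alt_region,
        isoform_junctions=iso_junctions,
        isoform_role=iso_role,
    )
    return transcripts, truth


def generate_annotation(cfg: SimConfig,
                        seed: Optional[int] = None
                        ) -> tuple[TranscriptDatabase, SyntheticTruth]:
    """Generate the transcript database and its ground truth."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    types = _assign_types(cfg, rng)
    db = TranscriptDatabase()
    truths = []
    for i, etype in enumerate(types):
        gene_id = f"GENE{i:04d}"
        strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
        psi = d = None
        if etype in NMD_TYPES:
            psi = (
                cfg.psi_fixed if cfg.psi_fixed is not None
                else float(rng.uniform(*cfg.psi_range))
            )
            if cfg.nmd_efficiency is not None:
                d = cfg.nmd_efficiency
            else:
                fold = float(rng.uniform(*cfg.fold_range))
                d = 1.0 - (1.0 - psi) / (fold - psi)
                d = min(max(d, 0.0), 1.0)
        block_start = 100_000 + i * _GENE_SPACING
        transcripts, truth = _build_gene(
            rng, gene_id, etype, block_start, strand, psi, d
        )
        for tx in transcripts:
            db.add(tx)
        truths.append(truth)
    truth = SyntheticTruth(config=_config_dict(cfg), genes=truths)
    return db, truth


def _config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["samples"] = [list(s) for s in cfg.samples]
    return d


# ---------------------------------------------------------------------------
# junction-count simulation
# ---------------------------------------------------------------------------

def simulate_counts(truth: SyntheticTruth, cfg: SimConfig, sample_id: str,
                    seed: int, chx: Optional[bool] = None) -> JunctionCountTable:
    """Draw one sample's junction-count table from the degradation model."""
    rng = np.random.default_rng(seed)
    chx = cfg.chx if chx is None else chx
    counts: dict[JunctionKey, int] = {}
    for g in truth.genes:
        weights: dict[str, float] = {}
        if g.event_type in NMD_TYPES:
            s = 1.0 if chx else 1.0 - (g.nmd_efficiency or 0.0)
            total = g.psi_true * s + (1.0 - g.psi_true)
            for tx_id, role in g.isoform_role.items():
                w = g.psi_true * s if role == "np" else 1.0 - g.psi_true
                weights[tx_id] = w / total
        else:
            roles = g.isoform_role
            if len(roles) == 1:
                weights = {tx_id: 1.0 for tx_id in roles}
            else:
                for tx_id, role in roles.items():
                    weights[tx_id] = role if isinstance(role, float) else 1.0 - next(
                        r for r in roles.values() if isinstance(r, float)
                    )
        lam: dict[JunctionKey, float] = {}
        for tx_id, jlist in g.isoform_junctions.items():
            for jt in jlist:
                jk = JunctionKey(*jt)
                lam[jk] = lam.get(jk, 0.0) + cfg.depth * weights[tx_id]
        for jk in sorted(lam):
            counts[jk] = counts.get(jk, 0) + int(rng.poisson(lam[jk]))
    return JunctionCountTable(sample_id, counts)


def write_star_sj_file(table: JunctionCountTable, path: str | Path) -> None:
    """Serialize a count table in the STAR ``SJ.out.tab`` dialect."""
    code = {"+": 1, "-": 2, ".": 0}
    lines = []
    for jk in sorted(table.counts):
        lines.append(
            f"{jk.chrom}\t{jk.start + 1}\t{jk.end}\t{code[jk.strand]}"
            f"\t0\t1\t{table.counts[jk]}\t0\t38"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# conservation / QC / disease fixtures
# ---------------------------------------------------------------------------

def _truth_exon_sets(truth: SyntheticTruth
                     ) -> dict[str, list[tuple[str, int, int, str]]]:
    """The generator's own three exon sets (mirrors the partition rule)."""
    set1, set2 = [], []
    for g in truth.genes:
        if g.event_type == "EI":
            set1.append((g.chrom, *g.alt_region, g.strand))
        elif g.event_type == "none" and g.alt_region is not None:
            set2.append((g.chrom, *g.alt_region, g.strand))
    return {"set1": set1, "set2": set2}


def simulate_track_and_tables(truth: SyntheticTruth, cfg: SimConfig, seed: int,
                              db: TranscriptDatabase):
    """Plant conservation scores, QC metrics and disease tables.

    Returns ``(bedgraph_runs, qc_metrics_df, disease_df, gene_info_df)``
    and records the planted truth on ``truth`` in place.  Conservation
    exceedance is planted exactly: ``round(frac * n)`` exons of each set
    receive a mean score above the threshold.
    """
    rng = np.random.default_rng(seed)
    sets = _truth_exon_sets(truth)
    set12 = {tuple(e) for e in sets["set1"]} | {tuple(e) for e in sets["set2"]}
    set3 = sorted({
        (e.chrom, e.start, e.end, e.strand)
        for tx in db if tx.biotype == "protein_coding"
        for e in tx.exons
    } - set12)
    all_sets = {"set1": sorted(set(map(tuple, sets["set1"]))),
                "set2": sorted(set(map(tuple, sets["set2"]))),
                "set3": set3}

    runs = []
    truth.conservation = []
    thr = cfg.conserved_threshold
    for name in ("set1", "set2", "set3"):
        exons = all_sets[name]
        n = len(exons)
        n_hi = int(round(cfg.set_exceedance[name] * n))
        hi_idx = set(rng.permutation(n)[:n_hi].tolist())
        for i, (chrom, start, end, strand) in enumerate(exons):
            if i in hi_idx:
                mean = float(rng.uniform(min(thr + 0.02, 0.99), 0.99))
            else:
                mean = float(rng.uniform(0.05, max(thr - 0.05, 0.05)))
            runs.append((chrom, start, end, round(mean, 4)))
            truth.conservation.append(
                (name, chrom, start, end, strand, i in hi_idx, round(mean, 4))
            )
    runs.sort()

    # QC metrics with planted failures
    qc_rows = []
    truth.qc = []
    for i in range(cfg.n_qc_samples):
        sid = f"QC{i:03d}"
        capture = float(rng.uniform(0.75, 0.95))
        r1 = float(rng.uniform(0.10, 0.30))
        r2 = float(np.clip(r1 + rng.uniform(-0.05, 0.05), 0.0, 1.0))
        reasons = []
        if i < cfg.n_qc_fail_capture:
            capture = float(rng.uniform(0.40, 0.65))
            reasons.append("capture_efficiency")
        elif i < cfg.n_qc_fail_capture + cfg.n_qc_fail_dup:
            r2 = float(np.clip(r1 + rng.uniform(0.20, 0.35), 0.0, 1.0))
            reasons.append("r1_r2_dup_difference")
        qc_rows.append({
            "sample_id": sid,
            "mean_base_quality": round(float(rng.uniform(30, 38)), 2),
            "gc_percent": round(float(rng.uniform(40, 55)), 2),
            "adapter_flag": False,
            "dup_rate_r1": round(r1, 4),
            "dup_rate_r2": round(r2, 4),
            "uniquely_mapped_fraction": round(capture, 4),
            "coverage_uniformity_flag": False,
            "insert_size_flag": False,
        })
        truth.qc.append((sid, not reasons, reasons))

    # disease table with one alias-only association
    nmd_genes = truth.nmd_gene_ids()
    n_dis = max(1, int(round(cfg.disease_fraction * len(nmd_genes)))) \
        if nmd_genes else 0
    disease_genes = sorted(
        np.array(nmd_genes)[rng.permutation(len(nmd_genes))[:n_dis]].tolist()
    ) if n_dis else []
    truth.disease_genes = disease_genes
    truth.alias_only_gene = disease_genes[0] if disease_genes else None
    dis_rows, info_rows = [], []
    for k, gene in enumerate(disease_genes):
        symbol = f"ALIAS_{gene}" if gene == truth.alias_only_gene else gene
        dis_rows.append({
            "symbol": symbol,
            "disorder_id": f"ORPHA:{9000 + k}",
            "disorder_name": f"synthetic disorder {k}",
        })
    for g in truth.genes:
        syn = f"ALIAS_{g.gene_id}" if g.gene_id == truth.alias_only_gene else "-"
        info_rows.append({"Symbol": g.gene_id, "Synonyms": syn})
    disease_df = pd.DataFrame(
        dis_rows, columns=["symbol", "disorder_id", "disorder_name"]
    )
    gene_info_df = pd.DataFrame(info_rows, columns=["Symbol", "Synonyms"])
    return runs, pd.DataFrame(qc_rows), disease_df, gene_info_df


# ---------------------------------------------------------------------------
# annotation writers and fixture bundle
# ---------------------------------------------------------------------------

def write_gtf(db: TranscriptDatabase, path: str | Path) -> None:
    """Write the database as a GENCODE-dialect GTF (exon + stop_codon rows)."""
    biotype_str = {
        "nmd": "nonsense_mediated_decay",
        "protein_coding": "protein_coding",
        "noncoding": "misc_RNA",
        "other": "misc_RNA",
    }
    lines = []
    for tx in db:
        attrs = (
            f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
            f'transcript_type "{biotype_str[tx.biotype]}"; '
            f'gene_name "{tx.gene_symbol}";'
        )
        for e in tx.exons:
            lines.append(
                f"{tx.chrom}\tnmdscan\texon\t{e.start + 1}\t{e.end}\t.\t"
                f"{tx.strand}\t.\t{attrs}"
            )
        if tx.cds_end is not None:
            if tx.strand == "+":
                s0, e0 = tx.cds_end - 2, tx.cds_end + 1
            else:
                s0, e0 = tx.cds_end, tx.cds_end + 3
            lines.append(
                f"{tx.chrom}\tnmdscan\tstop_codon\t{s0 + 1}\t{e0}\t.\t"
                f"{tx.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_genepred(transcripts: Iterable[tuple[TranscriptModel, str]],
                   path: str | Path) -> None:
    """Write (transcript, accession) pairs as a genePred table."""
    lines = []
    for tx, accession in transcripts:
        tx_start, tx_end = tx.exons[0].start, tx.exons[-1].end
        if tx.cds_end is None or accession.startswith("NR_"):
            cds_start = cds_end = tx_start
        elif tx.strand == "+":
            cds_start, cds_end = tx_start, tx.cds_end + 1
        else:
            cds_start, cds_end = tx.cds_end, tx_end
        starts = ",".join(str(e.start) for e in tx.exons) + ","
        ends = ",".join(str(e.end) for e in tx.exons) + ","
        lines.append(
            f"{accession}\t{tx.chrom}\t{tx.strand}\t{tx_start}\t{tx_end}\t"
            f"{cds_start}\t{cds_end}\t{len(tx.exons)}\t{starts}\t{ends}\t"
            f"{tx.gene_id}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_fixtures(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the full fixture bundle; returns the file map.

    Emits GTF and genePred annotation, one ``SJ.out.tab`` per configured
    sample plus a manifest, a conservation bedGraph, QC metrics, disease
    and gene_info tables, a SUPPA2-style ``.ioe`` event file, and the
    ground-truth JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    db, truth = generate_annotation(cfg)

    paths: dict[str, Path] = {}
    paths["gtf"] = out / "annotation.gtf"
    write_gtf(db, paths["gtf"])

    # a fraction of genes also appear as RefSeq-style genePred rows
    rng = np.random.default_rng(cfg.seed + 101)
    gene_ids = db.gene_ids
    n_gp = int(round(cfg.genepred_fraction * len(gene_ids)))
    gp_genes = set(
        np.array(gene_ids)[rng.permutation(len(gene_ids))[:n_gp]].tolist()
    )
    gp_rows, acc = [], 0
    for tx in db:
        if tx.gene_id in gp_genes:
            prefix = "NR" if tx.biotype in ("nmd", "noncoding") else "NM"
            gp_rows.append((tx, f"{prefix}_{acc:06d}"))
            acc += 1
    paths["genepred"] = out / "annotation.genepred"
    write_genepred(gp_rows, paths["genepred"])

    manifest_rows = []
    for idx, (sample_id, condition) in enumerate(cfg.samples):
        table = simulate_counts(
            truth, cfg, sample_id, seed=cfg.seed * 1000 + idx,
            chx=(condition == "chx"),
        )
        sj_path = out / f"SJ_{sample_id}.out.tab"
        write_star_sj_file(table, sj_path)
        manifest_rows.append(
            {"sample_id": sample_id, "path": str(sj_path), "condition": condition}
        )
        paths[f"sj_{sample_id}"] = sj_path
    paths["manifest"] = out / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(paths["manifest"], sep="\t", index=False)

    runs, qc_df, disease_df, gene_info_df = simulate_track_and_tables(
        truth, cfg, cfg.seed + 202, db
    )
    paths["bedgraph"] = out / "conservation.bedgraph"
    with open(paths["bedgraph"], "w") as fh:
        for chrom, start, end, score in runs:
            fh.write(f"{chrom}\t{start}\t{end}\t{score}\n")
    paths["qc_metrics"] = out / "qc_metrics.tsv"
    qc_df.to_csv(paths["qc_metrics"], sep="\t", index=False)
    paths["disease"] = out / "disease.tsv"
    disease_df.to_csv(paths["disease"], sep="\t", index=False)
    paths["gene_info"] = out / "gene_info.tsv"
    gene_info_df.to_csv(paths["gene_info"], sep="\t", index=False)

    from .event_catalog import enumerate_events, write_ioe
    events = enumerate_events(db)
    paths["ioe"] = out / "events.ioe"
    write_ioe(events, paths["ioe"], db)

    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(truth.to_json())
    paths["db"] = out / "db.jsonl"
    db.save(paths["db"])
    return paths
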