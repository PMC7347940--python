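# Methods

## Model and pipeline

`nmdscan` quantifies alternative-splicing events that couple to
nonsense-mediated decay (AS-NMD). The pipeline is annotation-driven: it
never inspects sequence. Stop-codon positions and transcript biotypes
come from the annotation (or the synthetic generator), and NMD status is
derived two independent ways:

1. **Junction exclusivity.** A junction is `NMD` iff every transcript
   containing it has an NMD-eligible biotype (`nmd` from the GENCODE
   `nonsense_mediated_decay` type, or `noncoding` from RefSeq `NR_`
   accessions). One protein-coding — or unrecognised — carrier forces
   `coding`. Unrecognised biotype strings map to `other` and count as
   non-NMD: mislabeling toward "coding" avoids false NMD calls.
2. **The 50-nt rule.** A transcript is `nmd_predicted` when the last base
   of its stop codon lies at least `min_ptc_distance_nt` (default 50,
   inclusive — "at least" is inclusive language) spliced nucleotides
   upstream of its 3′-most exon–exon junction, and the stop is not in the
   last exon. The distance is the count of spliced bases strictly between
   the stop's last base and the junction. Transcripts with one exon or no
   stop are `not_applicable`.

### Coordinates

All internal coordinates are 0-based half-open; GTF (1-based inclusive),
`SJ.out.tab` (1-based inclusive intron bounds) and wiggle (1-based) are
converted at the I/O boundary, and the converters are round-trip tested.
genePred is already half-open. A junction key is the intron interval plus
chromosome and strand; identical coordinates on opposite strands are
distinct keys because donor/acceptor roles differ. Junctions shorter than
`min_intron_length` (default 20 nt, configurable; the annotation sources
do not prescribe a value) cause the transcript to be rejected with a
warning — this guards degenerate synthetic inputs.

### Event semantics

Events are enumerated per gene from junction/exon geometry,
SUPPA2-compatible:

* **SE** — a transcript's internal exon whose two flanking junctions'
  outer boundaries are bridged by a skipping junction present in the
  gene. Classification tests the skipping junction first (`ES_NMD`), then
  either inclusion junction (`EI_NMD`), else `cassette_exon`; the
  ordering matters because one junction set can satisfy both, and the
  skipping-first precedence is asserted by test.
* **A3/A5** — two junctions sharing one splice site, differing at the
  other, whose variable-side exons share their far boundary (this far-
  boundary condition is what distinguishes a genuine splice-site choice
  from the flank of a cassette exon). Exactly one NMD junction →
  `A3_NMD`/`A5_NMD`; both → `dropped_complex` (excluded from all
  downstream quantification); neither → `non_NMD`. Whether the NMD label
  must sit on the PTC-generating junction specifically is not decidable
  without sequence, so label-on-exactly-one is used.
* **RI** — a junction of the gene strictly inside a single exon of
  another transcript. This includes classical retention *and* exitron
  geometry; one event per (intron, host exon) pair, labeled by the
  alternative-intron junction alone.

Events are deduplicated by (type, coordinates, strand). Event ids follow
the SUPPA2 grammar with 1-based splice-site coordinates, so `.ioe` ingest
and native enumeration are interchangeable (identity is tested on shared
fixtures; RI flanking-junction sets are not encoded in ids and are
restored from the database after ingest).

### PSI estimators and filters

For cassette events, counts are pooled across merged events sharing the
same alternative exon (and label), with junctions deduplicated before
summation so a junction shared by two merged events is counted once. The
factor 2 on `sj_skip` reflects that one isoform copy feeds two inclusion
junctions but one skipping junction. For AI events the host-exon
expression is estimated as the mean of the 3′- and 5′-splice-site
junction sums pooled over all parent exons, and the AI usage is clipped
at that estimate. Zero denominators give an *undefined* Ψ, never a
silent 0 or 1; no pseudocounts are used anywhere. The AI formula is
implemented as the exact stated expression (no additional smoothing).

The read filter (default ≥ 3, inclusive) applies to the NMD-supporting
junction role — inclusion junctions for EI, the skipping junction for ES,
the NMD splice-site junction for A3/A5, the AI junction for AI — because
that is the evidence the event's NMD call rests on; an `all_roles` scope
is available. The Ψ filter (default 0.03) is inclusive.

Multi-sample handling defaults to per-sample PSI with an event
catalogued when it passes in ≥ 1 sample and reported PSI the maximum
across passing samples; this is the weaker assumption when the
per-sample-vs-pooled question is open. A pooled-counts mode sums the
junction tables first. Headline counters count each gene once; per-type
tallies may count a gene in several types.

### QC, disease, conservation

Sample exclusion: capture efficiency < 0.70 (inclusive pass at 0.70),
|dup(R1) − dup(R2)| above a cutoff, or any raised boolean flag. The
duplication-difference cutoff has no published value; the default is
0.10 absolute, configurable and recorded in the report. Raw-metric
computation is out of scope — the module consumes a documented TSV.

Disease annotation uppercases both sides before matching and expands
NCBI `gene_info` synonyms; an alias claimed by two canonical symbols is
dropped with a warning (documented choice; ambiguity resolution is not
otherwise specified). Orphadata XML is out of scope: the expected input
is a flattened TSV (`symbol`, `disorder_id`, `disorder_name`), which a
few lines of `xml2`/`pandas` produce from the public export.

Conservation partitions exons into (1) poison exons (alt regions of
`EI_NMD` events), (2) non-NMD cassette exons, (3) all remaining
protein-coding exons; NMD membership wins when an exon appears in both
(1) and (2), and exons are deduplicated by coordinates. "Spliced region"
is the exon body; a `--flank N` option exists (default 0) for analyses
that include flanking intronic sequence. The conserved fraction counts
exons with defined mean ≥ 0.8 over exons with defined mean, per unique
exon (not per event). bedGraph and fixed-step wiggle are the supported
track dialects; bases without data are distinguished from score 0 and
excluded from means.

## Synthetic generative model

Each gene gets a 6-exon productive isoform and, per its assigned type, a
non-productive isoform realizing that geometry (poison exon between
exons 3 and 4; skipping of exon 3 with a frameshift PTC downstream; a
176-nt alternative 3′ss extension — the scale of a well-characterised
synaptic-gene event; an 80-nt 5′ss extension; an 80-nt exitron inside an
enlarged exon 3). Biotypes are assigned *by running the 50-nt rule on
the constructed model*, never by fiat, and generation fails loudly if
the construction violates its intent. About 30 % of genes are placed on
the minus strand by reflecting the plus-strand layout. Control genes are
single-isoform or carry a non-NMD cassette event.

Key parameters (defaults):

| parameter | default | meaning |
|---|---|---|
| `psi_range` | (0.186, 0.89) | uniform support of true non-productive fraction ψ, matching the observed post-NMD-inhibition abundance band |
| `fold_range` | (1.1, 9.0) | uniform CHX/DMSO fold-increase band; per-gene NMD efficiency is solved from it as d = 1 − (1−ψ)/(fold−ψ) |
| `depth` | 1000 | expected junction read pairs per unit isoform abundance |
| `event_type_mix` | EI 15/60, ES 9/60, A3 6/60, A5 6/60, AI 4/60, none 20/60 | cassette events dominate, as in genome-wide AS-NMD catalogs; 40 of 60 genes carry an event |
| `set_exceedance` | set1 0.16, set2 0.08, set3 0.60 | planted fraction of exon means ≥ 0.8 per conservation set |

Counts: each junction of an isoform draws
`Poisson(depth × isoform_fraction)` independently, with fractions
ψ(1−d) and 1−ψ (renormalised; d = 0 under CHX). One simulated count is
one uniquely mapped read pair. Poisson (no overdispersion) suffices for
ratio-estimator recovery tests; a negative-binomial switch would slot in
at one call site. Under this model the SE estimator is consistent —
each included-isoform copy feeds both inclusion junctions — and the
observed non-productive read fraction follows the closed form
ψ(1−d)/(ψ(1−d)+1−ψ) exactly in expectation.

Conservation planting is **exact**: `round(frac × n)` exons of each set
draw means above the threshold (uniform 0.82–0.99), the rest below
(0.05–0.75), written as one constant-score bedGraph run per exon. This
makes exceedance recovery deterministic rather than binomial, so the
recovery test verifies the averaging path, not sampling luck. QC tables
plant a configurable number of capture-efficiency and duplication
failures; the disease table associates ~30 % of NMD-event genes, one of
them reachable only through a `gene_info` alias.

### What the generator does and does not emulate

It reproduces the statistical structure the estimators assume: junction
counts proportional to isoform abundance with Poisson noise, NMD
degradation as a per-gene Bernoulli survival, clean splice-site sharing.
It does **not** emulate overdispersion, mapping artifacts, multi-mapping
reads, annotation errors, overlapping genes, or complex events beyond
the four types — so green recovery tests demonstrate correctness of the
estimators and plumbing under the stated model, not robustness to real
RNA-seq pathologies.

## Numerical and design notes

* Problem sizes in tests and the acceptance script (200 genes for the
  labeling oracle, 100 for enumeration, 15 genes × depth 10⁵ for
  recovery, 1000 exons for conservation, a 60-gene end-to-end run) were
  chosen to make every statistical tolerance comfortably attainable
  while keeping the whole suite in the tens of seconds.
* End-to-end catalog recovery is asserted on a CHX-condition sample:
  with NMD active, a gene at ψ = 0.186 and 9× fold increase has observed
  Ψ ≈ 2.1 %, below the 3 % reporting threshold — exact recovery of every
  planted gene is only expected under NMD inhibition, which is precisely
  why inhibition is part of the validation design being modelled.
* Quadratic standard-curve inversion selects, when both roots fall in
  the standards' range, the root on the monotone branch covering the
  standards (same side of the parabola's vertex as the bulk of the
  range); signals outside the fitted standard signal range are flagged
  as extrapolation. ΔΔCt uses arithmetic means of technical-replicate
  Ct values with no outlier rejection.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; generator outputs are byte-reproducible, and database
  serialization is sorted JSON-lines so repeated loads are
  byte-identical.

## Known limitations

No sequence-level ORF finding, liftover, read alignment, BAM parsing or
TPM estimation; mutually exclusive exons and alternative first/last
exons are not enumerated; cross-species junction mapping is out of
scope. The RefSeq "NR" reading as the `NR_` accession prefix is an
interpretation (the obvious one for UCSC genePred input) and is isolated
in one function. When GENCODE and RefSeq disagree, all transcripts from
both sources are pooled before applying junction exclusivity.
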