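"""Synthetic multi-individual dataset with implanted splice-site-creating SNVs.

Generates a toy genome (one gene per contig), a GTF annotation, one VCF
and one SAM of spliced junction reads per individual, and a truth table.
Every annotated intron is canonical (GT..AG on the transcribed strand,
polypyrimidine tract before the acceptor) and every CDS is a clean ORF.
For each true SCM the *alternate* allele completes the canonical
dinucleotide of a novel donor (GT) or acceptor (AG) at a planned offset
while the reference allele leaves it broken; carriers receive
novel-junction reads at a configurable junction allele fraction, with a
dropout probability modelling low expression. Decoy SNVs either sit
outside every attribution window or violate the cross-individual
concordance rules (novel reads in a non-carrier, or fewer carriers with
the event than without).

Reads are emitted as already-aligned SAM: the pipeline's contract starts
at spliced alignments, so no sequencing/alignment step is simulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import revcomp, write_fasta, write_sam, write_vcf
from .gene_model import Transcript, write_annotation
from .personalize import SnvRecord, apply_snvs

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

KIND_SCM = "scm"
KIND_DECOY_NONCARRIER = "decoy_non_carrier_event"
KIND_DECOY_DISCORDANT = "decoy_discordant"
KIND_DECOY_OUTSIDE = "decoy_outside_window"


@dataclass
class SimConfig:
    """Study conditions for the simulated cohort.

    Defaults emulate the published data regime: a JAF setpoint of 0.21
    (the worked exon-extension example), junction depths of tens of
    reads, 75-bp spliced reads, and a cohort in which most events are
    carried by a handful of heterozygous individuals.
    """

    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 6)
    exon_len: tuple[int, int] = (90, 150)
    intron_len: tuple[int, int] = (150, 400)
    n_individuals: int = 30
    n_true_scms: int = 15
    n_decoy_snvs: int = 10
    event_mix: dict[str, float] = field(
        default_factory=lambda: {
            "extension_donor": 0.25,
            "extension_acceptor": 0.25,
            "shrinkage_donor": 0.25,
            "shrinkage_acceptor": 0.25,
        }
    )
    length_change: tuple[int, int] = (4, 18)
    target_jaf: float = 0.21
    read_depth: int = 50
    dropout_rate: float = 0.05
    read_length: int = 75
    min_anchor: int = 8  # per-read aligned anchor, > the 5 bp filter
    carriers_range: tuple[int, int] = (2, 6)
    flank: int = 200
    seed: int = 42

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_genes", "n_individuals", "n_true_scms", "read_depth",
                     "read_length", "min_anchor", "flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_decoy_snvs < 0:
            raise ValueError("n_decoy_snvs must be >= 0")
        if not (0.0 < self.target_jaf < 1.0):
            raise ValueError("target_jaf must be in (0, 1)")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must be in [0, 1]")
        if abs(sum(self.event_mix.values()) - 1.0) > 1e-9:
            raise ValueError("event_mix fractions must sum to 1")
        if self.n_true_scms > self.n_genes:
            raise ValueError("one event per gene: n_true_scms <= n_genes")
        if self.carriers_range[1] >= self.n_individuals:
            raise ValueError("carriers_range must leave at least one non-carrier")
        lo, hi = self.length_change
        if lo < 4:
            raise ValueError("length_change must be >= 4 bp")
        if hi > self.exon_len[0] - 30 or hi > self.intron_len[0] - 25:
            raise ValueError(
                "length_change upper bound too large for the exon/intron geometry"
            )
        if self.read_length < 2 * self.min_anchor:
            raise ValueError("read_length must allow two anchors")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("exons_per_gene", "exon_len", "intron_len", "length_change",
                    "carriers_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class TruthRecord:
    """Ground truth for one implanted SNV (true SCM or decoy)."""

    scm_id: str
    kind: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    gene: str
    transcript_id: str
    carriers: tuple[str, ...]
    event_type: Optional[str] = None
    side: Optional[str] = None
    delta_len: Optional[int] = None
    annotated_boundary: Optional[int] = None
    novel_boundary: Optional[int] = None
    intron_start: Optional[int] = None
    intron_end: Optional[int] = None
    novel_read_individuals: tuple[str, ...] = ()
    expected_jaf: Optional[float] = None
    expected_verdict: str = "absent"

    @property
    def snv_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def novel_junction(self) -> Optional[tuple[int, int]]:
        if self.novel_boundary is None:
            return None
        if self.annotated_boundary == self.intron_end:
            return (self.intron_start, self.novel_boundary)
        return (self.novel_boundary, self.intron_end)


@dataclass
class SimData:
    config: SimConfig
    genome: dict[str, str]
    transcripts: list[Transcript]
    truths: list[TruthRecord]
    individuals: list[str]
    snvs_by_individual: dict[str, list[SnvRecord]] = field(default_factory=dict)
    alignments_by_individual: dict[str, list] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genome construction


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_BASES, size=n))


def _set_intron_motifs(seq: list[str], s: int, e: int, strand: str,
                       rng: np.random.Generator) -> set[int]:
    """Canonical dinucleotides + random pyrimidine-rich acceptor tract."""
    protected: set[int] = set()
    if strand == "+":
        seq[s], seq[s + 1] = "G", "T"
        seq[e - 2], seq[e - 1] = "A", "G"
        protected.update((s, s + 1, e - 2, e - 1))
        tract = range(e - 18, e - 2)
        pyr = ("C", "T")
    else:
        seq[s], seq[s + 1] = "C", "T"  # acceptor AG on transcribed strand
        seq[e - 2], seq[e - 1] = "A", "C"  # donor GT on transcribed strand
        protected.update((s, s + 1, e - 2, e - 1))
        tract = range(s + 2, s + 18)
        pyr = ("G", "A")  # pyrimidines on the transcribed strand
    for p in tract:
        if rng.random() < 0.9:
            seq[p] = pyr[int(rng.integers(2))]
    return protected


def _acceptor_tract_positions(s: int, e: int, strand: str) -> range:
    """The 18 intronic bases of the annotated acceptor window."""
    return range(e - 18, e) if strand == "+" else range(s, s + 18)


def _enforce_tract(seq: list[str], s: int, e: int, strand: str,
                   protected: set[int]) -> None:
    """Guarantee >=12 transcribed-strand pyrimidines in the acceptor tract."""
    positions = _acceptor_tract_positions(s, e, strand)
    pyr = ("C", "T") if strand == "+" else ("G", "A")
    count = sum(1 for p in positions if seq[p] in pyr)
    for p in positions:
        if count >= 12:
            break
        if p in protected or seq[p] in pyr:
            continue
        seq[p] = pyr[1]
        count += 1


def _cds_positions(t: Transcript) -> list[int]:
    """Genomic positions of CDS bases in transcription order."""
    out: list[int] = []
    exons = t.exons if t.strand == "+" else list(reversed(t.exons))
    for s, e in exons:
        cs, ce = max(s, t.cds_start), min(e, t.cds_end)
        if cs >= ce:
            continue
        rng_ = range(cs, ce) if t.strand == "+" else range(ce - 1, cs - 1, -1)
        out.extend(rng_)
    return out


_STOPS = {"TAA", "TAG", "TGA"}
_STOP_FIX = {0: "C", 1: "C", 2: "C"}  # any single C substitution breaks a stop


def _finalize_cds(seq: list[str], t: Transcript, protected: set[int]) -> None:
    """Force start/stop codons and remove internal stops in the annotated frame."""
    pos = _cds_positions(t)
    if len(pos) < 9 or len(pos) % 3 != 0:
        raise ValueError(f"{t.id}: degenerate CDS geometry")

    def put(p: int, base: str) -> None:
        if p in protected:
            raise ValueError(f"{t.id}: CDS codon collides with implanted site")
        seq[p] = base if t.strand == "+" else revcomp(base)

    for p, base in zip(pos[:3], "ATG"):
        put(p, base)
    for p, base in zip(pos[-3:], "TAA"):
        put(p, base)
    # clear internal stop codons, avoiding protected bases
    for i in range(3, len(pos) - 3, 3):
        codon_pos = pos[i : i + 3]
        codon = "".join(
            seq[p] if t.strand == "+" else revcomp(seq[p]) for p in codon_pos
        )
        if codon in _STOPS:
            for k in (0, 1, 2):
                if codon_pos[k] not in protected:
                    put(codon_pos[k], _STOP_FIX[k])
                    break
            else:  # pragma: no cover - implant spans are at most 2 bases
                raise ValueError(f"{t.id}: cannot clear stop codon")


def _build_gene(
    rng: np.random.Generator, cfg: SimConfig, chrom: str, strand: str, gene_idx: int
) -> tuple[list[str], Transcript, set[int]]:
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_lens = [int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
                 for _ in range(n_exons)]
    intron_lens = [int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
                   for _ in range(n_exons - 1)]
    total = cfg.flank * 2 + sum(exon_lens) + sum(intron_lens)
    seq = _random_seq(rng, total)

    exons: list[tuple[int, int]] = []
    pos = cfg.flank
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < n_exons - 1:
            pos += intron_lens[i]

    protected: set[int] = set()
    introns = [(exons[i][1], exons[i + 1][0]) for i in range(n_exons - 1)]
    for s, e in introns:
        protected |= _set_intron_motifs(seq, s, e, strand, rng)

    # CDS spanning all exons, trimmed to a whole number of codons
    cds_start = exons[0][0] + 12
    cds_end = exons[-1][1] - 12
    coding = sum(min(e, cds_end) - max(s, cds_start)
                 for s, e in exons if min(e, cds_end) > max(s, cds_start))
    if strand == "+":
        cds_end -= coding % 3
    else:
        cds_start += coding % 3

    t = Transcript(
        id=f"TX{gene_idx:03d}",
        gene=f"GENE{gene_idx:03d}",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
    )
    return seq, t, protected


# ---------------------------------------------------------------------------
# event planning


def _plan_event(
    rng: np.random.Generator, cfg: SimConfig, t: Transcript
) -> tuple[str, str, int, int, int, int, tuple[int, int]]:
    """Choose intron, type, side and geometry for one event in this gene.

    Returns (event_type, side, delta, annotated_boundary, novel_boundary,
    genomic intron index, novel junction interval).
    """
    n_introns = t.n_introns
    if n_introns >= 3:
        gi = int(rng.integers(1, n_introns - 1))
    else:
        gi = int(rng.integers(0, n_introns))
    labels = sorted(cfg.event_mix)
    probs = [cfg.event_mix[k] for k in labels]
    choice = labels[int(rng.choice(len(labels), p=probs))]
    event_type, side = choice.split("_")
    s, e = t.introns()[gi]

    exon_left = t.exons[gi]
    exon_right = t.exons[gi + 1]
    lo, hi = cfg.length_change
    delta = int(rng.integers(lo, hi + 1))

    strand = t.strand
    if (side == "donor") == (strand == "+"):
        # the replaced site sits at the genomic left end of the intron
        ab = s
        if event_type == "extension":
            nb = s + delta
        else:
            nb = s - delta
        junction = (nb, e)
    else:
        ab = e
        if event_type == "extension":
            nb = e - delta
        else:
            nb = e + delta
        junction = (s, nb)

    # feasibility: novel boundary strictly interior with margin
    if event_type == "extension" and not (s + 3 < nb < e - 3):
        raise ValueError("length change does not fit the intron")
    if event_type == "shrinkage":
        ex_s, ex_e = exon_left if ab == s else exon_right
        if not (ex_s + 3 < nb < ex_e - 3):
            raise ValueError("length change does not fit the exon")

    signed_delta = delta if event_type == "extension" else -delta
    return event_type, side, signed_delta, ab, nb, gi, junction


def _novel_site_dinuc(side: str, strand: str, nb: int) -> list[tuple[int, str]]:
    """Genomic positions + bases of the canonical dinucleotide at a novel site."""
    if side == "donor":
        return [(nb, "G"), (nb + 1, "T")] if strand == "+" else [(nb - 2, "A"), (nb - 1, "C")]
    return [(nb - 2, "A"), (nb - 1, "G")] if strand == "+" else [(nb, "C"), (nb + 1, "T")]


def _implant_site(
    rng: np.random.Generator,
    seq: list[str],
    side: str,
    strand: str,
    nb: int,
    protected: set[int],
) -> tuple[int, str, str]:
    """Break the canonical dinucleotide in the reference; SNV alt completes it.

    Returns (snv position, ref base, alt base).
    """
    dinuc = _novel_site_dinuc(side, strand, nb)
    snv_pos, needed = dinuc[int(rng.integers(2))]
    for p, base in dinuc:
        if p != snv_pos:
            seq[p] = base
        protected.add(p)
    others = [b for b in "ACGT" if b != needed]
    ref = others[int(rng.integers(3))]
    seq[snv_pos] = ref
    return snv_pos, ref, needed


# ---------------------------------------------------------------------------
# top-level genome simulation


def simulate_genome(
    config: SimConfig,
) -> tuple[dict[str, str], list[Transcript], list[TruthRecord]]:
    """Build the genome, annotation and truth table (deterministic in seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    individuals = [f"IND{i:03d}" for i in range(cfg.n_individuals)]

    genome: dict[str, str] = {}
    transcripts: list[Transcript] = []
    truths: list[TruthRecord] = []
    builds: list[tuple[list[str], Transcript, set[int]]] = []

    for g in range(cfg.n_genes):
        chrom = f"chr{g + 1}"
        strand = "+" if g % 2 == 0 else "-"
        builds.append(_build_gene(rng, cfg, chrom, strand, g))

    # allocate decoys: event-forming decoys need their own gene
    free_genes = list(range(cfg.n_true_scms, cfg.n_genes))
    n_event_decoys = min(cfg.n_decoy_snvs, len(free_genes))
    decoy_plan: list[str] = []
    for i in range(cfg.n_decoy_snvs):
        if i < n_event_decoys:
            decoy_plan.append(
                KIND_DECOY_NONCARRIER if i % 2 == 0 else KIND_DECOY_DISCORDANT
            )
        else:
            decoy_plan.append(KIND_DECOY_OUTSIDE)

    def sample_carriers(k: int) -> tuple[str, ...]:
        idx = rng.choice(cfg.n_individuals, size=k, replace=False)
        return tuple(individuals[i] for i in sorted(idx))

    scm_counter = 0

    def event_truth(kind: str, gene_idx: int) -> TruthRecord:
        nonlocal scm_counter
        seq, t, protected = builds[gene_idx]
        etype, side, delta, ab, nb, gi, junction = _plan_event(rng, cfg, t)
        snv_pos, ref, alt = _implant_site(rng, seq, side, t.strand, nb, protected)
        k = int(rng.integers(cfg.carriers_range[0], cfg.carriers_range[1] + 1))
        carriers = sample_carriers(k)
        if kind == KIND_SCM:
            readers = carriers  # dropout applied at read time
            verdict = "accepted"
        elif kind == KIND_DECOY_NONCARRIER:
            non_carriers = [i for i in individuals if i not in carriers]
            extra = non_carriers[int(rng.integers(len(non_carriers)))]
            readers = tuple(sorted(carriers + (extra,)))
            verdict = "rejected_nonCarrier_event"
        else:  # discordant: at most half of the carriers show the event
            readers = carriers[: k // 2]
            verdict = "rejected_concordance"
        s, e = t.introns()[gi]
        rec = TruthRecord(
            scm_id=f"SCM{scm_counter:03d}",
            kind=kind,
            chrom=t.chrom,
            pos=snv_pos,
            ref=ref,
            alt=alt,
            gene=t.gene,
            transcript_id=t.id,
            carriers=carriers,
            event_type=etype,
            side=side,
            delta_len=delta,
            annotated_boundary=ab,
            novel_boundary=nb,
            intron_start=s,
            intron_end=e,
            novel_read_individuals=readers,
            expected_jaf=cfg.target_jaf,
            expected_verdict=verdict,
        )
        scm_counter += 1
        return rec

    for g in range(cfg.n_true_scms):
        truths.append(event_truth(KIND_SCM, g))
    for i, kind in enumerate(d for d in decoy_plan if d != KIND_DECOY_OUTSIDE):
        truths.append(event_truth(kind, free_genes[i]))

    # finalize CDS after implants, then place outside-window decoys
    for seq, t, protected in builds:
        for s, e in t.introns():
            _enforce_tract(seq, s, e, t.strand, protected)
        _finalize_cds(seq, t, protected)

    n_outside = sum(1 for d in decoy_plan if d == KIND_DECOY_OUTSIDE)
    for i in range(n_outside):
        gene_idx = i % cfg.n_genes
        seq, t, protected = builds[gene_idx]
        avoid = set(t.exon_boundaries())
        avoid |= {tr.novel_boundary for tr in truths
                  if tr.chrom == t.chrom and tr.novel_boundary is not None}
        span = (t.exons[0][0], t.exons[-1][1])
        for _ in range(200):
            p = int(rng.integers(span[0], span[1]))
            if p in protected:
                continue
            if any(abs(p - b) < 30 for b in avoid):
                continue
            break
        else:  # pragma: no cover
            raise RuntimeError("could not place outside-window decoy")
        ref = seq[p]
        alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
        k = int(rng.integers(cfg.carriers_range[0], cfg.carriers_range[1] + 1))
        truths.append(
            TruthRecord(
                scm_id=f"SCM{scm_counter:03d}",
                kind=KIND_DECOY_OUTSIDE,
                chrom=t.chrom,
                pos=p,
                ref=ref,
                alt=alt,
                gene=t.gene,
                transcript_id=t.id,
                carriers=sample_carriers(k),
                expected_verdict="absent",
            )
        )
        protected.add(p)
        scm_counter += 1

    for seq, t, _ in builds:
        genome[t.chrom] = "".join(seq)
        transcripts.append(t)
    return genome, transcripts, truths


# ---------------------------------------------------------------------------
# read simulation


def _junction_reads(
    rng: np.random.Generator,
    pseq: str,
    chrom: str,
    js: int,
    je: int,
    n: int,
    cfg: SimConfig,
    strand: str,
    qprefix: str,
) -> list[tuple[str, str, int, str, str, str]]:
    """``n`` spliced reads over the junction, anchors >= cfg.min_anchor."""
    out = []
    gap = je - js
    for i in range(n):
        left = int(rng.integers(cfg.min_anchor, cfg.read_length - cfg.min_anchor + 1))
        right = cfg.read_length - left
        pos0 = js - left
        seq = pseq[pos0:js] + pseq[je : je + right]
        cigar = f"{left}M{gap}N{right}M"
        out.append((f"{qprefix}:{i}", chrom, pos0, cigar, seq, strand))
    return out


def simulate_reads(
    genome: dict[str, str],
    transcripts: Sequence[Transcript],
    truths: Sequence[TruthRecord],
    config: SimConfig,
) -> tuple[dict[str, list[SnvRecord]], dict[str, list]]:
    """Per-individual SNV lists and SAM alignment rows.

    Carriers of a true SCM draw Jn ~ Binomial(depth, target JAF) novel
    reads (zeroed with the dropout probability) and depth − Jn annotated
    reads; everyone else draws Poisson(depth) annotated reads per intron.
    Read sequences come from each individual's personalized genome.
    """
    cfg = config
    rng = np.random.default_rng((cfg.seed, 1))
    individuals = [f"IND{i:03d}" for i in range(cfg.n_individuals)]

    truth_by_intron: dict[tuple[str, int, int], TruthRecord] = {}
    for tr in truths:
        if tr.novel_boundary is not None:
            truth_by_intron[(tr.chrom, tr.intron_start, tr.intron_end)] = tr

    snvs_by_individual: dict[str, list[SnvRecord]] = {ind: [] for ind in individuals}
    for tr in truths:
        for ind in tr.carriers:
            snvs_by_individual[ind].append(
                SnvRecord(tr.chrom, tr.pos, tr.ref, tr.alt, ind, "het")
            )

    alignments: dict[str, list] = {}
    for ind in individuals:
        pgenome = apply_snvs(genome, snvs_by_individual[ind])
        rows: list = []
        for t in transcripts:
            pseq = pgenome[t.chrom]
            for s, e in t.introns():
                tr = truth_by_intron.get((t.chrom, s, e))
                novel_n = 0
                if tr is not None and ind in tr.novel_read_individuals:
                    dropped = (
                        tr.kind == KIND_SCM and rng.random() < cfg.dropout_rate
                    )
                    if not dropped:
                        novel_n = int(rng.binomial(cfg.read_depth, tr.expected_jaf))
                        ann_n = cfg.read_depth - novel_n
                    else:
                        ann_n = int(rng.poisson(cfg.read_depth))
                else:
                    ann_n = int(rng.poisson(cfg.read_depth))
                rows.extend(
                    _junction_reads(
                        rng, pseq, t.chrom, s, e, ann_n, cfg, t.strand,
                        f"{ind}:{t.chrom}:{s}-{e}:a",
                    )
                )
                if novel_n:
                    js, je = tr.novel_junction
                    rows.extend(
                        _junction_reads(
                            rng, pseq, t.chrom, js, je, novel_n, cfg, t.strand,
                            f"{ind}:{t.chrom}:{js}-{je}:n",
                        )
                    )
        alignments[ind] = rows
    return snvs_by_individual, alignments


# ---------------------------------------------------------------------------
# dataset I/O


def simulate(config: SimConfig) -> SimData:
    """Full in-memory simulation."""
    genome, transcripts, truths = simulate_genome(config)
    snvs, alignments = simulate_reads(genome, transcripts, truths, config)
    return SimData(
        config=config,
        genome=genome,
        transcripts=transcripts,
        truths=truths,
        individuals=[f"IND{i:03d}" for i in range(config.n_individuals)],
        snvs_by_individual=snvs,
        alignments_by_individual=alignments,
    )


def write_dataset(data: SimData, outdir: str | Path) -> Path:
    """Write genome.fa, annotation.gtf, truth.tsv, vcf/ and sam/ under outdir."""
    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    (outdir / "sam").mkdir(parents=True, exist_ok=True)
    write_fasta(data.genome, outdir / "genome.fa")
    write_annotation(data.transcripts, outdir / "annotation.gtf")
    contigs = {name: len(seq) for name, seq in data.genome.items()}
    for ind in data.individuals:
        write_vcf(
            [(s.chrom, s.pos, ".", s.ref, s.alt, "0/1")
             for s in data.snvs_by_individual[ind]],
            contigs,
            ind,
            outdir / "vcf" / f"{ind}.vcf",
        )
        write_sam(data.alignments_by_individual[ind], contigs,
                  outdir / "sam" / f"{ind}.sam")
    write_truth(data.truths, outdir / "truth.tsv")
    return outdir


def simulate_dataset(config: SimConfig, outdir: str | Path) -> SimData:
    data = simulate(config)
    write_dataset(data, outdir)
    return data


def write_truth(truths: Sequence[TruthRecord], path: str | Path) -> None:
    rows = []
    for tr in truths:
        row = asdict(tr)
        row["carriers"] = ",".join(tr.carriers)
        row["novel_read_individuals"] = ",".join(tr.novel_read_individuals)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_truth(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    out: list[TruthRecord] = []
    for r in df.to_dict("records"):
        for key in ("event_type", "side"):
            if pd.isna(r[key]):
                r[key] = None
        for key in ("delta_len", "annotated_boundary", "novel_boundary",
                    "intron_start", "intron_end"):
            r[key] = None if pd.isna(r[key]) else int(r[key])
        r["expected_jaf"] = None if pd.isna(r["expected_jaf"]) else float(r["expected_jaf"])
        r["carriers"] = tuple(str(r["carriers"]).split(",")) if r["carriers"] else ()
        nri = r["novel_read_individuals"]
        r["novel_read_individuals"] = (
            tuple(str(nri).split(",")) if isinstance(nri, str) and nri else ()
        )
        out.append(TruthRecord(**r))
    return out


# ---------------------------------------------------------------------------
# recovery evaluation


def evaluate_recovery(candidates, truths: Sequence[TruthRecord]) -> dict:
    """Compare pipeline candidates with the truth table.

    Precision/recall are over SNV identities of accepted candidates vs
    implanted true SCMs; decoys are checked for the expected verdict
    ('absent' decoys must yield no candidate at all).
    """
    accepted = {c.snv_key for c in candidates if c.accepted}
    verdicts: dict[tuple, set[str]] = {}
    for c in candidates:
        verdicts.setdefault(c.snv_key, set()).add(c.verdict)

    true_keys = {t.snv_key for t in truths if t.kind == KIND_SCM}
    tp = accepted & true_keys
    precision = len(tp) / len(accepted) if accepted else 1.0
    recall = len(tp) / len(true_keys) if true_keys else 1.0

    decoy_results = {}
    for t in truths:
        if t.kind == KIND_SCM:
            continue
        if t.expected_verdict == "absent":
            ok = t.snv_key not in verdicts
        else:
            ok = verdicts.get(t.snv_key) == {t.expected_verdict}
        decoy_results[t.scm_id] = ok
    return {
        "precision": precision,
        "recall": recall,
        "n_accepted": len(accepted),
        "n_true": len(true_keys),
        "decoys_correct": all(decoy_results.values()) if decoy_results else True,
        "decoy_results": decoy_results,
    }


# ---------------------------------------------------------------------------
# small standalone gene helper (used for randomized consequence sweeps)


def random_gene(
    rng: np.random.Generator,
    chrom: str = "chr1",
    strand: str = "+",
    n_exons: int = 4,
    exon_len: tuple[int, int] = (60, 120),
    intron_len: tuple[int, int] = (80, 200),
    flank: int = 60,
) -> tuple[str, Transcript]:
    """One clean random gene (canonical introns, stop-free ORF), no events."""
    cfg = SimConfig(
        n_genes=1,
        exons_per_gene=(n_exons, n_exons),
        exon_len=exon_len,
        intron_len=intron_len,
        n_individuals=2,
        n_true_scms=1,
        n_decoy_snvs=0,
        carriers_range=(1, 1),
        flank=flank,
        length_change=(4, min(exon_len[0] - 30, intron_len[0] - 25)),
        seed=int(rng.integers(2**31 - 1)),
    )
    seq, t, protected = _build_gene(rng, cfg, chrom, strand, 0)
    for s, e in t.introns():
        _enforce_tract(seq, s, e, strand, protected)
    _finalize_cds(seq, t, protected)
    return "".join(seq), t
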