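"""Transcript models and splice-site coordinate arithmetic.

All coordinates are 0-based, half-open on the forward genomic strand;
GTF I/O converts from/to 1-based inclusive at the boundary. A *donor*
boundary is encoded as the genomic coordinate of the exon/intron junction
at the 5' end of the intron in transcription orientation (the end of the
upstream exon in half-open convention), an *acceptor* as the coordinate of
the first exonic base of the downstream exon. On the minus strand the
donor therefore sits at the genomically-right edge of the intron.

Intron indices are in transcription order: intron ``i`` follows exon ``i``
of the transcript read 5'→3'. The *phase* of an intron is the number of
coding bases upstream of it modulo 3 (phase 0 = intron falls between
codons).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class SpliceSite:
    kind: str  # "donor" | "acceptor"
    boundary: int
    strand: str
    transcript_id: str
    intron_index: int  # transcription order


@dataclass
class Transcript:
    """A transcript: sorted genomic exons plus an optional CDS span.

    ``exons`` are (start, end) pairs in genomic order regardless of
    strand; ``cds_start``/``cds_end`` delimit the genomic CDS span
    (including both the start and stop codon).
    """

    id: str
    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: invalid strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.id}: invalid exon [{s}, {e})")
            if s < prev_end:
                raise ValueError(f"{self.id}: overlapping or unsorted exons")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.id}: partial CDS span")
        if self.cds_start is not None:
            if not any(s <= self.cds_start < e for s, e in self.exons):
                raise ValueError(f"{self.id}: cds_start outside exons")
            if not any(s < self.cds_end <= e for s, e in self.exons):
                raise ValueError(f"{self.id}: cds_end outside exons")

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic-order intron intervals."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def n_introns(self) -> int:
        return max(0, len(self.exons) - 1)

    def genomic_intron_index(self, transcription_index: int) -> int:
        if self.strand == "+":
            return transcription_index
        return self.n_introns - 1 - transcription_index

    def transcription_intron_index(self, genomic_index: int) -> int:
        # Involution: same formula both ways.
        return self.genomic_intron_index(genomic_index)

    def exon_boundaries(self) -> set[int]:
        out: set[int] = set()
        for s, e in self.exons:
            out.add(s)
            out.add(e)
        return out


# ---------------------------------------------------------------------------
# GTF I/O

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def load_annotation(gtf_path: str | Path) -> list[Transcript]:
    """Parse a GTF (Ensembl/UCSC attribute dialect) into Transcripts.

    Only ``exon`` and ``CDS`` features are consumed; 1-based inclusive
    coordinates are converted to 0-based half-open. Raises ``ValueError``
    naming the offending line for malformed rows, and a validation error
    for transcripts with overlapping exons.
    """
    builders: dict[str, dict] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{gtf_path}: malformed GTF line {lineno}: expected 9 "
                    f"tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start = int(start_s) - 1
                end = int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{gtf_path}: malformed GTF line {lineno}: "
                    f"non-integer coordinates"
                ) from exc
            attr = dict(_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            if tid is None:
                raise ValueError(
                    f"{gtf_path}: malformed GTF line {lineno}: missing transcript_id"
                )
            b = builders.setdefault(
                tid,
                {
                    "gene": attr.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                },
            )
            if feature == "exon":
                b["exons"].append((start, end))
            else:
                b["cds"].append((start, end))

    transcripts: list[Transcript] = []
    for tid, b in builders.items():
        exons = sorted(b["exons"])
        cds_start = cds_end = None
        if b["cds"]:
            cds_start = min(s for s, _ in b["cds"])
            cds_end = max(e for _, e in b["cds"])
        transcripts.append(
            Transcript(
                id=tid,
                gene=b["gene"],
                chrom=b["chrom"],
                strand=b["strand"],
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return transcripts


def write_annotation(transcripts: Iterable[Transcript], gtf_path: str | Path) -> None:
    """Write Transcripts back to GTF (exon + per-exon CDS rows)."""
    with open(gtf_path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene}"; transcript_id "{t.id}";'
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tscmscan\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
                if t.has_cds:
                    cs = max(s, t.cds_start)
                    ce = min(e, t.cds_end)
                    if cs < ce:
                        fh.write(
                            f"{t.chrom}\tscmscan\tCDS\t{cs + 1}\t{ce}\t.\t"
                            f"{t.strand}\t.\t{attrs}\n"
                        )


# ---------------------------------------------------------------------------
# Splice sites and intron phase


def annotated_splice_sites(t: Transcript) -> list[SpliceSite]:
    """One donor + one acceptor per intron, strand-aware.

    Returns sites in transcription order; a single-exon transcript yields
    an empty list.
    """
    sites: list[SpliceSite] = []
    introns = t.introns()
    for gi, (s, e) in enumerate(introns):
        ti = t.transcription_intron_index(gi)
        if t.strand == "+":
            donor, acceptor = s, e
        else:
            donor, acceptor = e, s
        sites.append(SpliceSite("donor", donor, t.strand, t.id, ti))
        sites.append(SpliceSite("acceptor", acceptor, t.strand, t.id, ti))
    sites.sort(key=lambda x: x.intron_index)
    return sites


def _coding_overlap(t: Transcript, lo: Optional[int] = None, hi: Optional[int] = None) -> int:
    """Number of CDS bases within exons, optionally restricted to [lo, hi)."""
    total = 0
    for s, e in t.exons:
        a = max(s, t.cds_start if lo is None else max(t.cds_start, lo))
        b = min(e, t.cds_end if hi is None else min(t.cds_end, hi))
        if a < b:
            total += b - a
    return total


def intron_phase(t: Transcript, intron_index: int) -> Optional[int]:
    """Phase of an intron (transcription-order index), or None.

    Phase = (number of coding bases transcription-upstream of the intron)
    mod 3. Undefined (None) for transcripts without CDS or introns falling
    entirely outside the CDS span.
    """
    if not t.has_cds:
        return None
    gi = t.genomic_intron_index(intron_index)
    introns = t.introns()
    if not (0 <= gi < len(introns)):
        raise IndexError(f"intron index {intron_index} out of range for {t.id}")
    s, e = introns[gi]
    if not (t.cds_start < s and e < t.cds_end):
        return None  # intron upstream or downstream of the CDS
    if t.strand == "+":
        upstream = _coding_overlap(t, hi=s)
    else:
        upstream = _coding_overlap(t, lo=e)
    return upstream % 3


def shifted_phase(old_phase: int, delta_len: int) -> int:
    """Intron phase after the upstream exonic length changes by delta_len.

    Positive delta = extension, negative = shrinkage; e.g. a phase-1
    intron downstream of a 17-bp shrinkage becomes phase 2.
    """
    if old_phase not in (0, 1, 2):
        raise ValueError(f"invalid phase {old_phase}")
    return (old_phase + delta_len) % 3


def resize_exon(t: Transcript, exon_index: int, side: str, delta: int) -> Transcript:
    """Return a copy of ``t`` with one exon edge moved by ``delta`` bases.

    ``side`` is 'left' or 'right' in genomic orientation; positive delta
    grows the exon. Used by simulation and oracle code; CDS span is
    clipped to remain within the exon union.
    """
    exons = list(t.exons)
    s, e = exons[exon_index]
    if side == "left":
        s -= delta
    elif side == "right":
        e += delta
    else:
        raise ValueError(side)
    if s >= e:
        raise ValueError("resize would empty the exon")
    exons[exon_index] = (s, e)
    return Transcript(
        id=t.id,
        gene=t.gene,
        chrom=t.chrom,
        strand=t.strand,
        exons=exons,
        cds_start=t.cds_start,
        cds_end=t.cds_end,
    )
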