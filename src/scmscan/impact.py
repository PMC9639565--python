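"""Transcript and protein consequences of extension/shrinkage events.

For a coding event the variant mRNA is respliced with the affected exon
resized at the event side, the annotated start codon is mapped through
the new structure, and translation is scanned for a premature
termination codon (PTC): any in-frame stop strictly upstream of the
position corresponding to the annotated stop. PTCs are classed by
whether they fall inside the (resized) event exon or in a downstream
exon via frameshift. In-frame, PTC-free events are checked for overlap
with known protein domains; 3-bp acceptor events are flagged when the
two alternative acceptors form a NAGNAG tandem motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from ._util import revcomp
from .gene_model import Transcript, intron_phase, shifted_phase
from .junction_events import SpliceEvent

PTC_NONE = "none"
PTC_IN_EVENT_EXON = "in_event_exon"
PTC_DOWNSTREAM = "downstream_frameshift"

DEFAULT_DOMAIN_EVALUE = 1e-4
NMD_RULE_NT = 50


@dataclass(frozen=True)
class DomainInterval:
    """A protein-domain hit in 1-based inclusive amino-acid coordinates."""

    protein_id: str
    start_aa: int
    end_aa: int
    domain: str
    e_value: float

    def __post_init__(self) -> None:
        if self.start_aa > self.end_aa:
            raise ValueError("start_aa > end_aa")


def load_domains(tsv_path: str | Path) -> list[DomainInterval]:
    """Read a domain table (transcript_id, start_aa, end_aa, domain, e_value)."""
    import pandas as pd

    df = pd.read_csv(tsv_path, sep="\t")
    return [
        DomainInterval(
            protein_id=str(r.transcript_id),
            start_aa=int(r.start_aa),
            end_aa=int(r.end_aa),
            domain=str(r.domain),
            e_value=float(r.e_value),
        )
        for r in df.itertuples()
    ]


@dataclass
class RebuiltTranscript:
    """Variant mRNA with key positions mapped into mRNA coordinates."""

    mrna: str
    cds_offset: Optional[int]  # None => start codon lost
    annotated_stop_pos: Optional[int]  # mRNA pos of the annotated stop codon start
    event_exon_span: tuple[int, int]  # mRNA half-open span of the resized exon
    last_junction_pos: Optional[int]  # mRNA pos of the final exon-exon junction

    @property
    def start_lost(self) -> bool:
        return self.cds_offset is None


@dataclass
class ImpactResult:
    event_key: tuple[str, str, int, int]
    coding: bool
    frameshift: bool
    old_phase: Optional[int]
    new_phase: Optional[int]
    ptc_class: str
    start_lost: bool = False
    domain_overlap: Optional[bool] = None  # None = unknown (no table)
    domain_names: list[str] = field(default_factory=list)
    nagnag: bool = False
    protein_delta: Optional[int] = None  # aa, for in-frame PTC-free events
    nmd_predicted: Optional[bool] = None


def _modified_exons(t: Transcript, event: SpliceEvent) -> list[tuple[int, int]]:
    exons = list(t.exons)
    s, e = exons[event.exon_index]
    if s == event.annotated_boundary:
        s = event.novel_boundary
    elif e == event.annotated_boundary:
        e = event.novel_boundary
    else:
        raise ValueError(
            f"event boundary {event.annotated_boundary} is not an edge of exon "
            f"{event.exon_index} of {t.id}"
        )
    if s >= e:
        raise ValueError("event removes the entire exon")
    exons[event.exon_index] = (s, e)
    return exons


def _splice(
    exons: Sequence[tuple[int, int]], seq: str, strand: str
) -> tuple[str, dict[int, int]]:
    """Concatenate exons into mRNA; return sequence + genomic→mRNA map."""
    order = exons if strand == "+" else list(reversed(exons))
    parts: list[str] = []
    gmap: dict[int, int] = {}
    offset = 0
    for s, e in order:
        if strand == "+":
            parts.append(seq[s:e])
            for i, p in enumerate(range(s, e)):
                gmap[p] = offset + i
        else:
            parts.append(revcomp(seq[s:e]))
            for i, p in enumerate(range(e - 1, s - 1, -1)):
                gmap[p] = offset + i
        offset += e - s
    return "".join(parts), gmap


def rebuild_transcript(
    t: Transcript, event: SpliceEvent, genome: Mapping[str, str]
) -> RebuiltTranscript:
    """Resplice the transcript with the event applied, strand-aware.

    The CDS reading frame is anchored by mapping the annotated start
    codon through the new exon structure; if the event removed it the
    result is flagged start-lost and the PTC scan is skipped.
    """
    seq = genome[t.chrom]
    exons = _modified_exons(t, event)
    mrna, gmap = _splice(exons, seq, t.strand)

    cds_offset: Optional[int] = None
    stop_pos: Optional[int] = None
    if t.has_cds:
        start_first = t.cds_start if t.strand == "+" else t.cds_end - 1
        stop_first = t.cds_end - 3 if t.strand == "+" else t.cds_start + 2
        cds_offset = gmap.get(start_first)
        stop_pos = gmap.get(stop_first)

    es, ee = exons[event.exon_index]
    span_points = [gmap[es], gmap[ee - 1]]
    span = (min(span_points), max(span_points) + 1)

    last_junction = None
    if len(exons) >= 2:
        total = sum(e - s for s, e in exons)
        last_len = (
            exons[-1][1] - exons[-1][0]
            if t.strand == "+"
            else exons[0][1] - exons[0][0]
        )
        last_junction = total - last_len

    return RebuiltTranscript(
        mrna=mrna,
        cds_offset=cds_offset,
        annotated_stop_pos=stop_pos,
        event_exon_span=span,
        last_junction_pos=last_junction,
    )


def scan_ptc(
    mrna: str,
    cds_offset: int,
    annotated_stop_pos: Optional[int],
    event_exon_span: tuple[int, int],
) -> tuple[str, Optional[int]]:
    """In-frame stop scan; returns (ptc_class, stop position in mRNA).

    Translates from the CDS offset; the first stop whose codon starts
    strictly upstream of the annotated stop position is a PTC, classed by
    whether it lies within the event exon's mRNA span.
    """
    cds = mrna[cds_offset:]
    cds = cds[: len(cds) - len(cds) % 3]
    protein = str(Seq(cds).translate())
    idx = protein.find("*")
    if idx == -1:
        return PTC_NONE, None
    stop_start = cds_offset + 3 * idx
    if annotated_stop_pos is not None and stop_start >= annotated_stop_pos:
        return PTC_NONE, stop_start
    lo, hi = event_exon_span
    if lo <= stop_start < hi:
        return PTC_IN_EVENT_EXON, stop_start
    return PTC_DOWNSTREAM, stop_start


def _cds_index(t: Transcript, pos: int) -> Optional[int]:
    """0-based index of a genomic position within the annotated CDS."""
    if not t.has_cds:
        return None
    if not (t.cds_start <= pos < t.cds_end):
        return None
    idx = 0
    exons = t.exons if t.strand == "+" else list(reversed(t.exons))
    for s, e in exons:
        cs, ce = max(s, t.cds_start), min(e, t.cds_end)
        if cs >= ce:
            continue
        if cs <= pos < ce:
            within = pos - cs if t.strand == "+" else ce - 1 - pos
            return idx + within
        idx += ce - cs
    return None


def affected_aa_interval(
    event: SpliceEvent, t: Transcript
) -> Optional[tuple[int, int]]:
    """1-based inclusive amino-acid interval touched by the event.

    Shrinkage: the codons of the removed exonic bases. Extension: the
    codon at the insertion point (the inserted residues sit between
    annotated codons). None when the event does not touch the CDS.
    """
    if not t.has_cds:
        return None
    ab, nb = event.annotated_boundary, event.novel_boundary
    if event.event_type == "shrinkage":
        lo, hi = min(ab, nb), max(ab, nb)
        lo = max(lo, t.cds_start)
        hi = min(hi, t.cds_end)
        if lo >= hi:
            return None
        c1 = _cds_index(t, lo)
        c2 = _cds_index(t, hi - 1)
        if c1 is None or c2 is None:
            return None
        aa_lo, aa_hi = sorted((c1 // 3, c2 // 3))
        return (aa_lo + 1, aa_hi + 1)
    # extension: anchor base on the exonic side of the annotated boundary
    s, e = t.exons[event.exon_index]
    if s == ab:
        anchor = ab  # exon starts at the boundary: first exonic base
    elif e == ab:
        anchor = ab - 1  # exon ends at the boundary: last exonic base
    else:
        return None
    c = _cds_index(t, anchor)
    if c is None:
        return None
    aa = c // 3 + 1
    return (aa, aa)


def domain_overlap(
    event: SpliceEvent,
    t: Transcript,
    domains: Optional[Sequence[DomainInterval]],
    e_threshold: float = DEFAULT_DOMAIN_EVALUE,
) -> tuple[Optional[bool], list[str]]:
    """Does the affected amino-acid interval hit any confident domain?

    Returns (None, []) when no domain table is available (unknown rather
    than false).
    """
    if domains is None:
        return None, []
    interval = affected_aa_interval(event, t)
    if interval is None:
        return False, []
    aa_lo, aa_hi = interval
    names = [
        d.domain
        for d in domains
        if d.protein_id == t.id
        and d.e_value <= e_threshold
        and d.start_aa <= aa_hi
        and d.end_aa >= aa_lo
    ]
    return bool(names), sorted(set(names))


def detect_nagnag(event: SpliceEvent, genome: Mapping[str, str]) -> bool:
    """True iff a 3-bp acceptor event has AG endings at both acceptors."""
    if event.side != "acceptor" or abs(event.delta_len) != 3:
        return False
    seq = genome[event.chrom]
    for b in (event.annotated_boundary, event.novel_boundary):
        if event.strand == "+":
            dinuc = seq[b - 2 : b].upper()
            if dinuc != "AG":
                return False
        else:
            dinuc = seq[b : b + 2].upper()
            if dinuc != "CT":  # AG on the transcribed strand
                return False
    return True


def _downstream_intron_phase(t: Transcript, event: SpliceEvent) -> Optional[int]:
    """Phase of the first intron transcription-downstream of the event exon."""
    gi = event.exon_index if t.strand == "+" else event.exon_index - 1
    if not (0 <= gi < t.n_introns):
        return None
    return intron_phase(t, t.transcription_intron_index(gi))


def _is_coding(event: SpliceEvent, t: Transcript) -> bool:
    if not t.has_cds:
        return False
    ab, nb = event.annotated_boundary, event.novel_boundary
    if event.event_type == "shrinkage":
        lo, hi = min(ab, nb), max(ab, nb)
        return lo < t.cds_end and hi > t.cds_start
    return t.cds_start < ab < t.cds_end


def classify_impact(
    event: SpliceEvent,
    t: Transcript,
    genome: Mapping[str, str],
    domains: Optional[Sequence[DomainInterval]] = None,
    e_threshold: float = DEFAULT_DOMAIN_EVALUE,
) -> ImpactResult:
    """Full consequence classification of one event on one transcript."""
    coding = _is_coding(event, t)
    old_phase = _downstream_intron_phase(t, event) if coding else None
    new_phase = (
        shifted_phase(old_phase, event.delta_len) if old_phase is not None else None
    )
    frameshift = coding and abs(event.delta_len) % 3 != 0
    nagnag = detect_nagnag(event, genome)

    ptc_class = PTC_NONE
    start_lost = False
    protein_delta: Optional[int] = None
    nmd: Optional[bool] = None
    dom: Optional[bool] = None
    dom_names: list[str] = []

    if coding:
        rebuilt = rebuild_transcript(t, event, genome)
        if rebuilt.start_lost:
            start_lost = True
        else:
            ptc_class, stop_pos = scan_ptc(
                rebuilt.mrna,
                rebuilt.cds_offset,
                rebuilt.annotated_stop_pos,
                rebuilt.event_exon_span,
            )
            if ptc_class != PTC_NONE and rebuilt.last_junction_pos is not None:
                nmd = stop_pos < rebuilt.last_junction_pos - NMD_RULE_NT
            if ptc_class == PTC_NONE:
                if event.delta_len % 3 == 0:
                    protein_delta = event.delta_len // 3
                dom, dom_names = domain_overlap(event, t, domains, e_threshold)

    return ImpactResult(
        event_key=event.key,
        coding=coding,
        frameshift=frameshift,
        old_phase=old_phase,
        new_phase=new_phase,
        ptc_class=ptc_class,
        start_lost=start_lost,
        domain_overlap=dom,
        domain_names=dom_names,
        nagnag=nagnag,
        protein_delta=protein_delta,
        nmd_predicted=nmd,
    )
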