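"""Splice-junction extraction and extension/shrinkage event classification.

A junction is the reference gap of an ``N`` CIGAR operation in a spliced
alignment. A junction becomes an exon *extension* or *shrinkage* event
when exactly one of its ends coincides with an annotated splice site of
some intron while the other end is novel (coincides with no annotated
exon boundary at all) and falls strictly inside the annotated intron
(extension: the adjacent exon grows into the intron) or strictly inside
the adjacent exon (shrinkage). Default filters follow the discovery
procedure: at least 2 supporting reads, and an aligned anchor of at least
5 bp on the novel side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from .gene_model import Transcript

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 2
DEFAULT_MIN_ANCHOR = 5

# CIGAR ops that consume the reference and count as aligned blocks
_ALIGNED_OPS = {0, 7, 8}  # M, =, X


@dataclass
class JunctionRecord:
    """An observed intron call aggregated over supporting reads.

    ``anchors`` holds one (left, right) pair per supporting read: the
    lengths of the aligned blocks immediately flanking the gap.
    """

    chrom: str
    intron_start: int  # first intronic base, 0-based
    intron_end: int  # one past the last intronic base
    strand: str  # "+", "-" or "."
    individual: str
    anchors: list[tuple[int, int]] = field(default_factory=list)

    @property
    def read_count(self) -> int:
        return len(self.anchors)

    @property
    def max_left_anchor(self) -> int:
        return max(a for a, _ in self.anchors)

    @property
    def max_right_anchor(self) -> int:
        return max(b for _, b in self.anchors)

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.intron_start, self.intron_end)


@dataclass
class SpliceEvent:
    """A classified exon extension/shrinkage event in one individual."""

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exon_index: int  # genomic-order index of the affected exon
    event_type: str  # "extension" | "shrinkage"
    side: str  # "donor" | "acceptor"
    annotated_boundary: int
    novel_boundary: int
    delta_len: int  # + extension, − shrinkage
    individual: str
    Jn: int = 0
    Ja: int = 0
    # genomic interval of the annotated intron being respliced
    intron_start: int = 0
    intron_end: int = 0

    @property
    def key(self) -> tuple[str, str, int, int]:
        """Reporting identity: (gene, side, annotated boundary, novel boundary)."""
        return (self.gene, self.side, self.annotated_boundary, self.novel_boundary)

    @property
    def jaf(self) -> Optional[float]:
        from .scm_attribution import jaf

        return jaf(self.Jn, self.Ja)


def extract_junctions(
    sam_path: str | Path,
    individual: str,
    genome: Optional[Mapping[str, str]] = None,
) -> list[JunctionRecord]:
    """Collect distinct N-gap junctions from a SAM/BAM with per-read anchors.

    Strand comes from the XS (or ts) tag when present, else from GT–AG
    orientation if ``genome`` is given, else ".".
    """
    junctions: dict[tuple[str, int, int], JunctionRecord] = {}
    mode = "rb" if str(sam_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(sam_path), mode, check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.cigartuples is None:
                continue
            xs = None
            if read.has_tag("XS"):
                xs = read.get_tag("XS")
            elif read.has_tag("ts"):
                xs = read.get_tag("ts")
            ref_pos = read.reference_start
            block = 0  # length of the current contiguous aligned block
            open_gap: Optional[tuple[int, int, int]] = None  # (gs, ge, left)
            for op, length in read.cigartuples:
                if op in _ALIGNED_OPS:
                    block += length
                    ref_pos += length
                elif op == 3:  # N: splice gap
                    if open_gap is not None:  # block closes the previous gap
                        gs, ge, left = open_gap
                        _record(junctions, read.reference_name, gs, ge, left, block, xs, individual)
                    open_gap = (ref_pos, ref_pos + length, block)
                    ref_pos += length
                    block = 0
                elif op == 2:  # D consumes reference, breaks the block
                    ref_pos += length
                    block = 0
                else:  # I/S/H/P break the aligned block, consume no reference
                    block = 0
            if open_gap is not None:
                gs, ge, left = open_gap
                _record(junctions, read.reference_name, gs, ge, left, block, xs, individual)
    out = list(junctions.values())
    if genome is not None:
        for j in out:
            if j.strand == ".":
                j.strand = _infer_strand(genome, j)
    out.sort(key=lambda j: j.key)
    return out


def _record(junctions, chrom, gs, ge, left, right, xs, individual) -> None:
    key = (chrom, gs, ge)
    rec = junctions.get(key)
    if rec is None:
        strand = xs if xs in ("+", "-") else "."
        rec = JunctionRecord(chrom, gs, ge, strand, individual)
        junctions[key] = rec
    elif rec.strand == "." and xs in ("+", "-"):
        rec.strand = xs
    rec.anchors.append((left, right))


def _infer_strand(genome: Mapping[str, str], j: JunctionRecord) -> str:
    seq = genome.get(j.chrom)
    if seq is None:
        return "."
    first2 = seq[j.intron_start : j.intron_start + 2].upper()
    last2 = seq[j.intron_end - 2 : j.intron_end].upper()
    if first2 == "GT" and last2 == "AG":
        return "+"
    if first2 == "CT" and last2 == "AC":
        return "-"
    return "."


# ---------------------------------------------------------------------------
# Classification


class AnnotationIndex:
    """Fast lookup of annotated intron ends and exon boundaries."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.boundaries: dict[str, set[int]] = {}
        # (chrom, strand, intron_start) -> [(transcript, genomic intron idx)]
        self.by_start: dict[tuple[str, str, int], list[tuple[Transcript, int]]] = {}
        self.by_end: dict[tuple[str, str, int], list[tuple[Transcript, int]]] = {}
        for t in transcripts:
            self.boundaries.setdefault(t.chrom, set()).update(t.exon_boundaries())
            for gi, (s, e) in enumerate(t.introns()):
                self.by_start.setdefault((t.chrom, t.strand, s), []).append((t, gi))
                self.by_end.setdefault((t.chrom, t.strand, e), []).append((t, gi))

    def is_exon_boundary(self, chrom: str, pos: int) -> bool:
        return pos in self.boundaries.get(chrom, ())


def classify_event(
    j: JunctionRecord,
    model: Iterable[Transcript] | AnnotationIndex,
    min_reads: int = DEFAULT_MIN_READS,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> list[SpliceEvent]:
    """Classify one junction against the gene model.

    Returns one event per matching transcript (the reporting layer
    deduplicates by (gene, side, annotated boundary, novel boundary)),
    or an empty list when the junction is annotated splicing, matches
    neither end, fails the read/anchor filters, or its novel end lies
    outside the adjacent intron/exon.
    """
    index = model if isinstance(model, AnnotationIndex) else AnnotationIndex(model)
    if j.read_count < min_reads:
        return []
    strands = [j.strand] if j.strand in ("+", "-") else ["+", "-"]
    events: list[SpliceEvent] = []
    for strand in strands:
        left_hits = index.by_start.get((j.chrom, strand, j.intron_start), [])
        right_hits = index.by_end.get((j.chrom, strand, j.intron_end), [])
        for t, gi in left_hits:
            ev = _classify_one(j, t, gi, matched="left", index=index, min_reads=min_reads, min_anchor=min_anchor)
            if ev is not None:
                events.append(ev)
        for t, gi in right_hits:
            ev = _classify_one(j, t, gi, matched="right", index=index, min_reads=min_reads, min_anchor=min_anchor)
            if ev is not None:
                events.append(ev)
    if j.strand == "." and len({e.strand for e in events}) > 1:
        logger.info(
            "junction %s:%d-%d matches annotation on both strands; dropped",
            j.chrom, j.intron_start, j.intron_end,
        )
        return []
    return events


def _classify_one(
    j: JunctionRecord,
    t: Transcript,
    gi: int,
    matched: str,
    index: AnnotationIndex,
    min_reads: int,
    min_anchor: int,
) -> Optional[SpliceEvent]:
    s, e = t.introns()[gi]
    if matched == "left":
        novel = j.intron_end
        if novel == e:
            return None  # fully annotated junction
        affected_exon = gi + 1
    else:
        novel = j.intron_start
        if novel == s:
            return None
        affected_exon = gi
    if index.is_exon_boundary(j.chrom, novel):
        return None  # novel end coincides with some annotated boundary

    # anchor confidence on the novel side, per supporting read
    if matched == "left":
        qualifying = sum(1 for _, r in j.anchors if r >= min_anchor)
    else:
        qualifying = sum(1 for l, _ in j.anchors if l >= min_anchor)
    if qualifying < min_reads:
        return None

    # which annotated site does the novel end replace?
    if matched == "left":
        # retained site at intron start; replaced site at intron end
        side = "acceptor" if t.strand == "+" else "donor"
        annotated = e
    else:
        side = "donor" if t.strand == "+" else "acceptor"
        annotated = s

    ex_s, ex_e = t.exons[affected_exon]
    if s < novel < e:
        event_type = "extension"
        delta = abs(novel - annotated)
    elif ex_s < novel < ex_e:
        event_type = "shrinkage"
        delta = -abs(novel - annotated)
    else:
        return None  # beyond the partner exon / inside another feature

    return SpliceEvent(
        transcript_id=t.id,
        gene=t.gene,
        chrom=j.chrom,
        strand=t.strand,
        exon_index=affected_exon,
        event_type=event_type,
        side=side,
        annotated_boundary=annotated,
        novel_boundary=novel,
        delta_len=delta,
        individual=j.individual,
        Jn=j.read_count,
        intron_start=s,
        intron_end=e,
    )


def count_annotated_support(
    junctions: Sequence[JunctionRecord], event: SpliceEvent
) -> SpliceEvent:
    """Fill Jn/Ja from the individual's junction list.

    Jn = reads on the novel junction, Ja = reads on the annotated junction
    of the same intron (0 if unobserved).
    """
    by_key = {j.key: j for j in junctions}
    # novel junction interval: the retained end is the one not replaced
    if event.annotated_boundary == event.intron_end:
        novel_key = (event.chrom, event.intron_start, event.novel_boundary)
    else:
        novel_key = (event.chrom, event.novel_boundary, event.intron_end)
    ann_key = (event.chrom, event.intron_start, event.intron_end)
    novel = by_key.get(novel_key)
    event.Jn = novel.read_count if novel is not None else event.Jn
    ann = by_key.get(ann_key)
    event.Ja = ann.read_count if ann is not None else 0
    return event


def find_events(
    junctions: Sequence[JunctionRecord],
    model: Iterable[Transcript] | AnnotationIndex,
    min_reads: int = DEFAULT_MIN_READS,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> list[SpliceEvent]:
    """Classify all junctions of one individual and fill Jn/Ja."""
    index = model if isinstance(model, AnnotationIndex) else AnnotationIndex(model)
    events: list[SpliceEvent] = []
    for j in junctions:
        for ev in classify_event(j, index, min_reads=min_reads, min_anchor=min_anchor):
            events.append(count_annotated_support(junctions, ev))
    return events
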