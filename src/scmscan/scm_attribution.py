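"""Attribution of splice events to candidate splice-site-creating SNVs.

Candidate SNVs are sought in the splice-site window anchored on the
*novel* boundary of each event: 3 exonic + 6 intronic bases for a donor
(9 bp) and 18 intronic + 3 exonic bases for an acceptor (21 bp). A
candidate is accepted only when, across the cohort, the number of
individuals carrying both the SNV and the event exceeds the number of
carriers without the event, and no non-carrier shows any novel-junction
read. The junction allele fraction JAF = Jn/(Jn+Ja) quantifies the
relative usage of the novel splice site per individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .gene_model import GenomicInterval
from .junction_events import JunctionRecord, SpliceEvent
from .personalize import SnvRecord

# Attribution window geometry (bases)
DONOR_EXONIC = 3
DONOR_INTRONIC = 6
ACCEPTOR_INTRONIC = 18
ACCEPTOR_EXONIC = 3

VERDICT_ACCEPTED = "accepted"
VERDICT_CONCORDANCE = "rejected_concordance"
VERDICT_NONCARRIER = "rejected_nonCarrier_event"


@dataclass(frozen=True)
class SpliceWindow:
    """Exonic + intronic attribution window around a splice boundary."""

    kind: str  # "donor" | "acceptor"
    exonic: GenomicInterval
    intronic: GenomicInterval
    boundary: int

    def contains(self, pos: int) -> bool:
        return self.exonic.contains(pos) or self.intronic.contains(pos)

    def offset_of(self, pos: int) -> int:
        """Signed offset relative to the boundary, transcription-oriented.

        Exonic positions are negative (−1 = exonic base adjacent to the
        boundary), intronic positions positive (+1 = intronic base
        adjacent to the boundary), for donors and acceptors alike.
        """
        strand = self.exonic.strand
        b = self.boundary
        exonic = self.exonic.contains(pos)
        if not exonic and not self.intronic.contains(pos):
            raise ValueError(f"position {pos} outside window")
        if self.kind == "donor":
            if strand == "+":
                return pos - b if exonic else pos - b + 1
            return -(pos - b + 1) if exonic else b - pos
        else:  # acceptor
            if strand == "+":
                return -(pos - b + 1) if exonic else b - pos
            return pos - b if exonic else pos - b + 1


def build_window(
    novel_boundary: int,
    kind: str,
    strand: str,
    chrom: str = "",
    contig_length: Optional[int] = None,
    acceptor_window_intronic: int = ACCEPTOR_INTRONIC,
) -> SpliceWindow:
    """Attribution window at a boundary: donor 3+6 bp, acceptor 18+3 bp.

    Mirrored on the minus strand. Windows running off the contig end are
    truncated (``contig_length`` given) with the same boundary anchor.
    """
    b = novel_boundary
    if kind == "donor":
        if strand == "+":
            ex = (b - DONOR_EXONIC, b)
            intr = (b, b + DONOR_INTRONIC)
        else:
            intr = (b - DONOR_INTRONIC, b)
            ex = (b, b + DONOR_EXONIC)
    elif kind == "acceptor":
        if strand == "+":
            intr = (b - acceptor_window_intronic, b)
            ex = (b, b + ACCEPTOR_EXONIC)
        else:
            ex = (b - ACCEPTOR_EXONIC, b)
            intr = (b, b + acceptor_window_intronic)
    else:
        raise ValueError(f"unknown site kind {kind!r}")

    def clip(iv: tuple[int, int]) -> GenomicInterval:
        s, e = iv
        s = max(0, s)
        if contig_length is not None:
            e = min(e, contig_length)
        return GenomicInterval(chrom or "window", s, e, strand)

    return SpliceWindow(kind=kind, exonic=clip(ex), intronic=clip(intr), boundary=b)


@dataclass
class ScmCandidate:
    """An SNV/event pairing with cohort concordance counts and verdict."""

    snv_key: tuple[str, int, str, str]  # chrom, pos, ref, alt
    event_key: tuple[str, str, int, int]  # gene, side, annotated, novel
    chrom: str
    strand: str
    event_type: str
    delta_len: int
    offset_in_window: int
    N_both: int = 0
    N_snv_only: int = 0
    N_event_only: int = 0
    verdict: str = ""
    jaf_by_individual: dict[str, float] = field(default_factory=dict)

    @property
    def mean_jaf(self) -> Optional[float]:
        if not self.jaf_by_individual:
            return None
        vals = list(self.jaf_by_individual.values())
        return sum(vals) / len(vals)

    @property
    def accepted(self) -> bool:
        return self.verdict == VERDICT_ACCEPTED


def jaf(Jn: int, Ja: int) -> Optional[float]:
    """Junction allele fraction Jn/(Jn+Ja); None when no reads at all."""
    if Jn < 0 or Ja < 0:
        raise ValueError("negative read counts")
    total = Jn + Ja
    if total == 0:
        return None
    return Jn / total


def candidate_snvs(
    event: SpliceEvent,
    snvs_by_individual: Mapping[str, Sequence[SnvRecord]],
    acceptor_window_intronic: int = ACCEPTOR_INTRONIC,
) -> list[tuple[SnvRecord, int]]:
    """SNVs of any individual inside the event's novel-boundary window.

    Returns (record, offset) pairs; multiple SNVs in one window are all
    returned and scored independently downstream. Duplicate SNV
    identities across individuals collapse to one entry.
    """
    window = build_window(
        event.novel_boundary,
        event.side,
        event.strand,
        chrom=event.chrom,
        acceptor_window_intronic=acceptor_window_intronic,
    )
    seen: dict[tuple[str, int, str, str], tuple[SnvRecord, int]] = {}
    for individual in sorted(snvs_by_individual):
        for snv in snvs_by_individual[individual]:
            if snv.chrom != event.chrom or not window.contains(snv.pos):
                continue
            if snv.key not in seen:
                seen[snv.key] = (snv, window.offset_of(snv.pos))
    return list(seen.values())


def concordance_filter(
    snv: SnvRecord | tuple[str, int, str, str],
    event_individuals: Iterable[str],
    carriers: Iterable[str],
    novel_read_individuals: Optional[Iterable[str]] = None,
) -> tuple[int, int, int, str]:
    """Cross-individual concordance counts and verdict for one SNV/event pair.

    N_both = carriers showing the event; N_snv_only = carriers without it
    (tolerated: low expression can hide a true event); N_event_only =
    non-carriers with at least one novel-junction read (fatal: the SNV
    cannot be causal). Accepted iff N_both > N_snv_only and
    N_event_only == 0.
    """
    carriers = set(carriers)
    with_event = set(event_individuals)
    novel_reads = set(novel_read_individuals) if novel_read_individuals is not None else with_event
    n_both = len(carriers & with_event)
    n_snv_only = len(carriers - with_event)
    n_event_only = len(novel_reads - carriers)
    if n_event_only > 0:
        verdict = VERDICT_NONCARRIER
    elif n_both > n_snv_only:
        verdict = VERDICT_ACCEPTED
    else:
        verdict = VERDICT_CONCORDANCE
    return n_both, n_snv_only, n_event_only, verdict


def attribute(
    events: Sequence[SpliceEvent],
    snvs_by_individual: Mapping[str, Sequence[SnvRecord]],
    junctions_by_individual: Optional[Mapping[str, Sequence[JunctionRecord]]] = None,
    acceptor_window_intronic: int = ACCEPTOR_INTRONIC,
) -> list[ScmCandidate]:
    """Pair events with candidate SNVs cohort-wide and apply concordance.

    ``events`` is the per-individual event table (post-filter); when
    ``junctions_by_individual`` is given, the strict non-carrier rule
    counts any individual with ≥1 novel-junction read, even below the
    event filters.
    """
    # group events by reporting identity
    by_key: dict[tuple, list[SpliceEvent]] = {}
    for ev in events:
        by_key.setdefault(ev.key, []).append(ev)

    carriers_of: dict[tuple[str, int, str, str], set[str]] = {}
    for individual, snvs in snvs_by_individual.items():
        for snv in snvs:
            carriers_of.setdefault(snv.key, set()).add(individual)

    candidates: list[ScmCandidate] = []
    for key in sorted(by_key):
        group = by_key[key]
        rep = group[0]
        event_individuals = {ev.individual for ev in group}
        novel_reads: Optional[set[str]] = None
        if junctions_by_individual is not None:
            if rep.annotated_boundary == rep.intron_end:
                jkey = (rep.chrom, rep.intron_start, rep.novel_boundary)
            else:
                jkey = (rep.chrom, rep.novel_boundary, rep.intron_end)
            novel_reads = set()
            for individual, juncs in junctions_by_individual.items():
                if any(j.key == jkey for j in juncs):
                    novel_reads.add(individual)
        for snv, offset in candidate_snvs(
            rep, snvs_by_individual, acceptor_window_intronic=acceptor_window_intronic
        ):
            carriers = carriers_of[snv.key]
            n_both, n_snv_only, n_event_only, verdict = concordance_filter(
                snv, event_individuals, carriers, novel_reads
            )
            cand = ScmCandidate(
                snv_key=snv.key,
                event_key=rep.key,
                chrom=rep.chrom,
                strand=rep.strand,
                event_type=rep.event_type,
                delta_len=rep.delta_len,
                offset_in_window=offset,
                N_both=n_both,
                N_snv_only=n_snv_only,
                N_event_only=n_event_only,
                verdict=verdict,
            )
            for ev in group:
                if ev.individual in carriers:
                    value = jaf(ev.Jn, ev.Ja)
                    if value is not None:
                        cand.jaf_by_individual[ev.individual] = value
            candidates.append(cand)
    return candidates
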