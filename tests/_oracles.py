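"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: list-based splicing, manual reverse complement and
codon stepping, no reuse of the package's mapping helpers.
"""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_STOPS = {"TAA", "TAG", "TGA"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def oracle_ptc(seq: str, transcript, event):
    """Naive splice-and-translate PTC scan.

    Returns (ptc_class, stop position in mRNA or None); mirrors the
    scientific definition directly: resize the affected exon, splice,
    locate the start codon, step codons until a stop, compare with the
    annotated stop position.
    """
    exons = [list(x) for x in transcript.exons]
    ex = exons[event.exon_index]
    if ex[0] == event.annotated_boundary:
        ex[0] = event.novel_boundary
    elif ex[1] == event.annotated_boundary:
        ex[1] = event.novel_boundary
    else:
        raise AssertionError("event boundary not on affected exon")

    gpos = [p for s, e in exons for p in range(s, e)]
    mrna = "".join(seq[s:e] for s, e in exons)
    if transcript.strand == "-":
        mrna = rc(mrna)
        gpos = gpos[::-1]

    start_g = (
        transcript.cds_start if transcript.strand == "+" else transcript.cds_end - 1
    )
    if start_g not in gpos:
        return "start_lost", None
    cds_off = gpos.index(start_g)
    stop_g = (
        transcript.cds_end - 3 if transcript.strand == "+" else transcript.cds_start + 2
    )
    stop_pos = gpos.index(stop_g) if stop_g in gpos else None

    es, ee = exons[event.exon_index]
    span_idx = sorted((gpos.index(es), gpos.index(ee - 1)))
    span = (span_idx[0], span_idx[1] + 1)

    i = cds_off
    while i + 3 <= len(mrna):
        codon = mrna[i : i + 3]
        if codon in _STOPS:
            if stop_pos is not None and i >= stop_pos:
                return "none", i
            if span[0] <= i < span[1]:
                return "in_event_exon", i
            return "downstream_frameshift", i
        i += 3
    return "none", None


def random_event_for(rng, transcript, max_delta: int = 30):
    """Draw a random well-formed extension/shrinkage event on a transcript."""
    from scmscan.junction_events import SpliceEvent

    t = transcript
    gi = int(rng.integers(0, t.n_introns))
    s, e = t.introns()[gi]
    side = ("donor", "acceptor")[int(rng.integers(2))]
    etype = ("extension", "shrinkage")[int(rng.integers(2))]
    replaced_left = (side == "donor") == (t.strand == "+")
    if replaced_left:
        ab, exon_idx = s, gi
    else:
        ab, exon_idx = e, gi + 1
    ex_s, ex_e = t.exons[exon_idx]
    if etype == "extension":
        hi = min(max_delta, e - s - 1)
    else:
        hi = min(max_delta, ex_e - ex_s - 1)
    delta = int(rng.integers(1, hi + 1))
    if replaced_left:
        nb = ab + delta if etype == "extension" else ab - delta
    else:
        nb = ab - delta if etype == "extension" else ab + delta
    return SpliceEvent(
        transcript_id=t.id,
        gene=t.gene,
        chrom=t.chrom,
        strand=t.strand,
        exon_index=exon_idx,
        event_type=etype,
        side=side,
        annotated_boundary=ab,
        novel_boundary=nb,
        delta_len=delta if etype == "extension" else -delta,
        individual="IND000",
    )
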