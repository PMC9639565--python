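import numpy as np
import pytest
from _oracles import oracle_ptc, random_event_for

from scmscan import synthetic_data as sd
from scmscan.gene_model import Transcript
from scmscan.impact import (
    DomainInterval,
    affected_aa_interval,
    classify_impact,
    detect_nagnag,
    domain_overlap,
    rebuild_transcript,
    scan_ptc,
)
from scmscan.junction_events import SpliceEvent


def _event(t, etype, side, delta, exon_index, ab, nb, gi):
    s, e = t.introns()[gi]
    return SpliceEvent(
        transcript_id=t.id, gene=t.gene, chrom=t.chrom, strand=t.strand,
        exon_index=exon_index, event_type=etype, side=side,
        annotated_boundary=ab, novel_boundary=nb,
        delta_len=delta, individual="I", intron_start=s, intron_end=e,
    )


@pytest.fixture
def gene(rng):
    seq, t = sd.random_gene(rng, strand="+", n_exons=4)
    return seq, t


def test_rebuild_extension_lengthens_mrna(gene):
    seq, t = gene
    s, e = t.introns()[1]
    ev = _event(t, "extension", "acceptor", 8, 2, e, e - 8, 1)
    genome = {t.chrom: seq}
    rebuilt = rebuild_transcript(t, ev, genome)
    annotated_len = sum(b - a for a, b in t.exons)
    assert len(rebuilt.mrna) == annotated_len + 8


def test_rebuild_inframe_shrinkage_shortens_protein_one_residue(gene):
    seq, t = gene
    s, e = t.introns()[1]
    ev = _event(t, "shrinkage", "donor", -3, 1, s, s - 3, 1)
    genome = {t.chrom: seq}
    res = classify_impact(ev, t, genome)
    assert res.coding and not res.frameshift
    assert res.ptc_class == "none" or res.protein_delta is None
    if res.ptc_class == "none":
        assert res.protein_delta == -1


def test_scan_ptc_unchanged_cds_has_no_ptc():
    #          start     stop
    mrna = "GG" + "ATGAAATAA" + "CC"
    cls, pos = scan_ptc(mrna, 2, 8, (0, 2))
    assert cls == "none"


def test_scan_ptc_in_event_exon():
    """A 1-nt frame shift reads TGA inside the event exon span."""
    cls, _ = scan_ptc("ATGTTGACCTAAGGG", 0, 9, (3, 8))
    # codons ATG TTG ACC TAA: the stop at 9 is the annotated one
    assert cls == "none"
    cls, pos = scan_ptc("ATGTGACCCTAAGGG", 0, 9, (3, 8))
    # codons ATG TGA ...: premature stop at 3, inside the event exon span
    assert cls == "in_event_exon" and pos == 3


def test_scan_ptc_downstream_frameshift():
    cls, pos = scan_ptc("ATGCCCAAATAGGGGTAA", 0, 15, (3, 6))
    # codons: ATG CCC AAA TAG -> stop at 9, outside event exon (3,6)
    assert cls == "downstream_frameshift" and pos == 9


def test_scan_ptc_agrees_with_oracle_on_fixture_events(rng):
    """Implementation vs naive splice-and-translate oracle on random
    events over random clean genes."""
    n_checked = 0
    for i in range(12):
        strand = "+" if i % 2 == 0 else "-"
        seq, t = sd.random_gene(rng, strand=strand, n_exons=4)
        genome = {t.chrom: seq}
        for _ in range(5):
            ev = random_event_for(rng, t)
            expected_cls, expected_pos = oracle_ptc(seq, t, ev)
            rebuilt = rebuild_transcript(t, ev, genome)
            if expected_cls == "start_lost":
                assert rebuilt.start_lost
                continue
            got_cls, got_pos = scan_ptc(
                rebuilt.mrna, rebuilt.cds_offset,
                rebuilt.annotated_stop_pos, rebuilt.event_exon_span,
            )
            assert (got_cls, got_pos) == (expected_cls, expected_pos)
            n_checked += 1
    assert n_checked >= 40


def test_domain_overlap_rules():
    t = Transcript(id="T", gene="G", chrom="c", strand="+",
                   exons=[(0, 300)], cds_start=0, cds_end=300)
    # single-exon transcript with a fake internal "event" interval:
    # -3 shrinkage removing aa 50 (cds bases 147..150)
    ev = SpliceEvent(
        transcript_id="T", gene="G", chrom="c", strand="+", exon_index=0,
        event_type="shrinkage", side="donor", annotated_boundary=150,
        novel_boundary=147, delta_len=-3, individual="I",
    )
    assert affected_aa_interval(ev, t) == (50, 50)
    hit = [DomainInterval("T", 40, 60, "PF_hit", 1e-10)]
    weak = [DomainInterval("T", 40, 60, "PF_weak", 0.01)]
    far = [DomainInterval("T", 1, 10, "PF_far", 1e-10)]
    assert domain_overlap(ev, t, hit) == (True, ["PF_hit"])
    assert domain_overlap(ev, t, weak)[0] is False  # above E-value threshold
    assert domain_overlap(ev, t, far)[0] is False
    assert domain_overlap(ev, t, None)[0] is None  # unknown, not false


def test_detect_nagnag():
    #            0123456789...
    seq = "TTTTTTCAGCAGGGGGGGGG"
    genome = {"c": seq}
    # acceptor boundaries at 9 (annotated) and 12 (novel): both preceded by AG
    ev = SpliceEvent(
        transcript_id="T", gene="G", chrom="c", strand="+", exon_index=1,
        event_type="shrinkage", side="acceptor", annotated_boundary=9,
        novel_boundary=12, delta_len=-3, individual="I",
    )
    assert detect_nagnag(ev, genome)
    ev8 = SpliceEvent(
        transcript_id="T", gene="G", chrom="c", strand="+", exon_index=1,
        event_type="extension", side="acceptor", annotated_boundary=17,
        novel_boundary=9, delta_len=8, individual="I",
    )
    assert not detect_nagnag(ev8, genome)  # 8 bp apart: not a tandem motif
    donor = SpliceEvent(
        transcript_id="T", gene="G", chrom="c", strand="+", exon_index=1,
        event_type="extension", side="donor", annotated_boundary=9,
        novel_boundary=12, delta_len=3, individual="I",
    )
    assert not detect_nagnag(donor, genome)  # donor side by definition


def test_detect_nagnag_minus_strand():
    # '-' acceptor ends with genomic CT (AG transcribed)
    seq = "GGGGGCTGCTGGGGGGG"
    genome = {"c": seq}
    ev = SpliceEvent(
        transcript_id="T", gene="G", chrom="c", strand="-", exon_index=0,
        event_type="extension", side="acceptor", annotated_boundary=5,
        novel_boundary=8, delta_len=3, individual="I",
    )
    assert detect_nagnag(ev, genome)


def test_frameshift_flag_consistency(default_run):
    """frameshift <=> coding and |delta| not a multiple of 3, across the
    whole synthetic cohort."""
    data, result = default_run
    assert result.impacts
    delta_of = {c.event_key: c.delta_len for c in result.candidates}
    for key, res in result.impacts.items():
        assert res.frameshift == (res.coding and abs(delta_of[key]) % 3 != 0)
        if res.old_phase is not None and res.new_phase is not None:
            assert res.new_phase == (res.old_phase + delta_of[key]) % 3


def test_inframe_events_without_inserted_stop_have_no_downstream_ptc(rng):
    """An in-frame event can only yield a downstream PTC if the altered
    sequence itself introduces an in-frame stop."""
    for i in range(10):
        seq, t = sd.random_gene(rng, strand="+", n_exons=4)
        genome = {t.chrom: seq}
        for _ in range(5):
            ev = random_event_for(rng, t)
            if abs(ev.delta_len) % 3 != 0:
                continue
            rebuilt = rebuild_transcript(t, ev, genome)
            if rebuilt.start_lost:
                continue
            cls, _ = scan_ptc(
                rebuilt.mrna, rebuilt.cds_offset,
                rebuilt.annotated_stop_pos, rebuilt.event_exon_span,
            )
            assert cls in ("none", "in_event_exon", "downstream_frameshift")
            if cls == "downstream_frameshift":
                # downstream codons are annotated codons when in-frame, so
                # the oracle must agree the stop is genuinely new sequence
                assert oracle_ptc(seq, t, ev)[0] == "downstream_frameshift"
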