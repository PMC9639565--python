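import pytest

from scmscan import synthetic_data as sd
from scmscan.gene_model import Transcript
from scmscan.junction_events import (
    AnnotationIndex,
    JunctionRecord,
    classify_event,
    count_annotated_support,
    extract_junctions,
    find_events,
)

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n"


def _sam(tmp_path, lines, name="x.sam"):
    p = tmp_path / name
    p.write_text(SAM_HEADER + "".join(lines))
    return p


def _read(qname, pos1, cigar, seq="A" * 20):
    return f"{qname}\t0\tchr1\t{pos1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n"


def test_extract_junctions_cigar_arithmetic(tmp_path):
    # read at 1-based 91 with 10M100N10M spans intron [100, 200)
    path = _sam(tmp_path, [_read("r1", 91, "10M100N10M")])
    (j,) = extract_junctions(path, "I1")
    assert (j.intron_start, j.intron_end) == (100, 200)
    assert j.anchors == [(10, 10)]


def test_extract_junctions_aggregates_and_keeps_short_anchors(tmp_path):
    path = _sam(
        tmp_path,
        [
            _read("r1", 91, "10M100N10M"),
            _read("r2", 96, "5M100N15M"),
            _read("r3", 97, "4M100N20M", seq="A" * 24),
        ],
    )
    (j,) = extract_junctions(path, "I1")
    assert j.read_count == 3
    assert (4, 20) in j.anchors  # short left anchor recorded, filterable later
    assert j.max_left_anchor == 10 and j.max_right_anchor == 20


def test_extract_junctions_multiple_gaps_per_read(tmp_path):
    path = _sam(tmp_path, [_read("r1", 91, "10M100N10M100N10M", seq="A" * 30)])
    js = extract_junctions(path, "I1")
    assert [(j.intron_start, j.intron_end) for j in js] == [(100, 200), (210, 310)]
    assert js[0].anchors == [(10, 10)] and js[1].anchors == [(10, 10)]


@pytest.fixture
def model():
    # + strand: exons [900,1000), [2000,2100), [3000,3100); intron0 [1000,2000)
    t = Transcript(id="T", gene="G", chrom="chr1", strand="+",
                   exons=[(900, 1000), (2000, 2100), (3000, 3100)])
    return AnnotationIndex([t])


def _junc(s, e, n=3, anchors=None, strand="+"):
    j = JunctionRecord("chr1", s, e, strand, "I1")
    j.anchors = anchors if anchors is not None else [(10, 10)] * n
    return j


def test_acceptor_extension_classification(model):
    # novel end 8 bp inside the intron before the annotated acceptor at 2000
    (ev,) = classify_event(_junc(1000, 1992), model)
    assert ev.event_type == "extension" and ev.side == "acceptor"
    assert ev.delta_len == 8
    assert (ev.annotated_boundary, ev.novel_boundary) == (2000, 1992)
    assert ev.exon_index == 1


def test_donor_shrinkage_classification(model):
    # novel donor 17 bp inside the upstream exon
    (ev,) = classify_event(_junc(983, 2000), model)
    assert ev.event_type == "shrinkage" and ev.side == "donor"
    assert ev.delta_len == -17
    assert (ev.annotated_boundary, ev.novel_boundary) == (1000, 983)
    assert ev.exon_index == 0


def test_annotated_and_unmatched_junctions_yield_nothing(model):
    assert classify_event(_junc(1000, 2000), model) == []  # annotated intron
    assert classify_event(_junc(1234, 1567), model) == []  # matches neither end
    # novel end on another annotated exon boundary is not an event
    assert classify_event(_junc(1000, 3000), model) == []


def test_read_and_anchor_filters(model):
    assert classify_event(_junc(1000, 1992, n=1), model) == []  # 1 read
    # anchors on the novel (right) side below 5 bp in all reads
    j = _junc(1000, 1992, anchors=[(20, 4), (20, 3)])
    assert classify_event(j, model) == []
    # one qualifying read is not enough; two are
    j = _junc(1000, 1992, anchors=[(20, 4), (20, 9)])
    assert classify_event(j, model) == []
    j = _junc(1000, 1992, anchors=[(20, 6), (20, 9)])
    assert len(classify_event(j, model)) == 1


def test_novel_end_beyond_partner_exon_is_discarded(model):
    # beyond the downstream exon's far boundary (2100)
    assert classify_event(_junc(1000, 2150), model) == []


def test_minus_strand_side_labels():
    t = Transcript(id="T", gene="G", chrom="chr1", strand="-",
                   exons=[(900, 1000), (2000, 2100)])
    index = AnnotationIndex([t])
    # left end retained, novel end inside the intron: on '-' the replaced
    # site at the intron's genomic-right end is the donor
    (ev,) = classify_event(_junc(1000, 1992, strand="-"), index)
    assert ev.side == "donor" and ev.event_type == "extension"
    assert ev.delta_len == 8


def test_count_annotated_support(model):
    novel = _junc(1000, 1992, n=21)
    annotated = _junc(1000, 2000, n=79)
    (ev,) = classify_event(novel, model)
    ev = count_annotated_support([novel, annotated], ev)
    assert (ev.Jn, ev.Ja) == (21, 79)
    # annotated junction absent -> Ja = 0
    (ev2,) = classify_event(novel, model)
    ev2 = count_annotated_support([novel], ev2)
    assert (ev2.Jn, ev2.Ja) == (21, 0)


def test_two_novel_junctions_share_annotated_support(model):
    j1, j2 = _junc(1000, 1992), _junc(1000, 1989)
    annotated = _junc(1000, 2000, n=40)
    events = find_events([j1, j2, annotated], model)
    assert len(events) == 2
    assert all(ev.Ja == 40 for ev in events)
    assert {ev.Jn for ev in events} == {3}


def test_exact_recovery_without_decoys_or_dropout(tmp_path):
    """Every implanted event is recovered for every carrier; non-carriers
    produce no events."""
    cfg = sd.SimConfig(
        n_genes=5, n_true_scms=5, n_decoy_snvs=0, n_individuals=8,
        read_depth=40, dropout_rate=0.0, carriers_range=(2, 4), seed=5,
    )
    data = sd.simulate_dataset(cfg, tmp_path)
    index = AnnotationIndex(data.transcripts)
    truth_by_junction = {
        (t.chrom, *t.novel_junction): t for t in data.truths
    }
    for ind in data.individuals:
        junctions = extract_junctions(
            tmp_path / "sam" / f"{ind}.sam", ind, genome=data.genome
        )
        events = find_events(junctions, index)
        found = {(e.chrom, *_novel_junction_of(e)) for e in events}
        expected = {
            key for key, t in truth_by_junction.items() if ind in t.carriers
        }
        assert found == expected
        for e in events:
            assert not index.is_exon_boundary(e.chrom, e.novel_boundary)
            t = truth_by_junction[(e.chrom, *_novel_junction_of(e))]
            assert e.event_type == t.event_type and e.side == t.side
            assert e.delta_len == t.delta_len


def _novel_junction_of(ev):
    if ev.annotated_boundary == ev.intron_end:
        return (ev.intron_start, ev.novel_boundary)
    return (ev.novel_boundary, ev.intron_end)


def test_mirror_symmetry_under_reverse_complement(tmp_path):
    """Reverse-complementing the locus (genome, annotation, alignments)
    preserves event type, side and |delta| with the strand flipped."""
    from scmscan._util import revcomp

    L = 5000
    t = Transcript(id="T", gene="G", chrom="chr1", strand="+",
                   exons=[(900, 1000), (2000, 2100)])
    index_fwd = AnnotationIndex([t])
    (ev_fwd,) = classify_event(_junc(1000, 1992, strand="+"), index_fwd)

    # mirrored locus: interval [s,e) -> [L-e, L-s), strand flips
    t_rc = Transcript(id="T", gene="G", chrom="chr1", strand="-",
                      exons=[(L - 2100, L - 2000), (L - 1000, L - 900)])
    index_rc = AnnotationIndex([t_rc])
    (ev_rc,) = classify_event(
        _junc(L - 1992, L - 1000, strand="-"), index_rc
    )
    assert ev_rc.event_type == ev_fwd.event_type
    assert ev_rc.side == ev_fwd.side  # biological role is strand-relative
    assert abs(ev_rc.delta_len) == abs(ev_fwd.delta_len)
    assert ev_rc.novel_boundary == L - ev_fwd.novel_boundary
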