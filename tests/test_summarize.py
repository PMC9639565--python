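import numpy as np
import pandas as pd
import pytest

from scmscan import synthetic_data as sd
from scmscan.junction_events import SpliceEvent
from scmscan.scm_attribution import ScmCandidate
from scmscan.summarize import (
    base_frequencies,
    bh_adjust,
    cohort_report,
    correlations,
    length_change_histogram,
    per_individual_counts,
    sharing_histogram,
    spectrum,
)


def _event(ind, gene="G1", nb=1992, etype="extension", side="acceptor"):
    return SpliceEvent(
        transcript_id="T", gene=gene, chrom="chr1", strand="+", exon_index=1,
        event_type=etype, side=side, annotated_boundary=2000, novel_boundary=nb,
        delta_len=8 if etype == "extension" else -8, individual=ind,
        intron_start=1000, intron_end=2000,
    )


def test_per_individual_counts_with_zero_rows():
    events = [
        _event("I1"), _event("I1", gene="G2", nb=1990),
        _event("I1", gene="G3", nb=1980, etype="shrinkage"),
        _event("I2"),
        _event("I2"),  # duplicate row for the same individual collapses
    ]
    df = per_individual_counts(events, roster=["I1", "I2", "I3"])
    assert df.loc["I1", "n_extension"] == 2
    assert df.loc["I1", "n_shrinkage"] == 1
    assert df.loc["I2", "n_extension"] == 1
    assert tuple(df.loc["I3"]) == (0, 0)  # zero rows representable
    assert df.attrs["mean_extension"] == pytest.approx(1.0)
    assert per_individual_counts([], roster=[]).empty


def test_sharing_histogram():
    events = [_event("I1"), _event("I2"), _event("I3"),
              _event("I1", gene="G2"), _event("I2", gene="G3", nb=1985)]
    hist = sharing_histogram(events)
    assert hist == {1: 2, 3: 1}
    # conservation: totals equal distinct events
    assert sum(hist.values()) == len({e.key for e in events})


def test_sharing_histogram_matches_truth(quick_dataset):
    """On synthetic data the sharing histogram equals the implanted
    carrier-set design (dropout is 0 in this cohort)."""
    from scmscan.junction_events import extract_junctions, find_events

    data, outdir = quick_dataset
    events = []
    for ind in data.individuals:
        junctions = extract_junctions(
            outdir / "sam" / f"{ind}.sam", ind, genome=data.genome
        )
        events.extend(find_events(junctions, data.transcripts))
    hist = sharing_histogram(events)
    expected: dict[int, int] = {}
    for tr in data.truths:
        if tr.novel_boundary is None:
            continue
        n = len(tr.novel_read_individuals)
        expected[n] = expected.get(n, 0) + 1
    assert hist == dict(sorted(expected.items()))


def _candidate(pos, alt, offset, side="donor", verdict="accepted"):
    return ScmCandidate(
        snv_key=("chr1", pos, "C", alt),
        event_key=("G1", side, 2000, 1992),
        chrom="chr1", strand="+", event_type="extension", delta_len=8,
        offset_in_window=offset, verdict=verdict,
    )


def test_spectrum_counts_and_conservation():
    cands = [
        _candidate(1992, "G", 1),
        _candidate(1993, "G", 2),
        _candidate(1980, "T", 1),
    ]
    mat = spectrum(cands, frame="novel_boundary")
    assert mat.values.sum() == len(cands)
    assert mat.loc[("donor", 1), "G"] == 1
    assert mat.loc[("donor", 1), "T"] == 1
    assert mat.loc[("donor", 2), "G"] == 1
    with pytest.raises(ValueError):
        spectrum(cands, frame="nope")


def test_spectrum_matches_implantation_design(quick_dataset, tmp_path):
    from scmscan import pipeline

    data, outdir = quick_dataset
    cfg = pipeline.PipelineConfig(
        genome=str(outdir / "genome.fa"), gtf=str(outdir / "annotation.gtf"),
        vcf_dir=str(outdir / "vcf"), sam_dir=str(outdir / "sam"),
        out_dir=str(tmp_path / "out"),
    )
    result = pipeline.run(cfg, write_outputs=False)
    accepted = [c for c in result.candidates if c.accepted]
    mat = spectrum(accepted, frame="novel_boundary")
    assert mat.values.sum() == len(accepted)
    truth_alt = {}
    for tr in data.truths:
        if tr.kind == sd.KIND_SCM:
            truth_alt[tr.alt] = truth_alt.get(tr.alt, 0) + 1
    got_alt = mat.sum(axis=0).to_dict()
    for base, n in truth_alt.items():
        assert got_alt[base] == n
    # true SCMs sit on the canonical dinucleotide: offsets +1/+2
    offsets = {off for (_side, off) in mat.index}
    assert offsets <= {1, 2}


def test_base_frequencies_rows_sum_to_one():
    freq = base_frequencies(["GT", "GA", "GC"])
    assert np.allclose(freq.sum(axis=1), 1.0)
    assert freq.loc[0, "G"] == pytest.approx(1.0)


def test_correlations_exact_and_degenerate():
    df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8],
                       "z": [-1.0, -2, -3, -4], "c": [1.0, 1, 1, 1]})
    out = correlations(df, {
        "pos": ("x", "y"), "neg": ("x", "z"), "flat": ("x", "c"),
    })
    assert out["pos"][0] == pytest.approx(1.0)
    assert out["neg"][0] == pytest.approx(-1.0)
    assert np.isnan(out["flat"][0])


def test_correlation_recovers_planted_dependence(rng):
    """JAF generated as an increasing function of score + noise gives a
    strongly positive Pearson r, cross-checked against a from-scratch
    covariance computation."""
    n = 100
    score = rng.normal(0, 1, n)
    jaf = 0.2 + 0.05 * score + rng.normal(0, 0.03, n)
    df = pd.DataFrame({"delta_score": score, "jaf": jaf})
    (r, p) = correlations(df, {"c": ("delta_score", "jaf")})["c"]
    assert r > 0 and p < 0.01
    manual = (
        np.mean((score - score.mean()) * (jaf - jaf.mean()))
        / (score.std() * jaf.std())
    )
    assert r == pytest.approx(manual, abs=1e-12)


def test_length_change_histogram_bins_distinct_events():
    events = [_event("I1"), _event("I2"),  # same event twice
              _event("I1", gene="G2", etype="shrinkage")]
    df = length_change_histogram(events)
    assert df["n_events"].sum() == 2


def test_bh_adjust_monotone():
    adj = bh_adjust([0.01, 0.02, 0.9])
    assert adj[0] <= adj[1] <= adj[2]
    assert all(a >= p for a, p in zip(adj, [0.01, 0.02, 0.9]))


def test_cohort_report_formulas():
    rep = cohort_report(
        n_total_events=8, n_coding=6, n_ptc_events=3, n_domain_events=1,
        n_nagnag=2, n_acceptor_scms=4, n_extension=2, n_shrinkage=6,
    )
    assert rep["functional_impact_pct"] == pytest.approx(100 * 4 / 8)
    assert rep["silent_inframe_pct"] == pytest.approx(100 * 2 / 8)
    assert rep["nagnag_pct"] == pytest.approx(50.0)
    assert rep["shrinkage_extension_ratio"] == pytest.approx(3.0)
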