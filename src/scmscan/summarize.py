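"""Cohort-level summaries of events and SCM candidates.

Event identity for deduplication and sharing is (gene, side, annotated
boundary, novel boundary): transcript-level duplicates of the same
physical junction collapse here. Pearson correlations are reported with
two-sided p-values and no multiple-testing correction by default
(Benjamini–Hochberg is available as an option).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .junction_events import SpliceEvent
from .scm_attribution import ScmCandidate, build_window


def per_individual_counts(
    events: Sequence[SpliceEvent], roster: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Extension/shrinkage event counts per individual (deduplicated).

    ``roster`` lists the full cohort so individuals with zero events
    still get a row; cohort means are in ``df.attrs['mean_extension']``
    and ``df.attrs['mean_shrinkage']``.
    """
    seen: dict[tuple[str, tuple], str] = {}
    counts: dict[str, dict[str, int]] = {}
    roster = list(roster) if roster is not None else sorted({e.individual for e in events})
    for ind in roster:
        counts[ind] = {"n_extension": 0, "n_shrinkage": 0}
    for ev in events:
        dedup_key = (ev.individual, ev.key)
        if dedup_key in seen:
            continue
        seen[dedup_key] = ev.event_type
        if ev.individual not in counts:
            counts[ev.individual] = {"n_extension": 0, "n_shrinkage": 0}
        counts[ev.individual][f"n_{ev.event_type}"] += 1
    df = pd.DataFrame.from_dict(counts, orient="index").sort_index()
    if df.empty:
        df = pd.DataFrame(columns=["n_extension", "n_shrinkage"])
    df.attrs["mean_extension"] = float(df["n_extension"].mean()) if len(df) else float("nan")
    df.attrs["mean_shrinkage"] = float(df["n_shrinkage"].mean()) if len(df) else float("nan")
    return df


def sharing_histogram(events: Sequence[SpliceEvent]) -> dict[int, int]:
    """Histogram: number of individuals sharing an event -> number of events."""
    carriers: dict[tuple, set[str]] = {}
    for ev in events:
        carriers.setdefault(ev.key, set()).add(ev.individual)
    hist: dict[int, int] = {}
    for inds in carriers.values():
        hist[len(inds)] = hist.get(len(inds), 0) + 1
    return dict(sorted(hist.items()))


def length_change_histogram(
    events: Sequence[SpliceEvent], bin_width: int = 10
) -> pd.DataFrame:
    """Distinct-event counts of |delta| per bin, split by event type."""
    rows = {}
    for ev in events:
        rows[ev.key] = (ev.event_type, abs(ev.delta_len))
    df = pd.DataFrame(rows.values(), columns=["event_type", "abs_delta"])
    if df.empty:
        return pd.DataFrame(columns=["event_type", "bin", "n_events"])
    df["bin"] = (df["abs_delta"] // bin_width) * bin_width
    return (
        df.groupby(["event_type", "bin"]).size().rename("n_events").reset_index()
    )


def spectrum(
    candidates: Sequence[ScmCandidate],
    frame: str = "novel_boundary",
) -> pd.DataFrame:
    """Positional frequency/spectrum matrix of accepted SCMs.

    Rows are window offsets (negative = exonic, positive = intronic,
    relative to the chosen reference boundary), columns are alternate
    bases; cells count SCMs. Totals equal the number of SCMs supplied.
    """
    if frame not in ("novel_boundary", "annotated_boundary"):
        raise ValueError(frame)
    rows: list[tuple[str, int, str]] = []
    for c in candidates:
        _chrom, pos, _ref, alt = c.snv_key
        _gene, side, annotated, _novel = c.event_key
        if frame == "novel_boundary":
            offset = c.offset_in_window
        else:
            offset = _offset_unbounded(pos, annotated, side, c.strand)
        rows.append((side, offset, alt))
    df = pd.DataFrame(rows, columns=["side", "offset", "alt"])
    if df.empty:
        return pd.DataFrame(columns=list("ACGT"))
    mat = df.pivot_table(index=["side", "offset"], columns="alt",
                         aggfunc="size", fill_value=0)
    for base in "ACGT":
        if base not in mat.columns:
            mat[base] = 0
    return mat[list("ACGT")]


def _offset_unbounded(pos: int, boundary: int, side: str, strand: str) -> int:
    """Window-convention offset without window-membership limits."""
    if side == "donor":
        intronic = pos >= boundary if strand == "+" else pos < boundary
    else:
        intronic = pos < boundary if strand == "+" else pos >= boundary
    d = pos - boundary if strand == "+" else boundary - 1 - pos
    # d counts 0,1,2,... moving 5'->3' in transcription from the boundary
    if side == "donor":
        return d + 1 if intronic else d
    return -d if intronic else -(d + 1)


def base_frequencies(windows: Iterable[str]) -> pd.DataFrame:
    """Per-position base frequency matrix (logo export) from aligned windows."""
    seqs = [w.upper() for w in windows]
    if not seqs:
        return pd.DataFrame(columns=list("ACGT"))
    length = len(seqs[0])
    counts = np.zeros((length, 4))
    index = {b: i for i, b in enumerate("ACGT")}
    for s in seqs:
        for i, b in enumerate(s):
            if b in index:
                counts[i, index[b]] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(freq, columns=list("ACGT"))


def correlations(df: pd.DataFrame, pairs: Mapping[str, tuple[str, str]]) -> dict:
    """Pearson r and two-sided p for named column pairs.

    Zero variance in either variable yields (nan, nan) for that entry.
    """
    out: dict[str, tuple[float, float]] = {}
    for name, (xcol, ycol) in pairs.items():
        sub = df[[xcol, ycol]].dropna()
        x, y = sub[xcol].to_numpy(float), sub[ycol].to_numpy(float)
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            out[name] = (float("nan"), float("nan"))
            continue
        r, p = stats.pearsonr(x, y)
        out[name] = (float(r), float(p))
    return out


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values (off by default in reports)."""
    return list(stats.false_discovery_control(pvalues, method="bh"))


def cohort_report(
    n_total_events: int,
    n_coding: int,
    n_ptc_events: int,
    n_domain_events: int,
    n_nagnag: int,
    n_acceptor_scms: int,
    n_extension: int,
    n_shrinkage: int,
) -> dict[str, float]:
    """Derived cohort fractions from event/impact counts.

    functional_impact_pct: events generating a PTC or hitting a protein
    domain, as a percentage of all events. silent_inframe_pct: coding
    events doing neither. nagnag_pct: acceptor-side SCMs forming NAGNAG
    motifs. shrinkage_extension_ratio: shrinkage per extension event.
    """
    return {
        "functional_impact_pct": 100.0 * (n_ptc_events + n_domain_events) / n_total_events,
        "silent_inframe_pct": 100.0 * ((n_coding - n_ptc_events) - n_domain_events) / n_total_events,
        "nagnag_pct": 100.0 * n_nagnag / n_acceptor_scms if n_acceptor_scms else float("nan"),
        "shrinkage_extension_ratio": n_shrinkage / n_extension if n_extension else float("nan"),
    }
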