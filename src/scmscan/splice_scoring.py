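"""Splice-site strength: sequence windows and a PWM log-odds scorer.

Scoring windows follow the MaxEntScan conventions: a 9-mer for donors
(3 exonic + 6 intronic bases) and a 23-mer for acceptors (20 intronic +
3 exonic bases) — note the acceptor *scoring* window (20 nt intronic)
is deliberately distinct from the 18-nt acceptor *attribution* window.
The built-in scorer is a position weight matrix trained on the annotated
splice sites of the input gene model (pseudocount 0.5, uniform 0.25
background, log2 odds in bits); maximum-entropy and neural-network
scores computed externally can be ingested from TSV instead.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np

from ._util import revcomp
from .gene_model import Transcript, annotated_splice_sites
from .personalize import SnvRecord

logger = logging.getLogger(__name__)

DONOR_LEN = 9  # 3 exonic + 6 intronic
ACCEPTOR_LEN = 23  # 20 intronic + 3 exonic
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

PSEUDOCOUNT = 0.5
BACKGROUND = 0.25
MIN_TRAINING_INTRONS = 50


@dataclass
class SpliceScore:
    kind: str  # donor | acceptor
    ref_score: Optional[float]
    alt_score: Optional[float]
    source: str  # pwm | maxentscan | spliceai
    probability: Optional[float] = None  # spliceai only

    @property
    def delta(self) -> Optional[float]:
        if self.ref_score is None or self.alt_score is None:
            return None
        return self.alt_score - self.ref_score


def window_coords(boundary: int, kind: str, strand: str) -> tuple[int, int]:
    """Genomic span of the scoring window at a boundary."""
    b = boundary
    if kind == "donor":
        return (b - 3, b + 6) if strand == "+" else (b - 6, b + 3)
    if kind == "acceptor":
        return (b - 20, b + 3) if strand == "+" else (b - 3, b + 20)
    raise ValueError(f"unknown site kind {kind!r}")


def extract_score_windows(
    boundary: int,
    kind: str,
    strand: str,
    genome: Mapping[str, str],
    chrom: str,
    snv: Optional[SnvRecord] = None,
) -> tuple[str, str]:
    """Reference and alternate scoring windows, transcription-oriented.

    The alternate differs from the reference at exactly the SNV position
    (complemented on the minus strand); an SNV outside the window is a
    caller bug and raises.
    """
    lo, hi = window_coords(boundary, kind, strand)
    seq = genome[chrom]
    if lo < 0 or hi > len(seq):
        raise ValueError(f"window [{lo},{hi}) off contig {chrom}")
    ref = seq[lo:hi].upper()
    alt = ref
    if snv is not None:
        if not (lo <= snv.pos < hi):
            raise ValueError(f"SNV at {snv.pos} outside window [{lo},{hi})")
        i = snv.pos - lo
        if ref[i] != snv.ref:
            raise ValueError(
                f"SNV ref {snv.ref} != genome base {ref[i]} at {chrom}:{snv.pos}"
            )
        alt = ref[:i] + snv.alt + ref[i + 1 :]
    if strand == "-":
        ref, alt = revcomp(ref), revcomp(alt)
    return ref, alt


# ---------------------------------------------------------------------------
# PWM


def pwm_from_sequences(seqs: Iterable[str], pseudocount: float = PSEUDOCOUNT) -> np.ndarray:
    """(L, 4) log2-odds weight matrix from aligned equal-length sequences.

    Per-position base frequency f = (count + pseudocount) / (n + 4·pseudocount),
    weight = log2(f / 0.25).
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("no training sequences")
    length = len(seqs[0])
    counts = np.zeros((length, 4), dtype=float)
    for s in seqs:
        if len(s) != length:
            raise ValueError("training sequences differ in length")
        for i, base in enumerate(s.upper()):
            idx = _BASE_INDEX.get(base)
            if idx is not None:
                counts[i, idx] += 1
    n = len(seqs)
    freq = (counts + pseudocount) / (n + 4 * pseudocount)
    return np.log2(freq / BACKGROUND)


def train_pwm(
    transcripts: Iterable[Transcript],
    genome: Mapping[str, str],
    min_introns: int = MIN_TRAINING_INTRONS,
) -> tuple[np.ndarray, np.ndarray]:
    """Train donor (9×4) and acceptor (23×4) PWMs on annotated sites."""
    donors: list[str] = []
    acceptors: list[str] = []
    for t in transcripts:
        for site in annotated_splice_sites(t):
            ref, _ = extract_score_windows(
                site.boundary, site.kind, site.strand, genome, t.chrom
            )
            (donors if site.kind == "donor" else acceptors).append(ref)
    n_introns = len(donors)
    if n_introns < min_introns:
        raise ValueError(
            f"only {n_introns} annotated introns; at least {min_introns} are "
            "needed to train the PWM — provide a larger annotation"
        )
    return pwm_from_sequences(donors), pwm_from_sequences(acceptors)


def pwm_score(seq: str, pwm: np.ndarray) -> float:
    """Sum of per-position weights in bits; N contributes 0."""
    if len(seq) != pwm.shape[0]:
        raise ValueError(f"sequence length {len(seq)} != PWM length {pwm.shape[0]}")
    score = 0.0
    for i, base in enumerate(seq.upper()):
        idx = _BASE_INDEX.get(base)
        if idx is not None:
            score += float(pwm[i, idx])
    return score


def save_pwm(pwm: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"bases": "ACGT", "weights": pwm.tolist()}, fh)


def load_pwm(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        return np.asarray(json.load(fh)["weights"], dtype=float)


def score_site(
    boundary: int,
    kind: str,
    strand: str,
    genome: Mapping[str, str],
    chrom: str,
    pwms: tuple[np.ndarray, np.ndarray],
    snv: Optional[SnvRecord] = None,
) -> SpliceScore:
    """PWM score of the reference and (optionally) alternate window."""
    donor_pwm, acceptor_pwm = pwms
    pwm = donor_pwm if kind == "donor" else acceptor_pwm
    ref, alt = extract_score_windows(boundary, kind, strand, genome, chrom, snv)
    return SpliceScore(
        kind=kind,
        ref_score=pwm_score(ref, pwm),
        alt_score=pwm_score(alt, pwm),
        source="pwm",
    )


# ---------------------------------------------------------------------------
# External scores


def ingest_external_scores(
    tsv_path: str | Path, source: str
) -> dict[tuple, SpliceScore]:
    """Attach externally computed scores keyed by (gene, side, annotated, novel).

    ``maxentscan`` rows carry ref_score/alt_score columns; ``spliceai``
    rows carry a gain probability. A warning is emitted when the
    reference scores higher than the alternate in a majority of
    maxentscan rows, which usually means swapped columns.
    """
    import pandas as pd

    if source not in ("maxentscan", "spliceai"):
        raise ValueError(f"unknown score source {source!r}")
    df = pd.read_csv(tsv_path, sep="\t")
    out: dict[tuple, SpliceScore] = {}
    n_inverted = 0
    for r in df.itertuples():
        key = (str(r.gene), str(r.side), int(r.annotated_boundary), int(r.novel_boundary))
        if source == "maxentscan":
            score = SpliceScore(
                kind=str(r.side),
                ref_score=float(r.ref_score),
                alt_score=float(r.alt_score),
                source=source,
            )
            if score.ref_score > score.alt_score:
                n_inverted += 1
        else:
            score = SpliceScore(
                kind=str(r.side),
                ref_score=None,
                alt_score=None,
                source=source,
                probability=float(r.probability),
            )
        out[key] = score
    if source == "maxentscan" and out and n_inverted > len(out) / 2:
        warnings.warn(
            "reference allele scores higher than alternate in most rows; "
            "ref_score/alt_score columns may be swapped",
            stacklevel=2,
        )
    return out
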