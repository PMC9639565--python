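"""Individual-specific genomes by SNV substitution.

Re-implements the consensus step usually delegated to ``bcftools
consensus``: heterozygous and homozygous alternate SNVs are substituted
into a single consensus sequence. Because only single-nucleotide
substitutions are applied, every personalized coordinate equals the
reference coordinate, so junctions and windows are directly comparable
across individuals without liftover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pysam

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SnvRecord:
    """A biallelic SNV genotype call for one individual (0-based pos)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    individual: str
    genotype: str  # "het" | "hom_alt"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"non-ACGT allele {self.ref}>{self.alt}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def load_snvs(vcf_path: str | Path, individual: str) -> list[SnvRecord]:
    """Load the non-reference biallelic SNVs of one individual.

    Multi-allelic records are split into per-alt records; indels and other
    variant classes are skipped (count logged). A VCF without sample
    columns is rejected; a missing sample name raises an error listing the
    available samples.
    """
    vf = pysam.VariantFile(str(vcf_path))
    samples = list(vf.header.samples)
    if individual not in samples:
        raise ValueError(
            f"sample {individual!r} not in {vcf_path}; available: {samples}"
        )
    out: list[SnvRecord] = []
    n_skipped = 0
    for rec in vf:
        sample = rec.samples[individual]
        gt = sample.get("GT")
        if gt is None or all(a in (None, 0) for a in gt):
            continue
        alleles = [a for a in set(gt) if a not in (None, 0)]
        for ai in alleles:
            ref = rec.ref.upper()
            alt = rec.alleles[ai].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                n_skipped += 1
                continue
            genotype = "hom_alt" if all(a == ai for a in gt if a is not None) else "het"
            out.append(
                SnvRecord(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    ref=ref,
                    alt=alt,
                    individual=individual,
                    genotype=genotype,
                )
            )
    if n_skipped:
        logger.info("%s: skipped %d non-SNV allele(s)", vcf_path, n_skipped)
    return out


def apply_snvs(genome: Mapping[str, str], snvs: list[SnvRecord]) -> dict[str, str]:
    """Substitute alternate alleles into the reference sequences.

    Every record's ref allele must match the reference base at its
    position (data-integrity guard); contig lengths are unchanged.
    """
    mutable: dict[str, list[str]] = {}
    out = {name: seq for name, seq in genome.items()}
    for snv in snvs:
        if snv.chrom not in out:
            raise KeyError(f"contig {snv.chrom!r} not in genome")
        if snv.chrom not in mutable:
            mutable[snv.chrom] = list(out[snv.chrom])
        seq = mutable[snv.chrom]
        have = seq[snv.pos].upper()
        if have == snv.alt:
            continue  # already substituted: re-application is a no-op
        if have != snv.ref:
            raise ValueError(
                f"ref mismatch at {snv.chrom}:{snv.pos}: VCF says {snv.ref}, "
                f"FASTA has {have}"
            )
        seq[snv.pos] = snv.alt
    for name, seq in mutable.items():
        out[name] = "".join(seq)
    return out
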