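"""Internal helpers: sequence ops and plain-text writers for FASTA/VCF/SAM."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into a plain dict of upper-case sequences."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_vcf(
    records: Sequence[tuple[str, int, str, str, str, str]],
    contigs: Mapping[str, int],
    sample: str,
    path: str | Path,
) -> None:
    """Write a minimal single-sample VCF 4.2.

    ``records`` rows are (chrom, pos0, id, ref, alt, genotype) with
    0-based positions; written 1-based.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for chrom, pos0, vid, ref, alt, gt in sorted(records):
            fh.write(
                f"{chrom}\t{pos0 + 1}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n"
            )


def write_sam(
    alignments: Iterable[tuple[str, str, int, str, str, str]],
    contigs: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write a minimal SAM: rows (qname, chrom, pos0, cigar, seq, xs_strand)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for qname, chrom, pos0, cigar, seq, xs in alignments:
            tags = f"\tXS:A:{xs}" if xs in ("+", "-") else ""
            fh.write(
                f"{qname}\t0\t{chrom}\t{pos0 + 1}\t60\t{cigar}\t*\t0\t0\t"
                f"{seq}\t*{tags}\n"
            )
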