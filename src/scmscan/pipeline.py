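"""End-to-end driver: alignments + VCFs + annotation -> SCM candidate table.

Stages: junction extraction per individual -> event classification ->
cohort-wide SNV attribution with concordance -> impact classification of
accepted candidates -> PWM splice-site scoring -> cohort summaries. Each
stage is also usable on its own through the module functions; this layer
only wires them together and writes the per-stage TSV outputs plus a
JSON run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import (
    gene_model,
    impact,
    junction_events,
    personalize,
    scm_attribution,
    splice_scoring,
    summarize,
)
from ._util import read_fasta

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome: str
    gtf: str
    vcf_dir: str
    sam_dir: str
    out_dir: str = "scm_scan_out"
    min_reads: int = junction_events.DEFAULT_MIN_READS
    min_anchor: int = junction_events.DEFAULT_MIN_ANCHOR
    acceptor_window_intronic: int = scm_attribution.ACCEPTOR_INTRONIC
    domain_table: Optional[str] = None
    domain_e_value: float = impact.DEFAULT_DOMAIN_EVALUE
    external_scores: Optional[str] = None
    external_source: str = "maxentscan"
    pwm_min_introns: int = splice_scoring.MIN_TRAINING_INTRONS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class RunResult:
    events: list
    junctions_by_individual: dict
    snvs_by_individual: dict
    candidates: list
    impacts: dict
    scores: dict
    report: dict
    per_individual: pd.DataFrame = field(default_factory=pd.DataFrame)


def _discover_individuals(sam_dir: Path, vcf_dir: Path) -> list[tuple[str, Path, Path]]:
    out = []
    for sam in sorted(list(sam_dir.glob("*.sam")) + list(sam_dir.glob("*.bam"))):
        ind = sam.stem
        vcf = vcf_dir / f"{ind}.vcf"
        if not vcf.exists():
            vcf = vcf_dir / f"{ind}.vcf.gz"
        if not vcf.exists():
            raise FileNotFoundError(f"no VCF for individual {ind} in {vcf_dir}")
        out.append((ind, sam, vcf))
    if not out:
        raise FileNotFoundError(f"no SAM/BAM files in {sam_dir}")
    return out


def run(config: PipelineConfig, write_outputs: bool = True) -> RunResult:
    genome = read_fasta(config.genome)
    transcripts = gene_model.load_annotation(config.gtf)
    index = junction_events.AnnotationIndex(transcripts)
    tx_by_id = {t.id: t for t in transcripts}

    individuals = _discover_individuals(Path(config.sam_dir), Path(config.vcf_dir))
    events: list = []
    junctions_by_individual: dict[str, list] = {}
    snvs_by_individual: dict[str, list] = {}
    for ind, sam, vcf in individuals:
        junctions = junction_events.extract_junctions(sam, ind, genome=genome)
        junctions_by_individual[ind] = junctions
        snvs_by_individual[ind] = personalize.load_snvs(vcf, ind)
        events.extend(
            junction_events.find_events(
                junctions, index,
                min_reads=config.min_reads, min_anchor=config.min_anchor,
            )
        )
    logger.info("classified %d event-individual pairs", len(events))

    candidates = scm_attribution.attribute(
        events,
        snvs_by_individual,
        junctions_by_individual=junctions_by_individual,
        acceptor_window_intronic=config.acceptor_window_intronic,
    )
    accepted = [c for c in candidates if c.accepted]
    logger.info("%d candidates, %d accepted", len(candidates), len(accepted))

    domains = (
        impact.load_domains(config.domain_table) if config.domain_table else None
    )
    events_by_key: dict = {}
    for ev in events:
        events_by_key.setdefault(ev.key, ev)
    impacts = {}
    for cand in accepted:
        ev = events_by_key[cand.event_key]
        t = tx_by_id[ev.transcript_id]
        impacts[cand.event_key] = impact.classify_impact(
            ev, t, genome, domains=domains, e_threshold=config.domain_e_value
        )

    scores: dict = {}
    try:
        pwms = splice_scoring.train_pwm(
            transcripts, genome, min_introns=config.pwm_min_introns
        )
    except ValueError as exc:
        logger.warning("PWM training skipped: %s", exc)
        pwms = None
    if pwms is not None:
        for cand in accepted:
            ev = events_by_key[cand.event_key]
            chrom, pos, ref, alt = cand.snv_key
            snv = personalize.SnvRecord(chrom, pos, ref, alt, "cohort", "het")
            scores[cand.event_key] = splice_scoring.score_site(
                ev.novel_boundary, ev.side, ev.strand, genome, chrom, pwms, snv=snv
            )
    if config.external_scores:
        scores.update(
            splice_scoring.ingest_external_scores(
                config.external_scores, config.external_source
            )
        )

    roster = [ind for ind, _, _ in individuals]
    per_ind = summarize.per_individual_counts(events, roster=roster)
    sharing = summarize.sharing_histogram(events)
    n_acc_scm = sum(1 for c in accepted if c.event_key[1] == "acceptor")
    n_nagnag = sum(1 for k in impacts if impacts[k].nagnag)
    n_coding = sum(1 for r in impacts.values() if r.coding)
    n_ptc = sum(1 for r in impacts.values() if r.ptc_class != impact.PTC_NONE)
    n_domain = sum(1 for r in impacts.values() if r.domain_overlap)
    type_counts = {"extension": 0, "shrinkage": 0}
    for c in accepted:
        type_counts[c.event_type] += 1
    report = {
        "n_individuals": len(roster),
        "n_event_individual_pairs": len(events),
        "n_distinct_events": len({e.key for e in events}),
        "n_candidates": len(candidates),
        "n_accepted": len(accepted),
        "accepted_by_type": type_counts,
        "mean_extension_per_individual": per_ind.attrs.get("mean_extension"),
        "mean_shrinkage_per_individual": per_ind.attrs.get("mean_shrinkage"),
        "sharing_histogram": {str(k): v for k, v in sharing.items()},
        "n_coding": n_coding,
        "n_ptc": n_ptc,
        "n_domain_overlap": n_domain,
        "n_nagnag": n_nagnag,
        "n_acceptor_scms": n_acc_scm,
        "mean_jaf_accepted": (
            float(pd.Series([c.mean_jaf for c in accepted]).dropna().mean())
            if accepted else None
        ),
    }

    result = RunResult(
        events=events,
        junctions_by_individual=junctions_by_individual,
        snvs_by_individual=snvs_by_individual,
        candidates=candidates,
        impacts=impacts,
        scores=scores,
        report=report,
        per_individual=per_ind,
    )
    if write_outputs:
        _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    events_df = pd.DataFrame(
        [
            {
                "gene": e.gene,
                "transcript": e.transcript_id,
                "chrom": e.chrom,
                "strand": e.strand,
                "exon_index": e.exon_index,
                "type": e.event_type,
                "side": e.side,
                "annotated_boundary": e.annotated_boundary,
                "novel_boundary": e.novel_boundary,
                "delta_len": e.delta_len,
                "Jn": e.Jn,
                "Ja": e.Ja,
                "individual": e.individual,
            }
            for e in result.events
        ]
    )
    events_df.to_csv(out_dir / "events.tsv", sep="\t", index=False)

    cand_df = pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "pos": c.snv_key[1],
                "ref": c.snv_key[2],
                "alt": c.snv_key[3],
                "gene": c.event_key[0],
                "side": c.event_key[1],
                "annotated_boundary": c.event_key[2],
                "novel_boundary": c.event_key[3],
                "event_type": c.event_type,
                "delta_len": c.delta_len,
                "offset_in_window": c.offset_in_window,
                "N_both": c.N_both,
                "N_snv_only": c.N_snv_only,
                "N_event_only": c.N_event_only,
                "verdict": c.verdict,
                "mean_jaf": c.mean_jaf,
            }
            for c in result.candidates
        ]
    )
    cand_df.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)

    imp_df = pd.DataFrame(
        [
            {
                "gene": key[0],
                "side": key[1],
                "annotated_boundary": key[2],
                "novel_boundary": key[3],
                "coding": r.coding,
                "frameshift": r.frameshift,
                "old_phase": r.old_phase,
                "new_phase": r.new_phase,
                "ptc_class": r.ptc_class,
                "start_lost": r.start_lost,
                "domain_overlap": r.domain_overlap,
                "domains": ";".join(r.domain_names),
                "nagnag": r.nagnag,
                "protein_delta": r.protein_delta,
                "nmd_predicted": r.nmd_predicted,
            }
            for key, r in result.impacts.items()
        ]
    )
    imp_df.to_csv(out_dir / "impacts.tsv", sep="\t", index=False)

    score_df = pd.DataFrame(
        [
            {
                "gene": key[0],
                "side": key[1],
                "annotated_boundary": key[2],
                "novel_boundary": key[3],
                "source": s.source,
                "ref_score": s.ref_score,
                "alt_score": s.alt_score,
                "delta": s.delta,
                "probability": s.probability,
            }
            for key, s in result.scores.items()
        ]
    )
    score_df.to_csv(out_dir / "scores.tsv", sep="\t", index=False)
    result.per_individual.to_csv(out_dir / "per_individual.tsv", sep="\t")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2)
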