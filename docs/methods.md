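# Methods

## Model and procedure

A splice-site-creating mutation (SCM) is an SNV that completes a
functional donor (GT) or acceptor (AG) splice site where none is
annotated. When such a site is used, the spliceosome pairs it with the
annotated site on the *other* end of the intron, so the affected exon
either extends into the intron (novel site intronic) or shrinks (novel
site exonic). The pipeline detects these events from spliced alignments
and attributes them to SNVs in four steps.

**Junction extraction.** Every `N` CIGAR operation in a SAM/BAM defines
an intron call `[start, end)` (0-based half-open, first intronic base to
one past the last). Supporting reads are aggregated per distinct gap;
for each read we record the lengths of the aligned blocks immediately
flanking the gap (the anchors). Junction strand comes from the `XS`/`ts`
tag, else from GT–AG orientation against the reference, else stays
undetermined (such junctions are matched against both strands and
dropped if they match annotation on both).

**Event classification.** A junction is an extension/shrinkage event iff
(a) ≥ `min_reads` supporting reads (default 2); (b) exactly one end
coincides with an annotated splice site of some intron while the other
end coincides with *no* annotated exon boundary of any transcript;
(c) at least `min_reads` supporting reads have ≥ `min_anchor` bp
(default 5) of aligned anchor on the novel side — the anchor filter
exists to guarantee mapping confidence specifically on the inconsistent
side, so it is applied per read there; (d) the novel end lies strictly
inside the annotated intron (extension) or strictly inside the adjacent
exon (shrinkage). Novel ends beyond the partner exon or inside other
annotated features are discarded: pseudo-exon activation, intron
retention and exon skipping are out of scope. Events are evaluated per
transcript and deduplicated at reporting level by
`(gene, side, annotated boundary, novel boundary)`, because annotations
rarely nominate a canonical isoform; this is an interpretation, flagged
here.

**Attribution.** Candidate SNVs are sought in splice-site windows
anchored on the **novel** boundary: donor = 3 exonic + 6 intronic bp
(9 bp), acceptor = 18 intronic + 3 exonic bp (21 bp), mirrored on the
minus strand. Offsets are reported transcription-oriented (exonic
−1, −2, …; intronic +1, +2, …). Cohort concordance then requires, for
acceptance, `N_both > N_snv_only` (carriers may lack the event — low
expression hides true events, hence a tolerant inequality rather than
equality) and `N_event_only = 0`, where `N_event_only` counts
non-carriers with *any* novel-junction read, even below the event
filters — a single read in a non-carrier already proves the SNV is not
necessary for the site. "Carrier" means any non-reference genotype;
zygosity is not distinguished. Multiple SNVs in one window are scored
independently; no winner is chosen. Per-individual usage of the novel
site is the junction allele fraction `JAF = Jn/(Jn+Ja)`, undefined (not
zero) when no junction reads exist at the locus.

**Impact.** An event is coding when the changed interval intersects the
CDS. The variant mRNA is respliced with the affected exon resized; the
annotated start codon is located through the new structure (events that
remove it are reported start-lost and not PTC-scanned). Translation in
the new frame stops at the first stop codon; a stop strictly upstream of
the mRNA position of the annotated stop is a PTC, classed
`in_event_exon` or `downstream_frameshift` by its position relative to
the resized exon. PTC status does not gate on the 50-nt NMD rule — NMD
is often incomplete, which is precisely why such transcripts remain
observable — but the rule is computed as an optional annotation
(`nmd_predicted`). In-frame PTC-free events are intersected with protein
domains (default E-value ≤ 1e-4, the conventional hmmscan threshold;
running hmmscan itself is out of scope, the table is consumed as TSV). A
missing domain table yields "unknown", never "false". NAGNAG: a 3-bp
acceptor event whose two alternative acceptors both end in AG; the
motif's definition requires exactly 3 nt between the sites, so longer
acceptor shifts are never flagged. The standard stop-codon table
(TAA/TAG/TGA) is assumed.

**Scoring.** Strength windows follow the MaxEntScan input conventions:
donor 9-mer (3 exonic + 6 intronic), acceptor 23-mer (20 intronic + 3
exonic). The 20-nt intronic scoring span is deliberately kept distinct
from the 18-nt attribution window; both are configurable. The built-in
scorer is a PWM: per-position base frequencies over all annotated sites
of the input annotation with pseudocount 0.5 and uniform 0.25
background, stored as log2-odds (bits); at least 50 training introns are
required. Both alleles are scored at the **novel** boundary — the site whose
existence is in question — so the delta isolates the SNV's effect on
that site's strength. The PWM is a deliberately simple,
fully documented scorer; maximum-entropy and neural-network scores
computed outside can be attached from TSV and are never re-derived. The
discovery logic does not gate on any strength score; scores are
descriptive.

## Synthetic data generator

The generator emulates the data regime the method targets: a cohort of
heterozygous carriers, canonical GT–AG introns with polypyrimidine
tracts (≥ 10 pyrimidines enforced among the 18 intronic acceptor-window
bases), clean ORFs (start/stop forced, internal stops in the annotated
frame removed), one event per gene, 75-bp spliced reads with anchors ≥
8 bp emitted directly as aligned SAM (the aligner stage is not part of
the pipeline's contract), and junction depths of tens of reads. For each
true SCM the reference carries a broken canonical dinucleotide at the
planned novel boundary and the alternate allele completes it; carriers
draw `Jn ~ Binomial(depth, JAF)` novel reads, zeroed with the dropout
probability that models low expression. Defaults: 20 genes × 4–6 exons
(≥ 50 introns guaranteed for PWM training), 30 individuals, 15 true
SCMs, 10 decoys, length changes 4–18 bp, target JAF 0.21, depth 50,
dropout 0.05, seed 42.

Decoys probe each rejection rule: SNVs placed ≥ 30 bp outside every
attribution window (must produce no candidate), events whose novel
junction also appears in one non-carrier (`rejected_nonCarrier_event`),
and events observed in at most half of the SNV carriers
(`rejected_concordance`). Because events need their own gene, the
number of event-forming decoys is capped by the genes left free after
true-SCM assignment; the remainder are placed outside windows.

What the generator does **not** model — sequencing error, indels,
paired-end inserts, alignment artefacts, overlapping isoforms,
expression-level variation beyond binary dropout, linkage between SNVs
— bounds what the passing tests show: they validate the discovery
logic, coordinate arithmetic and filters, not robustness to real
alignment noise or annotation complexity.

## Numerical and design choices

* Internal coordinates are 0-based half-open; GTF/VCF convert at the
  boundary. Donor boundaries are encoded at the exon/intron junction
  point (exon end, half-open), acceptors at the exon start; on the minus
  strand the donor sits at the genomically-right intron edge.
* Intron phase is undefined (None) outside the CDS; such events are
  treated as non-coding and only annotated for length.
* Personalized genomes substitute heterozygous SNVs into a single
  consensus (no diploid output), matching standard consensus-building
  behaviour; since only SNVs are applied, no liftover is ever needed.
  Re-applying an SNV whose alternate is already present is a no-op, so
  substitution is idempotent; any other reference mismatch is a fatal
  data-integrity error.
* The 2-read junction filter is applied per individual — the unit at
  which events are attributed; pooling across individuals would blur
  the concordance counts. An interpretation, made explicit here.
* JAF with `Jn + Ja = 0` is reported as missing, never 0, to avoid
  conflating "no usage" with "no data".
* Pearson correlations use the exact two-sided p-value from scipy;
  p-values are unadjusted by default with Benjamini–Hochberg available.
* Test problem sizes: the end-to-end suite runs the default 30-individual
  cohort once per session (~120k alignments, a few seconds) and the PTC
  oracle sweep uses 200 randomized events — small enough for a laptop,
  large enough to hit all four event-type × side combinations on both
  strands.

## Known limitations

* GTF only (no GFF3); incomplete CDS annotations are not handled.
* Events evaluated per transcript; no isoform-aware collapsing beyond
  the reporting-level deduplication.
* The PWM treats positions independently; it reproduces direction
  (mutant site stronger) but not calibrated strength differences of
  maximum-entropy models.
* Domain overlap uses the annotated protein's coordinates for the
  affected interval; insertions report the insertion-point residue.
* No population allele-frequency estimation beyond the input cohort and
  no linkage-aware attribution.
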