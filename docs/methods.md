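# Methods

## The selection model

An allotetraploid genome carries two diverged subgenomes (here labelled A
and B, chromosome `A_k` pairing with its homoeolog `B_k`) plus additional
duplicated loci (paralogs). A candidate SNP called against such a genome
can be (a) a genuine segregating polymorphism, (b) a fixed difference
between the target locus and its homoeologous locus that read collapse
turns into a fake heterozygote, or (c) an artifact of paralogous copies.
The package's selection cascade operationalizes "true SNP" as:

1. **Copy number** — the 601-base window around the candidate (300 bases
   each side) has at most `max_hits` (default 55) local-alignment hits
   against the genome. A "hit" is one HSP row of the 12-column tabular
   output after an e-value cut (default 1e-50). HSP-row counting matches
   observed per-query match counts of up to ~79 and keeps the rule
   implementation-independent.
2. **Informativeness** — polymorphism information content strictly above
   `pic_min` (default 0.30), with

   PIC = 1 − Σᵢ pᵢ² − 2 ΣᵢΣⱼ>ᵢ pᵢ² pⱼ²

   over allele frequencies counted on 2×(non-missing diploid calls)
   slots. Monomorphic markers score 0; an even biallelic marker scores
   0.375.
3. **Distinguishability** — the best-scoring hit is the target itself;
   the best remaining hit on the partner chromosome is taken as the
   homoeolog; all other hits are paralogs. For each non-target hit the
   reference sequence under the hit (orientation-normalized,
   intersection of the aligned span with the target window) must differ
   from the corresponding target subsequence at ≥ 1 position (a
   "flanking SNP"). An identical region means reads from that copy
   cannot be assigned, and the candidate is dropped. Hits that do not
   cover the target column cannot recruit reads at the locus; they pass,
   flagged. Gapped hits imply non-identity and pass, flagged.
4. **Homoeologous base** — the reference base at the position the
   homoeolog hit aligns to the target column must equal the target's
   reference base; a difference marks the candidate as a probable
   subgenome artifact. In the chip cascade a candidate with *no*
   partner-chromosome hit passes vacuously (nothing contradicts it) and
   is flagged; the transcriptome cascade — whose inputs were never
   pre-screened for subgenome artifacts — instead *requires* hits on
   both the target and partner chromosomes and rejects such candidates.

The transcriptome cascade adds quality gates before alignment: markers
must be polymorphic among the panel, pass PIC, have summed depth
≥ `overall_dp_min` (default 100), per-accession depth ≥ `indiv_dp_min`
(default 10) and per-accession genotype quality ≥ `gq_min` (default 30).
Because transcript (cDNA) alignments fragment across introns, round 1
aligns a transcript subsequence *starting at the SNP base* only to locate
the genomic coordinate (the best hit must align from query position 1);
round 2 re-aligns the genomic 601-base window for the distinguishability
and homoeolog-base checks. The chromosome-count steps (≥ 2 chromosomes;
target + partner both hit) are evaluated on round-1 hits by default,
reproducing the as-run order; `defer_single_hit_filter=True` evaluates
them on round-2 hits instead, which avoids discarding candidates whose
transcript alignment was intron-fragmented — the order the retrospective
correction recommends.

One reporting subtlety: the chip report keeps exactly six rows (`input`,
`hit_count`, `pic`, `matched_with_target_site`, `distinguishable`,
`true_snp`); the biallelic requirement (probes target biallelic SNPs, so
> 2 observed alleles disqualifies) is folded into
`matched_with_target_site` as a site-validity condition, with fate reason
`multiallelic`.

## Artificial reference

Each selected target contributes a 301-base contig with the SNP at offset
151 (`contig_half_width` = 150), plus one contig per homoeolog/paralog
hit so off-target reads have a better destination than the target contig.
Decoy contigs are centered on the subject position that the hit aligns to
the target column (ungapped projection); when the projection is ambiguous
(gapped hit, or span not covering the column) the window centers on the
subject-span midpoint and the contig is flagged `ambiguous_center`.
Minus-strand windows are reverse-complemented so every contig reads in
target orientation — the 151st base stays the homologous base. Decoy
windows with identical origin intervals are emitted once per marker.
Windows falling off a chromosome end are skipped with a warning; a
*target* window doing so rejects the marker. Contig ids are
`<marker>|<role>|<ordinal>`, `|` being forbidden in marker ids.

Downstream alignment/calling is out of scope; the documented command
chain is BWA SAMPE → duplicate marking → GATK HaplotypeCaller with
`-stand-call-conf 20`.

## Genotype analytics

* Quality presets: Filter One = GQ ≥ 30 and DP ≥ 10; Filter Two = GQ ≥ 6
  and DP ≥ 2. Missing genotypes stay missing; unknown GQ/DP fails every
  threshold (conservative, since both fields are filtered on).
* A marker is polymorphic within a group when ≥ 2 in-group accessions
  pass the filter and their genotypes are not all identical
  (heterozygote vs homozygote counts as a difference). Single-accession
  groups cannot contribute and are routed to the concordance analysis;
  `allow_single=True` admits them with a zero count. Because per-group
  totals double-count shared markers, the union across groups is
  reported separately (`union_polymorphic_markers`) and no relation
  between the two is asserted.
* Concordance partitions the reference accession's target calls into
  missing / quality-filtered / called and reports the fraction of called
  genotypes that are homozygous-reference.
* All rates use exact rational arithmetic (`fractions.Fraction`) and are
  rounded only for display, with ties away from zero: whole percents for
  recovery, one decimal for concordance, two decimals for mapping rates.
* Multi-allelic VCF records collapse by allele-index presence
  (all-0 → 0/0, all-non-zero-equal → 1/1, otherwise heterozygous) and
  are flagged.

## The synthetic generator

`synthetic_data.simulate_genome` emulates the features of real
allotetraploid data that the cascade's correctness depends on, and only
those:

* B chromosomes derive from A partners by per-base substitution at
  `subgenome_divergence` (default 0.02, i.e. ~98 % A/B identity);
* planted markers on a non-overlapping window grid, in four classes —
  `TRUE_SNP` (homoeologous base equal, ≥ 1 flanking difference versus
  every copy, segregating), `HOMOEOLOG_DECOY` (homoeologous base
  differs), `IDENTICAL_FLANK_DECOY` (one extra copy identical across the
  whole window), `HIGH_COPY_DECOY` (`high_copy_count` = 56 near-identical
  copies, one more than the default hit threshold tolerates);
* background paralog families unrelated to any marker.

Defaults: 2 chromosome pairs × 60 kb, 12/4/4/2 markers per class, 48
accessions, paralog copies at 3 % divergence, flank half-width 300.
Divergence is substitution-only, keeping coordinate projection between
copies trivial; gapped projection is still implemented for real data in
`artificial_reference`. Two constructive constraints keep planted truth
recoverable by definition: (1) if natural divergence leaves a window
identical, one flanking difference is forced; (2) a marker's extra copies
are never placed on the partner chromosome of its target, since a copy
there could outscore the true homoeologous window and the best-partner-hit
heuristic would read the copy's arbitrary base, breaking the planted
class's contract on the homoeologous site.

Population genotypes are Hardy–Weinberg draws at `alt_allele_freq`
(default 0.5: planted true SNPs emulate markers that already passed
informativeness selection, so their expected PIC of 0.375 sits well clear
of the 0.30 threshold rather than on its boundary). Decoys are
monomorphic among accessions — their apparent polymorphism is structural
— while `apparent_chip_genotypes` produces the array's view, in which
decoys appear uniformly heterozygous, so tests exercise each decoy's
dedicated filter rather than letting PIC remove everything. Depth is
negative-binomial (n = 10, p = 0.2; mean 40), genotype quality a discrete
mixture over {99, 90, 75, 60, 45, 35}; `fail_rate` (default 0.02) knocks
GQ below 30 and `missing_rate` (default 0.02) blanks calls. All
randomness flows from one seed; emitted files record the parameters in a
header comment.

`naive_local_search` is the aligner stand-in: an exhaustive ungapped scan
of every diagonal on both strands, trimming each full-span comparison to
the maximal segment bounded by matches and reporting it when it is
≥ `min_length` (default 60) with identity ≥ `min_identity` (default
0.9). The e-value column is a monotone transform of the mismatch count
(so e-value thresholds behave sensibly) and the score is
2·matches − 3·mismatches; ordering is the package-wide deterministic hit
order (score, then subject name, then subject start). It detects
near-full-length ungapped copies — exactly what the generator plants —
and is cross-checked in the tests against an independent optimal local
aligner (Biopython `PairwiseAligner`) on small instances.

## What passing tests do and do not show

The synthetic fixtures prove the cascade's *logic*: exact recovery of
planted truth (precision = recall = 1 across seeds), weakly decreasing
step counts with exhaustive fate accounting, filter nesting, and
agreement with brute-force oracles. They do not model indels, sequencing
error, intron structure in transcripts, uneven coverage, or reference
bias, so they say nothing about the error modes those cause in real
data — the quality filters exist precisely because real calls are
noisier than the simulator's.

## Problem sizes

Default study conditions (acceptance script): 4 × 60 kb chromosomes, 22
planted markers, 48 accessions, 56 high-copy copies against the 55-hit
threshold — a full run takes a few seconds. The pytest fixtures scale to
4 × 30 kb, 10 markers, 8 copies against a `max_hits` of 6, preserving
every inequality that keeps the filters live
(`high_copy_count > max_hits`; ordinary markers' hit counts stay ≤
`max_hits`).

## Known limitations

* The homoeolog is identified by the best-hit-on-partner-chromosome
  heuristic; a paralog on the partner chromosome that outscores the true
  homoeologous window will be mislabelled. Real pipelines share this
  limitation.
* `check_distinguishable` compares reference-extracted sequences under an
  ungapped projection; gapped hits are conservatively treated as
  distinguishable (identical sequences cannot align with gaps).
* The transcriptome cascade trusts the round-1 best hit for the genomic
  coordinate; intron-fragmented alignments can demote the correct locus
  (mitigated by `defer_single_hit_filter`).
* No read-level simulation: mapping statistics are consumed as counts,
  not recomputed from reads.
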