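# polytarget

Homoeolog/paralog-aware SNP target selection and targeted-resequencing
genotype analysis for allotetraploid genomes.

## The problem

Breeding programs need a few hundred reliable, polymorphic SNP markers —
not the tens of thousands a chip or GBS run produces — and they need them
cheaply and repeatably. Targeted resequencing with custom probes delivers
that, **if** the targets are *true SNPs*: polymorphisms that segregate
among accessions, rather than artifacts of reads collapsing across an
allotetraploid's two subgenomes (A and B, ~98 % identical in cultivated
peanut-like genomes) or across duplicated loci.

`polytarget` implements the bioinformatic side of such a platform:

1. **Target selection** (`target_selection`) — filtering cascades that turn
   raw SNP candidates (chip, transcriptome, KASP, WGS sources; `M_`/`T_`/
   `K_`/`R_` marker prefixes) into true-SNP targets. A candidate survives
   when:
   * it has ≤ 55 local-alignment hits against the genome (not high-copy);
   * its polymorphism information content exceeds 0.30, with
     PIC = 1 − Σᵢ pᵢ² − 2 ΣᵢΣⱼ>ᵢ pᵢ² pⱼ²;
   * every homoeologous/paralogous region differs from the 601-base target
     window at ≥ 1 flanking position (reads from the copies are
     distinguishable);
   * the reference base at the homoeologous site **equals** the target
     base (a differing base means the apparent SNP is a fixed subgenome
     difference).
2. **Artificial reference** (`artificial_reference`) — one 301-base contig
   per selected target (SNP at position 151) plus one contig per
   homoeologous/paralogous hit region, giving off-target reads somewhere
   better to map.
3. **Genotype analysis** (`genotype_analysis`) — quality presets
   Filter One (GQ ≥ 30, DP ≥ 10) and Filter Two (GQ ≥ 6, DP ≥ 2),
   target-site extraction from merged VCFs, per-group polymorphism counts,
   concordance against the reference accession, recovery rate, mapping
   arithmetic and probe bookkeeping.
4. **Synthetic data** (`synthetic_data`) — a seeded allotetraploid
   simulator with planted true SNPs and three decoy classes, plus an
   exhaustive ungapped local-search oracle, so the entire pipeline runs and
   is tested without any external data or aligner.
5. **I/O and conventions** (`core_io`) — FASTA, 12-column alignment-hit
   tables, VCF GT:GQ:DP reading, 1-based inclusive coordinates, and the
   configurable A/B chromosome-pairing scheme.

## Worked example

Simulate a fixture, select targets, and inspect the cascade:

```bash
polytarget simulate --seed 1 --outdir sim \
    --chrom-length 30000 --n-true-snps 5 --n-homoeolog-decoys 2 \
    --n-identical-flank-decoys 2 --n-high-copy-decoys 1 --high-copy-count 8
polytarget select-chip --genome sim/genome.fasta --markers sim/markers.tsv \
    --genotypes sim/genotypes.tsv --hits sim/hits.tsv --outdir sel --max-hits 6
```

```
simulated 10 markers on 4 chromosomes -> sim
selected 5/10 targets -> sel
```

`sel/step_report.tsv` shows the survivor count after each filter — 10
candidates in, the high-copy decoy lost at the hit count, the two
identical-flank decoys at distinguishability, the two homoeolog decoys at
the target-site base check, and exactly the five planted true SNPs
selected:

```
step                        count
input                       10
hit_count                   9
pic                         9
matched_with_target_site    9
distinguishable             7
true_snp                    5
```

The mapping arithmetic works directly from read counts:

```bash
polytarget stats --raw 23035880 --mapped 13402453 --on-target 8825651 \
    --n-accessions 48 --n-contigs 7755 --n-target-contigs 2770
```

```
mapping rate: 58.18%
on-target rate: 65.85%
mean reads/accession: 279218
mean reads/accession/contig: 36
mean coverage/accession/target contig: 66.38
```

i.e. 58.18 % of raw reads mapped to the artificial reference, 65.85 % of
mapped reads landed on target contigs, and each accession averaged 66.38
reads of coverage per target contig.

Downstream of an external aligner/caller (the documented commands are BWA
SAMPE → duplicate marking → GATK HaplotypeCaller with
`-stand-call-conf 20`), `filter-vcf`, `summarize-groups` and `concordance`
consume the merged VCF together with the reference registry.

## File formats

* **markers.tsv** — `marker_id  source  chromosome  position  ref  alt`
* **genotypes.tsv** — marker × accession diploid codes (`A/G`, `./.`)
* **hits.tsv** — 12-column tabular hits (`qseqid sseqid pident length
  mismatch gapopen qstart qend sstart send evalue bitscore`)
* **registry.tsv** — `contig_id  marker_id  role  target_offset
  chromosome  start  end  strand  flags`
* **groups.tsv** — `accession  group_id`
* VCF 4.x with `GT:GQ:DP`; FASTA for genomes and contigs.

See `docs/methods.md` for the model, parameter defaults and the design
decisions behind the simulator and the cascades.
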