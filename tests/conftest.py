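"""Shared fixtures: one small seeded synthetic experiment reused across the
suite, plus an engineered transcriptome fixture where every cascade step
rejects exactly one candidate."""
from __future__ import annotations

import dataclasses

import pandas as pd
import pytest
from hypothesis import settings

from polytarget.artificial_reference import build_artificial_reference
from polytarget.core_io import GenotypeCall, Zygosity
from polytarget.synthetic_data import (
    SimulationParams,
    apparent_chip_genotypes,
    emit_synthetic_vcf,
    naive_local_search,
    simulate_experiment,
    simulate_genome,
)
from polytarget.target_selection import PipelineConfig, run_chip_pipeline

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

# Scaled-down study conditions: 10 planted markers over 120 kb keep every
# filter exercised (the high-copy class needs high_copy_count > max_hits)
# while the exhaustive aligner stays fast.
SMALL_PARAMS = SimulationParams(
    seed=1,
    chrom_length=30_000,
    n_true_snps=5,
    n_homoeolog_decoys=2,
    n_identical_flank_decoys=2,
    n_high_copy_decoys=1,
    high_copy_count=8,
)
SMALL_CONFIG = PipelineConfig(max_hits=6)


@pytest.fixture(scope="session")
def small_experiment():
    return simulate_experiment(SMALL_PARAMS, config=SMALL_CONFIG)


@pytest.fixture(scope="session")
def chip_genotypes(small_experiment):
    return apparent_chip_genotypes(small_experiment.truth, small_experiment.params)


@pytest.fixture(scope="session")
def chip_result(small_experiment, chip_genotypes):
    exp = small_experiment
    return run_chip_pipeline(exp.truth.chip_markers(), chip_genotypes, exp.hits,
                             exp.genome, SMALL_CONFIG)


@pytest.fixture(scope="session")
def reference_build(small_experiment, chip_result):
    return build_artificial_reference(chip_result.selected, small_experiment.genome,
                                      SMALL_CONFIG)


@pytest.fixture(scope="session")
def synthetic_vcf(tmp_path_factory, small_experiment, reference_build):
    path = tmp_path_factory.mktemp("vcf") / "calls.vcf"
    emit_synthetic_vcf(reference_build.contigs, small_experiment.truth,
                       small_experiment.population, path,
                       params=small_experiment.params, flanking_rate=0.5)
    return path


# ---------------------------------------------------------------------------
# Engineered transcriptome fixture: 13 candidates, one lost per filter step.
# ---------------------------------------------------------------------------

TRANSCRIPTOME_PARAMS = SimulationParams(
    seed=7,
    chrom_length=30_000,
    n_true_snps=11,
    n_homoeolog_decoys=1,
    n_identical_flank_decoys=1,
    n_high_copy_decoys=0,
)


@dataclasses.dataclass
class TranscriptomeFixture:
    genome: object
    calls: pd.DataFrame
    contig_sequences: dict
    round1_hits: dict
    config: PipelineConfig
    search: object
    survivor: str


@pytest.fixture(scope="session")
def transcriptome_fixture():
    genome, truth = simulate_genome(TRANSCRIPTOME_PARAMS)
    recs = truth.records
    # Candidate 11 is the identical-flank decoy, 12 the homoeolog decoy,
    # 13 a clean true SNP; 1-10 are true SNPs sabotaged one step each.
    order = [recs[i] for i in [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 12, 11, 10]]
    names = [f"rna{i + 1:02d}" for i in range(13)]
    n_acc = 12
    zmap = [Zygosity.REF_HOM, Zygosity.HET, Zygosity.ALT_HOM]
    calls, contig_seqs, r1 = {}, {}, {}
    for name, rec in zip(names, order):
        dosage = [i % 3 for i in range(n_acc)]
        gq = [99] * n_acc
        dp = [50] * n_acc
        if name == "rna01":  # monomorphic
            dosage = [0] * n_acc
        if name == "rna02":  # one rare heterozygote: PIC below threshold
            dosage = [0] * (n_acc - 1) + [1]
        if name == "rna03":  # summed depth 96 < 100
            dp = [8] * n_acc
        if name == "rna04":  # one accession below per-accession depth
            dp = [50] * (n_acc - 1) + [5]
        if name == "rna05":  # one accession below genotype quality
            gq = [99] * (n_acc - 1) + [20]
        calls[name] = {
            f"a{j}": GenotypeCall(zmap[d], gq=g, dp=v)
            for j, (d, g, v) in enumerate(zip(dosage, gq, dp))
        }
        query = genome.fetch(rec.chromosome, rec.position, rec.position + 199)
        if name != "rna06":  # missing contig sequence
            contig_seqs[name] = query
        hits = naive_local_search(query, genome, query_id=name)
        if name == "rna07":  # no alignment match
            hits = []
        if name == "rna08":  # best hit does not start at the SNP base
            hits = [
                dataclasses.replace(h, q_start=3)
                if h.q_start == 1 and h.subject_chromosome == rec.chromosome else h
                for h in hits
            ]
        if name == "rna09":  # mapped to a single chromosome
            hits = [h for h in hits if h.subject_chromosome == rec.chromosome]
        if name == "rna10":  # two chromosomes, but not the homoeologous one
            keep = [h for h in hits if h.subject_chromosome == rec.chromosome]
            other = next(h for h in hits if h.subject_chromosome != rec.chromosome)
            fake_chrom = "A02" if rec.chromosome != "A02" else "A01"
            hits = keep + [dataclasses.replace(other, subject_chromosome=fake_chrom)]
        r1[name] = hits
    calls_df = pd.DataFrame.from_dict(calls, orient="index")
    return TranscriptomeFixture(
        genome=genome,
        calls=calls_df,
        contig_sequences=contig_seqs,
        round1_hits=r1,
        config=PipelineConfig(),
        search=lambda qid, seq: naive_local_search(seq, genome, query_id=qid),
        survivor="T_rna13",
    )
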