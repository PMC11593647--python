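"""Selection cascades: PIC, hit classification, distinguishability and the
chip/transcriptome pipelines."""
from __future__ import annotations

import itertools
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from polytarget.core_io import AlignmentHit, MarkerSource, ReferenceGenome, SnpLocus
from polytarget.synthetic_data import (
    SimulationParams,
    TRUE_SNP,
    apparent_chip_genotypes,
    simulate_experiment,
)
from polytarget.target_selection import (
    AlleleFrequencySpectrum,
    NoDataError,
    PipelineConfig,
    StepReport,
    allele_spectrum_from_calls,
    check_distinguishable,
    check_true_snp,
    classify_matches,
    compute_pic,
    filter_hit_count,
    merge_target_sets,
    run_chip_pipeline,
    run_transcriptome_pipeline,
)


class TestPic:
    @pytest.mark.parametrize("freqs, expected", [
        ((1.0,), 0.0),
        ((0.5, 0.5), 0.375),
        ((0.9, 0.1), 0.1638),
    ])
    def test_hand_evaluated_values(self, freqs, expected):
        assert compute_pic(AlleleFrequencySpectrum(freqs)) == pytest.approx(expected)

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            AlleleFrequencySpectrum((0.5, 0.4))

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6))
    def test_range_and_label_permutation_invariance(self, weights):
        total = sum(weights)
        freqs = tuple(w / total for w in weights)
        # renormalize exactly enough for the invariant check
        freqs = tuple(f / sum(freqs) for f in freqs)
        pic = compute_pic(AlleleFrequencySpectrum(freqs))
        assert 0.0 <= pic < 1.0
        for perm in itertools.islice(itertools.permutations(freqs), 6):
            assert compute_pic(AlleleFrequencySpectrum(perm)) == pytest.approx(pic)

    @given(st.floats(0.5, 0.99))
    def test_biallelic_evenness_monotonicity(self, p):
        even = compute_pic(AlleleFrequencySpectrum((0.5, 0.5)))
        skewed = compute_pic(AlleleFrequencySpectrum((p, 1.0 - p)))
        assert even >= skewed


class TestAlleleSpectrum:
    @pytest.mark.parametrize("calls, expected", [
        (["AA", "AA", "AB", "BB"], (0.625, 0.375)),
        (["AA", "AA"], (1.0,)),
        (["AA", "./.", "AB"], (0.75, 0.25)),
        (["A/A", "A/G", "G/G", "./."], (0.5, 0.5)),
    ])
    def test_counted_over_allele_slots(self, calls, expected):
        assert allele_spectrum_from_calls(calls).frequencies == pytest.approx(expected)

    def test_all_missing_is_no_data(self):
        with pytest.raises(NoDataError):
            allele_spectrum_from_calls(["./.", "./."])


def hit(subject="A01", bit=100.0, q_start=1, q_end=101, s_start=10, s_end=110):
    return AlignmentHit("q", subject, 99.0, q_end - q_start + 1, 1, 0,
                        q_start, q_end, s_start, s_end, 1e-60, bit)


@pytest.fixture(scope="module")
def four_chrom_genome():
    rng = random.Random(5)
    seq = lambda: "".join(rng.choice("ACGT") for _ in range(500))
    return ReferenceGenome({n: seq() for n in ("A03", "B03", "A05", "B08")})


class TestClassifyMatches:
    def test_best_is_target_partner_is_homoeolog(self, four_chrom_genome):
        hits = [hit("A03", 200), hit("B03", 150), hit("A05", 120), hit("B08", 110)]
        c = classify_matches(hits, four_chrom_genome)
        assert c.target_hit.subject_chromosome == "A03"
        assert c.homoeolog_hit.subject_chromosome == "B03"
        assert {h.subject_chromosome for h in c.paralog_hits} == {"A05", "B08"}

    def test_single_hit_has_no_homoeolog(self, four_chrom_genome):
        c = classify_matches([hit("A03", 200)], four_chrom_genome)
        assert c.homoeolog_hit is None
        assert c.paralog_hits == []

    def test_two_partner_hits_best_is_homoeolog(self, four_chrom_genome):
        hits = [hit("A03", 200), hit("B03", 150, s_start=10, s_end=110),
                hit("B03", 140, s_start=300, s_end=400)]
        c = classify_matches(hits, four_chrom_genome)
        assert c.homoeolog_hit.bit_score == 150
        assert c.paralog_hits[0].bit_score == 140

    def test_agrees_with_bruteforce_argmax(self, four_chrom_genome):
        rng = random.Random(11)
        chroms = ["A03", "B03", "A05", "B08"]
        for _ in range(100):
            hits = [hit(rng.choice(chroms), bit=rng.randint(50, 200),
                        s_start=rng.randint(1, 300)) for _ in range(rng.randint(1, 8))]
            # adjust s_end to keep coordinates coherent
            hits = [AlignmentHit(h.query_id, h.subject_chromosome, h.percent_identity,
                                 h.alignment_length, h.mismatches, h.gap_opens,
                                 h.q_start, h.q_end, h.s_start, h.s_start + 100,
                                 h.e_value, h.bit_score) for h in hits]
            c = classify_matches(hits, four_chrom_genome)
            key = lambda h: (h.bit_score, h.subject_chromosome < h.subject_chromosome)
            ordered = sorted(hits, key=lambda h: (-h.bit_score, h.subject_chromosome, h.s_start))
            best = ordered[0]
            assert c.target_hit == best
            partner = four_chrom_genome.partner_of(best.subject_chromosome)
            on_partner = [h for h in ordered[1:] if h.subject_chromosome == partner]
            expected_hom = on_partner[0] if on_partner else None
            assert c.homoeolog_hit == expected_hom
            assert len(c.paralog_hits) == len(hits) - 1 - (expected_hom is not None)


class TestTrueSnpCheck:
    def test_same_base_is_true_snp(self):
        assert check_true_snp("G", "G") is True

    def test_differing_base_is_subgenome_artifact(self):
        assert check_true_snp("G", "A") is False

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            check_true_snp("N", "G")


class TestDistinguishable:
    def test_identical_planted_copy_detected(self, small_experiment, chip_result):
        exp = small_experiment
        report = chip_result.report
        for marker in exp.truth.ids_of("IDENTICAL_FLANK_DECOY"):
            assert report.fates[marker] == "distinguishable"

    def test_diverged_homoeolog_is_distinguishable(self, small_experiment, chip_result):
        selected = {c.marker_id: c for c in chip_result.selected}
        for marker, cand in selected.items():
            ok, verdicts = check_distinguishable(cand.flank, cand.classified,
                                                 small_experiment.genome)
            assert ok
            assert all(v.distinguishable for v in verdicts)

    def test_offender_identified(self, small_experiment, chip_result):
        for marker in small_experiment.truth.ids_of("IDENTICAL_FLANK_DECOY"):
            assert "identical copy" in chip_result.report.reasons[marker]


class TestHitCountFilter:
    @pytest.mark.parametrize("n_hits, kept", [(56, False), (55, True), (1, True)])
    def test_boundary_at_55(self, n_hits, kept):
        report = StepReport()
        from polytarget.target_selection import SnpCandidate
        cand = SnpCandidate(locus=SnpLocus("M_1", MarkerSource.CHIP, "A01", 500, "A"))
        hits = {"M_1": [hit(s_start=i + 1, s_end=i + 101) for i in range(n_hits)]}
        survivors = filter_hit_count([cand], hits, PipelineConfig(), report)
        assert bool(survivors) is kept

    def test_zero_hits_rejected_as_no_match(self):
        report = StepReport()
        from polytarget.target_selection import SnpCandidate
        cand = SnpCandidate(locus=SnpLocus("M_1", MarkerSource.CHIP, "A01", 500, "A"))
        assert filter_hit_count([cand], {}, PipelineConfig(), report) == []
        assert report.reasons["M_1"] == "no_match"


class TestChipPipeline:
    def test_engineered_counts_and_fates(self):
        """2 high-copy fail the hit count, then 3 monomorphic true SNPs fail
        PIC, none fail site verification, 2 identical-flank decoys fail
        distinguishability, 1 homoeolog decoy fails the base check."""
        params = SimulationParams(seed=3, chrom_length=30_000, n_true_snps=5,
                                  n_homoeolog_decoys=1, n_identical_flank_decoys=2,
                                  n_high_copy_decoys=2, high_copy_count=8)
        config = PipelineConfig(max_hits=6)
        exp = simulate_experiment(params, config=config)
        genotypes = apparent_chip_genotypes(exp.truth, params)
        true_ids = sorted(exp.truth.ids_of(TRUE_SNP))
        for marker in true_ids[:3]:
            ref = next(r.ref for r in exp.truth if r.marker_id == marker)
            genotypes.loc[marker] = f"{ref}/{ref}"
        result = run_chip_pipeline(exp.truth.chip_markers(), genotypes, exp.hits,
                                   exp.genome, config)
        assert result.report.counts() == [10, 8, 5, 5, 3, 2]
        assert {c.marker_id for c in result.selected} == set(true_ids[3:])
        fates = result.report.fate_frame()
        assert len(fates) == 10

    def test_all_monomorphic_selects_none(self, small_experiment):
        exp = small_experiment
        genotypes = apparent_chip_genotypes(exp.truth, exp.params)
        for record in exp.truth:
            genotypes.loc[record.marker_id] = f"{record.ref}/{record.ref}"
        result = run_chip_pipeline(exp.truth.chip_markers(), genotypes, exp.hits,
                                   exp.genome, exp.config)
        assert result.selected == []
        assert dict(result.report.steps)["pic"] == 0

    def test_counts_weakly_decreasing(self, chip_result):
        counts = chip_result.report.counts()
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_step_names(self, chip_result):
        assert [s for s, _ in chip_result.report.steps] == [
            "input", "hit_count", "pic", "matched_with_target_site",
            "distinguishable", "true_snp"]


class TestTranscriptomePipeline:
    def test_each_step_rejects_exactly_one(self, transcriptome_fixture):
        fx = transcriptome_fixture
        result = run_transcriptome_pipeline(
            fx.calls, fx.contig_sequences, fx.round1_hits, fx.genome,
            config=fx.config, search=fx.search)
        counts = result.report.counts()
        assert counts == list(range(13, 0, -1))
        assert [c.marker_id for c in result.selected] == [fx.survivor]

    def test_step_names_and_fates(self, transcriptome_fixture):
        fx = transcriptome_fixture
        result = run_transcriptome_pipeline(
            fx.calls, fx.contig_sequences, fx.round1_hits, fx.genome,
            config=fx.config, search=fx.search)
        assert [s for s, _ in result.report.steps] == [
            "input", "polymorphic", "pic", "overall_dp", "indiv_dp", "gq",
            "has_contig_seq", "blast_matched", "snp_site_matched",
            "multi_chromosome", "target_and_homoeolog", "distinguishable",
            "true_snp"]
        fates = result.report.fates
        assert fates["rna01"] == "polymorphic"
        assert fates["rna08"] == "snp_site_matched"
        assert fates["rna12"] == "true_snp"

    def test_selected_markers_carry_rna_prefix(self, transcriptome_fixture):
        fx = transcriptome_fixture
        result = run_transcriptome_pipeline(
            fx.calls, fx.contig_sequences, fx.round1_hits, fx.genome,
            config=fx.config, search=fx.search)
        assert all(c.marker_id.startswith("T_") for c in result.selected)
        assert all(c.locus.source is MarkerSource.RNA for c in result.selected)


def locus(marker, source, chrom, pos, ref="A"):
    return SnpLocus(marker, source, chrom, pos, ref)


class TestMergeTargets:
    def test_per_source_and_subgenome_counts(self):
        sets = {
            MarkerSource.CHIP: [locus("M_1", MarkerSource.CHIP, "A01", 100),
                                locus("M_2", MarkerSource.CHIP, "B01", 200)],
            MarkerSource.WGS: [locus("R_1", MarkerSource.WGS, "A01", 300)],
        }
        merged = merge_target_sets(sets)
        assert len(merged.frame) == 3
        assert merged.counts.loc["Total", "Total"] == 3
        assert merged.counts.loc["CHIP", "A"] == 1
        assert merged.counts.loc["CHIP", "B"] == 1
        assert merged.counts.loc["Total", "A"] == 2

    def test_duplicate_locus_collapsed_with_warning(self):
        sets = {
            MarkerSource.CHIP: [locus("M_1", MarkerSource.CHIP, "A01", 100)],
            MarkerSource.KASP: [locus("K_1", MarkerSource.KASP, "A01", 100)],
        }
        with pytest.warns(UserWarning, match="duplicate"):
            merged = merge_target_sets(sets)
        assert len(merged.frame) == 1
        assert merged.dropped_duplicates == ["K_1"]

    def test_conflicting_ref_base_is_error(self):
        sets = {
            MarkerSource.CHIP: [locus("M_1", MarkerSource.CHIP, "A01", 100, ref="A")],
            MarkerSource.KASP: [locus("K_1", MarkerSource.KASP, "A01", 100, ref="G")],
        }
        with pytest.raises(ValueError, match="conflicting"):
            merge_target_sets(sets)
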