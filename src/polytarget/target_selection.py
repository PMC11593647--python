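"""Filtering cascades that turn raw SNP candidates into "true SNP" targets.

In an allotetraploid, a candidate polymorphism can be an artifact of reads
collapsing across the two subgenomes (a homoeolog difference) or across
duplicated loci (paralogs).  A candidate is kept as a *true SNP* target
when

* it does not sit in a high-copy region (too many alignment hits),
* it is informative in the population (PIC above threshold),
* every homoeologous/paralogous copy differs from the target window at a
  flanking position, so reads from the copies can be told apart, and
* the reference base at the homoeologous site equals the target base, so
  the observed polymorphism segregates among accessions rather than
  between subgenomes.

Two cascades are provided: the chip cascade (candidates with known genomic
coordinates and population genotypes) and the transcriptome cascade
(candidates on transcript contigs whose genomic coordinates are first
located via a round of local alignment).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from ._util import complement
from .core_io import (
    AlignmentHit,
    DEFAULT_EVALUE_MAX,
    FlankEdgeError,
    FlankedSequence,
    GenotypeCall,
    MarkerSource,
    ReferenceGenome,
    SnpLocus,
    SubgenomePairing,
    Zygosity,
    extract_flanks,
    sort_hits,
)

SELECTED = "SELECTED"


@dataclass
class PipelineConfig:
    """Thresholds of the selection cascades.

    Defaults: candidates with more than 55 hits are dropped as high-copy;
    PIC must exceed 0.30; windows are 601 bp for distinguishability
    screening (half-width 300) and 301 bp for reference contigs
    (half-width 150); hits above e-value 1e-50 are ignored; transcriptome
    candidates need summed depth >= 100, per-accession depth >= 10 and
    per-accession genotype quality >= 30.
    """

    max_hits: int = 55
    pic_min: float = 0.30
    flank_half_width: int = 300
    contig_half_width: int = 150
    evalue_max: float = DEFAULT_EVALUE_MAX
    overall_dp_min: int = 100
    indiv_dp_min: int = 10
    gq_min: int = 30
    defer_single_hit_filter: bool = False

    def __post_init__(self):
        for name in ("max_hits", "pic_min", "flank_half_width", "contig_half_width",
                     "evalue_max", "overall_dp_min", "indiv_dp_min", "gq_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# --------------------------------------------------------------------------
# Polymorphism information content
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleFrequencySpectrum:
    """Allele frequencies p_1..p_n for one marker; must sum to 1."""

    frequencies: tuple[float, ...]

    def __post_init__(self):
        if any(p < 0 for p in self.frequencies):
            raise ValueError("negative allele frequency")
        if not math.isclose(sum(self.frequencies), 1.0, abs_tol=1e-9):
            raise ValueError(f"frequencies sum to {sum(self.frequencies)}, not 1")

    @property
    def n(self) -> int:
        return len(self.frequencies)


def compute_pic(spectrum: AlleleFrequencySpectrum) -> float:
    """Polymorphism information content.

    PIC = 1 - sum_i p_i^2 - 2 * sum_{i<j} p_i^2 p_j^2.

    A monomorphic marker scores 0; an even biallelic marker (0.5/0.5)
    scores 0.375.
    """
    p = spectrum.frequencies
    homo = sum(x * x for x in p)
    cross = sum(
        p[i] ** 2 * p[j] ** 2
        for i in range(len(p) - 1)
        for j in range(i + 1, len(p))
    )
    return 1.0 - homo - 2.0 * cross


class NoDataError(ValueError):
    """All calls for a marker are missing."""


_MISSING_TOKENS = {"", ".", "./.", ".|.", "--", "NN"}


def _split_genotype(call: str) -> tuple[str, str] | None:
    call = call.strip()
    if call in _MISSING_TOKENS:
        return None
    for sep in ("/", "|"):
        if sep in call:
            a, b = call.split(sep, 1)
            if a == "." or b == ".":
                return None
            return a, b
    if len(call) == 2:
        return call[0], call[1]
    raise ValueError(f"cannot parse genotype {call!r}")


def allele_spectrum_from_calls(calls: Iterable[str]) -> AlleleFrequencySpectrum:
    """Allele frequencies counted over 2*(non-missing diploid calls) slots.

    Accepts diploid genotype codes like ``AA``, ``A/G`` or ``0/1``;
    missing entries (``./.`` and friends) are excluded.
    """
    counts: dict[str, int] = {}
    for call in calls:
        pair = _split_genotype(str(call))
        if pair is None:
            continue
        for allele in pair:
            counts[allele] = counts.get(allele, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise NoDataError("no data: all calls missing")
    freqs = tuple(counts[a] / total for a in sorted(counts))
    return AlleleFrequencySpectrum(freqs)


def _spectrum_from_zygosities(calls: Iterable[GenotypeCall]) -> AlleleFrequencySpectrum:
    tokens = []
    for call in calls:
        if call.gt is Zygosity.MISSING:
            continue
        tokens.append(call.gt.value)
    if not tokens:
        raise NoDataError("no data: all calls missing")
    return allele_spectrum_from_calls(tokens)


# --------------------------------------------------------------------------
# Hit classification
# --------------------------------------------------------------------------

@dataclass
class ClassifiedHits:
    """Partition of one query's hits into target / homoeolog / paralogs.

    The best-scoring hit is the target; among the rest, the best hit on
    the partner chromosome of the target's chromosome is the homoeolog;
    everything else is a paralog.
    """

    target_hit: AlignmentHit
    homoeolog_hit: AlignmentHit | None
    paralog_hits: list[AlignmentHit]

    @property
    def others(self) -> list[AlignmentHit]:
        extra = [] if self.homoeolog_hit is None else [self.homoeolog_hit]
        return extra + list(self.paralog_hits)


def classify_matches(hits: Sequence[AlignmentHit], genome: ReferenceGenome) -> ClassifiedHits:
    if not hits:
        raise ValueError("cannot classify an empty hit list")
    ordered = sort_hits(hits)
    target = ordered[0]
    partner = genome.partner_of(target.subject_chromosome)
    homoeolog = None
    if partner is not None:
        for hit in ordered[1:]:
            if hit.subject_chromosome == partner:
                homoeolog = hit
                break
    paralogs = [h for h in ordered[1:] if h is not homoeolog]
    return ClassifiedHits(target_hit=target, homoeolog_hit=homoeolog, paralog_hits=paralogs)


def project_query_to_subject(hit: AlignmentHit, q_pos: int) -> int | None:
    """Ungapped projection of a query coordinate through a hit.

    Returns None when the hit does not cover q_pos or the alignment has
    gaps (projection ambiguous).
    """
    if not (hit.q_start <= q_pos <= hit.q_end):
        return None
    if hit.is_gapped:
        return None
    offset = q_pos - hit.q_start
    return hit.s_start + offset if hit.strand == "+" else hit.s_start - offset


@dataclass(frozen=True)
class HitVerdict:
    hit: AlignmentHit
    distinguishable: bool
    covers_target: bool
    note: str = ""


def check_distinguishable(
    target: FlankedSequence,
    others: ClassifiedHits | Sequence[AlignmentHit],
    genome: ReferenceGenome,
) -> tuple[bool, list[HitVerdict]]:
    """True unless some homoeolog/paralog region is identical to the target.

    For each non-target hit, the subject-side sequence over the
    intersection of the hit's aligned span with the target window is
    extracted from the reference (reverse-complemented for minus-strand
    hits) and compared with the corresponding target subsequence.  An
    identical region means reads from that copy cannot be told apart from
    target reads, so the candidate is not distinguishable.  Hits that do
    not cover the target site cannot recruit reads at the locus and count
    as distinguishable, flagged.  Gapped hits imply the region is not
    identical and also count as distinguishable.
    """
    hits = others.others if isinstance(others, ClassifiedHits) else list(others)
    verdicts: list[HitVerdict] = []
    for hit in hits:
        covers = hit.q_start <= target.target_offset <= hit.q_end
        if not covers:
            verdicts.append(HitVerdict(hit, True, False, "does not cover target site"))
            continue
        if hit.is_gapped:
            verdicts.append(HitVerdict(hit, True, True, "gapped alignment"))
            continue
        lo = max(hit.q_start, 1)
        hi = min(hit.q_end, len(target.sequence))
        target_sub = target.sequence[lo - 1:hi]
        chrom = hit.subject_chromosome
        if hit.strand == "+":
            s_lo = hit.s_start + (lo - hit.q_start)
            s_hi = hit.s_start + (hi - hit.q_start)
            subject_sub = genome.fetch(chrom, s_lo, s_hi)
        else:
            s_at_lo = hit.s_start - (lo - hit.q_start)
            s_at_hi = hit.s_start - (hi - hit.q_start)
            from ._util import revcomp
            subject_sub = revcomp(genome.fetch(chrom, s_at_hi, s_at_lo))
        identical = subject_sub == target_sub
        verdicts.append(HitVerdict(hit, not identical, True,
                                   "identical over window" if identical else ""))
    return all(v.distinguishable for v in verdicts), verdicts


def homoeolog_base_at_target(
    target: FlankedSequence, hit: AlignmentHit, genome: ReferenceGenome
) -> str | None:
    """Reference base at the homoeologous position of the target site,
    read in target orientation; None when the hit does not cover the site
    or the projection is ambiguous."""
    s_pos = project_query_to_subject(hit, target.target_offset)
    if s_pos is None:
        return None
    base = genome.base(hit.subject_chromosome, s_pos)
    return complement(base) if hit.strand == "-" else base


def check_true_snp(target_base: str, homoeolog_base: str) -> bool:
    """A candidate is a true SNP only when the target-site base equals the
    base at the homoeologous site; a difference means the "polymorphism"
    is likely a fixed subgenome difference."""
    for b in (target_base, homoeolog_base):
        if b not in {"A", "C", "G", "T"}:
            raise ValueError(f"non-ACGT base {b!r} at target site")
    return target_base == homoeolog_base


# --------------------------------------------------------------------------
# Step reports
# --------------------------------------------------------------------------

CHIP_STEPS = ("input", "hit_count", "pic", "matched_with_target_site",
              "distinguishable", "true_snp")

TRANSCRIPTOME_STEPS = ("input", "polymorphic", "pic", "overall_dp", "indiv_dp",
                       "gq", "has_contig_seq", "blast_matched",
                       "snp_site_matched", "multi_chromosome",
                       "target_and_homoeolog", "distinguishable", "true_snp")


@dataclass
class StepReport:
    """Ordered (step, surviving count) rows plus the per-candidate fate.

    Counts are weakly decreasing; fate maps each marker either to the step
    that rejected it or to SELECTED, and a reason dict carries detail.
    """

    steps: list[tuple[str, int]] = field(default_factory=list)
    fates: dict[str, str] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)

    def add_step(self, name: str, count: int) -> None:
        if self.steps and count > self.steps[-1][1]:
            raise AssertionError(f"step {name}: count increased")
        self.steps.append((name, count))

    def reject(self, marker_id: str, step: str, reason: str = "") -> None:
        self.fates[marker_id] = step
        self.reasons[marker_id] = reason or step

    def select(self, marker_id: str) -> None:
        self.fates[marker_id] = SELECTED
        self.reasons[marker_id] = SELECTED

    def counts(self) -> list[int]:
        return [count for _, count in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "count"])

    def fate_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m, fate, self.reasons.get(m, "")) for m, fate in self.fates.items()],
            columns=["marker_id", "fate", "reason"],
        )

    def validate(self) -> None:
        counts = self.counts()
        assert all(a >= b for a, b in zip(counts, counts[1:])), "counts increased"
        n_selected = sum(1 for f in self.fates.values() if f == SELECTED)
        assert counts[-1] == n_selected, "final count != selected"
        assert counts[0] == len(self.fates), "fate list not exhaustive"


# --------------------------------------------------------------------------
# Candidate container and chip cascade
# --------------------------------------------------------------------------

@dataclass
class SnpCandidate:
    """A candidate carried through a cascade with everything later stages
    need: its PIC, flanking window, classified hits and flags."""

    locus: SnpLocus
    pic: float | None = None
    spectrum: AlleleFrequencySpectrum | None = None
    flank: FlankedSequence | None = None
    classified: ClassifiedHits | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def marker_id(self) -> str:
        return self.locus.marker_id


@dataclass
class PipelineResult:
    selected: list[SnpCandidate]
    report: StepReport


def filter_hit_count(
    candidates: Sequence[SnpCandidate],
    hits_by_query: Mapping[str, Sequence[AlignmentHit]],
    config: PipelineConfig,
    report: StepReport,
    step: str = "hit_count",
) -> list[SnpCandidate]:
    """Keep candidates with 1..max_hits alignment hits.

    A "hit" is one HSP row of the tabular file after the e-value cut.
    Zero hits rejects with reason no_match; more than max_hits rejects as
    high-copy."""
    kept = []
    for cand in candidates:
        hits = hits_by_query.get(cand.marker_id) or []
        if not hits:
            report.reject(cand.marker_id, step, "no_match")
        elif len(hits) > config.max_hits:
            report.reject(cand.marker_id, step, f"{len(hits)} hits > {config.max_hits}")
        else:
            kept.append(cand)
    return kept


def run_chip_pipeline(
    markers: Sequence[SnpLocus],
    genotype_matrix: pd.DataFrame,
    hits_by_query: Mapping[str, Sequence[AlignmentHit]],
    genome: ReferenceGenome,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Chip-data cascade: hit count, PIC, site verification,
    distinguishability, homoeolog-base check.

    ``markers`` are assumed pre-restricted to the caller's quality class
    (the array's "PolyHighResolution" call is an input predicate, not
    recomputed here).  ``genotype_matrix`` is marker x accession with
    diploid genotype strings.
    """
    config = config or PipelineConfig()
    report = StepReport()
    alive = [SnpCandidate(locus=m) for m in markers]
    report.add_step("input", len(alive))

    alive = filter_hit_count(alive, hits_by_query, config, report)
    report.add_step("hit_count", len(alive))

    kept = []
    for cand in alive:
        if cand.marker_id not in genotype_matrix.index:
            report.reject(cand.marker_id, "pic", "no_data")
            continue
        try:
            spectrum = allele_spectrum_from_calls(genotype_matrix.loc[cand.marker_id])
        except NoDataError:
            report.reject(cand.marker_id, "pic", "no_data")
            continue
        pic = compute_pic(spectrum)
        cand.spectrum, cand.pic = spectrum, pic
        if pic > config.pic_min:
            kept.append(cand)
        else:
            report.reject(cand.marker_id, "pic", f"PIC {pic:.4f} <= {config.pic_min}")
    alive = kept
    report.add_step("pic", len(alive))

    # Verification that the candidate's coordinates and reference base agree
    # with the genome, plus the biallelic requirement for probe design.
    kept = []
    for cand in alive:
        try:
            flank = extract_flanks(genome, cand.locus, config.flank_half_width)
        except FlankEdgeError:
            report.reject(cand.marker_id, "matched_with_target_site", "edge")
            continue
        except KeyError:
            report.reject(cand.marker_id, "matched_with_target_site", "unknown_chromosome")
            continue
        if flank.target_base != cand.locus.ref_base:
            report.reject(cand.marker_id, "matched_with_target_site", "site_mismatch")
            continue
        if cand.spectrum is not None and cand.spectrum.n > 2:
            report.reject(cand.marker_id, "matched_with_target_site", "multiallelic")
            continue
        cand.flank = flank
        kept.append(cand)
    alive = kept
    report.add_step("matched_with_target_site", len(alive))

    kept = []
    for cand in alive:
        cand.classified = classify_matches(hits_by_query[cand.marker_id], genome)
        ok, verdicts = check_distinguishable(cand.flank, cand.classified, genome)
        if ok:
            if any(not v.covers_target for v in verdicts):
                cand.flags.append("hit_not_covering_target")
            kept.append(cand)
        else:
            offenders = [v.hit.subject_chromosome for v in verdicts if not v.distinguishable]
            report.reject(cand.marker_id, "distinguishable",
                          "identical copy on " + ",".join(offenders))
    alive = kept
    report.add_step("distinguishable", len(alive))

    kept = []
    for cand in alive:
        hom = cand.classified.homoeolog_hit
        if hom is None:
            # No hit on the partner chromosome: nothing contradicts the
            # candidate, keep it but flag the vacuous pass.
            cand.flags.append("no_homoeolog")
            kept.append(cand)
            continue
        hbase = homoeolog_base_at_target(cand.flank, hom, genome)
        if hbase is None:
            cand.flags.append("homoeolog_site_not_covered")
            kept.append(cand)
            continue
        if check_true_snp(cand.locus.ref_base, hbase):
            kept.append(cand)
        else:
            report.reject(cand.marker_id, "true_snp",
                          f"homoeolog base {hbase} != target {cand.locus.ref_base}")
    alive = kept
    report.add_step("true_snp", len(alive))

    for cand in alive:
        report.select(cand.marker_id)
    report.validate()
    return PipelineResult(selected=alive, report=report)


# --------------------------------------------------------------------------
# Transcriptome cascade
# --------------------------------------------------------------------------

def _all_pass(calls: Iterable[GenotypeCall], getter, minimum: int) -> bool:
    for call in calls:
        value = getter(call)
        if value is None or value < minimum:
            return False
    return True


def run_transcriptome_pipeline(
    calls: pd.DataFrame,
    contig_sequences: Mapping[str, str],
    round1_hits: Mapping[str, Sequence[AlignmentHit]],
    genome: ReferenceGenome,
    round2_hits: Mapping[str, Sequence[AlignmentHit]] | None = None,
    config: PipelineConfig | None = None,
    search: Callable[[str, str], Sequence[AlignmentHit]] | None = None,
) -> PipelineResult:
    """Transcriptome cascade.

    ``calls`` is a marker x accession table of GenotypeCall (GT with
    per-accession GQ/DP) from variant calls on transcript contigs.
    ``contig_sequences`` maps marker_id to the transcript subsequence
    beginning at the SNP base (the round-1 query).  ``round1_hits`` are the
    hits of those queries against the genome; the best hit supplies the
    genomic coordinate of the SNP, and requiring q_start == 1 ensures the
    SNP base itself was aligned.  Round-2 queries are full flanking windows
    extracted from the genome at that coordinate; their hits come either
    from ``round2_hits`` (keyed by marker) or from ``search(marker_id,
    sequence)``.

    With ``config.defer_single_hit_filter`` the chromosome-count checks are
    evaluated on the round-2 (genomic window) hits instead of the round-1
    transcript hits, which avoids discarding candidates whose transcript
    alignment was fragmented by introns.
    """
    config = config or PipelineConfig()
    if round2_hits is None and search is None:
        raise ValueError("provide round2_hits or a search callable")
    report = StepReport()
    state: dict[str, dict] = {m: {} for m in calls.index}
    alive = list(calls.index)
    report.add_step("input", len(alive))

    def run_step(name, keep_fn):
        nonlocal alive
        kept = []
        for marker in alive:
            ok, reason = keep_fn(marker)
            if ok:
                kept.append(marker)
            else:
                report.reject(marker, name, reason)
        alive = kept
        report.add_step(name, len(alive))

    def polymorphic(marker):
        observed = {c.gt for c in calls.loc[marker] if not c.is_missing}
        if not observed:
            return False, "no_data"
        if Zygosity.HET in observed or len(observed) >= 2:
            return True, ""
        return False, "monomorphic"

    run_step("polymorphic", polymorphic)

    def pic_step(marker):
        spectrum = _spectrum_from_zygosities(calls.loc[marker])
        pic = compute_pic(spectrum)
        state[marker]["pic"] = pic
        state[marker]["spectrum"] = spectrum
        if pic > config.pic_min:
            return True, ""
        return False, f"PIC {pic:.4f} <= {config.pic_min}"

    run_step("pic", pic_step)

    run_step("overall_dp", lambda m: (
        (total := sum(c.dp for c in calls.loc[m] if c.dp is not None)) >= config.overall_dp_min,
        f"summed DP {total} < {config.overall_dp_min}"))

    run_step("indiv_dp", lambda m: (
        _all_pass(calls.loc[m], lambda c: c.dp, config.indiv_dp_min),
        f"some accession DP < {config.indiv_dp_min}"))

    run_step("gq", lambda m: (
        _all_pass(calls.loc[m], lambda c: c.gq, config.gq_min),
        f"some accession GQ < {config.gq_min}"))

    run_step("has_contig_seq", lambda m: (
        bool(contig_sequences.get(m)), "no contig sequence"))

    run_step("blast_matched", lambda m: (
        bool(round1_hits.get(m)), "no_match"))

    def snp_site(marker):
        hits = sort_hits(round1_hits[marker])
        best = hits[0]
        if best.q_start != 1:
            return False, f"best hit starts at query position {best.q_start}"
        state[marker]["r1_hits"] = hits
        # The round-1 query begins at the SNP base, so its genomic
        # coordinate is the subject start of the best hit (either strand).
        locus = SnpLocus(
            marker_id=marker if marker.startswith("T_") else f"T_{marker}",
            source=MarkerSource.RNA,
            chromosome=best.subject_chromosome,
            position=best.s_start,
            ref_base=genome.base(best.subject_chromosome, best.s_start),
        )
        state[marker]["locus"] = locus
        return True, ""

    run_step("snp_site_matched", snp_site)

    def get_round2(marker):
        """Extract the genomic window and fetch its hits; cached."""
        if "r2_hits" in state[marker]:
            return state[marker].get("flank"), state[marker]["r2_hits"]
        locus = state[marker]["locus"]
        flank = extract_flanks(genome, locus, config.flank_half_width)
        if round2_hits is not None:
            hits = sort_hits(round2_hits.get(marker, ()))
        else:
            hits = sort_hits(search(marker, flank.sequence))
        state[marker]["flank"] = flank
        state[marker]["r2_hits"] = hits
        return flank, hits

    def chromosome_hits(marker):
        if config.defer_single_hit_filter:
            try:
                _, hits = get_round2(marker)
            except FlankEdgeError:
                return None
            return hits
        return state[marker]["r1_hits"]

    def multi_chromosome(marker):
        hits = chromosome_hits(marker)
        if hits is None:
            return False, "edge"
        chroms = {h.subject_chromosome for h in hits}
        if len(chroms) >= 2:
            return True, ""
        return False, "single chromosome"

    run_step("multi_chromosome", multi_chromosome)

    def target_and_homoeolog(marker):
        hits = chromosome_hits(marker)
        if hits is None:
            return False, "edge"
        target_chrom = state[marker]["locus"].chromosome
        partner = genome.partner_of(target_chrom)
        chroms = {h.subject_chromosome for h in hits}
        if partner is not None and target_chrom in chroms and partner in chroms:
            return True, ""
        return False, "no hit on homoeologous chromosome"

    run_step("target_and_homoeolog", target_and_homoeolog)

    def distinguishable(marker):
        try:
            flank, hits = get_round2(marker)
        except FlankEdgeError:
            return False, "edge"
        if not hits:
            return False, "no round-2 hits"
        classified = classify_matches(hits, genome)
        state[marker]["classified"] = classified
        ok, verdicts = check_distinguishable(flank, classified, genome)
        if ok:
            return True, ""
        offenders = [v.hit.subject_chromosome for v in verdicts if not v.distinguishable]
        return False, "identical copy on " + ",".join(offenders)

    run_step("distinguishable", distinguishable)

    def true_snp(marker):
        classified = state[marker]["classified"]
        hom = classified.homoeolog_hit
        if hom is None:
            # Unlike the chip cascade, candidates here were never vetted for
            # subgenome artifacts upstream, so a missing homoeolog hit after
            # the genomic-window alignment is disqualifying.
            return False, "no_homoeolog"
        hbase = homoeolog_base_at_target(state[marker]["flank"], hom, genome)
        if hbase is None:
            return False, "homoeolog site not covered"
        locus = state[marker]["locus"]
        if check_true_snp(locus.ref_base, hbase):
            return True, ""
        return False, f"homoeolog base {hbase} != target {locus.ref_base}"

    run_step("true_snp", true_snp)

    selected = []
    for marker in alive:
        report.select(marker)
        selected.append(SnpCandidate(
            locus=state[marker]["locus"],
            pic=state[marker].get("pic"),
            spectrum=state[marker].get("spectrum"),
            flank=state[marker].get("flank"),
            classified=state[marker].get("classified"),
        ))
    report.validate()
    return PipelineResult(selected=selected, report=report)


# --------------------------------------------------------------------------
# Merging selected sets
# --------------------------------------------------------------------------

@dataclass
class MergedTargets:
    frame: pd.DataFrame
    counts: pd.DataFrame
    dropped_duplicates: list[str]


def merge_target_sets(
    selected_by_source: Mapping[MarkerSource, Sequence[SnpLocus]],
    pairing: SubgenomePairing | None = None,
) -> MergedTargets:
    """Combine per-source selections into one target table.

    Reports per-source and per-subgenome counts; duplicate loci (same
    chromosome and position from different sources) collapse to the first
    occurrence with a warning, and conflicting reference bases at the same
    locus are an error.
    """
    pairing = pairing or SubgenomePairing()
    rows = []
    seen: dict[tuple[str, int], SnpLocus] = {}
    dropped: list[str] = []
    for source, loci in selected_by_source.items():
        for locus in loci:
            key = (locus.chromosome, locus.position)
            if key in seen:
                if seen[key].ref_base != locus.ref_base:
                    raise ValueError(
                        f"conflicting ref base at {key}: "
                        f"{seen[key].marker_id} vs {locus.marker_id}"
                    )
                dropped.append(locus.marker_id)
                continue
            seen[key] = locus
            parsed = pairing.parse(locus.chromosome)
            subgenome = parsed[0] if parsed else "other"
            rows.append({
                "marker_id": locus.marker_id,
                "source": source.value,
                "chromosome": locus.chromosome,
                "position": locus.position,
                "ref": locus.ref_base,
                "alt": locus.alt_base or "",
                "subgenome": subgenome,
            })
    if dropped:
        warnings.warn(f"collapsed {len(dropped)} duplicate loci: {dropped[:5]}...")
    frame = pd.DataFrame(rows, columns=["marker_id", "source", "chromosome",
                                        "position", "ref", "alt", "subgenome"])
    counts = (
        frame.pivot_table(index="source", columns="subgenome", values="marker_id",
                          aggfunc="count", fill_value=0)
        if len(frame) else pd.DataFrame()
    )
    if len(counts):
        counts["Total"] = counts.sum(axis=1)
        counts.loc["Total"] = counts.sum(axis=0)
    return MergedTargets(frame=frame, counts=counts, dropped_duplicates=dropped)
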