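"""Synthetic allotetraploid fixtures with a known planted truth.

The generator emulates the salient structure of a cultivated-peanut-style
genome for pipeline testing: two subgenomes (A and B) at ~98 percent
identity, duplicated (paralogous) regions, and four classes of planted
candidate markers:

* TRUE_SNP          — segregates among accessions; the homoeologous site
                      carries the same base and every homologous copy
                      differs somewhere in the flanking window;
* HOMOEOLOG_DECOY   — the homoeologous site carries a different base, so
                      the apparent polymorphism is a subgenome difference;
* IDENTICAL_FLANK_DECOY — one extra copy whose whole flanking window is
                      identical to the target's, so reads cannot be told
                      apart;
* HIGH_COPY_DECOY   — more near-identical copies than the hit-count
                      threshold tolerates.

A correct selection cascade keeps exactly the TRUE_SNP class.  Divergence
is substitution-only, which keeps coordinate projection between copies
trivial; gapped projection in real data is handled elsewhere.

``naive_local_search`` is a deterministic, exhaustive ungapped scanner
producing 12-column-compatible hits, standing in for an external aligner
so the whole pipeline runs self-contained.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import revcomp
from .core_io import (
    AlignmentHit,
    MarkerSource,
    Origin,
    ReferenceGenome,
    SnpLocus,
    extract_flanks,
    sort_hits,
)
from .target_selection import PipelineConfig

TRUE_SNP = "TRUE_SNP"
HOMOEOLOG_DECOY = "HOMOEOLOG_DECOY"
IDENTICAL_FLANK_DECOY = "IDENTICAL_FLANK_DECOY"
HIGH_COPY_DECOY = "HIGH_COPY_DECOY"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_IDX = {65: 0, 67: 1, 71: 2, 84: 3}


@dataclass
class SimulationParams:
    """Study conditions for one synthetic experiment.

    Defaults mirror the system being emulated: two subgenomes at 2 percent
    divergence, 48 accessions, markers needing more than 55 alignment hits
    to count as high-copy (hence 56 planted copies for that decoy class),
    601-base screening windows, and a biallelic alternate-allele frequency
    of 0.5: planted true SNPs emulate markers that already passed
    informativeness selection, so they sit well clear of the 0.30 PIC
    threshold rather than at its boundary.
    """

    seed: int = 0
    n_chrom_pairs: int = 2
    chrom_length: int = 60_000
    subgenome_divergence: float = 0.02
    n_paralog_families: int = 3
    paralog_copy_range: tuple[int, int] = (0, 2)
    paralog_divergence: float = 0.03
    n_true_snps: int = 12
    n_homoeolog_decoys: int = 4
    n_identical_flank_decoys: int = 4
    n_high_copy_decoys: int = 2
    high_copy_count: int = 56
    high_copy_divergence: float = 0.005
    flank_half_width: int = 300
    n_accessions: int = 48
    alt_allele_freq: float = 0.5
    missing_rate: float = 0.02
    fail_rate: float = 0.02

    def __post_init__(self):
        for name in ("subgenome_divergence", "paralog_divergence", "alt_allele_freq",
                     "missing_rate", "fail_rate", "high_copy_divergence"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("chrom_length", "n_chrom_pairs", "flank_half_width", "n_accessions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_markers(self) -> int:
        return (self.n_true_snps + self.n_homoeolog_decoys
                + self.n_identical_flank_decoys + self.n_high_copy_decoys)

    def describe(self) -> str:
        return " ".join(f"{f.name}={getattr(self, f.name)}"
                        for f in dataclasses.fields(self))


@dataclass
class TruthRecord:
    marker_id: str
    klass: str
    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str
    copies: list[Origin] = field(default_factory=list)

    def locus(self) -> SnpLocus:
        return SnpLocus(
            marker_id=self.marker_id,
            source=MarkerSource.CHIP,
            chromosome=self.chromosome,
            position=self.position,
            ref_base=self.ref,
            alt_base=self.alt,
        )


@dataclass
class TruthTable:
    records: list[TruthRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.marker_id, r.klass, r.chromosome, r.position, r.ref, r.alt,
              len(r.copies)) for r in self.records],
            columns=["marker_id", "class", "chromosome", "position", "ref",
                     "alt", "n_extra_copies"],
        )

    def chip_markers(self) -> list[SnpLocus]:
        return [r.locus() for r in self.records]

    def ids_of(self, klass: str) -> set[str]:
        return {r.marker_id for r in self.records if r.klass == klass}

    def __iter__(self):
        return iter(self.records)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _encode_ascii(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _mutate(rng, arr: np.ndarray, rate: float) -> np.ndarray:
    """Per-base substitution at the given rate (indices 0..3)."""
    out = arr.copy()
    mask = rng.random(arr.size) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, n)) % 4
    return out


def _revcomp_idx(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]


def simulate_genome(params: SimulationParams) -> tuple[ReferenceGenome, TruthTable]:
    """Build the genome and plant all marker classes.

    B-subgenome chromosomes derive from their A partners by per-base
    substitution at ``subgenome_divergence``.  Planted windows are laid out
    on a non-overlapping grid so classes cannot interfere.  Deterministic:
    the same seed yields a byte-identical genome.
    """
    rng = np.random.default_rng(params.seed)
    half = params.flank_half_width
    window = 2 * half + 1
    length = params.chrom_length

    a_names = [f"A{k:02d}" for k in range(1, params.n_chrom_pairs + 1)]
    b_names = [f"B{k:02d}" for k in range(1, params.n_chrom_pairs + 1)]
    seqs: dict[str, np.ndarray] = {}
    for a in a_names:
        seqs[a] = rng.integers(0, 4, length, dtype=np.int8)
    for a, b in zip(a_names, b_names):
        seqs[b] = _mutate(rng, seqs[a], params.subgenome_divergence)

    # Non-overlapping window grid.  Marker slots live on A chromosomes (the
    # homoeologous window is the same coordinate on the B partner, which is
    # reserved alongside); copy/family slots may live anywhere free.
    margin = half + 16
    spacing = window + 24
    centers = list(range(margin + half, length - margin - half + 1, spacing))
    a_slots = [(a, c) for a in a_names for c in centers]
    rng.shuffle(a_slots)

    n_copy_slots_needed = (
        params.n_identical_flank_decoys
        + params.n_high_copy_decoys * params.high_copy_count
        + (params.n_true_snps + params.n_homoeolog_decoys) * params.paralog_copy_range[1]
        + params.n_paralog_families * 2
    )
    if params.n_markers > len(a_slots):
        raise ValueError("chromosome too short for requested plantings")

    marker_slots = a_slots[:params.n_markers]
    used = {(a, c) for a, c in marker_slots}
    used |= {(b, c) for (a, c) in marker_slots for b in [b_names[a_names.index(a)]]}
    dest_pool = [(name, c) for name in seqs for c in centers if (name, c) not in used]
    rng.shuffle(dest_pool)
    if n_copy_slots_needed > len(dest_pool):
        raise ValueError("chromosome too short for requested plantings")

    def take_dest(exclude: str | None = None) -> tuple[str, int]:
        skipped = []
        while dest_pool:
            slot = dest_pool.pop()
            if exclude is not None and slot[0] == exclude:
                skipped.append(slot)
                continue
            dest_pool.extend(skipped)
            return slot
        raise ValueError("chromosome too short for requested plantings")

    def plant_copy(src_window: np.ndarray, divergence: float,
                   force_flank_diff: bool, exclude: str | None = None) -> Origin:
        """Copy a window to a free slot, optionally mutated, random strand.

        A marker's extra copies are never placed on the partner chromosome
        of its target: a copy there could outscore the real homoeologous
        window and the planted class definition (which fixes the base at
        the homoeologous site) would no longer hold.
        """
        chrom_d, c_d = take_dest(exclude)
        seg = _mutate(rng, src_window, divergence) if divergence > 0 else src_window.copy()
        if force_flank_diff and np.array_equal(seg, src_window):
            off = half - 17
            seg[off] = (seg[off] + int(rng.integers(1, 4))) % 4
        strand = "+" if rng.random() < 0.5 else "-"
        placed = seg if strand == "+" else _revcomp_idx(seg)
        seqs[chrom_d][c_d - half:c_d + half + 1] = placed
        return Origin(chrom_d, c_d - half + 1, c_d + half + 1, strand)

    classes = (
        [TRUE_SNP] * params.n_true_snps
        + [HOMOEOLOG_DECOY] * params.n_homoeolog_decoys
        + [IDENTICAL_FLANK_DECOY] * params.n_identical_flank_decoys
        + [HIGH_COPY_DECOY] * params.n_high_copy_decoys
    )
    records: list[TruthRecord] = []
    for i, (klass, (chrom_a, c0)) in enumerate(zip(classes, marker_slots), start=1):
        chrom_b = b_names[a_names.index(chrom_a)]
        a_arr, b_arr = seqs[chrom_a], seqs[chrom_b]
        ref_idx = int(a_arr[c0])
        alt_idx = (ref_idx + int(rng.integers(1, 4))) % 4

        if klass == HOMOEOLOG_DECOY:
            if b_arr[c0] == ref_idx:
                b_arr[c0] = (ref_idx + int(rng.integers(1, 4))) % 4
        else:
            b_arr[c0] = ref_idx

        # Guarantee the homoeologous window is distinguishable: at least one
        # difference besides the target column itself.
        a_win = a_arr[c0 - half:c0 + half + 1]
        b_win = b_arr[c0 - half:c0 + half + 1]
        diffs = int((a_win != b_win).sum())
        if b_arr[c0] != ref_idx:
            diffs -= 1
        if diffs == 0:
            off = c0 - 11
            b_arr[off] = (b_arr[off] + int(rng.integers(1, 4))) % 4

        copies: list[Origin] = []
        src_window = a_arr[c0 - half:c0 + half + 1].copy()
        if klass in (TRUE_SNP, HOMOEOLOG_DECOY):
            lo, hi = params.paralog_copy_range
            for _ in range(int(rng.integers(lo, hi + 1))):
                copies.append(plant_copy(src_window, params.paralog_divergence, True,
                                         exclude=chrom_b))
        elif klass == IDENTICAL_FLANK_DECOY:
            copies.append(plant_copy(src_window, 0.0, False, exclude=chrom_b))
        elif klass == HIGH_COPY_DECOY:
            for _ in range(params.high_copy_count):
                copies.append(plant_copy(src_window, params.high_copy_divergence, True,
                                         exclude=chrom_b))

        records.append(TruthRecord(
            marker_id=f"M_{i:04d}",
            klass=klass,
            chromosome=chrom_a,
            position=c0 + 1,
            ref=_decode(np.array([ref_idx]))[0],
            alt=_decode(np.array([alt_idx]))[0],
            copies=copies,
        ))

    # Background duplications unrelated to any marker.
    for _ in range(params.n_paralog_families):
        chrom_s, c_s = take_dest()
        src = seqs[chrom_s][c_s - half:c_s + half + 1].copy()
        plant_copy(src, params.paralog_divergence, True)

    genome = ReferenceGenome({name: _decode(arr.astype(np.intp)) for name, arr in seqs.items()})
    return genome, TruthTable(records)


# --------------------------------------------------------------------------
# Naive local search (aligner stand-in / oracle)
# --------------------------------------------------------------------------

def naive_local_search(
    query: str,
    genome: ReferenceGenome,
    query_id: str = "query",
    min_identity: float = 0.9,
    min_length: int = 60,
) -> list[AlignmentHit]:
    """Exhaustive ungapped scan of both strands at every offset.

    At each diagonal the full-span comparison is trimmed to the maximal
    segment starting and ending with a match; the segment is reported when
    it is at least ``min_length`` long with identity >= ``min_identity``.
    The e-value column is a monotone transform of the mismatch count
    (more mismatches, larger e-value) so that e-value thresholds behave
    sensibly; the bit score is 2*matches - 3*mismatches.  Ordering is the
    deterministic hit order used everywhere (score, subject, s_start).
    """
    m = len(query)
    if m < min_length:
        raise ValueError(f"query shorter than min_length ({m} < {min_length})")
    queries = {"+": _encode_ascii(query.upper()), "-": _encode_ascii(revcomp(query.upper()))}
    hits: list[AlignmentHit] = []
    prefilter = min_identity * m - 8  # trimming recovers at most the end runs
    for chrom in genome.names():
        g = _encode_ascii(genome.chromosomes[chrom])
        if g.size < m:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(g, m)
        for strand, q in queries.items():
            for start in range(0, windows.shape[0], 8192):
                block = windows[start:start + 8192]
                eq = block == q
                n_match = eq.sum(axis=1)
                for idx in np.nonzero(n_match >= prefilter)[0]:
                    row = eq[idx]
                    true_pos = np.nonzero(row)[0]
                    if true_pos.size == 0:
                        continue
                    a, b = int(true_pos[0]), int(true_pos[-1])
                    seglen = b - a + 1
                    matches = int(row[a:b + 1].sum())
                    if seglen < min_length or matches / seglen < min_identity:
                        continue
                    i = start + int(idx)
                    mismatches = seglen - matches
                    score = 2 * matches - 3 * mismatches
                    e_value = 0.0 if score > 300 else 10.0 ** (-score)
                    if strand == "+":
                        q_start, q_end = a + 1, b + 1
                        s_start, s_end = i + a + 1, i + b + 1
                    else:
                        q_start, q_end = m - b, m - a
                        s_start, s_end = i + b + 1, i + a + 1
                    hits.append(AlignmentHit(
                        query_id=query_id,
                        subject_chromosome=chrom,
                        percent_identity=round(100.0 * matches / seglen, 2),
                        alignment_length=seglen,
                        mismatches=mismatches,
                        gap_opens=0,
                        q_start=q_start,
                        q_end=q_end,
                        s_start=s_start,
                        s_end=s_end,
                        e_value=e_value,
                        bit_score=float(score),
                    ))
    return sort_hits(hits)


# --------------------------------------------------------------------------
# Population genotypes
# --------------------------------------------------------------------------

@dataclass
class PopulationData:
    genotypes: pd.DataFrame  # marker x accession, strings like "A/G" or "./."
    dp: pd.DataFrame
    gq: pd.DataFrame

    @property
    def accessions(self) -> list[str]:
        return list(self.genotypes.columns)


def simulate_population(truth: TruthTable, params: SimulationParams,
                        rng: np.random.Generator | None = None) -> PopulationData:
    """Hardy-Weinberg genotypes for TRUE_SNP markers at the configured
    alternate-allele frequency; decoy classes are monomorphic among
    accessions (their apparent polymorphism is structural, not segregating).

    Depth is negative-binomial (n=10, p=0.2; mean 40 reads), genotype
    quality a discrete mixture concentrated at high values; ``fail_rate``
    knocks GQ below 30 and ``missing_rate`` blanks the call.
    """
    rng = rng if rng is not None else np.random.default_rng([params.seed, 1])
    accessions = [f"ACC{i:03d}" for i in range(1, params.n_accessions + 1)]
    gt_rows, dp_rows, gq_rows = {}, {}, {}
    for record in truth:
        n = params.n_accessions
        if record.klass == TRUE_SNP:
            dosage = rng.binomial(2, params.alt_allele_freq, n)
        else:
            dosage = np.zeros(n, dtype=int)
        ref, alt = record.ref, record.alt
        gts = np.array([f"{ref}/{ref}", f"{ref}/{alt}", f"{alt}/{alt}"])[dosage]
        missing = rng.random(n) < params.missing_rate
        gts = np.where(missing, "./.", gts)
        dp = rng.negative_binomial(10, 0.2, n)
        gq = rng.choice([99, 90, 75, 60, 45, 35], size=n,
                        p=[0.35, 0.20, 0.15, 0.12, 0.10, 0.08])
        fail = rng.random(n) < params.fail_rate
        gq = np.where(fail, rng.integers(0, 30, n), gq)
        gt_rows[record.marker_id] = gts
        dp_rows[record.marker_id] = dp
        gq_rows[record.marker_id] = gq
    genotypes = pd.DataFrame.from_dict(gt_rows, orient="index", columns=accessions)
    dp = pd.DataFrame.from_dict(dp_rows, orient="index", columns=accessions)
    gq = pd.DataFrame.from_dict(gq_rows, orient="index", columns=accessions)
    return PopulationData(genotypes=genotypes, dp=dp, gq=gq)


def apparent_chip_genotypes(truth: TruthTable, params: SimulationParams) -> pd.DataFrame:
    """Genotype matrix as an array platform would report it.

    TRUE_SNP markers carry their real segregating genotypes; decoy markers
    *also* appear polymorphic — a fixed subgenome or paralog difference
    shows up as heterozygosity in every accession when reads (or probes)
    collapse across copies.  With this matrix the PIC filter cannot remove
    the decoys, so each decoy class must fall to its dedicated cascade
    step.
    """
    population = simulate_population(truth, params)
    genotypes = population.genotypes.copy()
    for record in truth:
        if record.klass != TRUE_SNP:
            genotypes.loc[record.marker_id] = f"{record.ref}/{record.alt}"
    return genotypes


def assign_groups(accessions: Sequence[str], group_size: int = 3) -> pd.DataFrame:
    """Deterministic partition of accessions into consecutive groups."""
    rows = [
        {"accession": acc, "group_id": f"G{i // group_size + 1:02d}"}
        for i, acc in enumerate(accessions)
    ]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# VCF emission
# --------------------------------------------------------------------------

def emit_synthetic_vcf(
    contigs: Sequence,
    truth: TruthTable,
    population: PopulationData,
    path,
    params: SimulationParams | None = None,
    flanking_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> None:
    """Write a merged VCF of target-site calls on the artificial reference.

    Markers polymorphic among accessions get one record at the target
    offset of their target contig; with ``flanking_rate`` some markers
    additionally get a record at another offset (a flanking SNP, which the
    target-site extraction must report separately).  The file round-trips
    through read_genotype_calls.
    """
    rng = rng if rng is not None else np.random.default_rng(
        [params.seed if params else 0, 2])
    target_contigs = {c.marker_id: c for c in contigs if c.role == "target"}
    accessions = population.accessions
    lines = ["##fileformat=VCFv4.2"]
    if params is not None:
        lines.append(f"##synthetic_params={params.describe()}")
    for contig in contigs:
        lines.append(f"##contig=<ID={contig.contig_id},length={len(contig.sequence)}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(accessions),
    ]

    def sample_field(gt_str, ref, alt, gq, dp):
        if gt_str == "./.":
            return "./.:.:."
        code = {f"{ref}/{ref}": "0/0", f"{ref}/{alt}": "0/1",
                f"{alt}/{ref}": "0/1", f"{alt}/{alt}": "1/1"}[gt_str]
        return f"{code}:{gq}:{dp}"

    for record in truth:
        contig = target_contigs.get(record.marker_id)
        if contig is None:
            continue
        gts = population.genotypes.loc[record.marker_id]
        dp = population.dp.loc[record.marker_id]
        gq = population.gq.loc[record.marker_id]
        visible_alt = any(record.alt in g for g in gts)
        all_missing = all(g == "./." for g in gts)
        # A truly segregating site stays in the merged VCF even when every
        # call in this panel happens to be missing.
        if visible_alt or (record.klass == TRUE_SNP and all_missing):
            fields = [sample_field(gts[a], record.ref, record.alt, gq[a], dp[a])
                      for a in accessions]
            lines.append("\t".join([
                contig.contig_id, str(contig.target_offset), record.marker_id,
                record.ref, record.alt, ".", "PASS", ".", "GT:GQ:DP", *fields,
            ]))
        if flanking_rate > 0 and rng.random() < flanking_rate:
            offset = int(rng.integers(10, len(contig.sequence) - 10))
            if offset == contig.target_offset:
                offset += 1
            fref = contig.sequence[offset - 1]
            falt = "ACGT"[("ACGT".index(fref) + 1) % 4]
            fields = []
            for a in accessions:
                dosage = int(rng.integers(0, 3))
                code = ["0/0", "0/1", "1/1"][dosage]
                fields.append(f"{code}:{int(gq[a])}:{int(dp[a])}")
            lines.append("\t".join([
                contig.contig_id, str(offset), f"{record.marker_id}_flank",
                fref, falt, ".", "PASS", ".", "GT:GQ:DP", *fields,
            ]))

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# One-call experiment bundle
# --------------------------------------------------------------------------

@dataclass
class SyntheticExperiment:
    params: SimulationParams
    config: PipelineConfig
    genome: ReferenceGenome
    truth: TruthTable
    population: PopulationData
    flanks: dict[str, str]
    hits: dict[str, list[AlignmentHit]]


def simulate_experiment(
    params: SimulationParams,
    config: PipelineConfig | None = None,
    min_identity: float = 0.9,
) -> SyntheticExperiment:
    """Genome + truth + population + per-marker window hits, ready for the
    selection cascade.  The planted high-copy count must exceed the
    configured hit-count threshold for that decoy class to be meaningful."""
    config = config or PipelineConfig(flank_half_width=params.flank_half_width)
    genome, truth = simulate_genome(params)
    population = simulate_population(truth, params)
    flanks: dict[str, str] = {}
    hits: dict[str, list[AlignmentHit]] = {}
    for record in truth:
        flank = extract_flanks(genome, record.locus(), params.flank_half_width)
        flanks[record.marker_id] = flank.sequence
        hits[record.marker_id] = naive_local_search(
            flank.sequence, genome, query_id=record.marker_id,
            min_identity=min_identity,
        )
    return SyntheticExperiment(
        params=params, config=config, genome=genome, truth=truth,
        population=population, flanks=flanks, hits=hits,
    )
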