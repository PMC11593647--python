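"""Readers, writers and shared conventions for the targeting pipeline.

This module owns the coordinate and naming conventions everything else
depends on:

* coordinates are 1-based and inclusive throughout, matching BLAST tabular
  and VCF conventions;
* chromosome names are mapped to subgenomes (A/B) and paired with their
  homoeologous partner through a configurable regex scheme;
* local-alignment hits are the standard 12-column tabular layout
  (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
  evalue bitscore), with minus-strand hits encoded as sstart > send.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

BLAST_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

#: Hits with an e-value above this are discarded by default.
DEFAULT_EVALUE_MAX = 1e-50

_VALID_ALPHABET = frozenset("ACGTN")


class MarkerSource(Enum):
    """Origin of a candidate SNP, with its marker-id prefix convention.

    Targets from the SNP chip are named ``M_``, transcriptome-derived ones
    ``T_``, KASP assay controls ``K_`` and whole-genome-sequencing targets
    ``R_``.
    """

    CHIP = "CHIP"
    RNA = "RNA"
    KASP = "KASP"
    WGS = "WGS"

    @property
    def prefix(self) -> str:
        return {"CHIP": "M_", "RNA": "T_", "KASP": "K_", "WGS": "R_"}[self.value]

    @classmethod
    def from_marker_id(cls, marker_id: str) -> "MarkerSource | None":
        for source in cls:
            if marker_id.startswith(source.prefix):
                return source
        return None


@dataclass(frozen=True)
class SnpLocus:
    """A putative SNP at a 1-based genomic position."""

    marker_id: str
    source: MarkerSource
    chromosome: str
    position: int
    ref_base: str
    alt_base: str | None = None

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"{self.marker_id}: position must be >= 1")
        sniffed = MarkerSource.from_marker_id(self.marker_id)
        if sniffed is not None and sniffed is not self.source:
            raise ValueError(
                f"{self.marker_id}: prefix implies {sniffed.value}, "
                f"declared source is {self.source.value}"
            )


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 12-column local-alignment hit table.

    Subject coordinates are stored exactly as reported: a minus-strand hit
    has ``s_start > s_end``; the strand is always derived, never stored.
    """

    query_id: str
    subject_chromosome: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self):
        if self.q_start > self.q_end:
            raise ValueError(f"{self.query_id}: q_start > q_end")
        if self.e_value < 0:
            raise ValueError(f"{self.query_id}: negative e-value")

    @property
    def strand(self) -> str:
        return "+" if self.s_start <= self.s_end else "-"

    @property
    def subject_span(self) -> tuple[int, int]:
        """(low, high) subject coordinates regardless of strand."""
        return (min(self.s_start, self.s_end), max(self.s_start, self.s_end))

    @property
    def is_gapped(self) -> bool:
        return self.gap_opens > 0 or self.alignment_length != (self.q_end - self.q_start + 1)

    def to_row(self) -> tuple:
        return (
            self.query_id, self.subject_chromosome, self.percent_identity,
            self.alignment_length, self.mismatches, self.gap_opens,
            self.q_start, self.q_end, self.s_start, self.s_end,
            self.e_value, self.bit_score,
        )


def hit_sort_key(hit: AlignmentHit) -> tuple:
    """Total order on hits of one query: best score first; ties broken
    lexicographically by subject name, then ascending s_start."""
    return (-hit.bit_score, hit.subject_chromosome, hit.s_start)


def sort_hits(hits: Iterable[AlignmentHit]) -> list[AlignmentHit]:
    return sorted(hits, key=hit_sort_key)


@dataclass(frozen=True)
class Origin:
    """1-based inclusive genomic interval a sequence was taken from."""

    chromosome: str
    start: int
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class FlankedSequence:
    """A window of sequence centered on a SNP site.

    ``target_offset`` is the 1-based index of the SNP base within
    ``sequence``; for a window of half-width *w* it is always *w + 1*.
    """

    marker_id: str
    sequence: str
    target_offset: int
    origin: Origin

    @property
    def half_width(self) -> int:
        return self.target_offset - 1

    @property
    def target_base(self) -> str:
        return self.sequence[self.target_offset - 1]


class FlankEdgeError(ValueError):
    """Raised when a locus sits within half_width of a chromosome end."""

    reason = "edge"


# --------------------------------------------------------------------------
# Chromosome naming / subgenome pairing
# --------------------------------------------------------------------------

def _parse_arahy(m: re.Match) -> tuple[str, int] | None:
    n = int(m.group(1))
    if 1 <= n <= 10:
        return ("A", n)
    if 11 <= n <= 20:
        return ("B", n - 10)
    return None


def _parse_generic(m: re.Match) -> tuple[str, int] | None:
    return (m.group(1).upper(), int(m.group(2)))


class SubgenomePairing:
    """Regex-based map from chromosome names to (subgenome, index).

    The default scheme understands both ``Arahy.01``–``Arahy.20``
    (01–10 = A01–A10, 11–20 = B01–B10) and names ending in an explicit
    subgenome letter plus index such as ``A03``, ``chrB12`` or ``B.3``.
    Unrecognized names belong to subgenome "other" and have no partner.
    """

    DEFAULT_PATTERNS: Sequence[tuple[re.Pattern, Callable]] = (
        (re.compile(r"^Arahy\.(\d{2})$"), _parse_arahy),
        (re.compile(r"([AaBb])\.?0*(\d{1,2})$"), _parse_generic),
    )

    def __init__(self, patterns=None):
        self.patterns = tuple(patterns) if patterns is not None else self.DEFAULT_PATTERNS

    def parse(self, name: str) -> tuple[str, int] | None:
        for regex, mapper in self.patterns:
            m = regex.search(name)
            if m:
                parsed = mapper(m)
                if parsed is not None:
                    return parsed
        return None


class ReferenceGenome:
    """In-memory reference with subgenome-aware chromosome pairing."""

    def __init__(self, chromosomes: Mapping[str, str], pairing: SubgenomePairing | None = None):
        if not chromosomes:
            raise ValueError("reference contains no sequences")
        self.pairing = pairing or SubgenomePairing()
        self.chromosomes: dict[str, str] = {}
        for name, seq in chromosomes.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            bad = set(seq) - _VALID_ALPHABET
            if bad:
                raise ValueError(f"chromosome {name!r} has invalid bases: {sorted(bad)}")
            self.chromosomes[name] = seq
        self._keys = {name: self.pairing.parse(name) for name in self.chromosomes}
        self._by_key: dict[tuple[str, int], str] = {}
        for name, key in self._keys.items():
            if key is not None:
                if key in self._by_key:
                    raise ValueError(
                        f"chromosomes {self._by_key[key]!r} and {name!r} both parse to {key}"
                    )
                self._by_key[key] = name

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, name: str) -> int:
        return len(self.chromosomes[name])

    def subgenome_of(self, name: str) -> str:
        key = self._keys.get(name)
        return key[0] if key is not None else "other"

    def partner_of(self, name: str) -> str | None:
        """Homoeologous chromosome (A_k <-> B_k), or None if unpaired."""
        key = self._keys.get(name)
        if key is None:
            return None
        sub, idx = key
        flipped = ("B" if sub == "A" else "A", idx)
        return self._by_key.get(flipped)

    def fetch(self, chromosome: str, start: int, end: int) -> str:
        """1-based inclusive slice."""
        seq = self.chromosomes[chromosome]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(f"{chromosome}:{start}-{end} out of range (len {len(seq)})")
        return seq[start - 1:end]

    def base(self, chromosome: str, position: int) -> str:
        return self.fetch(chromosome, position, position)


def load_reference(path, pairing: SubgenomePairing | None = None) -> ReferenceGenome:
    """Load a FASTA reference; names kept verbatim, sequences uppercased."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    chromosomes: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chromosomes:
            raise ValueError(f"duplicate record name {record.id!r} in {path}")
        seq = str(record.seq)
        if not seq:
            raise ValueError(f"record {record.id!r} in {path} is empty")
        chromosomes[record.id] = seq
    if not chromosomes:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceGenome(chromosomes, pairing=pairing)


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def extract_flanks(genome: ReferenceGenome, locus: SnpLocus, half_width: int) -> FlankedSequence:
    """Window of 2*half_width+1 bases centered on the locus.

    Loci within half_width of a chromosome end are rejected rather than
    padded: downstream steps assume full symmetric windows.
    """
    if locus.chromosome not in genome:
        raise KeyError(f"{locus.marker_id}: unknown chromosome {locus.chromosome!r}")
    start = locus.position - half_width
    end = locus.position + half_width
    if start < 1 or end > genome.length(locus.chromosome):
        raise FlankEdgeError(
            f"{locus.marker_id}: window {start}-{end} exceeds chromosome "
            f"{locus.chromosome} (len {genome.length(locus.chromosome)})"
        )
    seq = genome.fetch(locus.chromosome, start, end)
    return FlankedSequence(
        marker_id=locus.marker_id,
        sequence=seq,
        target_offset=half_width + 1,
        origin=Origin(locus.chromosome, start, end),
    )


# --------------------------------------------------------------------------
# Local-alignment hit tables
# --------------------------------------------------------------------------

def parse_blast_table(path, evalue_max: float = DEFAULT_EVALUE_MAX) -> dict[str, list[AlignmentHit]]:
    """Parse a 12-column tabular hit file, grouped by query.

    Rows with e-value above ``evalue_max`` are dropped.  Within a query,
    hits are ordered best bit-score first with deterministic tie-breaking
    (subject name, then s_start), so re-parsing a shuffled file yields the
    identical ordering.
    """
    grouped: dict[str, list[AlignmentHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = AlignmentHit(
                    query_id=fields[0],
                    subject_chromosome=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if hit.e_value > evalue_max:
                continue
            grouped.setdefault(hit.query_id, []).append(hit)
    return {query: sort_hits(hits) for query, hits in grouped.items()}


def write_blast_table(hits: Iterable[AlignmentHit], path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        for hit in hits:
            fh.write("\t".join(str(v) for v in hit.to_row()) + "\n")


# --------------------------------------------------------------------------
# Genotype calls
# --------------------------------------------------------------------------

class Zygosity(Enum):
    REF_HOM = "0/0"
    HET = "0/1"
    ALT_HOM = "1/1"
    MISSING = "./."


@dataclass(frozen=True)
class GenotypeCall:
    """One accession x marker call. Unknown GQ/DP are None and conservatively
    fail every quality threshold."""

    gt: Zygosity
    gq: int | None = None
    dp: int | None = None
    multiallelic: bool = False

    @property
    def is_missing(self) -> bool:
        return self.gt is Zygosity.MISSING


def _classify_gt(alleles: tuple) -> tuple[Zygosity, bool]:
    if alleles is None or any(a is None for a in alleles):
        return Zygosity.MISSING, False
    multiallelic = any(a >= 2 for a in alleles)
    # Multi-allelic calls collapse by allele-index presence.
    if all(a == 0 for a in alleles):
        return Zygosity.REF_HOM, multiallelic
    if all(a >= 1 for a in alleles):
        if len(set(alleles)) == 1:
            return Zygosity.ALT_HOM, multiallelic
        return Zygosity.HET, multiallelic
    return Zygosity.HET, multiallelic


def read_genotype_calls(path, registry: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read GT:GQ:DP fields from a VCF into a (contig, position) x accession
    table of GenotypeCall.

    Missing genotypes (./.) are preserved as MISSING; absent GQ/DP fields
    are recorded as unknown.  Contigs absent from the artificial-reference
    registry (when given) trigger a warning but are kept.
    """
    import pysam

    known_contigs = None
    if registry is not None:
        known_contigs = set(registry["contig_id"])

    rows: dict[tuple[str, int], dict[str, GenotypeCall]] = {}
    warned: set[str] = set()
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for record in vcf:
            if known_contigs is not None and record.chrom not in known_contigs and record.chrom not in warned:
                warnings.warn(f"contig {record.chrom!r} not in reference registry; keeping")
                warned.add(record.chrom)
            calls = {}
            for sample in samples:
                data = record.samples[sample]
                gt, multi = _classify_gt(data.get("GT"))
                gq = data.get("GQ")
                dp = data.get("DP")
                calls[sample] = GenotypeCall(
                    gt=gt,
                    gq=None if gq is None else int(gq),
                    dp=None if dp is None else int(dp),
                    multiallelic=multi,
                )
            rows[(record.chrom, record.pos)] = calls
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    if len(frame):
        frame.index = pd.MultiIndex.from_tuples(frame.index, names=["contig", "position"])
    else:
        frame.index = pd.MultiIndex.from_tuples([], names=["contig", "position"])
        frame = frame.reindex(columns=samples)
    return frame
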