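"""Post-variant-calling analytics for targeted-resequencing genotypes.

Covers the quality presets (Filter One: GQ >= 30 and DP >= 10; Filter Two:
GQ >= 6 and DP >= 2), extraction of calls at the 151st position of target
contigs, per-group polymorphism counts, concordance against the reference
accession, target recovery, read-mapping arithmetic and probe bookkeeping.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import round_half_away
from .core_io import GenotypeCall, MarkerSource, Zygosity

__all__ = [
    "GenotypeCall", "Zygosity", "FilterSpec", "FilterResult", "FILTER_ONE",
    "FILTER_TWO", "apply_filter", "target_site_table", "TargetSiteTable",
    "drop_reference_only_sites", "count_group_polymorphisms", "GroupSummary",
    "union_polymorphic_markers", "mean_group_count", "concordance_vs_reference",
    "ConcordanceSummary",
    "recovery_rate", "mapping_stats", "MappingStats", "probe_totals",
    "ProbeTotals",
]

SOURCE_ORDER = ("CHIP", "RNA", "KASP", "WGS", "OTHER")


@dataclass(frozen=True)
class FilterSpec:
    name: str
    min_gq: int
    min_dp: int


FILTER_ONE = FilterSpec("one", min_gq=30, min_dp=10)
FILTER_TWO = FilterSpec("two", min_gq=6, min_dp=2)

FILTERS = {"one": FILTER_ONE, "two": FILTER_TWO}


class FilterResult(Enum):
    PASS = "PASS"
    FAIL = "FAIL"
    MISSING = "MISSING"


def apply_filter(call: GenotypeCall, spec: FilterSpec) -> FilterResult:
    """MISSING stays MISSING; a call fails when GQ or DP is below threshold
    (unknown GQ/DP fails conservatively)."""
    if call.is_missing:
        return FilterResult.MISSING
    if call.gq is None or call.dp is None:
        return FilterResult.FAIL
    if call.gq < spec.min_gq or call.dp < spec.min_dp:
        return FilterResult.FAIL
    return FilterResult.PASS


# --------------------------------------------------------------------------
# Target-site extraction
# --------------------------------------------------------------------------

@dataclass
class TargetSiteTable:
    """Marker x accession calls at the target offset of target contigs.

    ``flanking`` holds VCF records on target contigs at other offsets
    (SNPs in the flanks, not at the targeted locus); ``no_target_record``
    lists markers whose target contig had no record at the target offset.
    """

    matrix: pd.DataFrame
    flanking: pd.DataFrame
    no_target_record: list[str]


def target_site_table(calls: pd.DataFrame, registry: pd.DataFrame) -> TargetSiteTable:
    """Keep only records at (target contig, target_offset); report the rest.

    ``calls`` is the (contig, position) x accession table from
    read_genotype_calls; ``registry`` the artificial-reference registry.
    """
    targets = registry[registry.role == "target"]
    offset_of = dict(zip(targets.contig_id, targets.target_offset))
    marker_of = dict(zip(targets.contig_id, targets.marker_id))

    matrix_rows: dict[str, dict] = {}
    flanking_index = []
    for (contig, position), row in calls.iterrows():
        if contig not in offset_of:
            continue
        if position == offset_of[contig]:
            matrix_rows[marker_of[contig]] = dict(row)
        else:
            flanking_index.append((contig, position))
    matrix = pd.DataFrame.from_dict(matrix_rows, orient="index", columns=list(calls.columns))
    matrix.index.name = "marker_id"
    flanking = calls.loc[flanking_index] if flanking_index else calls.iloc[0:0]
    no_target = [m for c, m in marker_of.items() if m not in matrix_rows]
    return TargetSiteTable(matrix=matrix, flanking=flanking, no_target_record=no_target)


def drop_reference_only_sites(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop rows where every call is missing or homozygous reference."""
    def informative(row) -> bool:
        return any(c.gt in (Zygosity.HET, Zygosity.ALT_HOM) for c in row)

    if not len(matrix):
        return matrix
    keep = matrix.apply(informative, axis=1)
    return matrix.loc[keep]


# --------------------------------------------------------------------------
# Group polymorphism counts
# --------------------------------------------------------------------------

@dataclass
class GroupSummary:
    """Number of markers polymorphic within one accession group, split by
    marker source (CHIP/RNA/KASP/WGS by id prefix)."""

    group_id: str
    counts: dict[str, int] = field(default_factory=dict)
    markers: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _source_bucket(marker_id: str) -> str:
    source = MarkerSource.from_marker_id(marker_id)
    return source.value if source is not None else "OTHER"


def _normalize_groups(groups) -> dict[str, list[str]]:
    """Accepts accession->group mapping or a (accession, group_id) frame."""
    members: dict[str, list[str]] = {}
    if isinstance(groups, pd.DataFrame):
        pairs = zip(groups["accession"], groups["group_id"])
    else:
        pairs = groups.items()
    for accession, group in pairs:
        members.setdefault(str(group), []).append(accession)
    return members


def count_group_polymorphisms(
    matrix: pd.DataFrame,
    groups,
    spec: FilterSpec,
    allow_single: bool = False,
) -> list[GroupSummary]:
    """A marker counts for a group when, after quality filtering (failing
    and missing calls excluded), at least two in-group accessions are
    callable and their genotypes are not all identical.  A heterozygote
    against a homozygote counts as a difference.

    Single-accession groups are rejected unless ``allow_single`` (they can
    never contribute and belong in the reference-concordance analysis).
    """
    members = _normalize_groups(groups)
    unknown = [a for accs in members.values() for a in accs if a not in matrix.columns]
    if unknown:
        raise ValueError(f"accessions not in call matrix: {unknown[:5]}")
    summaries = []
    for group_id in sorted(members, key=str):
        accessions = members[group_id]
        if len(accessions) < 2 and not allow_single:
            raise ValueError(
                f"group {group_id} has {len(accessions)} accession(s); "
                "use allow_single or route it to concordance analysis"
            )
        summary = GroupSummary(group_id=group_id)
        for marker_id, row in matrix.iterrows():
            callable_gts = [
                row[a].gt for a in accessions
                if apply_filter(row[a], spec) is FilterResult.PASS
            ]
            if len(callable_gts) >= 2 and len(set(callable_gts)) >= 2:
                bucket = _source_bucket(marker_id)
                summary.counts[bucket] = summary.counts.get(bucket, 0) + 1
                summary.markers.append(marker_id)
        summaries.append(summary)
    return summaries


def group_summary_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"group_id": s.group_id}
        for bucket in SOURCE_ORDER:
            row[bucket] = s.counts.get(bucket, 0)
        row["Total"] = s.total
        rows.append(row)
    return pd.DataFrame(rows, columns=["group_id", *SOURCE_ORDER, "Total"])


def union_polymorphic_markers(summaries: Sequence[GroupSummary]) -> list[str]:
    """Markers polymorphic in at least one group.

    Per-group totals double-count markers shared between groups, so the
    union is reported alongside them rather than asserting any relation
    between the two.
    """
    seen: set[str] = set()
    for summary in summaries:
        seen.update(summary.markers)
    return sorted(seen)


def mean_group_count(summaries: Sequence[GroupSummary] | Sequence[int]) -> float:
    """Arithmetic mean of group totals, to one decimal."""
    totals = [s.total if isinstance(s, GroupSummary) else int(s) for s in summaries]
    if not totals:
        raise ValueError("no groups")
    return round_half_away(Fraction(sum(totals), len(totals)), 1)


# --------------------------------------------------------------------------
# Concordance against the reference accession
# --------------------------------------------------------------------------

@dataclass
class ConcordanceSummary:
    """Partition of target calls for the reference accession.

    Every target is missing, quality-filtered, or called; among called
    genotypes, homozygous-reference (0/0) calls agree with the reference
    and their fraction is the concordance.
    """

    n_targets: int
    n_missing: int
    n_filtered: int
    called_counts: dict[Zygosity, int]

    def __post_init__(self):
        if self.n_missing + self.n_filtered + self.n_called != self.n_targets:
            raise ValueError("partition does not sum to n_targets")

    @property
    def n_called(self) -> int:
        return sum(self.called_counts.values())

    @property
    def called_pct(self) -> float:
        return round_half_away(Fraction(100 * self.n_called, self.n_targets), 1)

    @property
    def concordance_pct(self) -> float:
        if self.n_called == 0:
            raise ValueError("no called genotypes")
        ref_hom = self.called_counts.get(Zygosity.REF_HOM, 0)
        return round_half_away(Fraction(100 * ref_hom, self.n_called), 1)

    @classmethod
    def from_counts(cls, n_targets, n_missing, n_filtered, called_counts):
        counts = {
            (Zygosity(k) if not isinstance(k, Zygosity) else k): v
            for k, v in called_counts.items()
        }
        return cls(n_targets, n_missing, n_filtered, counts)


def concordance_vs_reference(
    calls: Mapping[str, GenotypeCall] | pd.Series, spec: FilterSpec
) -> ConcordanceSummary:
    """Classify each target call of the reference accession as missing,
    filtered or called, and summarize called genotype classes."""
    items = calls.items() if hasattr(calls, "items") else calls
    n_targets = n_missing = n_filtered = 0
    called: dict[Zygosity, int] = {}
    for _, call in items:
        n_targets += 1
        result = apply_filter(call, spec)
        if result is FilterResult.MISSING:
            n_missing += 1
        elif result is FilterResult.FAIL:
            n_filtered += 1
        else:
            called[call.gt] = called.get(call.gt, 0) + 1
    return ConcordanceSummary(n_targets, n_missing, n_filtered, called)


# --------------------------------------------------------------------------
# Rates, mapping arithmetic, probe bookkeeping
# --------------------------------------------------------------------------

def recovery_rate(n_targets_with_any_polymorphism: int, n_targets: int) -> int:
    """Whole-percent fraction of designed targets that yielded at least one
    called polymorphism versus the reference."""
    if n_targets == 0:
        raise ValueError("no targets")
    if n_targets_with_any_polymorphism > n_targets:
        raise ValueError("numerator exceeds denominator")
    return round_half_away(Fraction(100 * n_targets_with_any_polymorphism, n_targets), 0)


@dataclass(frozen=True)
class MappingStats:
    raw_reads: int
    mapped_reads: int
    on_target_reads: int
    n_accessions: int
    n_contigs: int
    n_target_contigs: int
    mapping_rate_pct: float
    on_target_rate_pct: float
    off_target_rate_pct: float
    mean_reads_per_accession: int
    mean_reads_per_accession_per_contig: int
    mean_coverage_per_accession_per_target: float


def mapping_stats(
    raw: int,
    mapped: int,
    on_target: int,
    n_accessions: int,
    n_contigs: int,
    n_target_contigs: int,
) -> MappingStats:
    """Derived mapping rates and per-accession means, computed with exact
    rational arithmetic and rounded only for display (percentages to two
    decimals, read means to the nearest integer)."""
    if not (0 <= on_target <= mapped <= raw):
        raise ValueError("need on_target <= mapped <= raw (all non-negative)")
    for name, value in (("raw", raw), ("n_accessions", n_accessions),
                        ("n_contigs", n_contigs), ("n_target_contigs", n_target_contigs)):
        if value <= 0:
            raise ValueError(f"{name} must be positive")
    if mapped == 0:
        raise ValueError("no mapped reads")
    return MappingStats(
        raw_reads=raw,
        mapped_reads=mapped,
        on_target_reads=on_target,
        n_accessions=n_accessions,
        n_contigs=n_contigs,
        n_target_contigs=n_target_contigs,
        mapping_rate_pct=round_half_away(Fraction(100 * mapped, raw), 2),
        on_target_rate_pct=round_half_away(Fraction(100 * on_target, mapped), 2),
        off_target_rate_pct=round_half_away(Fraction(100 * (mapped - on_target), mapped), 2),
        mean_reads_per_accession=round_half_away(Fraction(mapped, n_accessions), 0),
        mean_reads_per_accession_per_contig=round_half_away(
            Fraction(mapped, n_accessions * n_contigs), 0),
        mean_coverage_per_accession_per_target=round_half_away(
            Fraction(on_target, n_accessions * n_target_contigs), 2),
    )


@dataclass(frozen=True)
class ProbeTotals:
    n_two_probe: int
    n_one_probe: int

    @property
    def total_probes(self) -> int:
        return 2 * self.n_two_probe + self.n_one_probe

    @property
    def total_targets(self) -> int:
        return self.n_two_probe + self.n_one_probe


def probe_totals(per_target_probe_counts: Iterable[int]) -> ProbeTotals:
    """Tally targets covered by one vs two probes; each target carries
    either one probe (read from one side) or two (read from both)."""
    n_two = n_one = 0
    for count in per_target_probe_counts:
        if count == 2:
            n_two += 1
        elif count == 1:
            n_one += 1
        else:
            raise ValueError(f"probe count must be 1 or 2, got {count}")
    return ProbeTotals(n_two_probe=n_two, n_one_probe=n_one)
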