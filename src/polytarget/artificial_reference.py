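"""Artificial alignment reference built from selected targets.

Instead of mapping reads against the full genome, targeted-resequencing
reads are aligned against a small reference of short contigs: one 301-base
contig centered on every selected target site (the SNP sits at the 151st
position) plus one contig for each homoeologous/paralogous region the
target's window hit.  Including the decoy regions gives reads from those
copies somewhere better to go, keeping them off the target contig.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ._util import revcomp
from .core_io import (
    FlankEdgeError,
    Origin,
    ReferenceGenome,
    extract_flanks,
    write_fasta,
)
from .target_selection import PipelineConfig, SnpCandidate, project_query_to_subject

ROLE_TARGET = "target"
ROLE_HOMOEOLOG = "homoeolog"
ROLE_PARALOG = "paralog"

ID_SEPARATOR = "|"

REGISTRY_COLUMNS = ("contig_id", "marker_id", "role", "target_offset",
                    "chromosome", "start", "end", "strand", "flags")


@dataclass(frozen=True)
class Contig:
    """A 301-base artificial-reference sequence.

    ``target_offset`` is the 1-based position homologous to the target
    site: 151 for target contigs and, by construction (windows centered on
    the projected site), for decoy contigs too.
    """

    contig_id: str
    sequence: str
    role: str
    marker_id: str
    target_offset: int
    origin: Origin
    flags: tuple[str, ...] = ()


@dataclass
class BuildResult:
    contigs: list[Contig]
    registry: pd.DataFrame
    skipped_markers: list[tuple[str, str]]
    skipped_hits: list[tuple[str, str]]

    def target_contig_of(self, marker_id: str) -> str:
        rows = self.registry[(self.registry.marker_id == marker_id)
                             & (self.registry.role == ROLE_TARGET)]
        return rows.iloc[0].contig_id


def registry_frame(contigs: Sequence[Contig]) -> pd.DataFrame:
    rows = [
        {
            "contig_id": c.contig_id,
            "marker_id": c.marker_id,
            "role": c.role,
            "target_offset": c.target_offset,
            "chromosome": c.origin.chromosome,
            "start": c.origin.start,
            "end": c.origin.end,
            "strand": c.origin.strand,
            "flags": ";".join(c.flags),
        }
        for c in contigs
    ]
    return pd.DataFrame(rows, columns=REGISTRY_COLUMNS)


def build_artificial_reference(
    selected: Sequence[SnpCandidate],
    genome: ReferenceGenome,
    config: PipelineConfig | None = None,
) -> BuildResult:
    """One contig per target plus one per homoeolog/paralog hit.

    Decoy contigs are centered on the subject position that the hit aligns
    to the target's SNP column (ungapped projection); when the projection
    is ambiguous (gapped hit or span not covering the site) the window is
    centered on the midpoint of the subject span and flagged.  Windows
    falling off a chromosome end are skipped with a warning (a target
    window doing so rejects the whole marker).  Decoy windows with
    identical origin intervals are emitted once.
    """
    config = config or PipelineConfig()
    half = config.contig_half_width
    q_target = config.flank_half_width + 1  # SNP column in the window query
    contigs: list[Contig] = []
    skipped_markers: list[tuple[str, str]] = []
    skipped_hits: list[tuple[str, str]] = []

    for cand in selected:
        if cand.classified is None:
            raise ValueError(f"{cand.marker_id}: candidate has no classified hits")
        if ID_SEPARATOR in cand.marker_id:
            raise ValueError(f"{cand.marker_id}: marker ids must not contain {ID_SEPARATOR!r}")
        try:
            target_flank = extract_flanks(genome, cand.locus, half)
        except FlankEdgeError:
            skipped_markers.append((cand.marker_id, "edge"))
            warnings.warn(f"{cand.marker_id}: target window hits chromosome end; marker dropped")
            continue
        marker_contigs = [Contig(
            contig_id=f"{cand.marker_id}{ID_SEPARATOR}{ROLE_TARGET}{ID_SEPARATOR}1",
            sequence=target_flank.sequence,
            role=ROLE_TARGET,
            marker_id=cand.marker_id,
            target_offset=half + 1,
            origin=target_flank.origin,
        )]
        seen_intervals = {(target_flank.origin.chromosome,
                           target_flank.origin.start, target_flank.origin.end)}

        roles = []
        if cand.classified.homoeolog_hit is not None:
            roles.append((ROLE_HOMOEOLOG, cand.classified.homoeolog_hit))
        roles.extend((ROLE_PARALOG, h) for h in cand.classified.paralog_hits)

        ordinal = {ROLE_HOMOEOLOG: 0, ROLE_PARALOG: 0}
        for role, hit in roles:
            flags: list[str] = []
            center = project_query_to_subject(hit, q_target)
            if center is None:
                lo, hi = hit.subject_span
                center = (lo + hi) // 2
                flags.append("ambiguous_center")
            chrom = hit.subject_chromosome
            start, end = center - half, center + half
            if start < 1 or end > genome.length(chrom):
                skipped_hits.append((cand.marker_id, f"{role} window {chrom}:{start}-{end} edge"))
                warnings.warn(f"{cand.marker_id}: {role} window off chromosome end; contig skipped")
                continue
            interval = (chrom, start, end)
            if interval in seen_intervals:
                continue
            seen_intervals.add(interval)
            seq = genome.fetch(chrom, start, end)
            if hit.strand == "-":
                seq = revcomp(seq)
            ordinal[role] += 1
            marker_contigs.append(Contig(
                contig_id=f"{cand.marker_id}{ID_SEPARATOR}{role}{ID_SEPARATOR}{ordinal[role]}",
                sequence=seq,
                role=role,
                marker_id=cand.marker_id,
                target_offset=half + 1,
                origin=Origin(chrom, start, end, hit.strand),
                flags=tuple(flags),
            ))
        contigs.extend(marker_contigs)

    return BuildResult(
        contigs=contigs,
        registry=registry_frame(contigs),
        skipped_markers=skipped_markers,
        skipped_hits=skipped_hits,
    )


def write_reference(contigs: Sequence[Contig], fasta_path, registry_path) -> None:
    """FASTA of contigs (ids = contig_id) plus a lossless registry TSV."""
    ids = [c.contig_id for c in contigs]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate contig ids: {dupes[:5]}")
    write_fasta(((c.contig_id, c.sequence) for c in contigs), fasta_path)
    registry_frame(contigs).to_csv(registry_path, sep="\t", index=False)


def read_registry(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"flags": str}, keep_default_na=False)
    missing = set(REGISTRY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"registry {path} missing columns {sorted(missing)}")
    return frame


def load_contigs(fasta_path, registry_path) -> list[Contig]:
    """Round-trip loader: reconstruct Contig objects from the two files."""
    from Bio import SeqIO

    registry = read_registry(registry_path).set_index("contig_id")
    contigs = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        row = registry.loc[record.id]
        contigs.append(Contig(
            contig_id=record.id,
            sequence=str(record.seq).upper(),
            role=row["role"],
            marker_id=row["marker_id"],
            target_offset=int(row["target_offset"]),
            origin=Origin(row["chromosome"], int(row["start"]), int(row["end"]), row["strand"]),
            flags=tuple(f for f in str(row["flags"]).split(";") if f),
        ))
    return contigs
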