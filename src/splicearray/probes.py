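"""Turn splice events into fixed-length junction-spanning probes.

The probe geometry is the heart of the virtual-microarray idea: with a
read length R and a required overhang m into the adjoining exon, each
probe takes F = R - m bases from either exon, for a total length L = 2F.
A read that fits entirely within the probe then overlaps each exon by at
least m bases — for the default 36-base reads and 8-base overhang this is
the classic 56-mer probe with 28-base flanks, which excludes reads that do
not truly span the junction.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import revcomp
from .io import ProbeRecord
from .junctions import EXON_INTRON, SpliceEvent


class GeometryError(ValueError):
    """Raised for probe geometries that cannot guarantee an overhang."""


@dataclass(frozen=True)
class ProbeGeometry:
    """Fixed probe dimensions derived from read length and overhang."""

    read_length: int
    flank_length: int
    min_overhang: int

    @property
    def probe_length(self) -> int:
        return 2 * self.flank_length


#: geometry used throughout the original study: 36-mers, 8-base overhang
PAPER_GEOMETRY_ARGS = dict(read_length=36, required_overhang=8)


def solve_geometry(read_length: int, required_overhang: int = 8) -> ProbeGeometry:
    """Choose flank/probe lengths so every contained read spans the junction.

    F = read_length - required_overhang, L = 2F.  A read of length R placed
    anywhere inside a 2F probe covers at least R - F = required_overhang
    bases of the exon on whichever side it covers least.
    """
    if not 1 <= required_overhang < read_length:
        raise GeometryError(
            f"required overhang must be in [1, read_length); got {required_overhang} "
            f"for read length {read_length}"
        )
    flank = read_length - required_overhang
    return ProbeGeometry(read_length=read_length, flank_length=flank,
                         min_overhang=required_overhang)


def paper_geometry() -> ProbeGeometry:
    return solve_geometry(**PAPER_GEOMETRY_ARGS)


def build_probe(
    event: SpliceEvent, genome: dict[str, str], geometry: ProbeGeometry,
    probe_id: str | None = None,
) -> ProbeRecord:
    """Build the junction probe for one event.

    The sequence is the last F genomic bases before the intron joined to
    the first F bases after it; on the '-' strand the concatenation is
    reverse-complemented so the probe reads in transcribed orientation.
    Exon-intron (retention) probes take F exonic plus F intronic bases
    around the boundary instead.
    """
    F = geometry.flank_length
    if event.kind != EXON_INTRON and event.min_anchor < F:
        raise GeometryError(
            f"{event.event_id}: flanking anchor {event.min_anchor} < flank {F}"
        )
    seq = genome[event.chrom]
    if event.kind == EXON_INTRON:
        left = seq[event.intron_start - F : event.intron_start]
        right = seq[event.intron_end : event.intron_end + F]
    else:
        left = seq[event.intron_start - F : event.intron_start]
        right = seq[event.intron_end : event.intron_end + F]
    if len(left) != F or len(right) != F:
        raise GeometryError(f"{event.event_id}: probe flank runs past chromosome end")
    probe_seq = left + right
    if event.strand == "-":
        probe_seq = revcomp(probe_seq)
    annotations = {
        "event_id": event.event_id,
        "gene": ",".join(event.gene_symbols) or "NULL",
        "chrom": event.chrom,
        "strand": event.strand,
        "intron_start": str(event.intron_start),
        "intron_end": str(event.intron_end),
        "kind": event.kind,
        "donor": event.donor_motif or "NA",
        "acceptor": event.acceptor_motif or "NA",
        "evidence": ",".join(event.evidence),
        "evidence_count": str(len(event.evidence)),
        "source": event.best_source,
    }
    return ProbeRecord(probe_id or event.event_id.replace("SE", "JP"), probe_seq, annotations)


def build_probes(
    events: list[SpliceEvent], genome: dict[str, str], geometry: ProbeGeometry
) -> list[ProbeRecord]:
    return [
        build_probe(ev, genome, geometry, probe_id=f"JP{i:06d}")
        for i, ev in enumerate(events, start=1)
    ]


def collapse_ambiguous_probes(
    probes: list[ProbeRecord],
) -> tuple[list[ProbeRecord], list[list[str]]]:
    """Collapse probes with identical sequences into one flagged representative.

    Reads hitting a collapsed (ambiguous) probe can never be assigned to a
    single event, so downstream unique counting ignores them; the catalog
    entry is retained rather than deleted.  Returns the collapsed probe
    list and a report of the duplicate groups (lists of probe ids).
    """
    by_seq: dict[str, list[ProbeRecord]] = {}
    order: list[str] = []
    for p in probes:
        if p.sequence not in by_seq:
            order.append(p.sequence)
        by_seq.setdefault(p.sequence, []).append(p)
    out: list[ProbeRecord] = []
    report: list[list[str]] = []
    for seq in order:
        group = by_seq[seq]
        if len(group) == 1:
            out.append(group[0])
            continue
        rep = group[0]
        merged = dict(rep.annotations)
        merged["ambiguous"] = "true"
        merged["collapsed_events"] = ",".join(
            p.annotations.get("event_id", p.probe_id) for p in group
        )
        out.append(ProbeRecord(rep.probe_id, rep.sequence, merged))
        report.append([p.probe_id for p in group])
    return out, report


def min_overhang_by_enumeration(geometry: ProbeGeometry) -> int:
    """Exhaustively measure the overhang guarantee for a geometry.

    Enumerates every offset at which a full read fits inside the probe and
    returns the minimum, over placements, of the read's overlap with the
    lesser-covered exon side.  For the default geometry this is 8, attained
    at the two extreme placements (read starting at probe position 1 or
    ending at the last probe base).
    """
    R, F, L = geometry.read_length, geometry.flank_length, geometry.probe_length
    overlaps = []
    for offset in range(0, L - R + 1):
        upstream = min(offset + R, F) - offset
        downstream = (offset + R) - max(offset, F)
        overlaps.append(min(upstream, downstream))
    return min(overlaps)
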