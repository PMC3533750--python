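"""Build the non-redundant, quality-filtered splice-event catalog.

A splice event is a unique intron: the key is (chrom, strand, intron_start,
intron_end, kind).  Every transcript contributes one raw observation per
adjacent exon pair; observations sharing a key are merged into one event
whose evidence list is the union of supporting accessions.

Filtering follows junction-array practice: an event survives if its intron
bears a canonical donor/acceptor motif pair (GT-AG by default, plus the
minor spliceosomal GC-AG and AT-AC), or unconditionally if two or more
independent transcripts support it.  An anchor filter drops events whose
flanking exons are too short to carry a full probe flank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from ._seq import revcomp
from .io import GeneModel

#: canonical intron motif pairs in transcribed orientation (donor, acceptor)
CANONICAL_MOTIFS = frozenset({("GT", "AG"), ("GC", "AG"), ("AT", "AC")})

#: priority of evidence classes when one transcript must represent an event
SOURCE_PRIORITY = {"refseq": 0, "mrna": 1, "est": 2, "predicted": 3}

EXON_EXON = "exon_exon"
EXON_INTRON = "exon_intron"


@dataclass(frozen=True)
class JunctionObservation:
    """One adjacent exon pair of one transcript."""

    chrom: str
    strand: str
    intron_start: int
    intron_end: int
    kind: str
    accession: str
    gene_symbol: str
    source: str
    upstream_anchor: int  # length of the exon ending at intron_start
    downstream_anchor: int  # length of the exon starting at intron_end

    @property
    def key(self) -> tuple:
        return (self.chrom, self.strand, self.intron_start, self.intron_end, self.kind)


@dataclass
class SpliceEvent:
    """A non-redundant junction keyed by its intron coordinates."""

    event_id: str
    chrom: str
    strand: str
    intron_start: int
    intron_end: int
    kind: str = EXON_EXON
    donor_motif: str = ""
    acceptor_motif: str = ""
    evidence: list[str] = field(default_factory=list)
    gene_symbols: list[str] = field(default_factory=list)
    source_classes: frozenset = frozenset()
    # longest flanking anchors over all supporting transcripts; min_anchor is
    # the best min(upstream, downstream) any single transcript achieves
    anchor_up: int = 0
    anchor_down: int = 0
    min_anchor: int = 0

    @property
    def key(self) -> tuple:
        return (self.chrom, self.strand, self.intron_start, self.intron_end, self.kind)

    @property
    def intron_length(self) -> int:
        return self.intron_end - self.intron_start

    @property
    def best_source(self) -> str:
        return min(self.source_classes, key=lambda s: SOURCE_PRIORITY.get(s, 99))


def extract_junctions(
    models: list[GeneModel], include_exon_intron: bool = False
) -> list[JunctionObservation]:
    """Emit one observation per adjacent exon pair per transcript.

    A model with k exons yields exactly k-1 exon_exon observations; a
    single-exon model yields none.  With ``include_exon_intron`` each intron
    additionally yields donor- and acceptor-side boundary observations
    (intron-retention probes), keyed by the boundary coordinate.
    """
    observations: list[JunctionObservation] = []
    for m in models:
        for i in range(len(m.exons) - 1):
            up_start, up_end = m.exons[i]
            down_start, down_end = m.exons[i + 1]
            common = dict(
                chrom=m.chrom,
                strand=m.strand,
                accession=m.transcript_id,
                gene_symbol=m.gene_symbol,
                source=m.source,
            )
            observations.append(
                JunctionObservation(
                    intron_start=up_end,
                    intron_end=down_start,
                    kind=EXON_EXON,
                    upstream_anchor=up_end - up_start,
                    downstream_anchor=down_end - down_start,
                    **common,
                )
            )
            if include_exon_intron:
                intron_len = down_start - up_end
                observations.append(
                    JunctionObservation(
                        intron_start=up_end,
                        intron_end=up_end,
                        kind=EXON_INTRON,
                        upstream_anchor=up_end - up_start,
                        downstream_anchor=intron_len,
                        **common,
                    )
                )
                observations.append(
                    JunctionObservation(
                        intron_start=down_start,
                        intron_end=down_start,
                        kind=EXON_INTRON,
                        upstream_anchor=intron_len,
                        downstream_anchor=down_end - down_start,
                        **common,
                    )
                )
    return observations


def deduplicate(observations: list[JunctionObservation]) -> list[SpliceEvent]:
    """Merge observations into one event per unique intron key.

    Evidence accessions are unioned (a transcript is counted once per
    event), gene symbols and source classes merged, and event ids assigned
    serially after sorting by (chrom, intron_start, intron_end, strand,
    kind) so the catalog is deterministic and order-independent.
    """
    by_key: dict[tuple, list[JunctionObservation]] = {}
    for obs in observations:
        by_key.setdefault(obs.key, []).append(obs)
    events = []
    for key in sorted(by_key, key=lambda k: (k[0], k[2], k[3], k[1], k[4])):
        group = by_key[key]
        chrom, strand, istart, iend, kind = key
        evidence = sorted({o.accession for o in group})
        events.append(
            SpliceEvent(
                event_id="",
                chrom=chrom,
                strand=strand,
                intron_start=istart,
                intron_end=iend,
                kind=kind,
                evidence=evidence,
                gene_symbols=sorted({o.gene_symbol for o in group if o.gene_symbol}),
                source_classes=frozenset(o.source for o in group),
                anchor_up=max(o.upstream_anchor for o in group),
                anchor_down=max(o.downstream_anchor for o in group),
                min_anchor=max(min(o.upstream_anchor, o.downstream_anchor) for o in group),
            )
        )
    for i, ev in enumerate(events, start=1):
        ev.event_id = f"SE{i:06d}"
    return events


def annotate_motifs(
    events: list[SpliceEvent], genome: dict[str, str], min_intron: int = 4
) -> list[SpliceEvent]:
    """Fill donor/acceptor 2-mers from the genome, in transcribed orientation.

    On '+' the donor is the first two intronic bases and the acceptor the
    last two; on '-' both are read from the reverse complement so that a
    canonical intron reports GT..AG regardless of strand.  Exon-exon introns
    shorter than ``min_intron`` cannot carry distinct motifs and are dropped
    with a warning.
    """
    kept = []
    for ev in events:
        if ev.kind == EXON_INTRON:
            kept.append(ev)
            continue
        if ev.intron_length < min_intron:
            warnings.warn(
                f"{ev.event_id}: intron of length {ev.intron_length} < {min_intron}; dropped"
            )
            continue
        seq = genome[ev.chrom]
        left = seq[ev.intron_start : ev.intron_start + 2]
        right = seq[ev.intron_end - 2 : ev.intron_end]
        if ev.strand == "+":
            ev.donor_motif, ev.acceptor_motif = left, right
        else:
            ev.donor_motif, ev.acceptor_motif = revcomp(right), revcomp(left)
        kept.append(ev)
    return kept


def quality_filter(
    events: list[SpliceEvent],
    min_multi_evidence: int = 2,
    canonical_motifs: frozenset = CANONICAL_MOTIFS,
    min_anchor: int | None = None,
) -> list[SpliceEvent]:
    """Keep canonical-motif events, or any event with multiple evidence.

    An event passes the motif rule iff (donor, acceptor) is in
    ``canonical_motifs``; events supported by at least
    ``min_multi_evidence`` transcripts are kept regardless of motif.  If
    ``min_anchor`` is given (the probe flank length), events for which no
    single supporting transcript offers both exonic anchors of at least
    that length are dropped — such events cannot carry a full probe.
    """
    kept = []
    for ev in events:
        if min_anchor is not None and ev.min_anchor < min_anchor:
            continue
        if ev.kind == EXON_INTRON:
            # boundary (retention) events carry no complete intron motif
            kept.append(ev)
        elif len(ev.evidence) >= min_multi_evidence:
            kept.append(ev)
        elif (ev.donor_motif, ev.acceptor_motif) in canonical_motifs:
            kept.append(ev)
    return kept


def build_events(
    models: list[GeneModel],
    genome: dict[str, str],
    min_multi_evidence: int = 2,
    canonical_motifs: frozenset = CANONICAL_MOTIFS,
    min_anchor: int | None = None,
    include_exon_intron: bool = False,
) -> list[SpliceEvent]:
    """Extract, deduplicate, annotate and filter in one call."""
    obs = extract_junctions(models, include_exon_intron=include_exon_intron)
    events = deduplicate(obs)
    events = annotate_motifs(events, genome)
    return quality_filter(
        events,
        min_multi_evidence=min_multi_evidence,
        canonical_motifs=canonical_motifs,
        min_anchor=min_anchor,
    )
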