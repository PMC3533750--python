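"""Readers and writers for every on-disk format the pipeline touches.

Genomic coordinates are 0-based half-open everywhere inside the package;
GTF input (1-based inclusive) is converted on read, BED is passed through.

Gene models can arrive as BED12, GTF (exon features), or a simple
tab-delimited exon table.  The BED12 ``name`` field may carry
``transcript_id|gene_symbol|source`` (pipe-separated); a bare name is taken
as the transcript id with an unknown gene and ``mrna`` source class.

Junction probes are written as FASTA with annotations as ``key=value``
pairs on the header line; values are percent-escaped so that whitespace,
``=`` and ``%`` survive a round trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SOURCE_CLASSES = ("refseq", "mrna", "est", "predicted")


class ParseError(ValueError):
    """Raised when an input file does not parse in its declared dialect."""


# ---------------------------------------------------------------------------
# domain records


@dataclass
class GeneModel:
    """A transcript as ordered exon blocks on the genome.

    ``exons`` are (start, end) 0-based half-open intervals sorted ascending
    and non-overlapping; ``source`` is an evidence class tag
    (refseq | mrna | est | predicted).
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    source: str = "mrna"

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"{self.transcript_id}: empty exon ({start},{end})")
            if start < prev_end:
                raise ValueError(f"{self.transcript_id}: exons unsorted/overlapping")
            prev_end = end

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class ProbeRecord:
    """A junction-spanning probe sequence plus key/value annotations."""

    probe_id: str
    sequence: str
    annotations: dict[str, str] = field(default_factory=dict)

    @property
    def ambiguous(self) -> bool:
        return self.annotations.get("ambiguous", "false") == "true"


@dataclass(frozen=True)
class JunctionRecord:
    """A junction as read back from a junction BED file."""

    chrom: str
    strand: str
    intron_start: int
    intron_end: int
    count: int = 1
    name: str = ""


# ---------------------------------------------------------------------------
# genome FASTA


def load_genome(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into a chrom -> uppercase sequence mapping."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ParseError(f"{path}: no FASTA records")
    return genome


def write_genome(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# gene models


def _bed12_to_model(fields: list[str], lineno: int) -> GeneModel:
    try:
        chrom = fields[0]
        chrom_start = int(fields[1])
        name = fields[3]
        strand = fields[5]
        block_count = int(fields[9])
        block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except (IndexError, ValueError) as exc:
        raise ParseError(f"line {lineno}: malformed BED12 record: {exc}") from exc
    if len(block_sizes) != block_count or len(block_starts) != block_count:
        raise ParseError(f"line {lineno}: blockCount disagrees with block lists")
    exons = [
        (chrom_start + bs, chrom_start + bs + sz)
        for bs, sz in zip(block_starts, block_sizes)
    ]
    parts = name.split("|")
    transcript_id = parts[0]
    gene_symbol = parts[1] if len(parts) > 1 else ""
    source = parts[2] if len(parts) > 2 else "mrna"
    return GeneModel(transcript_id, gene_symbol, chrom, strand, exons, source)


def _read_bed12(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"line {lineno}: expected 12 BED fields, got {len(fields)}")
            model = _bed12_to_model(fields, lineno)
            try:
                model.validate()
            except ValueError as exc:
                warnings.warn(f"line {lineno}: rejected gene model: {exc}")
                continue
            models.append(model)
    return models


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _read_gtf(path: Path) -> list[GeneModel]:
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"line {lineno}: expected 9 GTF fields, got {len(fields)}")
            if fields[2] != "exon":
                continue
            try:
                start = int(fields[3]) - 1  # 1-based inclusive -> 0-based half-open
                end = int(fields[4])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad coordinates: {exc}") from exc
            attrs = _parse_gtf_attributes(fields[8])
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ParseError(f"line {lineno}: exon line without transcript_id")
            source = fields[1].lower()
            if source not in SOURCE_CLASSES:
                source = "mrna"
            entry = per_tx.setdefault(
                tid,
                {
                    "chrom": fields[0],
                    "strand": fields[6],
                    "gene": attrs.get("gene_name", attrs.get("gene_id", "")),
                    "source": source,
                    "exons": [],
                },
            )
            entry["exons"].append((start, end))
            if tid not in order:
                order.append(tid)
    models = []
    for tid in order:
        entry = per_tx[tid]
        model = GeneModel(
            tid,
            entry["gene"],
            entry["chrom"],
            entry["strand"],
            sorted(entry["exons"]),
            entry["source"],
        )
        try:
            model.validate()
        except ValueError as exc:
            warnings.warn(f"rejected gene model {tid}: {exc}")
            continue
        models.append(model)
    return models


def _read_exon_table(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["transcript_id", "gene_symbol", "chrom", "strand", "exon_starts", "exon_ends"]
        if header[: len(required)] != required:
            raise ParseError(f"line 1: exon table header must begin {required}")
        has_source = "source" in header
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                starts = [int(x) for x in fields[4].rstrip(",").split(",")]
                ends = [int(x) for x in fields[5].rstrip(",").split(",")]
            except (IndexError, ValueError) as exc:
                raise ParseError(f"line {lineno}: malformed exon table row: {exc}") from exc
            if len(starts) != len(ends):
                raise ParseError(f"line {lineno}: exon_starts/exon_ends length mismatch")
            source = fields[6] if has_source and len(fields) > 6 else "mrna"
            model = GeneModel(fields[0], fields[1], fields[2], fields[3],
                              list(zip(starts, ends)), source)
            try:
                model.validate()
            except ValueError as exc:
                warnings.warn(f"line {lineno}: rejected gene model: {exc}")
                continue
            models.append(model)
    return models


def read_gene_models(path: str | Path, format: str = "bed12") -> list[GeneModel]:
    """Read gene models from ``path`` in one of {bed12, gtf, exon_table}."""
    path = Path(path)
    if format == "bed12":
        return _read_bed12(path)
    if format == "gtf":
        return _read_gtf(path)
    if format == "exon_table":
        return _read_exon_table(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def write_gene_models_bed12(models: Sequence[GeneModel], path: str | Path) -> int:
    """Write models as BED12 with ``transcript|gene|source`` in the name field."""
    with open(path, "w") as fh:
        for m in models:
            start = m.exons[0][0]
            end = m.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in m.exons)
            starts = ",".join(str(s - start) for s, _ in m.exons)
            name = f"{m.transcript_id}|{m.gene_symbol}|{m.source}"
            fh.write(
                f"{m.chrom}\t{start}\t{end}\t{name}\t0\t{m.strand}"
                f"\t{start}\t{end}\t0\t{len(m.exons)}\t{sizes}\t{starts}\n"
            )
    return len(models)


# ---------------------------------------------------------------------------
# probe FASTA with key=value headers

_ESCAPES = [("%", "%25"), ("=", "%3D"), (" ", "%20"), ("\t", "%09"), ("\n", "%0A")]


def _escape_value(value: str) -> str:
    for raw, enc in _ESCAPES:
        value = value.replace(raw, enc)
    return value


def _unescape_value(value: str) -> str:
    for raw, enc in reversed(_ESCAPES):
        value = value.replace(enc, raw)
    return value


def write_probe_fasta(probes: Sequence[ProbeRecord], path: str | Path) -> int:
    """Write probes as FASTA; header = probe_id then key=value annotations."""
    with open(path, "w") as fh:
        for p in probes:
            pairs = " ".join(f"{k}={_escape_value(str(v))}" for k, v in p.annotations.items())
            header = f">{p.probe_id} {pairs}".rstrip()
            fh.write(f"{header}\n{p.sequence}\n")
    return len(probes)


def read_probe_fasta(path: str | Path) -> list[ProbeRecord]:
    probes = []
    probe_id = None
    annotations: dict[str, str] = {}
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if probe_id is not None:
                    probes.append(ProbeRecord(probe_id, "".join(chunks), annotations))
                tokens = line[1:].split(" ")
                probe_id = tokens[0]
                annotations = {}
                for token in tokens[1:]:
                    if not token:
                        continue
                    key, _, value = token.partition("=")
                    annotations[key] = _unescape_value(value)
                chunks = []
            elif line:
                chunks.append(line.strip().upper())
    if probe_id is not None:
        probes.append(ProbeRecord(probe_id, "".join(chunks), annotations))
    return probes


# ---------------------------------------------------------------------------
# junction BED

def write_junction_bed(events: Iterable, path: str | Path, flank: int = 28) -> int:
    """Write splice events as 2-block BED records.

    The two blocks are the exonic anchors of length ``flank`` on either side
    of the intron; the score column carries the evidence count (the number
    of supporting transcript accessions).
    """
    n = 0
    with open(path, "w") as fh:
        for ev in events:
            count = len(ev.evidence)
            if count < 1:
                raise ValueError(f"{ev.event_id}: evidence count must be >= 1")
            start = ev.intron_start - flank
            end = ev.intron_end + flank
            fh.write(
                f"{ev.chrom}\t{start}\t{end}\t{ev.event_id}\t{count}\t{ev.strand}"
                f"\t{start}\t{end}\t0\t2\t{flank},{flank}\t0,{ev.intron_end - start}\n"
            )
            n += 1
    return n


def read_junction_bed(path: str | Path) -> list[JunctionRecord]:
    """Read junctions back from 2-block BED; inverse of :func:`write_junction_bed`."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"line {lineno}: expected 12 BED fields")
            chrom_start = int(fields[1])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != 2 or len(starts) != 2:
                raise ParseError(f"line {lineno}: junction BED requires exactly 2 blocks")
            intron_start = chrom_start + starts[0] + sizes[0]
            intron_end = chrom_start + starts[1]
            out.append(
                JunctionRecord(fields[0], fields[5], intron_start, intron_end,
                               count=int(fields[4]), name=fields[3])
            )
    return out


# ---------------------------------------------------------------------------
# reads


def read_reads(path: str | Path, format: str | None = None) -> tuple[list[str], list[str]]:
    """Read a FASTA/FASTQ file of reads; returns (ids, sequences).

    Quality strings are ignored: mapping uses a mismatch budget only.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in (".fq", ".fastq"):
            format = "fastq"
        elif suffix in (".fa", ".fasta", ".fna"):
            format = "fasta"
        else:
            with open(path) as fh:
                first = fh.read(1)
            format = "fastq" if first == "@" else "fasta"
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), format):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return ids, seqs


def write_fastq(ids: Sequence[str], seqs: Sequence[str], path: str | Path) -> int:
    with open(path, "w") as fh:
        for rid, seq in zip(ids, seqs):
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return len(ids)


# ---------------------------------------------------------------------------
# tables


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, individual_id, condition, [reads_path]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "individual_id", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id entries")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
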