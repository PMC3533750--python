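"""RPKM normalization, the cross-sample mega table, and coverage profiles.

Event-level RPKM treats the junction probe itself as the exon model, so
the feature length is the probe length (56 by default); the library size
is the sample's total uniquely probe-mapped reads, so that the
normalization reflects exactly the signal the virtual array sees.  Both
choices are explicit arguments for users who prefer otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hybridize import HybridizationResult, ReadHit
from .io import GeneModel, ProbeRecord
from .probes import ProbeGeometry


def rpkm(count: float, feature_length: int, library_size: float):
    """Reads per kilobase of feature per million mapped reads."""
    if np.any(np.asarray(feature_length) <= 0):
        raise ValueError("feature_length must be positive")
    if np.any(np.asarray(library_size) <= 0):
        raise ValueError("library_size must be positive")
    return count / ((feature_length / 1000.0) * (library_size / 1e6))


@dataclass
class EventCountTable:
    """Events x samples unique-hit counts with matched RPKM."""

    counts: pd.DataFrame
    rpkm: pd.DataFrame
    library_sizes: pd.Series
    probe_lengths: pd.Series

    @property
    def events(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def build_mega_table(
    per_sample: Mapping[str, HybridizationResult],
    probes: Sequence[ProbeRecord],
    library_sizes: Mapping[str, int] | None = None,
) -> EventCountTable:
    """Assemble per-sample counts into one events x samples table.

    Rows cover the entire probe database (zeros where unobserved), columns
    are samples in sorted order.  All samples must have been counted
    against the same probe database; a checksum mismatch is a hard error.
    Library sizes default to each sample's total uniquely mapped reads.
    """
    from .hybridize import probe_checksum

    expected = probe_checksum(probes)
    for sample, result in per_sample.items():
        if result.probe_checksum and result.probe_checksum != expected:
            raise ValueError(
                f"sample {sample}: counts come from a different probe database "
                f"(checksum {result.probe_checksum} != {expected})"
            )
    samples = sorted(per_sample)
    event_ids = [p.probe_id for p in probes]
    counts = pd.DataFrame(0, index=event_ids, columns=samples, dtype=int)
    for sample in samples:
        col = per_sample[sample].counts
        counts.loc[list(col.keys()), sample] = list(col.values())
    if library_sizes is None:
        sizes = pd.Series({s: per_sample[s].total_unique for s in samples}, dtype=float)
    else:
        sizes = pd.Series({s: float(library_sizes[s]) for s in samples})
    if (sizes <= 0).any():
        bad = sizes.index[sizes <= 0].tolist()
        raise ValueError(f"zero library size for samples {bad}; cannot normalize")
    lengths = pd.Series({p.probe_id: len(p.sequence) for p in probes}, dtype=float)
    rpkm_df = counts.div(lengths / 1000.0, axis=0).div(sizes / 1e6, axis=1)
    return EventCountTable(counts=counts, rpkm=rpkm_df,
                           library_sizes=sizes, probe_lengths=lengths.astype(int))


def exonic_union_length(models: Sequence[GeneModel]) -> int:
    """Total length of the union of exon intervals over a gene's isoforms."""
    intervals = sorted(
        (start, end) for m in models for start, end in m.exons
    )
    total = 0
    cur_start = cur_end = None
    for start, end in intervals:
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def gene_counts_from_events(
    table: EventCountTable, event_genes: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Gene x sample read counts from uniquely probe-mapped reads.

    Each uniquely mapped read belongs to exactly one probe, so summing a
    gene's event counts assigns each read to its gene once.  Events whose
    annotation lists several genes contribute to each listed gene.
    """
    rows: dict[str, np.ndarray] = {}
    for event_id, genes in event_genes.items():
        if event_id not in table.counts.index:
            continue
        vec = table.counts.loc[event_id].to_numpy()
        for gene in genes:
            if not gene or gene == "NULL":
                continue
            if gene in rows:
                rows[gene] = rows[gene] + vec
            else:
                rows[gene] = vec.copy()
    if not rows:
        return pd.DataFrame(columns=table.samples, dtype=int)
    return pd.DataFrame.from_dict(rows, orient="index", columns=table.samples)


def constitutive_probe_genes(
    probes: Sequence[ProbeRecord], models: Sequence[GeneModel]
) -> dict[str, list[str]]:
    """probe_id -> genes for which the probe's junction is constitutive.

    A junction is constitutive for a gene when every one of the gene's
    transcripts supports it; such junctions track whole-gene expression
    regardless of isoform usage, which makes them the right basis for a
    junction-derived gene-expression estimate (isoform-specific junctions
    would confuse splicing shifts with expression changes).
    """
    gene_tx: dict[str, set[str]] = {}
    for m in models:
        gene_tx.setdefault(m.gene_symbol, set()).add(m.transcript_id)
    out: dict[str, list[str]] = {}
    for p in probes:
        evidence = set(p.annotations.get("evidence", "").split(","))
        genes = []
        for gene in p.annotations.get("gene", "").split(","):
            if gene and gene != "NULL" and gene in gene_tx and gene_tx[gene] <= evidence:
                genes.append(gene)
        if genes:
            out[p.probe_id] = genes
    return out


def gene_counts_for_confound(
    table: EventCountTable,
    probes: Sequence[ProbeRecord],
    models: Sequence[GeneModel],
) -> pd.DataFrame:
    """Gene x sample counts for the expression confound test.

    Uses constitutive junctions where the gene has any; genes whose every
    junction is isoform-specific fall back to the sum over all their
    junctions (a usage-biased but available estimate).
    """
    constitutive = constitutive_probe_genes(probes, models)
    counts = gene_counts_from_events(table, constitutive)
    all_map = {
        p.probe_id: [g for g in p.annotations.get("gene", "").split(",")
                     if g and g != "NULL"]
        for p in probes
    }
    fallback = gene_counts_from_events(table, all_map)
    missing = fallback.index.difference(counts.index)
    if len(missing):
        counts = pd.concat([counts, fallback.loc[missing]])
    return counts


def gene_expression(
    gene_counts: pd.DataFrame,
    gene_lengths: Mapping[str, int],
    library_sizes: pd.Series,
) -> pd.DataFrame:
    """Gene-level RPKM: counts over the exonic-union length and library size."""
    lengths = pd.Series({g: gene_lengths[g] for g in gene_counts.index}, dtype=float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"gene(s) with zero exonic length: {bad}")
    return gene_counts.div(lengths / 1000.0, axis=0).div(library_sizes / 1e6, axis=1)


def base_level_profile(
    hits: Sequence[ReadHit], geometry: ProbeGeometry, window: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-base coverage on the two exonic flanks around one junction.

    Projects probe-mapped read placements onto the probe coordinate line
    and reports coverage of the ``window`` bases immediately upstream and
    downstream of the junction, in transcribed orientation.  If the window
    exceeds the flank it is truncated and flagged.
    """
    F = geometry.flank_length
    truncated = window > F
    w = min(window, F)
    coverage = np.zeros(2 * F, dtype=float)
    R = geometry.read_length
    for hit in hits:
        end = min(hit.offset + R, 2 * F)
        coverage[hit.offset : end] += 1
    upstream = coverage[F - w : F].copy()
    downstream = coverage[F : F + w].copy()
    return upstream, downstream, truncated
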