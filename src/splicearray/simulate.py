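"""Synthetic genomes, multi-isoform gene models, and RNA-seq reads with
planted differential splicing.

The generator emulates the study design end to end: a matched pair of
condition ("tumor") and control ("normal") samples per individual,
36-base reads drawn uniformly along spliced transcripts, negative
binomial count noise around depth-scaled means, and per-gene individual
random effects shared within each matched pair (the variance component
the paired test is designed to cancel).

Splicing changes are planted by shifting isoform usage between
conditions: for a planted linear fold change f, the alternative isoform
takes usage f/(1+f) in tumor and 1/(1+f) in normal, so junctions unique
to it change by exactly f while junctions unique to the primary isoform
change by 1/f.  Expression changes are planted by scaling a gene's read
depth in tumor, leaving usage untouched.

Reads are sampled in transcript space, so the expected number of
detectable (probe-containable) reads per junction has the closed form
  E[count] = n_transcript_reads * (L - R + 1) / (len_t - R + 1)
with L the probe length; this is the ground-truth oracle the pipeline's
observed counts are checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import _COMP_CODE, decode, encode
from .io import (
    GeneModel,
    write_fastq,
    write_gene_models_bed12,
    write_genome,
    write_table,
)

DEFAULT_OVERHANG = 8


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (80, 220)
    intron_length: tuple[int, int] = (100, 400)
    isoforms_per_gene: int = 2
    isoform_structures: tuple[str, ...] = ("skip", "alt5", "alt3")
    n_individuals: int = 10
    read_length: int = 36
    depth: int = 100_000  # reads per sample
    #: (gene_symbol, linear fold change) realized through isoform usage
    planted_splicing: tuple[tuple[str, float], ...] = ()
    #: (gene_symbol, linear fold change) on whole-gene expression
    planted_expression: tuple[tuple[str, float], ...] = ()
    dispersion: float = 0.02  # residual NB dispersion within matched pairs
    individual_sd: float = 0.4  # log2 SD of per-gene individual effects
    base_error_rate: float = 0.005
    expression_log2_spread: float = 1.5  # genes span +-this in log2 expression
    #: (gene_symbol, weight) fixed relative expression overriding the random draw
    gene_weights: tuple[tuple[str, float], ...] = ()
    alt_shift: tuple[int, int] = (6, 18)  # alt-5'/3' splice-site displacement
    condition: str = "tumor"
    control: str = "normal"

    def validate(self) -> None:
        min_flank = 2 * (self.read_length - DEFAULT_OVERHANG)
        if self.exon_length[0] < min_flank:
            raise ValueError(
                f"minimum exon length {self.exon_length[0]} < {min_flank}; "
                "probes would not be constructible"
            )
        if self.exon_length[0] - self.alt_shift[1] < self.read_length - DEFAULT_OVERHANG:
            raise ValueError("alt_shift can shorten exons below the probe flank")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        for _, fc in self.planted_splicing + self.planted_expression:
            if fc <= 0:
                raise ValueError("planted fold changes must be positive")
        if self.intron_length[0] < 10:
            raise ValueError("introns must be long enough to carry motifs")


def junction_key(chrom: str, strand: str, intron_start: int, intron_end: int) -> str:
    return f"{chrom}:{strand}:{intron_start}-{intron_end}"


@dataclass
class GroundTruth:
    """Per-sample expected junction counts and the planted differentials."""

    expected_counts: pd.DataFrame  # junction keys x samples (expected detections)
    differential: pd.DataFrame  # per-junction analytic tumor/normal fold change
    gene_fold_changes: pd.Series  # planted whole-gene expression fold changes
    transcript_junctions: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    genome: dict[str, str]
    models: list[GeneModel]
    sample_sheet: pd.DataFrame
    reads: dict[str, np.ndarray]  # sample_id -> (n_reads, R) uint8 codes
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# genome and models


def _derive_isoform(exons: list[tuple[int, int]], structure: str,
                    rng: np.random.Generator, shift: tuple[int, int]) -> list[tuple[int, int]]:
    n = len(exons)
    if structure == "skip":
        drop = int(rng.integers(1, n - 1))
        return exons[:drop] + exons[drop + 1 :]
    if structure == "alt5":
        i = int(rng.integers(0, n - 1))  # donor of intron i moves into exon i
        delta = int(rng.integers(shift[0], shift[1] + 1))
        out = list(exons)
        start, end = out[i]
        out[i] = (start, end - delta)
        return out
    if structure == "alt3":
        i = int(rng.integers(1, n))  # acceptor of intron i-1 moves into exon i
        delta = int(rng.integers(shift[0], shift[1] + 1))
        out = list(exons)
        start, end = out[i]
        out[i] = (start + delta, end)
        return out
    if structure == "retention":
        i = int(rng.integers(0, n - 1))
        out = exons[:i] + [(exons[i][0], exons[i + 1][1])] + exons[i + 2 :]
        return out
    raise ValueError(f"unknown isoform structure {structure!r}")


def simulate_genome_and_models(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome plus multi-isoform gene models, deterministic per seed.

    Every intron of every isoform is given a canonical GT..AG motif on the
    transcribed strand so the generated catalog survives the quality
    filter with single-transcript evidence.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    models: list[GeneModel] = []
    cursor = 300
    max_coord = 0
    gene_layouts = []
    for g in range(config.n_genes):
        symbol = f"GENE{g + 1:03d}"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exons = []
        pos = cursor
        for i in range(n_ex):
            length = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append((pos, pos + length))
            pos += length
            if i < n_ex - 1:
                pos += int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        isoforms = [exons]
        for j in range(1, config.isoforms_per_gene):
            structure = config.isoform_structures[(j - 1) % len(config.isoform_structures)]
            isoforms.append(_derive_isoform(exons, structure, rng, config.alt_shift))
        for j, iso in enumerate(isoforms, start=1):
            models.append(
                GeneModel(
                    transcript_id=f"{symbol}.T{j}",
                    gene_symbol=symbol,
                    chrom=chrom,
                    strand=strand,
                    exons=iso,
                    source="refseq" if j == 1 else "mrna",
                )
            )
        gene_layouts.append((symbol, strand))
        cursor = pos + 300
        max_coord = max(max_coord, pos)
    genome_len = max_coord + 300
    seq = rng.integers(0, 4, size=genome_len).astype(np.uint8)
    for m in models:
        for istart, iend in m.introns:
            if iend <= istart:
                continue
            if m.strand == "+":
                seq[istart : istart + 2] = encode("GT")
                seq[iend - 2 : iend] = encode("AG")
            else:
                seq[istart : istart + 2] = encode("CT")
                seq[iend - 2 : iend] = encode("AC")
    genome = {chrom: decode(seq)}
    for m in models:
        m.validate()
    return genome, models


# ---------------------------------------------------------------------------
# design: per-sample usage and gene means


def _transcript_sequence(genome: dict[str, str], model: GeneModel) -> np.ndarray:
    codes = np.concatenate(
        [encode(genome[model.chrom][s:e]) for s, e in model.exons]
    )
    if model.strand == "-":
        codes = _COMP_CODE[codes[::-1]]
    return codes


def _transcript_junction_keys(model: GeneModel) -> list[str]:
    return [
        junction_key(model.chrom, model.strand, s, e) for s, e in model.introns
    ]


def _build_design(models, config, rng):
    """Per-gene weights, per-condition isoform usage, planted effects."""
    genes: dict[str, list[GeneModel]] = {}
    for m in models:
        genes.setdefault(m.gene_symbol, []).append(m)
    planted_spl = dict(config.planted_splicing)
    planted_exp = dict(config.planted_expression)
    weights = {}
    usage = {}  # gene -> {condition: {transcript_id: fraction}}
    spread = config.expression_log2_spread
    fixed_weights = dict(config.gene_weights)
    for symbol, iso_models in genes.items():
        weights[symbol] = fixed_weights.get(symbol, 2.0 ** rng.uniform(-spread, spread))
        tx = [m.transcript_id for m in iso_models]
        if symbol in planted_spl and len(tx) >= 2:
            f = planted_spl[symbol]
            alt_normal = 1.0 / (1.0 + f)
            alt_tumor = f / (1.0 + f)
            usage[symbol] = {
                config.control: _split_usage(tx, alt_normal),
                config.condition: _split_usage(tx, alt_tumor),
            }
        else:
            even = {t: 1.0 / len(tx) for t in tx}
            usage[symbol] = {config.control: even, config.condition: dict(even)}
    cond_factor = {
        symbol: {
            config.control: 1.0,
            config.condition: planted_exp.get(symbol, 1.0),
        }
        for symbol in genes
    }
    return genes, weights, usage, cond_factor


def _split_usage(transcripts: list[str], alt_fraction: float) -> dict[str, float]:
    """Primary isoform gets 1 - alt_fraction; alternatives share the rest."""
    n_alt = len(transcripts) - 1
    out = {transcripts[0]: 1.0 - alt_fraction}
    for t in transcripts[1:]:
        out[t] = alt_fraction / n_alt
    return out


def expected_junction_fraction(
    transcript_length: int, read_length: int, overhang: int = DEFAULT_OVERHANG
) -> float:
    """Fraction of a transcript's read placements detectable at one junction.

    Of the len - R + 1 uniform start positions, exactly L - R + 1 place the
    read fully inside the junction's probe (L = 2(R - overhang)).
    """
    L = 2 * (read_length - overhang)
    total = transcript_length - read_length + 1
    if total <= 0:
        return 0.0
    return min(L - read_length + 1, total) / total


# ---------------------------------------------------------------------------
# reads


def _draw_nb(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return int(rng.poisson(lam))


def _reads_from_transcript(
    tcodes: np.ndarray, n_reads: int, read_length: int,
    base_error_rate: float, rng: np.random.Generator,
) -> np.ndarray:
    span = len(tcodes) - read_length + 1
    if span <= 0 or n_reads <= 0:
        return np.zeros((0, read_length), dtype=np.uint8)
    starts = rng.integers(0, span, size=n_reads)
    windows = np.lib.stride_tricks.sliding_window_view(tcodes, read_length)
    reads = windows[starts].copy()
    flip = rng.random(n_reads) < 0.5
    if flip.any():
        reads[flip] = _COMP_CODE[reads[flip][:, ::-1]]
    if base_error_rate > 0:
        err = rng.random(reads.shape) < base_error_rate
        if err.any():
            shifts = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
            reads[err] = (reads[err] + shifts) % 4
    return reads


def simulate_reads(
    genome: dict[str, str],
    models: list[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray], GroundTruth]:
    """Draw per-sample reads and the matching ground truth.

    Returns (sample_sheet, reads-per-sample, truth).  Reads are uint8 code
    matrices (decode with formats helpers or write with write_dataset).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    genes, weights, usage, cond_factor = _build_design(models, config, rng)
    tx_by_id = {m.transcript_id: m for m in models}
    tseqs = {m.transcript_id: _transcript_sequence(genome, m) for m in models}
    tx_junctions = {m.transcript_id: _transcript_junction_keys(m) for m in models}
    all_junctions = sorted({j for keys in tx_junctions.values() for j in keys})
    weight_total = sum(weights.values())

    samples = []
    for ind in range(1, config.n_individuals + 1):
        for condition in (config.condition, config.control):
            sample_id = f"{'T' if condition == config.condition else 'N'}{ind:02d}"
            samples.append((sample_id, f"I{ind:02d}", condition))
    sample_sheet = pd.DataFrame(samples, columns=["sample_id", "individual_id", "condition"])

    # individual-level per-gene effects, shared by both members of a pair
    ind_effects = {
        f"I{ind:02d}": {
            g: 2.0 ** rng.normal(0.0, config.individual_sd) for g in genes
        }
        for ind in range(1, config.n_individuals + 1)
    }

    reads: dict[str, np.ndarray] = {}
    expected = pd.DataFrame(0.0, index=all_junctions,
                            columns=sample_sheet["sample_id"].tolist())
    R = config.read_length
    for sample_id, individual, condition in samples:
        chunks = []
        for symbol, iso_models in genes.items():
            mean = (
                config.depth
                * weights[symbol]
                / weight_total
                * ind_effects[individual][symbol]
                * cond_factor[symbol][condition]
            )
            n_gene = _draw_nb(rng, mean, config.dispersion)
            use = usage[symbol][condition]
            tx_ids = [m.transcript_id for m in iso_models]
            fractions = np.array([use[t] for t in tx_ids])
            alloc = rng.multinomial(n_gene, fractions) if n_gene > 0 else np.zeros(len(tx_ids), int)
            for t, n_t in zip(tx_ids, alloc):
                chunks.append(
                    _reads_from_transcript(
                        tseqs[t], int(n_t), R, config.base_error_rate, rng
                    )
                )
                # expected detections use the pre-noise mean, not the draw
                mean_t = mean * use[t]
                frac = expected_junction_fraction(len(tseqs[t]), R)
                for jkey in tx_junctions[t]:
                    expected.loc[jkey, sample_id] += mean_t * frac
        reads[sample_id] = (
            np.concatenate(chunks) if chunks else np.zeros((0, R), dtype=np.uint8)
        )

    differential = _analytic_differential(
        genes, usage, cond_factor, tseqs, tx_junctions, config
    )
    gene_fc = pd.Series(dict(config.planted_expression), dtype=float, name="fold_change")
    truth = GroundTruth(
        expected_counts=expected,
        differential=differential,
        gene_fold_changes=gene_fc,
        transcript_junctions=tx_junctions,
    )
    return sample_sheet, reads, truth


def _analytic_differential(genes, usage, cond_factor, tseqs, tx_junctions, config):
    """Expected tumor/normal ratio per junction, from the design alone."""
    rows = []
    for symbol, iso_models in genes.items():
        per_junction: dict[str, dict[str, float]] = {}
        for m in iso_models:
            frac = expected_junction_fraction(len(tseqs[m.transcript_id]), config.read_length)
            for jkey in tx_junctions[m.transcript_id]:
                entry = per_junction.setdefault(jkey, {config.condition: 0.0, config.control: 0.0})
                for cond in (config.condition, config.control):
                    entry[cond] += (
                        usage[symbol][cond][m.transcript_id]
                        * cond_factor[symbol][cond]
                        * frac
                    )
        for jkey, entry in per_junction.items():
            num, den = entry[config.condition], entry[config.control]
            fc = np.inf if den == 0 else (num / den if num > 0 else 0.0)
            rows.append((jkey, symbol, fc))
    df = pd.DataFrame(rows, columns=["junction", "gene", "fold_change"])
    return df.set_index("junction")


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full dataset: genome, models, matched-pair samples, reads, truth."""
    genome, models = simulate_genome_and_models(config)
    rng = np.random.default_rng(config.seed + 1)
    sample_sheet, reads, truth = simulate_reads(genome, models, config, rng)
    return SimulatedDataset(genome, models, sample_sheet, reads, truth, config)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, models BED12, per-sample FASTQ, sheet and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "models": outdir / "models.bed",
        "sample_sheet": outdir / "sample_sheet.tsv",
        "truth_expected": outdir / "truth_expected_counts.tsv",
        "truth_differential": outdir / "truth_differential.tsv",
    }
    write_genome(dataset.genome, paths["genome"])
    write_gene_models_bed12(dataset.models, paths["models"])
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    sheet = dataset.sample_sheet.copy()
    read_paths = []
    for sample_id, matrix in dataset.reads.items():
        fq = reads_dir / f"{sample_id}.fastq"
        ids = [f"{sample_id}:{i}" for i in range(matrix.shape[0])]
        write_fastq(ids, [decode(row) for row in matrix], fq)
        # relative to the dataset directory so the sheet is relocatable
        read_paths.append((sample_id, str(fq.relative_to(outdir))))
    sheet = sheet.merge(
        pd.DataFrame(read_paths, columns=["sample_id", "reads_path"]), on="sample_id"
    )
    write_table(sheet, paths["sample_sheet"], index=False)
    write_table(dataset.truth.expected_counts, paths["truth_expected"])
    write_table(dataset.truth.differential, paths["truth_differential"])
    return paths


# ---------------------------------------------------------------------------
# count-level simulation (no reads) for statistical calibration studies


def simulate_event_counts(
    n_events: int,
    n_pairs: int,
    mean: float | np.ndarray,
    dispersion: float = 0.02,
    fold_changes: np.ndarray | None = None,
    individual_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Matched-pair junction counts straight from the noise model.

    Returns (condition, control) count matrices of shape
    (n_events, n_pairs).  ``mean`` is the control-side expected count;
    ``fold_changes`` multiplies the condition side.  A per-event,
    per-individual random effect of SD ``individual_sd`` (log2) is shared
    by both members of a pair.  Counts are gamma-Poisson (negative
    binomial) with the given dispersion.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mu = np.broadcast_to(np.asarray(mean, dtype=float)[..., None], (n_events, n_pairs))
    fc = np.ones(n_events) if fold_changes is None else np.asarray(fold_changes, float)
    effects = (
        2.0 ** rng.normal(0.0, individual_sd, size=(n_events, n_pairs))
        if individual_sd > 0
        else np.ones((n_events, n_pairs))
    )
    mu_ctrl = mu * effects
    mu_cond = mu_ctrl * fc[:, None]

    def draw(m):
        if dispersion <= 0:
            return rng.poisson(m)
        lam = rng.gamma(shape=1.0 / dispersion, scale=m * dispersion)
        return rng.poisson(lam)

    return draw(mu_cond), draw(mu_ctrl)
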