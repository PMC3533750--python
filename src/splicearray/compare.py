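"""Cross-sample / cross-method junction-set comparison.

Junction calls from any source are normalized to intron-coordinate keys
(chrom, strand, intron_start, intron_end) in the package's 0-based
half-open convention, after which comparisons are exact set operations —
no fuzzy coordinate matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .io import ParseError

JunctionKey = tuple[str, str, int, int]


@dataclass
class JunctionSet:
    """A labelled set of normalized junction keys."""

    label: str
    keys: set[JunctionKey] = field(default_factory=set)
    dropped: int = 0  # records discarded during normalization

    def __len__(self) -> int:
        return len(self.keys)


def normalize_external_junctions(
    source: str | Path | Sequence[str],
    label: str,
    convention: str = "zero_half_open",
    anchor_style: str = "block_coords",
) -> JunctionSet:
    """Normalize external junction BED lines to intron-coordinate keys.

    ``anchor_style='block_coords'`` expects 2-block BED12 records whose
    blocks are the exonic anchors; the intron is the gap between blocks.
    ``'intron_coords'`` expects the record interval itself to be the
    intron.  ``convention='one_inclusive'`` shifts 1-based inclusive
    intervals to the internal 0-based half-open convention.  Records whose
    blocks imply a non-positive intron are dropped and counted.
    """
    if convention not in ("zero_half_open", "one_inclusive"):
        raise ValueError(f"unknown coordinate convention {convention!r}")
    if anchor_style not in ("intron_coords", "block_coords"):
        raise ValueError(f"unknown anchor style {anchor_style!r}")
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    keys: set[JunctionKey] = set()
    dropped = 0
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: expected at least 3 BED fields")
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
        if anchor_style == "block_coords":
            if len(fields) < 12:
                raise ParseError(f"line {lineno}: block_coords requires BED12")
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != 2 or len(starts) != 2:
                dropped += 1
                continue
            intron_start = start + starts[0] + sizes[0]
            intron_end = start + starts[1]
        else:
            intron_start, intron_end = start, end
        if convention == "one_inclusive":
            intron_start -= 1
        if intron_end <= intron_start:
            dropped += 1
            continue
        keys.add((chrom, strand, intron_start, intron_end))
    return JunctionSet(label=label, keys=keys, dropped=dropped)


def intersect(sets: Sequence[JunctionSet]) -> set[JunctionKey]:
    """Exact intersection of junction key sets."""
    if not sets:
        raise ValueError("need at least one junction set")
    common = set(sets[0].keys)
    for s in sets[1:]:
        common &= s.keys
    return common


def cumulative_intersection_curve(sets: Sequence[JunctionSet]) -> list[int]:
    """Sizes [|S1|, |S1 n S2|, ..., |S1 n ... n Sn|]; non-increasing."""
    if not sets:
        raise ValueError("need at least one junction set")
    sizes = []
    common = set(sets[0].keys)
    sizes.append(len(common))
    for s in sets[1:]:
        common &= s.keys
        sizes.append(len(common))
    return sizes


def pairwise_overlap_matrix(sets: Sequence[JunctionSet]) -> pd.DataFrame:
    """|Si n Sj| for all pairs, labelled by set."""
    labels = [s.label for s in sets]
    data = [[len(a.keys & b.keys) for b in sets] for a in sets]
    return pd.DataFrame(data, index=labels, columns=labels)
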