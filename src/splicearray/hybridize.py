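"""In-silico hybridization: map reads onto junction probes and count.

A read "hybridizes" to a probe if it can be placed, without gaps, at some
offset on the probe (forward or reverse-complement) with Hamming distance
at most k (default 2, matching common short-read aligner settings), and
the placement spans the junction midpoint.  Only reads whose hits all fall
on a single non-ambiguous probe contribute to that probe's unique count;
everything else is tallied as multimapped or unmapped.

The production mapper uses a pigeonhole substring index: a read with at
most k mismatches must contain at least one of its k+1 disjoint chunks
exactly, so exact chunk lookups nominate candidate placements which are
then verified by Hamming distance.  ``oracle_map`` is an independent
brute-force scan retained for testing.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._seq import _COMP_CODE, N_CODE, encode, mismatches, revcomp_codes
from .io import ProbeRecord
from .probes import ProbeGeometry

FORWARD = "forward"
REVCOMP = "reverse-complement"


@dataclass(frozen=True)
class ReadHit:
    read_id: str
    probe_id: str
    offset: int
    strand: str
    mismatches: int


@dataclass
class HybridizationResult:
    """Unique per-probe counts plus the read-fate bookkeeping."""

    counts: dict[str, int]
    total_unique: int
    multimapped: int
    unmapped: int
    total_reads: int
    probe_checksum: str = ""
    hits_by_read: dict[str, list[ReadHit]] | None = None

    def summary(self) -> dict[str, int]:
        return {
            "total_reads": self.total_reads,
            "total_unique": self.total_unique,
            "multimapped": self.multimapped,
            "unmapped": self.unmapped,
        }


def probe_checksum(probes: Sequence[ProbeRecord]) -> str:
    """Stable digest of the probe database (ids + sequences)."""
    h = hashlib.sha256()
    for p in probes:
        h.update(p.probe_id.encode())
        h.update(b"\0")
        h.update(p.sequence.encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


class ProbeSet:
    """Probes encoded for mapping, with per-read-length chunk indexes."""

    def __init__(self, probes: Sequence[ProbeRecord], geometry: ProbeGeometry):
        if probes:
            lengths = {len(p.sequence) for p in probes}
            if lengths != {geometry.probe_length}:
                raise ValueError(
                    f"probe lengths {sorted(lengths)} disagree with geometry "
                    f"L={geometry.probe_length}"
                )
        self.probes = list(probes)
        self.geometry = geometry
        self.ids = [p.probe_id for p in probes]
        self.id_to_idx = {pid: i for i, pid in enumerate(self.ids)}
        self.ambiguous = np.array([p.ambiguous for p in probes], dtype=bool)
        self.checksum = probe_checksum(probes)
        L = geometry.probe_length
        self.matrix = (
            np.stack([encode(p.sequence) for p in probes])
            if probes
            else np.zeros((0, L), dtype=np.uint8)
        )
        self._chunk_indexes: dict[int, dict[int, np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.probes)

    def chunk_index(self, chunk_len: int) -> dict[int, np.ndarray]:
        """code -> array of packed (probe_idx * (L+1) + position) entries."""
        if chunk_len in self._chunk_indexes:
            return self._chunk_indexes[chunk_len]
        L = self.geometry.probe_length
        index: dict[int, list[int]] = {}
        if len(self.probes) and chunk_len <= L:
            powers = 4 ** np.arange(chunk_len - 1, -1, -1, dtype=np.int64)
            for pi in range(self.matrix.shape[0]):
                row = self.matrix[pi].astype(np.int64)
                for pos in range(L - chunk_len + 1):
                    window = row[pos : pos + chunk_len]
                    if (window == N_CODE).any():
                        continue
                    code = int(window @ powers)
                    index.setdefault(code, []).append(pi * (L + 1) + pos)
        packed = {code: np.asarray(v, dtype=np.int64) for code, v in index.items()}
        self._chunk_indexes[chunk_len] = packed
        return packed


def _spanning_offsets(read_len: int, geometry: ProbeGeometry) -> range:
    """Offsets at which a read both fits on the probe and spans the junction."""
    L, F = geometry.probe_length, geometry.flank_length
    lo = max(0, F - read_len + 1)
    hi = min(L - read_len, F - 1)
    return range(lo, hi + 1)


def _map_codes(
    codes: np.ndarray, probeset: ProbeSet, k: int, read_id: str = ""
) -> list[ReadHit]:
    geometry = probeset.geometry
    L = geometry.probe_length
    R = len(codes)
    if R < 2 * geometry.min_overhang:
        raise ValueError(
            f"read of length {R} shorter than twice the minimum overhang "
            f"({geometry.min_overhang})"
        )
    if R > L or len(probeset) == 0:
        return []
    chunk_len = max(1, R // (k + 1))
    index = probeset.chunk_index(chunk_len)
    offsets = _spanning_offsets(R, geometry)
    powers = 4 ** np.arange(chunk_len - 1, -1, -1, dtype=np.int64)
    hits: list[ReadHit] = []
    for strand, oriented in ((FORWARD, codes), (REVCOMP, revcomp_codes(codes))):
        oriented64 = oriented.astype(np.int64)
        candidates: set[tuple[int, int]] = set()
        for ci in range(k + 1):
            p = ci * chunk_len
            window = oriented64[p : p + chunk_len]
            if (window == N_CODE).any():
                continue
            entries = index.get(int(window @ powers))
            if entries is None:
                continue
            for packed in entries:
                pi, pos = divmod(int(packed), L + 1)
                off = pos - p
                if offsets.start <= off < offsets.stop:
                    candidates.add((pi, off))
        for pi, off in sorted(candidates):
            mm = mismatches(oriented, probeset.matrix[pi, off : off + R])
            if mm <= k:
                hits.append(ReadHit(read_id, probeset.ids[pi], off, strand, mm))
    return hits


def map_read(
    read: str | np.ndarray, probeset: ProbeSet, k: int = 2, read_id: str = ""
) -> list[ReadHit]:
    """All junction-spanning placements of a read within the mismatch budget.

    Both the read and its reverse complement are tried at every offset at
    which the read fits on a probe and crosses the junction midpoint; N
    bases mismatch everything.  Reads longer than the probe have no
    placements by construction; reads shorter than twice the minimum
    overhang are rejected.
    """
    codes = encode(read) if isinstance(read, str) else np.asarray(read, dtype=np.uint8)
    return _map_codes(codes, probeset, k, read_id=read_id)


def oracle_map(
    read: str | np.ndarray, probeset: ProbeSet, k: int = 2, read_id: str = ""
) -> list[ReadHit]:
    """Brute-force sliding-window Hamming scan; test oracle for map_read.

    Scores every probe at every junction-spanning offset on both strands
    (no candidate filtering), so it shares no logic with the indexed
    mapper beyond the mismatch rule itself.
    """
    codes = encode(read) if isinstance(read, str) else np.asarray(read, dtype=np.uint8)
    geometry = probeset.geometry
    R = len(codes)
    if R < 2 * geometry.min_overhang:
        raise ValueError("read shorter than twice the minimum overhang")
    if R > geometry.probe_length or len(probeset) == 0:
        return []
    offsets = _spanning_offsets(R, geometry)
    if len(offsets) == 0:
        return []
    # (P, n_offsets, R) windows of every probe at every spanning offset
    windows = np.lib.stride_tricks.sliding_window_view(
        probeset.matrix, R, axis=1
    )[:, offsets.start : offsets.stop]
    win_n = windows == N_CODE
    hits = []
    for strand, oriented in ((FORWARD, codes), (REVCOMP, revcomp_codes(codes))):
        mm = ((windows != oriented) | win_n | (oriented == N_CODE)).sum(axis=2)
        for pi, oi in zip(*np.nonzero(mm <= k)):
            hits.append(
                ReadHit(read_id, probeset.ids[pi], offsets.start + int(oi),
                        strand, int(mm[pi, oi]))
            )
    return hits


def _chunk_codes_matrix(reads: np.ndarray, chunk_len: int, n_chunks: int) -> np.ndarray:
    """Per-read integer codes of the first n_chunks disjoint chunks (-1 if N)."""
    powers = 4 ** np.arange(chunk_len - 1, -1, -1, dtype=np.int64)
    codes = np.empty((reads.shape[0], n_chunks), dtype=np.int64)
    for ci in range(n_chunks):
        window = reads[:, ci * chunk_len : (ci + 1) * chunk_len].astype(np.int64)
        codes[:, ci] = window @ powers
        codes[np.any(window == N_CODE, axis=1), ci] = -1
    return codes


def hybridize(
    reads: Sequence[str] | np.ndarray,
    probeset: ProbeSet,
    k: int = 2,
    read_ids: Sequence[str] | None = None,
    keep_hits: bool = False,
) -> HybridizationResult:
    """Map a read set and produce unique per-probe counts.

    A read counts once for a probe iff it has at least one hit and all its
    hits fall on that single, non-ambiguous probe.  Reads hitting several
    probes (or only ambiguous ones) are multimapped; reads with no hit, or
    too short/long to be placed, are unmapped.  The identity
    total_unique + multimapped + unmapped == total_reads always holds.
    """
    if isinstance(reads, np.ndarray):
        encoded: list[np.ndarray] | np.ndarray = reads
        n_reads = reads.shape[0]
    else:
        encoded = [encode(r) for r in reads]
        n_reads = len(encoded)
    counts: dict[str, int] = {p: 0 for p in probeset.ids}
    hits_by_read: dict[str, list[ReadHit]] = {} if keep_hits else None
    unique = multimapped = unmapped = 0
    min_len = 2 * probeset.geometry.min_overhang
    warned_short = False

    # fast path: uniform-length matrix input gets a vectorized candidate
    # prefilter; only reads sharing a chunk with some probe are verified
    if isinstance(encoded, np.ndarray) and encoded.ndim == 2 and len(probeset):
        R = encoded.shape[1]
        if R < min_len:
            raise ValueError("reads shorter than twice the minimum overhang")
        if R > probeset.geometry.probe_length:
            return HybridizationResult(counts, 0, 0, n_reads, n_reads,
                                       probe_checksum=probeset.checksum,
                                       hits_by_read=hits_by_read)
        chunk_len = max(1, R // (k + 1))
        index = probeset.chunk_index(chunk_len)
        universe = np.fromiter(index.keys(), dtype=np.int64, count=len(index))
        fwd = _chunk_codes_matrix(encoded, chunk_len, k + 1)
        rc_matrix = _COMP_CODE[encoded[:, ::-1]]
        rc = _chunk_codes_matrix(rc_matrix, chunk_len, k + 1)
        any_candidate = (
            np.isin(fwd, universe).any(axis=1) | np.isin(rc, universe).any(axis=1)
        )
        candidate_rows = np.flatnonzero(any_candidate)
        unmapped += int(n_reads - candidate_rows.size)
        iterator: Iterable[tuple[int, np.ndarray]] = (
            (int(i), encoded[int(i)]) for i in candidate_rows
        )
    else:
        iterator = enumerate(encoded)

    for i, codes in iterator:
        rid = read_ids[i] if read_ids is not None else f"read{i}"
        if len(codes) < min_len:
            if not warned_short:
                warnings.warn("reads shorter than twice the minimum overhang are unmapped")
                warned_short = True
            unmapped += 1
            continue
        hits = _map_codes(codes, probeset, k, read_id=rid)
        if keep_hits and hits:
            hits_by_read[rid] = hits
        if not hits:
            unmapped += 1
            continue
        probes_hit = {h.probe_id for h in hits}
        if len(probes_hit) == 1:
            pid = hits[0].probe_id
            if probeset.ambiguous[probeset.id_to_idx[pid]]:
                multimapped += 1
            else:
                counts[pid] += 1
                unique += 1
        else:
            multimapped += 1
    return HybridizationResult(
        counts=counts,
        total_unique=unique,
        multimapped=multimapped,
        unmapped=unmapped,
        total_reads=n_reads,
        probe_checksum=probeset.checksum,
        hits_by_read=hits_by_read,
    )
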