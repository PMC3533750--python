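"""Read-to-probe mapping: hit semantics, uniqueness, and conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import splicearray as sa
from splicearray._seq import decode, encode, revcomp, revcomp_codes


def _random_probeset(rng, n=30, geometry=None):
    geometry = geometry or sa.paper_geometry()
    L = geometry.probe_length
    probes = [
        sa.ProbeRecord(f"P{i:03d}", decode(rng.integers(0, 4, L).astype(np.uint8)))
        for i in range(n)
    ]
    return sa.ProbeSet(probes, geometry)


@pytest.fixture
def probeset(rng):
    return _random_probeset(rng)


def _hitset(hits):
    return sorted((h.probe_id, h.offset, h.strand, h.mismatches) for h in hits)


class TestMapRead:
    def test_exact_substring_single_hit(self, probeset):
        read = probeset.probes[3].sequence[10:46]
        hits = sa.map_read(read, probeset, k=2)
        exact = [h for h in hits if h.mismatches == 0]
        assert [(h.probe_id, h.offset, h.strand) for h in exact] == [("P003", 10, "forward")]

    def test_budget_excludes_three_mismatches(self, probeset):
        arr = encode(probeset.probes[0].sequence[5:41])
        for pos in (2, 17, 30):
            arr[pos] = (arr[pos] + 1) % 4
        assert sa.map_read(decode(arr), probeset, k=2) == []
        assert any(h.mismatches == 3 for h in sa.map_read(decode(arr), probeset, k=3))

    def test_read_matching_two_probes_returns_both(self, geometry, rng):
        shared = decode(rng.integers(0, 4, 36).astype(np.uint8))
        left = decode(rng.integers(0, 4, 10).astype(np.uint8))
        right = decode(rng.integers(0, 4, 10).astype(np.uint8))
        probes = [
            sa.ProbeRecord("PA", left + shared + right),
            sa.ProbeRecord("PB", right + shared + left),
        ]
        ps = sa.ProbeSet(probes, geometry)
        hits = sa.map_read(shared, ps, k=0)
        assert {h.probe_id for h in hits} == {"PA", "PB"}

    def test_n_counts_as_mismatch_to_everything(self, probeset):
        read = probeset.probes[0].sequence[0:36]
        arr = encode(read)
        arr[:3] = 4  # three N bases exceed k=2
        assert sa.map_read(decode(arr), probeset, k=2) == []
        arr2 = encode(read)
        arr2[0] = 4
        hits = sa.map_read(decode(arr2), probeset, k=2)
        assert any(h.probe_id == "P000" and h.mismatches == 1 for h in hits)

    def test_non_spanning_placements_excluded(self, rng):
        # long probes relative to the read make spanning a real constraint
        geometry = sa.solve_geometry(10, 2)  # F=8, L=16
        ps = _random_probeset(rng, n=5, geometry=geometry)
        for hit in sa.map_read(ps.probes[0].sequence[0:10], ps, k=9):
            assert hit.offset < 8 < hit.offset + 10

    def test_read_longer_than_probe_has_no_hits(self, probeset, rng):
        read = decode(rng.integers(0, 4, 60).astype(np.uint8))
        assert sa.map_read(read, probeset, k=2) == []

    def test_too_short_read_rejected(self, probeset):
        with pytest.raises(ValueError, match="overhang"):
            sa.map_read("ACGTACGTACG", probeset, k=2)

    def test_strand_symmetry(self, probeset, rng):
        read = probeset.probes[7].sequence[4:40]
        fwd = sa.map_read(read, probeset, k=2)
        rev = sa.map_read(revcomp(read), probeset, k=2)
        flip = {"forward": "reverse-complement", "reverse-complement": "forward"}
        assert _hitset(rev) == sorted(
            (h.probe_id, h.offset, flip[h.strand], h.mismatches) for h in fwd
        )

    def test_monotone_in_k(self, probeset, rng):
        arr = encode(probeset.probes[11].sequence[2:38])
        arr[5] = (arr[5] + 2) % 4
        read = decode(arr)
        previous: set = set()
        for k in range(0, 4):
            hits = set(_hitset(sa.map_read(read, probeset, k=k)))
            assert previous <= hits
            previous = hits


class TestOracleEquivalence:
    def test_saturating_budget_hits_every_spanning_offset(self, rng):
        ps = _random_probeset(rng, n=3)
        read = decode(rng.integers(0, 4, 36).astype(np.uint8))
        hits = sa.oracle_map(read, ps, k=36)
        assert len(hits) == 3 * 21 * 2  # probes x offsets x strands

    def test_map_read_equals_oracle_on_random_instances(self, rng):
        ps = _random_probeset(rng, n=20)
        for trial in range(300):
            if trial % 3 == 0:
                read = decode(rng.integers(0, 5, 36).astype(np.uint8))
            else:
                pi = int(rng.integers(0, 20))
                off = int(rng.integers(0, 21))
                arr = encode(ps.probes[pi].sequence)[off : off + 36].copy()
                nmut = int(rng.integers(0, 4))
                pos = rng.choice(36, size=nmut, replace=False)
                arr[pos] = (arr[pos] + rng.integers(1, 4, size=nmut)) % 4
                if rng.random() < 0.5:
                    arr = revcomp_codes(arr)
                read = decode(arr)
            k = int(rng.integers(0, 4))
            assert _hitset(sa.map_read(read, ps, k=k)) == _hitset(
                sa.oracle_map(read, ps, k=k)
            )


class TestHybridize:
    def test_unique_reads_counted_once(self, probeset, rng):
        reads = [probeset.probes[i].sequence[8:44] for i in range(10)]
        result = sa.hybridize(reads, probeset, k=0)
        assert result.total_unique == 10
        assert result.multimapped == 0
        assert sum(result.counts.values()) == 10

    def test_read_hitting_two_probes_is_multimapped(self, geometry, rng):
        shared = decode(rng.integers(0, 4, 36).astype(np.uint8))
        pad = decode(rng.integers(0, 4, 20).astype(np.uint8))
        probes = [
            sa.ProbeRecord("PA", shared + pad),
            sa.ProbeRecord("PB", pad + shared),
        ]
        ps = sa.ProbeSet(probes, geometry)
        result = sa.hybridize([shared], ps, k=2)
        assert result.multimapped == 1 and result.total_unique == 0

    def test_two_placements_on_same_probe_still_unique(self, geometry):
        period = "ACGT" * 14  # periodic probe: same read fits at offsets 4 apart
        ps = sa.ProbeSet([sa.ProbeRecord("PP", period)], geometry)
        read = period[8:44]
        hits = sa.map_read(read, ps, k=0)
        offsets = {h.offset for h in hits if h.strand == "forward"}
        assert len(offsets) > 1  # genuinely multiple placements
        result = sa.hybridize([read], ps, k=0)
        assert result.total_unique == 1 and result.counts["PP"] == 1

    def test_ambiguous_probe_hits_are_multimapped(self, geometry, rng):
        seq = decode(rng.integers(0, 4, 56).astype(np.uint8))
        probes, _ = sa.collapse_ambiguous_probes(
            [sa.ProbeRecord("PA", seq), sa.ProbeRecord("PB", seq)]
        )
        ps = sa.ProbeSet(probes, geometry)
        result = sa.hybridize([seq[0:36]], ps, k=0)
        assert result.multimapped == 1 and result.total_unique == 0

    def test_empty_probe_set_leaves_all_unmapped(self, geometry, rng):
        ps = sa.ProbeSet([], geometry)
        reads = [decode(rng.integers(0, 4, 36).astype(np.uint8)) for _ in range(5)]
        result = sa.hybridize(reads, ps, k=2)
        assert result.unmapped == 5 and result.total_unique == 0

    @settings(max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_read_fate_conservation(self, seed):
        rng = np.random.default_rng(seed)
        ps = _random_probeset(rng, n=8)
        n = int(rng.integers(1, 40))
        reads = np.empty((n, 36), dtype=np.uint8)
        for i in range(n):
            if rng.random() < 0.5:
                reads[i] = rng.integers(0, 4, 36)
            else:
                pi = int(rng.integers(0, 8))
                off = int(rng.integers(0, 21))
                reads[i] = encode(ps.probes[pi].sequence)[off : off + 36]
        result = sa.hybridize(reads, ps, k=2)
        assert result.total_unique + result.multimapped + result.unmapped == n
        assert sum(result.counts.values()) == result.total_unique

    def test_matrix_and_list_inputs_agree(self, probeset, rng):
        reads = [probeset.probes[i].sequence[6:42] for i in range(6)]
        reads += [decode(rng.integers(0, 4, 36).astype(np.uint8)) for _ in range(6)]
        matrix = np.stack([encode(r) for r in reads])
        a = sa.hybridize(reads, probeset, k=2)
        b = sa.hybridize(matrix, probeset, k=2)
        assert a.counts == b.counts and a.summary() == b.summary()
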