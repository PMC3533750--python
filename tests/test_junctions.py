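"""Splice-event extraction, deduplication, motif annotation and filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import splicearray as sa
from splicearray.junctions import JunctionObservation


def _model(transcript_id, exons, strand="+", gene="G", source="mrna"):
    return sa.GeneModel(transcript_id, gene, "chr1", strand, exons, source)


class TestExtractJunctions:
    def test_adjacent_exon_pairs(self):
        obs = sa.extract_junctions([_model("t1", [(0, 100), (200, 300), (400, 500)])])
        assert [(o.intron_start, o.intron_end) for o in obs] == [(100, 200), (300, 400)]
        assert all(o.accession == "t1" for o in obs)

    def test_single_exon_model_contributes_nothing(self):
        assert sa.extract_junctions([_model("t1", [(0, 100)])]) == []

    def test_k_exon_transcript_yields_k_minus_1(self):
        # mirrors a 46-exon kinesin RefSeq: 45 junctions
        exons = [(i * 200, i * 200 + 100) for i in range(46)]
        obs = sa.extract_junctions([_model("kif", exons)])
        assert len(obs) == 45

    def test_anchor_lengths_recorded(self):
        obs = sa.extract_junctions([_model("t1", [(0, 30), (200, 500)])])
        assert obs[0].upstream_anchor == 30
        assert obs[0].downstream_anchor == 300


class TestDeduplicate:
    def test_same_intron_merges_evidence(self):
        models = [
            _model("X", [(0, 100), (200, 300)]),
            _model("Y", [(50, 100), (200, 350)], source="est"),
        ]
        events = sa.deduplicate(sa.extract_junctions(models))
        assert len(events) == 1
        assert events[0].evidence == ["X", "Y"]
        assert events[0].source_classes == frozenset({"mrna", "est"})

    def test_different_intron_end_stays_separate(self):
        models = [
            _model("X", [(0, 100), (200, 300)]),
            _model("Y", [(0, 100), (250, 300)]),
        ]
        events = sa.deduplicate(sa.extract_junctions(models))
        assert len(events) == 2

    def test_empty_input(self):
        assert sa.deduplicate([]) == []

    def test_opposite_strand_same_coordinates_distinct(self):
        models = [
            _model("X", [(0, 100), (200, 300)], strand="+"),
            _model("Y", [(0, 100), (200, 300)], strand="-"),
        ]
        assert len(sa.deduplicate(sa.extract_junctions(models))) == 2


@st.composite
def observation_lists(draw):
    n = draw(st.integers(1, 20))
    obs = []
    for i in range(n):
        istart = draw(st.integers(10, 50)) * 10
        length = draw(st.integers(1, 5)) * 100
        obs.append(
            JunctionObservation(
                chrom="chr1",
                strand=draw(st.sampled_from("+-")),
                intron_start=istart,
                intron_end=istart + length,
                kind="exon_exon",
                accession=f"acc{draw(st.integers(0, 6))}",
                gene_symbol="G",
                source=draw(st.sampled_from(["refseq", "est"])),
                upstream_anchor=100,
                downstream_anchor=100,
            )
        )
    return obs


@settings(max_examples=60, derandomize=True)
@given(observation_lists(), st.randoms(use_true_random=False))
def test_deduplicate_is_order_independent_and_conservative(obs, rnd):
    events = sa.deduplicate(obs)
    assert len(events) <= len(obs)
    # evidence lists count each accession once per event
    n_unique_pairs = len({(o.key, o.accession) for o in obs})
    assert sum(len(e.evidence) for e in events) == n_unique_pairs
    shuffled = list(obs)
    rnd.shuffle(shuffled)
    events2 = sa.deduplicate(shuffled)
    assert [(e.key, e.evidence) for e in events] == [(e.key, e.evidence) for e in events2]
    # idempotence: keys survive a second pass unchanged
    assert {e.key for e in events} == {o.key for o in obs}


class TestAnnotateMotifs:
    def test_plus_strand_reads_genome_directly(self):
        genome = {"chr1": "A" * 100 + "GT" + "C" * 96 + "AG" + "T" * 100}
        events = sa.deduplicate(
            sa.extract_junctions([_model("t", [(50, 100), (200, 250)])])
        )
        [ev] = sa.annotate_motifs(events, genome)
        assert (ev.donor_motif, ev.acceptor_motif) == ("GT", "AG")

    def test_minus_strand_reports_transcribed_orientation(self):
        # plus-strand intron bases begin CT and end AC -> GT..AG transcribed
        genome = {"chr1": "A" * 100 + "CT" + "C" * 96 + "AC" + "T" * 100}
        events = sa.deduplicate(
            sa.extract_junctions([_model("t", [(50, 100), (200, 250)], strand="-")])
        )
        [ev] = sa.annotate_motifs(events, genome)
        assert (ev.donor_motif, ev.acceptor_motif) == ("GT", "AG")

    def test_short_intron_dropped(self):
        genome = {"chr1": "A" * 400}
        events = sa.deduplicate(
            sa.extract_junctions([_model("t", [(50, 100), (103, 150)])])
        )
        with pytest.warns(UserWarning, match="dropped"):
            assert sa.annotate_motifs(events, genome) == []


def _event_with(donor, acceptor, n_evidence):
    return sa.SpliceEvent(
        event_id="SE000001", chrom="chr1", strand="+",
        intron_start=100, intron_end=200,
        donor_motif=donor, acceptor_motif=acceptor,
        evidence=[f"a{i}" for i in range(n_evidence)],
        min_anchor=100,
    )


class TestQualityFilter:
    @pytest.mark.parametrize(
        "donor,acceptor,n,kept",
        [
            ("GT", "AG", 1, True),   # canonical survives alone
            ("GC", "AG", 1, True),
            ("AT", "AC", 1, True),
            ("GA", "AG", 1, False),  # non-canonical, single evidence
            ("GA", "AG", 2, True),   # multi-evidence overrides motif rule
        ],
    )
    def test_motif_and_evidence_rules(self, donor, acceptor, n, kept):
        out = sa.quality_filter([_event_with(donor, acceptor, n)])
        assert (len(out) == 1) is kept

    def test_gt_ag_only_configuration(self):
        out = sa.quality_filter(
            [_event_with("GC", "AG", 1)], canonical_motifs=frozenset({("GT", "AG")})
        )
        assert out == []

    def test_anchor_rule_drops_short_flanks(self):
        ev = _event_with("GT", "AG", 1)
        ev.min_anchor = 20
        assert sa.quality_filter([ev], min_anchor=28) == []
        assert len(sa.quality_filter([ev], min_anchor=20)) == 1

    @settings(max_examples=40, derandomize=True)
    @given(
        st.text(alphabet="ACGT", min_size=2, max_size=2),
        st.text(alphabet="ACGT", min_size=2, max_size=2),
        st.integers(2, 5),
    )
    def test_multi_evidence_never_removed(self, donor, acceptor, n):
        out = sa.quality_filter([_event_with(donor, acceptor, n)], min_multi_evidence=2)
        assert len(out) == 1


class TestExonIntronEvents:
    def test_disabled_by_default(self):
        obs = sa.extract_junctions([_model("t", [(0, 100), (200, 300)])])
        assert all(o.kind == "exon_exon" for o in obs)

    def test_boundary_observations_when_enabled(self):
        obs = sa.extract_junctions(
            [_model("t", [(0, 100), (200, 300)])], include_exon_intron=True
        )
        kinds = [(o.kind, o.intron_start, o.intron_end) for o in obs]
        assert ("exon_exon", 100, 200) in kinds
        assert ("exon_intron", 100, 100) in kinds  # donor-side boundary
        assert ("exon_intron", 200, 200) in kinds  # acceptor-side boundary

    def test_retention_events_survive_filter_and_build_contiguous_probes(
        self, tiny_genome, geometry
    ):
        model = _model("t", [(100, 200), (400, 500)])
        events = sa.build_events(
            [model], tiny_genome, min_anchor=geometry.flank_length,
            include_exon_intron=True,
        )
        retention = [e for e in events if e.kind == "exon_intron"]
        assert len(retention) == 2
        probe = sa.build_probe(retention[0], tiny_genome, geometry)
        b = retention[0].intron_start
        assert probe.sequence == tiny_genome["chr1"][b - 28 : b + 28]


def test_shared_structure_models_give_exon_count_minus_one(tiny_genome):
    exons = [(100, 200), (400, 500), (800, 900)]
    models = [_model(f"t{i}", exons) for i in range(5)]
    events = sa.build_events(models, tiny_genome, min_anchor=None)
    assert len(events) == len(exons) - 1
    assert all(len(e.evidence) == 5 for e in events)


def test_event_ids_deterministic(tiny_genome, tiny_models):
    a = sa.build_events(tiny_models, tiny_genome)
    b = sa.build_events(list(reversed(tiny_models)), tiny_genome)
    assert [(e.event_id, e.key) for e in a] == [(e.event_id, e.key) for e in b]
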