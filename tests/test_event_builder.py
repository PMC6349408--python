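from itertools import combinations

import pytest

from txevents.annotation_io import GeneModel
from txevents.event_builder import (
    EventSet,
    ExtensionSkippedWarning,
    TranscriptGroup,
    build_all,
    classify_truncation,
    construct_events,
    extend_transcript,
    mask_internal_variation,
    select_template,
    select_transcript_groups,
)
from txevents.annotation_io import EventRecord
from txevents.simulate import make_gene, random_gene_spec

from conftest import iv, mirror_chain, mirror_gene, tx


def chains(es):
    return sorted(ev.exon_chain() for ev in es.events)


def exhaustive_best_scaffold(transcripts) -> int:
    """Largest exact-intersection exon set over any transcript pair.

    Adding members can only shrink an intersection, so the optimum over
    all subsets of size >= 2 is attained by some pair.
    """
    best = 0
    for a, b in combinations(transcripts, 2):
        best = max(best, len(a.exon_set() & b.exon_set()))
    return best


def assert_terminal_only_variation(es: EventSet):
    """All events of a masked promoter/3'-end set must be identical after
    deleting each event's own terminal variable exon chain."""
    assert es.masked and es.event_type in ("upstream", "downstream")
    terminal_left = (es.strand == "+") == (es.event_type == "upstream")
    bodies = set()
    for ev in es.events:
        ordered = sorted(ev.exons, key=lambda e: e.start)
        if not terminal_left:
            ordered = ordered[::-1]
        k = 0
        while k < len(ordered) and (ordered[k].start, ordered[k].end) not in es.scaffold:
            k += 1
        bodies.add(tuple(sorted((e.start, e.end) for e in ordered[k:])))
    assert len(bodies) == 1


class TestClassifyTruncation:
    @pytest.mark.parametrize(
        "biotype,tags,expected",
        [
            ("protein_coding", {"cds_end_NF"}, (False, True)),
            ("protein_coding", {"cds_start_NF"}, (True, False)),
            ("protein_coding", {"cds_start_NF", "cds_end_NF"}, (True, True)),
            ("retained_intron", set(), (True, True)),
            ("processed_transcript", set(), (True, True)),
            ("nonsense_mediated_decay", set(), (True, True)),
            ("protein_coding", set(), (False, False)),
        ],
    )
    def test_tags_and_biotypes(self, biotype, tags, expected):
        t = tx("T1", [iv(0, 10), iv(20, 30)], biotype=biotype, tags=tags)
        status = classify_truncation(t)
        assert (status.start_truncated, status.end_truncated) == expected


class TestSelectTemplate:
    def test_longest_basic_wins(self):
        g = GeneModel("G1", [
            tx("T1", [iv(0, 500)], tags={"basic"}),
            tx("T2", [iv(0, 400), iv(600, 1100)], tags={"basic"}),
            tx("T3", [iv(0, 2000)]),  # longest but not basic
        ])
        assert select_template(g).transcript_id == "T2"

    def test_fallback_without_basic(self):
        g = GeneModel("G1", [
            tx("T1", [iv(0, 300)]),
            tx("T2", [iv(0, 400)]),
        ])
        # brute force over all transcripts
        expected = max(g.transcripts, key=lambda t: t.spliced_length).transcript_id
        assert select_template(g).transcript_id == expected == "T2"

    def test_tie_breaks_to_smallest_id(self):
        g = GeneModel("G1", [
            tx("T2", [iv(0, 500)], tags={"basic"}),
            tx("T1", [iv(100, 600)], tags={"basic"}),
        ])
        assert select_template(g).transcript_id == "T1"


class TestExtendTranscript:
    TEMPLATE = [iv(0, 100), iv(200, 300), iv(400, 500), iv(600, 700)]

    def template(self):
        return tx("TMPL", self.TEMPLATE, tags={"basic"})

    def test_start_truncated_gains_upstream_template_exons(self):
        t = tx("T1", [iv(200, 300), iv(400, 500)], tags={"cds_start_NF"})
        rep = extend_transcript(t, self.template(), classify_truncation(t))
        assert [(e.start, e.end) for e in rep.exons] == [(0, 100), (200, 300), (400, 500)]
        status = classify_truncation(rep)
        assert not status.start_truncated and not status.end_truncated

    def test_terminal_exon_widened_to_template_boundary(self):
        # 5'-terminal exon starts mid-way into template exon 2
        t = tx("T1", [iv(250, 300), iv(400, 500)], tags={"cds_start_NF"})
        rep = extend_transcript(t, self.template(), classify_truncation(t))
        assert [(e.start, e.end) for e in rep.exons] == [(0, 100), (200, 300), (400, 500)]

    def test_complete_transcript_is_noop(self):
        t = tx("T1", [iv(200, 300)])
        assert extend_transcript(t, self.template(), classify_truncation(t)) is t

    def test_idempotent(self):
        t = tx("T1", [iv(200, 300), iv(400, 500)], tags={"cds_start_NF", "cds_end_NF"})
        once = extend_transcript(t, self.template(), classify_truncation(t))
        twice = extend_transcript(once, self.template(), classify_truncation(once))
        assert [(e.start, e.end) for e in once.exons] == [
            (e.start, e.end) for e in twice.exons
        ]

    def test_original_chain_preserved_as_subsequence(self):
        t = tx("T1", [iv(200, 300), iv(400, 500)], tags={"cds_end_NF"})
        rep = extend_transcript(t, self.template(), classify_truncation(t))
        original = [(e.start, e.end) for e in t.exons]
        repaired = [(e.start, e.end) for e in rep.exons]
        assert [e for e in repaired if e in original] == original

    def test_minus_strand_start_truncation_extends_genomic_right(self):
        tmpl = tx("TMPL", [iv(0, 100, strand="-"), iv(200, 300, strand="-")],
                  strand="-", tags={"basic"})
        t = tx("T1", [iv(0, 100, strand="-")], strand="-", tags={"cds_start_NF"})
        rep = extend_transcript(t, tmpl, classify_truncation(t))
        assert [(e.start, e.end) for e in rep.exons] == [(0, 100), (200, 300)]

    def test_truncated_template_skips_with_warning(self):
        tmpl = tx("TMPL", self.TEMPLATE, tags={"basic", "cds_start_NF"})
        t = tx("T1", [iv(400, 500)], tags={"cds_start_NF"})
        with pytest.warns(ExtensionSkippedWarning):
            rep = extend_transcript(t, tmpl, classify_truncation(t))
        assert [(e.start, e.end) for e in rep.exons] == [(400, 500)]


class TestGrouping:
    def test_three_transcripts_sharing_two_exons(self):
        shared = [iv(200, 300), iv(400, 500)]
        g = GeneModel("G1", [
            tx("T1", [iv(0, 100)] + shared),
            tx("T2", shared),
            tx("T3", shared + [iv(600, 700)]),
        ])
        groups = select_transcript_groups(g)
        assert len(groups) == 1
        assert groups[0].member_ids == ["T1", "T2", "T3"]
        assert groups[0].scaffold == frozenset({(200, 300), (400, 500)})

    def test_two_disjoint_pairs_give_two_groups(self):
        g = GeneModel("G1", [
            tx("T1", [iv(0, 100), iv(200, 300)]),
            tx("T2", [iv(0, 100), iv(200, 300), iv(350, 380)]),
            tx("T3", [iv(1000, 1100), iv(1200, 1300)]),
            tx("T4", [iv(1000, 1100), iv(1200, 1300), iv(1400, 1500)]),
        ])
        groups = select_transcript_groups(g)
        assert len(groups) == 2
        assert groups[0].member_ids == ["T1", "T2"]
        assert groups[1].member_ids == ["T3", "T4"]

    def test_single_transcript_gene_yields_no_groups(self):
        g = GeneModel("G1", [tx("T1", [iv(0, 100)])])
        assert select_transcript_groups(g) == []

    def test_deterministic_under_permutation(self):
        gene, _ = make_gene(random_gene_spec(42))
        permuted = GeneModel(gene.gene_id, list(reversed(gene.transcripts)))
        a = select_transcript_groups(gene)
        b = select_transcript_groups(permuted)
        assert [(g.member_ids, g.scaffold) for g in a] == [
            (g.member_ids, g.scaffold) for g in b
        ]

    @pytest.mark.parametrize("seed", range(30))
    def test_group1_scaffold_matches_exhaustive_optimum(self, seed):
        gene, _ = make_gene(random_gene_spec(seed))
        groups = select_transcript_groups(gene)
        optimum = exhaustive_best_scaffold(gene.transcripts)
        if groups:
            assert len(groups[0].scaffold) <= optimum
            assert len(groups[0].scaffold) == optimum
        else:
            assert optimum == 0


class TestConstructEvents:
    def canonical(self):
        """Two transcripts: alt first exon, one skipped internal, alt last."""
        t1 = tx("T1", [iv(0, 100), iv(200, 300), iv(400, 500), iv(600, 700), iv(800, 900)])
        t2 = tx("T2", [iv(120, 160), iv(200, 300), iv(600, 700), iv(950, 1000)])
        g = GeneModel("G1", [t1, t2])
        (group,) = select_transcript_groups(g)
        return group, [t1, t2]

    def test_three_event_sets_with_two_events_each(self):
        group, members = self.canonical()
        assert group.scaffold == frozenset({(200, 300), (600, 700)})
        sets = construct_events(group, members)
        assert [(es.event_type, len(es.events)) for es in sets] == [
            ("upstream", 2),
            ("contained", 2),
            ("downstream", 2),
        ]
        up = sets[0]
        assert chains(up) == sorted([
            ((0, 100), (200, 300), (600, 700)),
            ((120, 160), (200, 300), (600, 700)),
        ])

    def test_identical_upstream_parts_drop_the_event_type(self):
        shared_first = iv(0, 100)
        t1 = tx("T1", [shared_first, iv(200, 300), iv(400, 500)])
        t2 = tx("T2", [shared_first, iv(200, 300), iv(600, 700)])
        g = GeneModel("G1", [t1, t2])
        (group,) = select_transcript_groups(g)
        sets = construct_events(group, [t1, t2])
        assert {es.event_type for es in sets} == {"downstream"}

    def test_scaffold_contained_in_every_event(self):
        for seed in range(20):
            gene, _ = make_gene(random_gene_spec(seed))
            for es in build_all(gene, mask=False):
                for ev in es.events:
                    assert es.scaffold <= set(ev.exon_chain())

    def test_strand_mirroring_yields_identical_events(self):
        group, members = self.canonical()
        plus_sets = {
            (es.event_type,): chains(es) for es in construct_events(group, members)
        }
        g = GeneModel("G1", members)
        mirrored = mirror_gene(g)
        (mgroup,) = select_transcript_groups(mirrored)
        minus_sets = {}
        for es in construct_events(mgroup, mirrored.transcripts):
            minus_sets[(es.event_type,)] = sorted(
                mirror_chain(c) for c in chains(es)
            )
        assert plus_sets == minus_sets

    def test_variable_exon_inside_scaffold_span_is_contained(self):
        # T2's extra exon lies between the two scaffold exons, so it must
        # feed the internal-exon event, not a promoter/3'-end event
        t1 = tx("T1", [iv(0, 100), iv(600, 700), iv(900, 1000)])
        t2 = tx("T2", [iv(600, 700), iv(750, 800), iv(900, 1000)])
        g = GeneModel("G1", [t1, t2])
        (group,) = select_transcript_groups(g)
        assert group.scaffold == frozenset({(600, 700), (900, 1000)})
        sets = construct_events(group, [t1, t2])
        by_type = {es.event_type: es for es in sets}
        assert set(by_type) == {"upstream", "contained"}
        assert chains(by_type["contained"]) == sorted([
            ((600, 700), (900, 1000)),
            ((600, 700), (750, 800), (900, 1000)),
        ])


class TestMasking:
    def upstream_set_with_internal_variation(self):
        """Hand-built promoter set where event A also skips an internal
        variable exon that event B carries."""
        scaffold = frozenset({(600, 700), (800, 900)})
        a = EventRecord.build("G1", 1, "upstream", "T1",
                              [iv(0, 100), iv(600, 700), iv(800, 900)])
        b = EventRecord.build("G1", 1, "upstream", "T2",
                              [iv(150, 200), iv(400, 500), iv(600, 700), iv(800, 900)])
        return EventSet("G1", 1, "upstream", [a, b], scaffold)

    def test_union_inserted_into_the_skipping_event(self):
        es = self.upstream_set_with_internal_variation()
        masked = mask_internal_variation(es)
        assert masked.masked
        got = {ev.representative: ev.exon_chain() for ev in masked.events}
        # A gains B's internal variable exon (400,500); both events now
        # differ only at their first exons
        assert got["T1"] == ((0, 100), (400, 500), (600, 700), (800, 900))
        assert got["T2"] == ((150, 200), (400, 500), (600, 700), (800, 900))
        assert_terminal_only_variation(masked)

    def test_terminal_only_variation_is_fixed_point(self):
        a = EventRecord.build("G1", 1, "upstream", "T1",
                              [iv(0, 100), iv(600, 700)])
        b = EventRecord.build("G1", 1, "upstream", "T2",
                              [iv(200, 300), iv(600, 700)])
        es = EventSet("G1", 1, "upstream", [a, b], frozenset({(600, 700)}))
        masked = mask_internal_variation(es)
        assert chains(masked) == chains(es)

    def test_idempotent(self):
        es = self.upstream_set_with_internal_variation()
        once = mask_internal_variation(es)
        twice = mask_internal_variation(once)
        assert chains(once) == chains(twice)

    def test_contained_sets_pass_through(self):
        a = EventRecord.build("G1", 1, "contained", "T1", [iv(0, 100), iv(600, 700)])
        b = EventRecord.build("G1", 1, "contained", "T2", [iv(600, 700)])
        es = EventSet("G1", 1, "contained", [a, b], frozenset({(600, 700)}))
        assert mask_internal_variation(es) is es


class TestBuildAll:
    def test_canonical_gene_produces_all_three_sets(self, canonical_gene):
        gene, truth = canonical_gene
        sets = build_all(gene)
        got = {(es.group_index, es.event_type): len(es.events) for es in sets}
        assert got == truth.n_events
        assert got == {(1, "upstream"): 2, (1, "contained"): 2, (1, "downstream"): 2}

    def test_truncated_member_repaired_then_grouped(self):
        from txevents.simulate import GeneStructureSpec, TranscriptOptions

        spec = GeneStructureSpec(
            transcripts=[
                TranscriptOptions(),
                TranscriptOptions(alt_first=1, truncate_end=True),
                TranscriptOptions(alt_last=1),
                TranscriptOptions(skip_internal=2),
            ],
            n_core_exons=5,
            seed=5,
        )
        gene, truth = make_gene(spec)
        # manual pipeline: classify/extend -> group -> construct -> mask
        template = select_template(gene)
        repaired = []
        for t in gene.transcripts:
            st = classify_truncation(t)
            repaired.append(extend_transcript(t, template, st) if st.any else t)
        rg = GeneModel(gene.gene_id, repaired)
        by_id = {t.transcript_id: t for t in rg.transcripts}
        manual = []
        for group in select_transcript_groups(rg):
            for es in construct_events(group, [by_id[i] for i in group.member_ids]):
                es = mask_internal_variation(es)
                if len(es.events) >= 2:
                    manual.append(es)
        auto = build_all(gene)
        assert [(e.group_index, e.event_type, chains(e)) for e in auto] == [
            (e.group_index, e.event_type, chains(e)) for e in manual
        ]
        assert {
            (es.group_index, es.event_type): len(es.events) for es in auto
        } == truth.n_events

    def test_identical_transcripts_give_no_events(self):
        exons = [iv(0, 100), iv(200, 300)]
        g = GeneModel("G1", [tx("T1", exons), tx("T2", list(exons))])
        assert build_all(g) == []

    def test_permuted_input_order_gives_identical_output(self, canonical_gene):
        gene, _ = canonical_gene
        permuted = GeneModel(gene.gene_id, list(reversed(gene.transcripts)))
        a = [(e.group_index, e.event_type, chains(e)) for e in build_all(gene)]
        b = [(e.group_index, e.event_type, chains(e)) for e in build_all(permuted)]
        assert a == b

    def test_masked_sets_satisfy_terminal_only_variation(self):
        for seed in range(50):
            gene, _ = make_gene(random_gene_spec(seed))
            for es in build_all(gene):
                if es.masked and es.event_type in ("upstream", "downstream"):
                    assert_terminal_only_variation(es)
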