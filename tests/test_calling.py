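"""Frequency tables, dominance threshold semantics, genotype projection."""

import numpy as np
import pytest

from coevoseq import (
    DominantMutationCaller,
    GenotypeProjector,
    MutationEvent,
    build_frequency_table,
    identify_dominant,
    planted_population,
    project_genotypes,
    sample_reads,
)
from coevoseq.calling import CalledRead, call_reads, events_from_table
from coevoseq.mutations import SUBSTITUTION
from coevoseq.references import HOST, PARASITE_ALPHA


def _sub(refs, site, alt=None):
    ref_base = refs.host[site - 1]
    if alt is None:
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref_base]
    return MutationEvent(site, SUBSTITUTION, ref_base, alt)


def _called(events_per_read, round=1, label=HOST):
    return [
        CalledRead(f"r{i}", round, label, frozenset(evs))
        for i, evs in enumerate(events_per_read)
    ]


class TestFrequencyTable:
    def test_direct_counting(self, refs):
        ev = _sub(refs, 3)
        called = _called([{ev}] * 3 + [set()] * 17)
        table = build_frequency_table(called)
        row = table.iloc[0]
        assert (row["count"], row["depth"]) == (3, 20)
        assert row["frequency"] == pytest.approx(0.15)

    def test_zero_error_simulation_gives_empty_table(self, refs):
        from coevoseq import SimulationConfig, simulate_serial_transfer

        cfg = SimulationConfig(
            n_rounds=2, host_length=refs.host_length,
            deletion_windows=dict(refs.windows), substitution_rate=0.0,
            indel_rate=0.0, deletion_event_rate=0.0, initial_population=500,
            droplet_cap=200, seed=1,
        )
        pops, _ = simulate_serial_transfer(cfg, refs)
        reads = sample_reads(pops[-1], 100, 0.0, seed=1)
        table = build_frequency_table(call_reads(reads, refs))
        assert table.empty

    def test_planted_frequency_recovered_within_3se(self, refs):
        ev = _sub(refs, 10)
        pop = planted_population(refs, {HOST: [((ev,), 0.5), ((), 0.5)]},
                                 20_000)
        reads = sample_reads(pop, 2000, 0.0, seed=4)
        table = build_frequency_table(call_reads(reads, refs))
        freq = table.loc[table["site"] == 10, "frequency"].iloc[0]
        assert abs(freq - 0.5) <= 3 * np.sqrt(0.25 / 2000)

    def test_empty_groups_absent_not_zero(self, refs):
        table = build_frequency_table(_called([{_sub(refs, 3)}], round=2))
        assert set(table["round"]) == {2}


class TestDominantCaller:
    def test_included_above_threshold(self, refs):
        table = build_frequency_table(
            _called([{_sub(refs, 3)}] * 3 + [set()] * 17)
        )
        dom = identify_dominant(table, 0.10)
        assert dom.events == [_sub(refs, 3)]

    def test_exactly_at_threshold_excluded(self, refs):
        table = build_frequency_table(
            _called([{_sub(refs, 3)}] * 2 + [set()] * 18)
        )
        assert len(identify_dominant(table, 0.10)) == 0  # strict "more than"

    def test_empty_table_empty_set(self):
        table = build_frequency_table([])
        assert len(identify_dominant(table)) == 0

    def test_threshold_range_enforced(self, refs):
        table = build_frequency_table(_called([set()]))
        for bad in (0.0, 1.0, 1.5):
            with pytest.raises(ValueError, match="threshold"):
                DominantMutationCaller(bad).fit(table)

    def test_distinct_site_collapse(self, refs):
        """Two events at one site count once in the site list."""
        e1 = _sub(refs, 3)
        e2 = MutationEvent(3, SUBSTITUTION, e1.ref,
                           next(b for b in "ACGT" if b not in (e1.ref, e1.alt)))
        e3 = _sub(refs, 7)
        table = build_frequency_table(
            _called([{e1}] * 4 + [{e2}] * 4 + [{e3}] * 4 + [set()] * 8)
        )
        caller = DominantMutationCaller().fit(table)
        assert caller.n_events_ == 3
        assert caller.n_sites_ == 2

    def test_matches_brute_force_scan(self, small_sim, refs):
        """Caller equals a direct scan over per-site counts on sim data."""
        _, pops, _ = small_sim
        reads = []
        for pop in pops:
            reads.extend(sample_reads(pop, 150, 1e-3, seed=pop.round))
        called = call_reads(reads, refs)
        table = build_frequency_table(called)
        dom = identify_dominant(table, 0.10)
        # brute force: recount every event from the raw calls
        expected = set()
        for (rnd, label) in {(c.round, c.class_label) for c in called}:
            group = [c for c in called
                     if c.round == rnd and c.class_label == label]
            counts = {}
            for c in group:
                for ev in c.events:
                    counts[ev] = counts.get(ev, 0) + 1
            for ev, n in counts.items():
                if n / len(group) > 0.10:
                    expected.add(ev)
        assert set(dom.events) == expected


class TestGenotypeProjection:
    def test_counting_example(self, refs):
        e1, e2 = _sub(refs, 3), _sub(refs, 7)
        dom_table = build_frequency_table(
            _called([{e1, e2}] * 2 + [{e2}] * 3 + [set()] * 5)
        )
        dom = identify_dominant(dom_table, 0.10)
        called = _called([set()] * 5 + [{e2}] * 3 + [{e1, e2}] * 2)
        genotypes = project_genotypes(called, dom, refs)
        assert [(g.vector_string, g.frequency, g.rank) for g in genotypes] == [
            ("00", 0.5, 1),
            ("01", 0.3, 2),
            ("11", 0.2, 3),
        ]

    def test_no_dominant_sites_single_genotype(self, refs):
        called = _called([set()] * 4)
        genotypes = project_genotypes(called, None, refs)
        assert len(genotypes) == 1
        assert genotypes[0].frequency == 1.0

    def test_frequencies_sum_to_one_before_truncation(self, refs):
        e1, e2 = _sub(refs, 3), _sub(refs, 7)
        dom = identify_dominant(
            build_frequency_table(_called([{e1}] * 5 + [{e2}] * 5)), 0.10
        )
        called = _called([{e1}] * 4 + [{e2}] * 3 + [{e1, e2}] * 2 + [set()])
        genotypes = project_genotypes(called, dom, refs, top_n=2)
        full = project_genotypes(called, dom, refs, top_n=100)
        assert sum(g.frequency for g in full) == pytest.approx(1.0)
        assert len(genotypes) == 2  # truncation happens after normalisation
        assert sum(g.frequency for g in genotypes) < 1.0

    def test_parasite_sites_masked_inside_window(self, refs):
        window = refs.window(PARASITE_ALPHA)
        inside = _sub(refs, window.start + 1)
        outside = _sub(refs, 3)
        dom = identify_dominant(
            build_frequency_table(_called([{inside, outside}] * 5 + [set()] * 5)),
            0.10,
        )
        called = _called([{outside}] * 2, label=PARASITE_ALPHA)
        [g] = project_genotypes(called, dom, refs)
        by_event = dict(zip(dom.events, g.vector))
        assert by_event[inside] == -1
        assert by_event[outside] == 1

    def test_ambiguous_reads_dropped(self, refs):
        ev = _sub(refs, 3)
        dom = identify_dominant(
            build_frequency_table(_called([{ev}] * 5 + [set()] * 5)), 0.10
        )
        called = [
            CalledRead("ok", 1, HOST, frozenset([ev])),
            CalledRead("amb", 1, HOST, frozenset(), frozenset({3})),
        ]
        projector = GenotypeProjector(dom, refs).fit(called)
        assert projector.n_dropped_ambiguous_ == 1
        assert len(projector.genotypes_) == 1

    def test_planted_two_haplotypes_recovered(self, refs):
        e1, e2 = _sub(refs, 10), _sub(refs, 20)
        pop = planted_population(
            refs, {HOST: [((e1,), 0.7), ((e1, e2), 0.3)]}, 20_000
        )
        reads = sample_reads(pop, 2000, 0.0, seed=6)
        called = call_reads(reads, refs)
        dom = identify_dominant(build_frequency_table(called), 0.10)
        genotypes = project_genotypes(called, dom, refs)
        assert len(genotypes) == 2
        freqs = sorted(g.frequency for g in genotypes)
        assert freqs[1] == pytest.approx(0.7, abs=3 * np.sqrt(0.21 / 2000))

    def test_events_from_table_round_trip(self, refs):
        evs = [{_sub(refs, 3)}, {_sub(refs, 7)}, set()]
        table = build_frequency_table(_called(evs))
        assert set(events_from_table(table)) == {_sub(refs, 3), _sub(refs, 7)}
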