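"""Synthetic serial-transfer generator: conservation, lineage, sampling."""

import numpy as np
import pytest
from scipy import stats

from coevoseq import (
    DeletionWindow,
    MutationEvent,
    PARASITE_ALPHA,
    SimulationConfig,
    generate_reference_set,
    planted_population,
    sample_reads,
    simulate_serial_transfer,
)
from coevoseq.mutations import SUBSTITUTION, apply_mutations
from coevoseq.references import HOST, scaled_deletion_windows


def _quiet_config(refs, **overrides) -> SimulationConfig:
    base = dict(
        n_rounds=4,
        host_length=refs.host_length,
        deletion_windows=dict(refs.windows),
        substitution_rate=0.0,
        indel_rate=0.0,
        deletion_event_rate=0.0,
        initial_population=800,
        droplet_cap=300,
        reads_per_round=100,
        seq_error_rate=0.0,
        seed=5,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestReferences:
    def test_window_excision_arithmetic(self):
        refs = generate_reference_set(2040, {PARASITE_ALPHA: DeletionWindow(100, 1920)})
        assert len(refs.sequence(PARASITE_ALPHA)) == 219  # 2040 - 1821

    def test_no_windows_host_only(self):
        refs = generate_reference_set(500, {})
        assert refs.classes == [HOST]

    def test_parasite_retains_both_termini(self, refs):
        par = refs.sequence(PARASITE_ALPHA)
        w = refs.window(PARASITE_ALPHA)
        assert refs.host.startswith(par[: w.start - 1])
        assert refs.host.endswith(par[w.start - 1 :])

    def test_window_must_leave_termini(self):
        with pytest.raises(ValueError, match="termini"):
            generate_reference_set(100, {PARASITE_ALPHA: DeletionWindow(1, 50)})

    def test_duplicate_windows_rejected(self):
        with pytest.raises(ValueError, match="share"):
            generate_reference_set(
                200,
                {"a": DeletionWindow(10, 100), "b": DeletionWindow(10, 100)},
            )

    def test_scaled_windows_keep_length_ratios(self):
        windows = scaled_deletion_windows(1020)
        refs = generate_reference_set(1020, windows)
        lengths = {c: len(refs.sequence(c)) for c in windows}
        assert lengths[PARASITE_ALPHA] == pytest.approx(110, abs=2)


class TestApplyMutations:
    def test_substitution_insertion_deletion(self):
        ref = "ACGTACGT"
        assert apply_mutations(ref, [MutationEvent(3, "substitution", "G", "T")]) == "ACTTACGT"
        assert apply_mutations(ref, [MutationEvent(4, "insertion", "", "GG")]) == "ACGTGGACGT"
        assert apply_mutations(ref, [MutationEvent(5, "deletion", "A", "")]) == "ACGTCGT"

    def test_window_masks_internal_events(self):
        ref = "ACGTACGT"
        w = DeletionWindow(3, 6)
        out = apply_mutations(ref, [MutationEvent(4, "substitution", "T", "A")], w)
        assert out == "ACGT"  # event inside the window is undefined

    def test_mismatched_ref_base_rejected(self):
        with pytest.raises(ValueError, match="reference has"):
            apply_mutations("ACGT", [MutationEvent(1, "substitution", "C", "T")])


class TestSerialTransfer:
    def test_zero_rates_conserve_sequences(self, refs):
        pops, truth = simulate_serial_transfer(_quiet_config(refs), refs)
        for pop in pops:
            for mol in pop.members:
                assert mol.sequence(refs) == refs.host
                assert mol.mutations == frozenset()
        assert truth.mutation_frequencies.empty
        assert truth.deletion_events == []

    def test_deletion_only_products_are_exact_excisions(self, refs):
        cfg = _quiet_config(refs, deletion_event_rate=0.01, n_rounds=6)
        pops, truth = simulate_serial_transfer(cfg, refs)
        parasites = [
            m for pop in pops for m in pop.members if m.class_label != HOST
        ]
        assert parasites, "deletion events should have produced parasites"
        for mol in parasites:
            assert mol.sequence(refs) == refs.sequence(mol.class_label)

    def test_parasite_ancestry_has_exactly_one_deletion(self, small_sim):
        _, pops, truth = small_sim
        parasites = {
            m.molecule_id for pop in pops for m in pop.members
            if m.class_label != HOST
        }
        assert parasites
        for mid in parasites:
            assert len(truth.deletion_events_on_path(mid)) == 1
        hosts = {
            m.molecule_id for pop in pops for m in pop.members
            if m.class_label == HOST
        }
        for mid in list(hosts)[:50]:
            assert truth.deletion_events_on_path(mid) == []

    def test_dilution_within_binomial_interval(self, refs, rng):
        cfg = _quiet_config(refs)
        from coevoseq.simulate import Molecule, _Simulator

        sim = _Simulator(cfg, refs, rng)
        members = [Molecule(0, None, HOST, frozenset(), 10_000)]
        kept = sum(m.copy_count for m in sim.dilute(members))
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.2)
        assert lo <= kept <= hi

    def test_reproducible_under_fixed_seed(self, refs):
        cfg = _quiet_config(refs, substitution_rate=1e-3,
                            deletion_event_rate=5e-3)
        pops1, truth1 = simulate_serial_transfer(cfg, refs)
        pops2, truth2 = simulate_serial_transfer(cfg, refs)
        for p1, p2 in zip(pops1, pops2):
            assert [(m.molecule_id, m.copy_count, m.mutations)
                    for m in p1.members] == [
                (m.molecule_id, m.copy_count, m.mutations) for m in p2.members
            ]
        assert truth1.mutation_frequencies.equals(truth2.mutation_frequencies)

    def test_excessive_carrying_capacity_rejected(self, refs):
        with pytest.raises(ValueError, match="population_cap"):
            _quiet_config(refs, droplet_cap=10**7).validate()

    def test_invalid_rates_rejected(self, refs):
        with pytest.raises(ValueError, match="dilution_keep"):
            _quiet_config(refs, dilution_keep=1.0).validate()
        with pytest.raises(ValueError, match="substitution_rate"):
            _quiet_config(refs, substitution_rate=1.5).validate()


class TestSampleReads:
    def test_no_error_reads_match_source(self, refs):
        pops, _ = simulate_serial_transfer(_quiet_config(refs), refs)
        reads = sample_reads(pops[-1], 50, 0.0, seed=1)
        assert len(reads) == 50
        assert all(r.sequence == refs.host for r in reads)
        assert all(r.round == pops[-1].round for r in reads)

    def test_same_seed_identical_readset(self, small_sim):
        _, pops, _ = small_sim
        r1 = sample_reads(pops[-1], 200, 1e-3, seed=42, passes_lambda=10)
        r2 = sample_reads(pops[-1], 200, 1e-3, seed=42, passes_lambda=10)
        assert r1 == r2

    def test_two_genotype_mixture_recovered(self, refs):
        ev = MutationEvent(5, SUBSTITUTION, refs.host[4], _other(refs.host[4]))
        pop = planted_population(
            refs, {HOST: [((ev,), 0.7), ((), 0.3)]}, 10_000
        )
        reads = sample_reads(pop, 2000, 0.0, seed=9)
        carrier = refs.host[:4] + ev.alt + refs.host[5:]
        p_hat = sum(r.sequence == carrier for r in reads) / 2000
        se = np.sqrt(0.7 * 0.3 / 2000)
        assert abs(p_hat - 0.7) <= 3 * se

    def test_empty_population_is_error(self, refs):
        from coevoseq.simulate import ReplicatorPopulation

        with pytest.raises(ValueError, match="empty"):
            sample_reads(ReplicatorPopulation(1, [], refs), 10, 0.0)

    def test_frequencies_converge_with_depth(self, refs):
        ev = MutationEvent(5, SUBSTITUTION, refs.host[4], _other(refs.host[4]))
        pop = planted_population(
            refs, {HOST: [((ev,), 0.4), ((), 0.6)]}, 50_000
        )
        carrier = refs.host[:4] + ev.alt + refs.host[5:]

        def err(n, seed):
            reads = sample_reads(pop, n, 0.0, seed=seed)
            return abs(sum(r.sequence == carrier for r in reads) / n - 0.4)

        small = np.mean([err(200, s) for s in range(5)])
        big = np.mean([err(20_000, s) for s in range(5)])
        assert big < small


def _other(base: str) -> str:
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
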