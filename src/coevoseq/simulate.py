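"""Synthetic serial-transfer coevolution of host and parasitic RNA replicators.

The generator emulates the droplet replication–dilution protocol: molecules
are partitioned into water-in-oil droplets (Poisson occupancy), replicate
within droplets — hosts autonomously, parasites only when a host shares the
droplet, with a length-dependent replication advantage — acquire point
mutations and rare large internal deletions that convert a host copy into a
parasite class, and are then diluted five-fold (each molecule kept with
probability ``dilution_keep``, default 0.2, matching removal of 80% of the
droplets) before the next round. Vigorous mixing between rounds is modelled
as full pooling: droplets are reshuffled every round.

Molecules are represented as (reference, mutation set) pairs in original-host
coordinates, so the simulation truth — per-round mutation frequencies,
deletion events, and the molecule parentage map — is exact by construction
rather than re-estimated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import ReadRecord
from .mutations import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    DeletionWindow,
    MutationEvent,
    apply_mutations,
)
from .references import (
    DEFAULT_DELETION_WINDOWS,
    DEFAULT_HOST_LENGTH,
    HOST,
    ReferenceSet,
    generate_reference_set,
)

_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Parameters of the serial-transfer simulation.

    Defaults reflect the protocol being emulated where it fixes them:
    ``dilution_keep=0.2`` (80% of droplets removed, i.e. five-fold dilution)
    and ``substitution_rate=1e-5`` per base per replication (the error rate
    of the replicase). The remaining values are desk-scale modelling
    choices, documented in the methods note.
    """

    n_rounds: int = 10
    dilution_keep: float = 0.2
    substitution_rate: float = 1.0e-5
    indel_rate: float = 1.0e-6
    deletion_event_rate: float = 1.0e-3
    deletion_windows: dict[str, DeletionWindow] = field(
        default_factory=lambda: dict(DEFAULT_DELETION_WINDOWS)
    )
    host_length: int = DEFAULT_HOST_LENGTH
    droplet_lambda: float = 5.0
    replication_factor_host: float = 8.0
    length_advantage_exponent: float = 1.0
    droplet_cap: int = 100
    initial_population: int = 5000
    population_cap: int = 2_000_000
    reads_per_round: int = 1000
    seq_error_rate: float = 1.0e-3
    seed: int = 0

    def validate(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if not 0.0 < self.dilution_keep < 1.0:
            raise ValueError("dilution_keep must lie in (0, 1)")
        for name in ("substitution_rate", "indel_rate", "deletion_event_rate",
                     "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.replication_factor_host < 1.0:
            raise ValueError("replication_factor_host must be >= 1")
        if self.initial_population < 1 or self.droplet_cap < 1:
            raise ValueError("population sizes must be positive")
        # the droplet count is fixed by the reaction volume, so the carrying
        # capacity is n_droplets * droplet_cap; reject configs that let the
        # population outgrow the configured cap
        capacity = self.n_droplets * self.droplet_cap
        if capacity > self.population_cap:
            raise ValueError(
                f"carrying capacity {capacity} (droplets x droplet_cap) "
                f"exceeds population_cap={self.population_cap}; reduce "
                "droplet_cap or initial_population, or raise the cap"
            )

    @property
    def n_droplets(self) -> int:
        return max(1, int(round(self.initial_population / self.droplet_lambda)))
        from .references import validate_windows

        validate_windows(self.deletion_windows, self.host_length)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        if "deletion_windows" in raw:
            raw["deletion_windows"] = {
                label: (se if isinstance(se, DeletionWindow)
                        else DeletionWindow(int(se[0]), int(se[1])))
                for label, se in raw["deletion_windows"].items()
            }
        # YAML 1.1 reads "1e-05" (no dot) as a string; coerce numerics
        for f in dataclasses.fields(cls):
            if f.name in raw and f.type in ("float", "int") and isinstance(
                raw[f.name], str
            ):
                caster = float if f.type == "float" else int
                raw[f.name] = caster(raw[f.name])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["deletion_windows"] = {
            label: [w.start, w.end] for label, w in self.deletion_windows.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class Molecule:
    """One sequence lineage: a mutation set with a copy count."""

    molecule_id: int
    parent_id: int | None
    class_label: str
    mutations: frozenset[MutationEvent]
    copy_count: int

    def sequence(self, references: ReferenceSet) -> str:
        return apply_mutations(
            references.host, self.mutations, references.window(self.class_label)
        )


@dataclass
class ReplicatorPopulation:
    """Post-replication population of one transfer round."""

    round: int
    members: list[Molecule]
    references: ReferenceSet

    @property
    def total_copies(self) -> int:
        return sum(m.copy_count for m in self.members)

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.members:
            out[m.class_label] = out.get(m.class_label, 0) + m.copy_count
        return out

    def mutation_frequencies(self) -> pd.DataFrame:
        """Exact per-class frequency of every mutation carried this round."""
        rows = []
        totals = self.class_counts()
        counts: dict[tuple[str, MutationEvent], int] = {}
        for m in self.members:
            for ev in m.mutations:
                if self.references.retained(m.class_label, ev.site):
                    key = (m.class_label, ev)
                    counts[key] = counts.get(key, 0) + m.copy_count
        for (label, ev), c in counts.items():
            rows.append(
                {
                    "round": self.round,
                    "class": label,
                    "site": ev.site,
                    "kind": ev.kind,
                    "ref": ev.ref,
                    "alt": ev.alt,
                    "label": ev.label,
                    "frequency": c / totals[label],
                }
            )
        return pd.DataFrame(
            rows,
            columns=["round", "class", "site", "kind", "ref", "alt", "label",
                     "frequency"],
        )


@dataclass(frozen=True)
class DeletionEvent:
    """A host replication that produced a parasite-class molecule."""

    round: int
    parent_id: int
    child_id: int
    class_label: str
    window: DeletionWindow


@dataclass
class SimulationTruth:
    """Ground truth planted by the simulation."""

    mutation_frequencies: pd.DataFrame
    deletion_events: list[DeletionEvent]
    parentage: dict[int, int | None]
    classes: dict[int, str]
    seed: int

    def ancestry(self, molecule_id: int) -> list[int]:
        chain = [molecule_id]
        while self.parentage.get(chain[-1]) is not None:
            chain.append(self.parentage[chain[-1]])
        return chain

    def deletion_events_on_path(self, molecule_id: int) -> list[DeletionEvent]:
        by_child = {ev.child_id: ev for ev in self.deletion_events}
        return [by_child[m] for m in self.ancestry(molecule_id) if m in by_child]

    def to_tsv(self, path: str | Path) -> None:
        freq = self.mutation_frequencies.assign(record="mutation_frequency")
        dele = pd.DataFrame(
            [
                {
                    "record": "deletion_event",
                    "round": ev.round,
                    "class": ev.class_label,
                    "site": ev.window.start,
                    "kind": "large_deletion",
                    "ref": "",
                    "alt": "",
                    "label": f"del{ev.window.start}-{ev.window.end}",
                    "frequency": np.nan,
                    "parent_id": ev.parent_id,
                    "child_id": ev.child_id,
                }
                for ev in self.deletion_events
            ]
        )
        pd.concat([freq, dele], ignore_index=True).to_csv(
            path, sep="\t", index=False
        )


class _Simulator:
    def __init__(self, config: SimulationConfig, references: ReferenceSet,
                 rng: np.random.Generator):
        self.cfg = config
        self.refs = references
        self.rng = rng
        self.next_id = 0
        self.parentage: dict[int, int | None] = {}
        self.classes: dict[int, str] = {}
        self.deletion_events: list[DeletionEvent] = []
        self._retained_sites = {
            label: np.array(
                [s for s in range(1, len(references.host) + 1)
                 if references.retained(label, s)]
            )
            for label in references.classes
        }

    def new_molecule(self, parent: Molecule | None, class_label: str,
                     mutations: frozenset[MutationEvent],
                     copies: int) -> Molecule:
        mol = Molecule(self.next_id,
                       None if parent is None else parent.molecule_id,
                       class_label, mutations, copies)
        self.parentage[mol.molecule_id] = mol.parent_id
        self.classes[mol.molecule_id] = class_label
        self.next_id += 1
        return mol

    def _replication_factor(self, class_label: str) -> float:
        if class_label == HOST:
            return self.cfg.replication_factor_host
        ratio = len(self.refs.host) / len(self.refs.sequence(class_label))
        return self.cfg.replication_factor_host * (
            ratio ** self.cfg.length_advantage_exponent
        )

    def _mutate_offspring(self, parent: Molecule, round_idx: int) -> Molecule:
        """One replicated copy that acquired at least one point mutation."""
        cfg, rng = self.cfg, self.rng
        sites = self._retained_sites[parent.class_label]
        length = len(sites)
        n_sub = rng.binomial(length, cfg.substitution_rate)
        n_indel = rng.binomial(length, cfg.indel_rate)
        if n_sub + n_indel == 0:
            n_sub = 1
        occupied = {ev.site for ev in parent.mutations}
        new_events: list[MutationEvent] = []
        for kind_pool, n in ((SUBSTITUTION, n_sub), (None, n_indel)):
            for _ in range(n):
                site = int(rng.choice(sites))
                if site in occupied:
                    continue  # rare collision; skip rather than stack events
                occupied.add(site)
                ref_base = self.refs.host[site - 1]
                if kind_pool == SUBSTITUTION:
                    alt = _BASES[int(rng.integers(4))]
                    while alt == ref_base:
                        alt = _BASES[int(rng.integers(4))]
                    new_events.append(
                        MutationEvent(site, SUBSTITUTION, ref_base, alt))
                elif rng.random() < 0.5:
                    new_events.append(
                        MutationEvent(site, INSERTION, "",
                                      _BASES[int(rng.integers(4))]))
                else:
                    new_events.append(
                        MutationEvent(site, DELETION, ref_base, ""))
        if not new_events:
            parent.copy_count += 1
            return parent
        return self.new_molecule(
            parent, parent.class_label,
            parent.mutations | frozenset(new_events), 1)

    def _deletion_child(self, parent: Molecule, round_idx: int) -> Molecule:
        label = str(self.rng.choice(sorted(self.cfg.deletion_windows)))
        window = self.cfg.deletion_windows[label]
        kept = frozenset(ev for ev in parent.mutations
                         if not window.contains(ev.site))
        child = self.new_molecule(parent, label, kept, 1)
        self.deletion_events.append(
            DeletionEvent(round_idx, parent.molecule_id, child.molecule_id,
                          label, window))
        return child

    def run_round(self, members: list[Molecule],
                  round_idx: int) -> list[Molecule]:
        cfg, rng = self.cfg, self.rng
        total = sum(m.copy_count for m in members)
        if total == 0:
            return []
        n_droplets = cfg.n_droplets  # fixed by the reaction volume
        # Poisson occupancy via uniform multinomial assignment of copies
        placement = np.zeros((len(members), 0), dtype=np.int64)
        per_mol = [
            rng.multinomial(m.copy_count, np.full(n_droplets, 1.0 / n_droplets))
            for m in members
        ]
        placement = np.vstack(per_mol) if per_mol else placement
        host_flags = np.array([m.class_label == HOST for m in members])
        occupied = np.nonzero(placement.sum(axis=0) > 0)[0]
        new_children: list[Molecule] = []
        for d in occupied:
            col = placement[:, d]
            idx = np.nonzero(col)[0]
            if not host_flags[idx].any():
                continue  # no replicase source: nothing replicates
            factors = np.array(
                [self._replication_factor(members[i].class_label) for i in idx]
            )
            proposed = rng.poisson(col[idx] * (factors - 1.0))
            excess = proposed.sum() - cfg.droplet_cap
            if excess > 0:  # finite resources per droplet
                proposed = rng.multinomial(
                    cfg.droplet_cap, proposed / proposed.sum())
            for i, n_off in zip(idx, proposed):
                mol = members[i]
                n_del = 0
                if mol.class_label == HOST and cfg.deletion_windows:
                    n_del = rng.binomial(n_off, cfg.deletion_event_rate)
                n_rep = n_off - n_del
                p_any = 1.0 - (1.0 - cfg.substitution_rate) ** len(
                    self._retained_sites[mol.class_label]
                ) * (1.0 - cfg.indel_rate) ** len(
                    self._retained_sites[mol.class_label]
                )
                n_mut = rng.binomial(n_rep, p_any)
                mol.copy_count += n_rep - n_mut
                for _ in range(n_mut):
                    child = self._mutate_offspring(mol, round_idx)
                    if child is not mol:
                        new_children.append(child)
                for _ in range(n_del):
                    new_children.append(self._deletion_child(mol, round_idx))
        members = members + new_children
        if sum(m.copy_count for m in members) > cfg.population_cap:
            raise RuntimeError(
                f"population exceeded population_cap={cfg.population_cap} "
                f"in round {round_idx}"
            )
        return members

    def dilute(self, members: list[Molecule]) -> list[Molecule]:
        survivors = []
        for m in members:
            kept = int(self.rng.binomial(m.copy_count, self.cfg.dilution_keep))
            if kept > 0:
                survivors.append(
                    Molecule(m.molecule_id, m.parent_id, m.class_label,
                             m.mutations, kept)
                )
        return survivors


def simulate_serial_transfer(
    config: SimulationConfig,
    references: ReferenceSet | None = None,
) -> tuple[list[ReplicatorPopulation], SimulationTruth]:
    """Run the replication–dilution protocol for ``config.n_rounds`` rounds.

    Returns one post-replication :class:`ReplicatorPopulation` per round
    (round indices start at 1) and the :class:`SimulationTruth` recording
    every planted mutation frequency, deletion event and parent–child link.
    If every molecule is lost to dilution the simulation ends early with the
    rounds completed so far.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if references is None:
        references = generate_reference_set(
            config.host_length, config.deletion_windows, seed=rng
        )
    sim = _Simulator(config, references, rng)
    founder = sim.new_molecule(None, HOST, frozenset(),
                               config.initial_population)
    members = [founder]
    populations: list[ReplicatorPopulation] = []
    freq_frames: list[pd.DataFrame] = []
    for round_idx in range(1, config.n_rounds + 1):
        members = sim.run_round(members, round_idx)
        snapshot = ReplicatorPopulation(
            round_idx,
            [dataclasses.replace(m) for m in members],
            references,
        )
        populations.append(snapshot)
        freq_frames.append(snapshot.mutation_frequencies())
        members = sim.dilute(members)
        if not members:
            break
    truth = SimulationTruth(
        mutation_frequencies=pd.concat(freq_frames, ignore_index=True),
        deletion_events=sim.deletion_events,
        parentage=sim.parentage,
        classes=sim.classes,
        seed=config.seed,
    )
    return populations, truth


def planted_population(
    references: ReferenceSet,
    haplotypes: Mapping[str, Sequence[tuple[Iterable[MutationEvent], float]]],
    copies_per_class: int,
    round_index: int = 1,
) -> ReplicatorPopulation:
    """Build a population with exact planted haplotype frequencies.

    ``haplotypes`` maps class label -> list of (mutation events, frequency);
    frequencies within a class must sum to 1. Copy counts are the rounded
    products, so the planted frequencies are exact up to rounding. Useful
    for validating frequency recovery without running the full simulation.
    """
    members: list[Molecule] = []
    next_id = 0
    for label, haps in haplotypes.items():
        total_f = sum(f for _, f in haps)
        if abs(total_f - 1.0) > 1e-9:
            raise ValueError(f"frequencies for {label} sum to {total_f}")
        for events, f in haps:
            count = int(round(f * copies_per_class))
            if count == 0:
                continue
            members.append(
                Molecule(next_id, None, label, frozenset(events), count)
            )
            next_id += 1
    if not members:
        raise ValueError("no molecules planted")
    return ReplicatorPopulation(round_index, members, references)


def sample_reads(
    population: ReplicatorPopulation,
    n: int,
    seq_error_rate: float,
    seed: int | np.random.Generator = 0,
    passes_lambda: float | None = None,
) -> list[ReadRecord]:
    """Draw ``n`` reads multinomially by copy count, with sequencing error.

    Each read's bases are flipped independently with ``seq_error_rate``.
    When ``passes_lambda`` is given, a CCS pass count of ``1 + Poisson`` is
    attached to every read. Identical seeds give identical read sets.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not population.members:
        raise ValueError("cannot sample reads from an empty population")
    rng = np.random.default_rng(seed)
    counts = np.array([m.copy_count for m in population.members], dtype=float)
    draws = rng.multinomial(n, counts / counts.sum())
    seqs = {i: m.sequence(population.references)
            for i, m in enumerate(population.members) if draws[i] > 0}
    reads: list[ReadRecord] = []
    read_idx = 0
    for i, n_reads in enumerate(draws):
        if n_reads == 0:
            continue
        mol = population.members[i]
        base_seq = seqs[i]
        length = len(base_seq)
        for _ in range(n_reads):
            seq = base_seq
            n_err = rng.binomial(length, seq_error_rate)
            if n_err > 0:
                arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                pos = rng.choice(length, size=n_err, replace=False)
                for p in pos:
                    cur = chr(arr[p])
                    alt = _BASES[int(rng.integers(4))]
                    while alt == cur:
                        alt = _BASES[int(rng.integers(4))]
                    arr[p] = ord(alt)
                seq = arr.tobytes().decode()
            passes = (
                None if passes_lambda is None
                else 1 + int(rng.poisson(passes_lambda))
            )
            reads.append(
                ReadRecord(
                    id=f"r{population.round}_{read_idx}",
                    sequence=seq,
                    round=population.round,
                    passes=passes,
                    class_label=mol.class_label,
                )
            )
            read_idx += 1
    return reads
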