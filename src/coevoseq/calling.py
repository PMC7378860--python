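"""Frequency tables, dominant-mutation identification, genotype projection.

The consensus-level analysis works in three steps. Per-read mutation calls
are aggregated into a per-(round, class) frequency table; mutations whose
frequency strictly exceeds a dominance threshold (default 10%) in at least
one sequenced round of one class form the *dominant* set; each read is then
projected onto its presence/absence vector over the dominant mutations,
identical vectors are pooled into genotypes, and the most frequent genotypes
per round and class are retained. Restricting genotypes to dominant sites
suppresses residual sequencing error and low-frequency quasispecies
variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from typing import Sequence
from sklearn.base import BaseEstimator

from .align import (
    AlignmentScoring,
    ReadCall,
    align_to_reference,
    call_mutations_detailed,
    pair_from_alignment_rows,
)
from .io import ReadRecord
from .mutations import MutationEvent
from .references import HOST, ReferenceSet

MASKED = -1

FREQ_COLUMNS = ["round", "class", "site", "kind", "ref", "alt", "label",
                "count", "depth", "frequency"]


@dataclass(frozen=True)
class CalledRead:
    """One read reduced to its mutation events in host coordinates."""

    id: str
    round: int
    class_label: str
    events: frozenset[MutationEvent]
    ambiguous_sites: frozenset[int] = frozenset()


def call_reads(
    reads: Sequence[ReadRecord],
    references: ReferenceSet,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> list[CalledRead]:
    """Align each read to its class reference and call mutation events.

    Reads must carry ``round`` and ``class_label`` annotations; unclassified
    reads are skipped. Alignments are cached per distinct sequence, which
    collapses the cost of deep read sets dominated by a few genotypes.
    """
    cache: dict[tuple[str, str], ReadCall] = {}
    out: list[CalledRead] = []
    for read in reads:
        if read.class_label is None or read.class_label not in references.classes:
            continue
        if read.round is None:
            raise ValueError(f"read {read.id!r} lacks a round annotation")
        key = (read.class_label, read.sequence)
        if key not in cache:
            pair = align_to_reference(
                read.sequence, references.sequence(read.class_label), scoring
            )
            cache[key] = call_mutations_detailed(
                pair, references.window(read.class_label)
            )
        call = cache[key]
        out.append(
            CalledRead(read.id, read.round, read.class_label,
                       call.events, call.ambiguous_sites)
        )
    return out


def call_aligned_reads(
    records: Sequence[ReadRecord],
    references: ReferenceSet,
    reference_id: str | None = None,
) -> list[CalledRead]:
    """Call mutations from a pre-aligned FASTA (reference row included).

    The reference row is the record whose id equals ``reference_id``, or the
    first record otherwise; its gapped sequence must equal the original host
    reference once degapped. Every other row is compared column-wise against
    it, so an external multiple alignment (all reads aligned with the
    original host) can be consumed without re-aligning.
    """
    if not records:
        return []
    if reference_id is None:
        ref_rec, rest = records[0], records[1:]
    else:
        matches = [r for r in records if r.id == reference_id]
        if not matches:
            raise ValueError(f"reference row {reference_id!r} not found")
        ref_rec = matches[0]
        rest = [r for r in records if r.id != reference_id]
    if ref_rec.sequence.replace("-", "") != references.host:
        raise ValueError(
            "alignment reference row does not match the original host sequence"
        )
    out: list[CalledRead] = []
    for rec in rest:
        if rec.round is None:
            raise ValueError(f"read {rec.id!r} lacks a round annotation")
        pair = pair_from_alignment_rows(ref_rec.sequence, rec.sequence)
        call = call_mutations_detailed(pair, window=None)
        label = rec.class_label or HOST
        window = references.window(label) if label in references.classes else None
        if window is not None:
            # a parasite aligned against the full host shows its class
            # deletion as a long gap run; drop those per-base events
            events = frozenset(
                ev for ev in call.events if not window.contains(ev.site)
            )
        else:
            events = call.events
        out.append(CalledRead(rec.id, rec.round, label, events,
                              call.ambiguous_sites))
    return out


def build_frequency_table(called_reads: Sequence[CalledRead]) -> pd.DataFrame:
    """Per-(round, class) frequency of every observed mutation event.

    Depth is the number of retained reads of that class in that round (every
    read is assumed to cover the full reference), and frequency is
    count/depth. Groups with zero reads simply do not appear.
    """
    depth: dict[tuple[int, str], int] = {}
    counts: dict[tuple[int, str, MutationEvent], int] = {}
    for cr in called_reads:
        key = (cr.round, cr.class_label)
        depth[key] = depth.get(key, 0) + 1
        for ev in cr.events:
            ckey = (cr.round, cr.class_label, ev)
            counts[ckey] = counts.get(ckey, 0) + 1
    rows = []
    for (rnd, label, ev), c in counts.items():
        d = depth[(rnd, label)]
        rows.append(
            {
                "round": rnd,
                "class": label,
                "site": ev.site,
                "kind": ev.kind,
                "ref": ev.ref,
                "alt": ev.alt,
                "label": ev.label,
                "count": c,
                "depth": d,
                "frequency": c / d,
            }
        )
    table = pd.DataFrame(rows, columns=FREQ_COLUMNS)
    return table.sort_values(["round", "class", "site", "label"],
                             ignore_index=True)


def events_from_table(table: pd.DataFrame) -> list[MutationEvent]:
    """Distinct :class:`MutationEvent` objects present in a frequency table."""
    seen = {}
    for row in table.itertuples():
        ev = MutationEvent(int(row.site), row.kind, row.ref, row.alt)
        seen[ev] = None
    return sorted(seen)


@dataclass
class DominantMutationSet:
    """Mutations exceeding the dominance threshold, with their witnesses."""

    events: list[MutationEvent]
    witnesses: pd.DataFrame  # the (round, class) rows that exceeded
    threshold: float

    @property
    def sites(self) -> list[int]:
        """Distinct mutated sites (several events can share one site)."""
        return sorted({ev.site for ev in self.events})

    def __len__(self) -> int:
        return len(self.events)


class DominantMutationCaller(BaseEstimator):
    """Identify mutations present in more than ``threshold`` of a population.

    A mutation is dominant if its frequency *strictly* exceeds the threshold
    in at least one (round, class) group of the frequency table. The default
    of 0.10 targets consensus-level changes while ignoring the mutational
    cloud maintained by error-prone replication.

    Attributes (after :meth:`fit`)
    ------------------------------
    dominant_set_ : DominantMutationSet
    events_ : list of MutationEvent
    sites_ : list of int
        Distinct sites carrying a dominant mutation.
    n_events_, n_sites_ : int
    """

    def __init__(self, threshold: float = 0.10):
        self.threshold = threshold

    def fit(self, table: pd.DataFrame, y=None) -> "DominantMutationCaller":
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")
        missing = set(FREQ_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"frequency table lacks columns {sorted(missing)}")
        hits = table[table["frequency"] > self.threshold]
        events = sorted(
            {
                MutationEvent(int(r.site), r.kind, r.ref, r.alt)
                for r in hits.itertuples()
            }
        )
        self.dominant_set_ = DominantMutationSet(
            events=events,
            witnesses=hits.reset_index(drop=True),
            threshold=self.threshold,
        )
        self.events_ = events
        self.sites_ = self.dominant_set_.sites
        self.n_events_ = len(events)
        self.n_sites_ = len(self.sites_)
        return self


def identify_dominant(
    table: pd.DataFrame, threshold: float = 0.10
) -> DominantMutationSet:
    """Functional wrapper over :class:`DominantMutationCaller`."""
    return DominantMutationCaller(threshold=threshold).fit(table).dominant_set_


@dataclass(frozen=True)
class Genotype:
    """Presence vector over the dominant mutations, pooled over reads.

    ``vector`` holds 0 (absent), 1 (present) or -1 (masked: the site lies
    inside this class's deletion window and carries no information).
    """

    vector: tuple[int, ...]
    class_label: str
    round: int
    frequency: float
    rank: int
    count: int = 0

    @property
    def vector_string(self) -> str:
        return "".join("-" if v == MASKED else str(v) for v in self.vector)


def _mask_for(events: Sequence[MutationEvent], class_label: str,
              references: ReferenceSet) -> np.ndarray:
    return np.array(
        [not references.retained(class_label, ev.site) for ev in events]
    )


class GenotypeProjector(BaseEstimator):
    """Project reads onto genotypes over the dominant mutation set.

    Each read becomes a presence vector over the dominant events (masked at
    sites inside its class's deletion window); identical vectors within a
    (round, class) group are pooled, frequencies are normalised within the
    group, and only the ``top_n`` most frequent genotypes are kept (rank
    ties broken by lexicographic vector order). Reads with an ambiguous base
    at an unmasked dominant site are dropped so vectors stay total.

    Attributes (after :meth:`fit`)
    ------------------------------
    genotypes_ : list of Genotype
    n_dropped_ambiguous_ : int
    """

    def __init__(self, dominant_set: DominantMutationSet | None = None,
                 references: ReferenceSet | None = None, top_n: int = 90):
        self.dominant_set = dominant_set
        self.references = references
        self.top_n = top_n

    def fit(self, called_reads: Sequence[CalledRead], y=None) -> "GenotypeProjector":
        if self.references is None:
            raise ValueError("references are required")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        events: list[MutationEvent] = (
            [] if self.dominant_set is None else list(self.dominant_set.events)
        )
        event_index = {ev: i for i, ev in enumerate(events)}
        dominant_sites = {ev.site for ev in events}
        masks = {
            label: _mask_for(events, label, self.references)
            for label in self.references.classes
        }
        pooled: dict[tuple[int, str, tuple[int, ...]], int] = {}
        group_sizes: dict[tuple[int, str], int] = {}
        dropped = 0
        for cr in called_reads:
            mask = masks[cr.class_label]
            unmasked_sites = {
                ev.site for i, ev in enumerate(events) if not mask[i]
            }
            if cr.ambiguous_sites & unmasked_sites:
                dropped += 1
                continue
            vec = [MASKED if mask[i] else 0 for i in range(len(events))]
            for ev in cr.events:
                i = event_index.get(ev)
                if i is not None and not mask[i]:
                    vec[i] = 1
            key = (cr.round, cr.class_label, tuple(vec))
            pooled[key] = pooled.get(key, 0) + 1
            gkey = (cr.round, cr.class_label)
            group_sizes[gkey] = group_sizes.get(gkey, 0) + 1
        genotypes: list[Genotype] = []
        for (rnd, label) in sorted(group_sizes):
            total = group_sizes[(rnd, label)]
            group = [
                (vec, c) for (r, l, vec), c in pooled.items()
                if r == rnd and l == label
            ]
            group.sort(key=lambda vc: (-vc[1], vc[0]))
            for rank, (vec, c) in enumerate(group[: self.top_n], start=1):
                genotypes.append(
                    Genotype(vec, label, rnd, c / total, rank, count=c)
                )
        self.genotypes_ = genotypes
        self.n_dropped_ambiguous_ = dropped
        self.event_list_ = events
        return self

    def fit_transform(self, called_reads: Sequence[CalledRead], y=None
                      ) -> list[Genotype]:
        return self.fit(called_reads).genotypes_


def project_genotypes(
    called_reads: Sequence[CalledRead],
    dominant_set: DominantMutationSet | None,
    references: ReferenceSet,
    top_n: int = 90,
) -> list[Genotype]:
    """Functional wrapper over :class:`GenotypeProjector`."""
    return GenotypeProjector(dominant_set, references, top_n).fit_transform(
        called_reads
    )


def genotypes_to_frame(genotypes: Sequence[Genotype]) -> pd.DataFrame:
    """Tabular view of genotypes (vector as a compact {0,1,-} string)."""
    return pd.DataFrame(
        [
            {
                "round": g.round,
                "class": g.class_label,
                "rank": g.rank,
                "frequency": g.frequency,
                "count": g.count,
                "vector": g.vector_string,
            }
            for g in genotypes
        ],
        columns=["round", "class", "rank", "frequency", "count", "vector"],
    )
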