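"""Lineage-level analysis: parasite-unique mutations, persistence, origins.

Three questions about host–parasite lineage structure are answered from the
frequency table and the projected genotypes. Which dominant mutations are
*unique* to a parasite class — never reaching dominance in the host within
the region the parasite retains — indicating an independently evolving
parasite lineage? How long does each dominant mutation persist across the
sequenced rounds? And which parasite genotypes perfectly match a host
genotype of the same or an earlier round once the large deletion is
ignored, marking candidate parasite-generation (deletion) events?
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .calling import DominantMutationSet, Genotype
from .mutations import MutationEvent
from .references import HOST, ReferenceSet
from .space import genotype_distance


@dataclass(frozen=True)
class UniqueMutation:
    event: MutationEvent
    first_round: int
    last_round: int


@dataclass
class UniqueMutationReport:
    """Dominant mutations specific to one parasite class."""

    class_label: str
    mutations: list[UniqueMutation]
    mode: str = "threshold"

    def __len__(self) -> int:
        return len(self.mutations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "class": self.class_label,
                    "site": m.event.site,
                    "kind": m.event.kind,
                    "label": m.event.label,
                    "first_round": m.first_round,
                    "last_round": m.last_round,
                }
                for m in self.mutations
            ],
            columns=["class", "site", "kind", "label", "first_round",
                     "last_round"],
        )


def _event_rows(table: pd.DataFrame, ev: MutationEvent,
                class_label: str) -> pd.DataFrame:
    return table[
        (table["class"] == class_label)
        & (table["site"] == ev.site)
        & (table["kind"] == ev.kind)
        & (table["ref"] == ev.ref)
        & (table["alt"] == ev.alt)
    ]


def find_unique_mutations(
    table: pd.DataFrame,
    dominant_set: DominantMutationSet,
    parasite_class: str,
    references: ReferenceSet,
    host_class: str = HOST,
    mode: str = "threshold",
) -> UniqueMutationReport:
    """Parasite-class dominant mutations never dominant in the host.

    Only sites in the parasite's retained region are considered — inside
    its deletion window there is no corresponding parasite sequence. In the
    default ``"threshold"`` mode a mutation is unique if its host frequency
    never exceeds the dominance threshold in any sequenced round (sequencing
    error makes literal absence unattainable in real data); ``"absent"``
    mode demands zero host reads carrying it.
    """
    for label in (parasite_class, host_class):
        if label not in set(table["class"]) | set(references.classes):
            raise ValueError(f"unknown class label {label!r}")
    if mode not in ("threshold", "absent"):
        raise ValueError(f"mode must be 'threshold' or 'absent', got {mode!r}")
    out: list[UniqueMutation] = []
    threshold = dominant_set.threshold
    for ev in dominant_set.events:
        if not references.retained(parasite_class, ev.site):
            continue
        para = _event_rows(table, ev, parasite_class)
        dominant_rounds = para.loc[para["frequency"] > threshold, "round"]
        if dominant_rounds.empty:
            continue  # not a dominant mutation of this parasite class
        host = _event_rows(table, ev, host_class)
        if mode == "threshold":
            shared = (host["frequency"] > threshold).any()
        else:
            shared = (host["count"] > 0).any()
        if not shared:
            out.append(
                UniqueMutation(ev, int(dominant_rounds.min()),
                               int(dominant_rounds.max()))
            )
    return UniqueMutationReport(parasite_class, out, mode)


@dataclass
class PersistenceTrack:
    """Rounds in which one mutation stayed above a frequency threshold."""

    event: MutationEvent
    class_label: str
    rounds_above: list[int]
    gaps: list[int] = field(default_factory=list)

    @property
    def first_round(self) -> int | None:
        return self.rounds_above[0] if self.rounds_above else None

    @property
    def last_round(self) -> int | None:
        return self.rounds_above[-1] if self.rounds_above else None


def track_persistence(
    table: pd.DataFrame,
    mutation: MutationEvent,
    threshold: float,
    class_label: str = HOST,
) -> PersistenceTrack:
    """Chronology of one mutation's above-threshold presence in one class.

    ``gaps`` lists sequenced rounds between the first and last appearance
    in which the mutation dropped back below the threshold — the
    appear/disappear pattern typical of arms-race dynamics.
    """
    known = {
        (int(r.site), r.kind, r.ref, r.alt) for r in table.itertuples()
    }
    if (mutation.site, mutation.kind, mutation.ref, mutation.alt) not in known:
        raise ValueError(f"mutation {mutation.label} not present in the table")
    rows = _event_rows(table, mutation, class_label)
    above = sorted(int(r) for r in rows.loc[rows["frequency"] > threshold,
                                            "round"])
    sequenced = sorted(int(r) for r in table.loc[table["class"] == class_label,
                                                 "round"].unique())
    gaps: list[int] = []
    if above:
        inside = [r for r in sequenced if above[0] < r < above[-1]]
        gaps = [r for r in inside if r not in set(above)]
    return PersistenceTrack(mutation, class_label, above, gaps)


@dataclass(frozen=True)
class OriginCandidate:
    host_index: int
    host_round: int
    round_gap: int  # parasite round minus host round (>= 0)


@dataclass
class OriginMatch:
    """Host genotypes a parasite genotype perfectly matches (deletion aside)."""

    parasite_index: int
    parasite_round: int
    candidates: list[OriginCandidate]


def match_parasite_origin(
    parasite_genotypes: Sequence[Genotype],
    host_genotypes: Sequence[Genotype],
) -> list[OriginMatch]:
    """Find candidate generation events: masked-distance-0 host matches.

    For every parasite genotype, host genotypes of the same or an earlier
    round at masked Hamming distance 0 are listed, nearest round first. A
    perfect match says the parasite could have arisen from that host
    lineage by the class deletion alone.
    """
    out: list[OriginMatch] = []
    for p_idx, pg in enumerate(parasite_genotypes):
        candidates: list[OriginCandidate] = []
        for h_idx, hg in enumerate(host_genotypes):
            if hg.round > pg.round:
                continue
            if genotype_distance(pg, hg) == 0:
                candidates.append(
                    OriginCandidate(h_idx, hg.round, pg.round - hg.round)
                )
        candidates.sort(key=lambda c: (c.round_gap, c.host_index))
        out.append(OriginMatch(p_idx, pg.round, candidates))
    return out


def summary_report(
    unique_reports: Sequence[UniqueMutationReport],
    tracks: Sequence[PersistenceTrack] = (),
    origins: Sequence[OriginMatch] = (),
) -> str:
    """Human-readable headline counts for the lineage analysis."""
    lines = ["Lineage analysis summary", "========================"]
    for rep in unique_reports:
        lines.append(
            f"{rep.class_label}: {len(rep)} unique mutation(s) "
            f"[{rep.mode} mode]"
        )
        for m in rep.mutations:
            lines.append(
                f"  {m.event.label}: rounds {m.first_round}-{m.last_round}"
            )
    if tracks:
        lines.append("Persistence:")
        for t in tracks:
            if t.rounds_above:
                gap = f", gaps at {t.gaps}" if t.gaps else ""
                lines.append(
                    f"  {t.event.label} ({t.class_label}): rounds "
                    f"{t.first_round}-{t.last_round}{gap}"
                )
            else:
                lines.append(
                    f"  {t.event.label} ({t.class_label}): never above threshold"
                )
    if origins:
        n_with = sum(1 for o in origins if o.candidates)
        lines.append(
            f"Origin events: {n_with}/{len(origins)} parasite genotypes match "
            "a host genotype (deletion ignored)"
        )
    return "\n".join(lines)
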