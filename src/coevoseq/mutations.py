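"""Mutation events in original-host reference coordinates.

All coordinates in this package are 1-based positions on the original host
reference. Parasite classes are host sequences with one large internal
deletion excised; mutations inside a class's deletion window are undefined
(masked) for that class. Sequences are handled internally in the DNA
alphabet (``U`` normalised to ``T`` at parse time); mutation labels are
rendered in the RNA alphabet, matching the ``C1986U`` naming convention used
for Q-beta replicase amplicons.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Iterable

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"

_KINDS = (SUBSTITUTION, INSERTION, DELETION)


def _rna(s: str) -> str:
    return s.replace("T", "U").replace("t", "u")


@dataclass(frozen=True, order=True)
class MutationEvent:
    """One substitution, insertion or deletion on the host reference.

    Parameters
    ----------
    site : int
        1-based position on the original host reference. For insertions the
        inserted string is anchored *after* ``site``.
    kind : str
        One of ``"substitution"``, ``"insertion"``, ``"deletion"``.
    ref : str
        Reference base at ``site`` (empty for insertions).
    alt : str
        Alternate base (substitution), inserted string (insertion), or empty
        (deletion).
    """

    site: int
    kind: str
    ref: str = ""
    alt: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.site < 1:
            raise ValueError(f"site must be >= 1, got {self.site}")
        if self.kind == SUBSTITUTION and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("substitution needs single ref and alt bases")
        if self.kind == INSERTION and not self.alt:
            raise ValueError("insertion needs a non-empty inserted string")
        if self.kind == DELETION and len(self.ref) != 1:
            raise ValueError("deletion events are single-base; decompose runs")

    @property
    def label(self) -> str:
        """Canonical name, e.g. ``C1986U``, ``ins1986A``, ``del1986C``."""
        if self.kind == SUBSTITUTION:
            return f"{_rna(self.ref)}{self.site}{_rna(self.alt)}"
        if self.kind == INSERTION:
            return f"ins{self.site}{_rna(self.alt)}"
        return f"del{self.site}{_rna(self.ref)}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class DeletionWindow:
    """A 1-based inclusive interval ``[start, end]`` on the host reference."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid window ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, site: int) -> bool:
        return self.start <= site <= self.end


def apply_mutations(
    reference: str,
    events: Iterable[MutationEvent],
    window: DeletionWindow | None = None,
) -> str:
    """Materialise a sequence from the host reference plus mutation events.

    Substitutions are applied first, then the sequence is rebuilt base by
    base, skipping single-base deletion sites and (for parasite classes) the
    large deletion ``window``, and appending insertion strings after their
    anchor site. Events whose sites fall inside ``window`` are ignored: they
    are undefined for the deleted class.
    """
    events = list(events)
    n = len(reference)
    subs: dict[int, str] = {}
    dels: set[int] = set()
    ins: dict[int, str] = {}
    for ev in events:
        if ev.site > n:
            raise ValueError(f"event {ev.label} beyond reference length {n}")
        if window is not None and window.contains(ev.site):
            continue
        if ev.kind == SUBSTITUTION:
            if reference[ev.site - 1] != ev.ref:
                raise ValueError(
                    f"event {ev.label}: reference has {reference[ev.site - 1]}"
                )
            subs[ev.site] = ev.alt
        elif ev.kind == DELETION:
            dels.add(ev.site)
        else:
            ins[ev.site] = ins.get(ev.site, "") + ev.alt
    out: list[str] = []
    for pos in range(1, n + 1):
        if window is not None and window.contains(pos):
            continue
        if pos not in dels:
            out.append(subs.get(pos, reference[pos - 1]))
        if pos in ins:
            out.append(ins[pos])
    return "".join(out)
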