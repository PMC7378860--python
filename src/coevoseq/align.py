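"""Global pairwise alignment of reads to class references and mutation calling.

Each read is aligned globally (Needleman–Wunsch with affine gaps) to the
reference of its RNA class; differences are then expressed as
:class:`~coevoseq.mutations.MutationEvent` objects in 1-based coordinates on
the *original host* reference. For parasite classes the read is aligned to
the class reference (host with the large deletion excised) and positions are
lifted across the deletion window, so the window itself never produces
events.

Scoring defaults: match +1, mismatch −2, and a gap of length k scores
−4 − (k − 1), i.e. gap open −4 covering the first gapped base and −1 per
additional base. ``N`` is scored neutrally (0 against every base) and never
produces a substitution event; instead the site is reported as ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .mutations import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    DeletionWindow,
    MutationEvent,
)

#: Sequences beyond this length must be provided pre-aligned.
MAX_ALIGN_LENGTH = 20000


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class AlignedPair:
    """A gapped reference/read pair from one global alignment."""

    ref_aligned: str
    read_aligned: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.ref_aligned) != len(self.read_aligned):
            raise ValueError("aligned strings must have equal length")


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "N" in (a, b):
                matrix[a, b] = 0.0
            else:
                matrix[a, b] = scoring.match if a == b else scoring.mismatch
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_to_reference(
    read: str,
    reference: str,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> AlignedPair:
    """Optimal global affine-gap alignment of ``read`` against ``reference``.

    Returns the engine's first optimal alignment, which is deterministic for
    fixed inputs. Raises for empty sequences and for sequences longer than
    :data:`MAX_ALIGN_LENGTH` (supply pre-aligned input instead).
    """
    if not read or not reference:
        raise ValueError("read and reference must be non-empty")
    if max(len(read), len(reference)) > MAX_ALIGN_LENGTH:
        raise ValueError(
            f"sequence longer than {MAX_ALIGN_LENGTH} nt; provide pre-aligned "
            "input (aligned-fasta) instead"
        )
    aligner = _make_aligner(scoring)
    alignment = next(iter(aligner.align(reference, read)))
    return AlignedPair(
        ref_aligned=str(alignment[0]),
        read_aligned=str(alignment[1]),
        score=float(alignment.score),
    )


def _lift(pos: int, window: DeletionWindow | None) -> int:
    """Class-reference coordinate -> original-host coordinate."""
    if window is None or pos < window.start:
        return pos
    return pos + len(window)


@dataclass(frozen=True)
class ReadCall:
    """Mutation events called from one aligned read."""

    events: frozenset[MutationEvent]
    ambiguous_sites: frozenset[int] = field(default_factory=frozenset)


def call_mutations(
    pair: AlignedPair,
    window: DeletionWindow | None = None,
) -> set[MutationEvent]:
    """Call substitution/insertion/deletion events from an aligned pair.

    One substitution per mismatch column; one deletion event per deleted
    reference base (multi-base gaps decompose into per-base events); one
    insertion event per reference-gap run, anchored after the preceding
    reference position. ``window`` is the class's deletion window for lifting
    parasite coordinates to host coordinates.
    """
    return call_mutations_detailed(pair, window).events  # type: ignore[return-value]


def call_mutations_detailed(
    pair: AlignedPair,
    window: DeletionWindow | None = None,
) -> ReadCall:
    """Like :func:`call_mutations` but also reports ambiguous (N) sites."""
    events: set[MutationEvent] = set()
    ambiguous: set[int] = set()
    ref_pos = 0  # 1-based position of the last consumed reference base
    pending_insertion: list[str] = []

    def flush_insertion() -> None:
        if pending_insertion:
            anchor = _lift(max(ref_pos, 1), window)
            events.add(
                MutationEvent(anchor, INSERTION, "", "".join(pending_insertion))
            )
            pending_insertion.clear()

    for ref_c, read_c in zip(pair.ref_aligned, pair.read_aligned):
        if ref_c == "-" and read_c == "-":
            continue
        if ref_c == "-":
            pending_insertion.append(read_c)
            continue
        flush_insertion()
        ref_pos += 1
        host_pos = _lift(ref_pos, window)
        if read_c == "-":
            events.add(MutationEvent(host_pos, DELETION, ref_c, ""))
        elif read_c != ref_c:
            if read_c == "N" or ref_c == "N":
                ambiguous.add(host_pos)
            else:
                events.add(MutationEvent(host_pos, SUBSTITUTION, ref_c, read_c))
    flush_insertion()
    return ReadCall(frozenset(events), frozenset(ambiguous))


def pair_from_alignment_rows(ref_row: str, read_row: str) -> AlignedPair:
    """Build an :class:`AlignedPair` from two rows of a multiple alignment.

    Columns gapped in both rows are dropped, which makes rows of a larger
    pre-computed alignment (e.g. a MAFFT alignment of all reads against the
    original host) usable pairwise.
    """
    ref_out, read_out = [], []
    for a, b in zip(ref_row, read_row):
        if a == "-" and b == "-":
            continue
        ref_out.append(a)
        read_out.append(b)
    return AlignedPair("".join(ref_out), "".join(read_out))
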