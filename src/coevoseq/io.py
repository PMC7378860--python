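"""Sequence IO: read/write FASTA and FASTQ, CCS pass filtering, length classes.

Reads are annotated through ``key=value`` fields in the description line
(``round=13 class=host mol=42 passes=7``), the convention the simulator
writes and the parsers here recover. RNA ``U`` is normalised to ``T`` at
parse time so RNA reads and cDNA sequencing can be mixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .references import HOST, PARASITE_ALPHA, PARASITE_BETA, PARASITE_GAMMA

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"

_ALPHABET = set("ACGTN")
_GAPPED_ALPHABET = _ALPHABET | {"-"}


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with its round/class/pass annotations."""

    id: str
    sequence: str
    round: int | None = None
    passes: int | None = None
    class_label: str | None = None

    def __len__(self) -> int:
        return len(self.sequence.replace("-", ""))


@dataclass(frozen=True)
class LengthBins:
    """Ordered non-overlapping length intervals defining the RNA classes."""

    bins: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        ordered = sorted(self.bins, key=lambda b: b[1])
        for (l1, a1, b1), (l2, a2, b2) in zip(ordered, ordered[1:]):
            if b1 >= a2:
                raise ValueError(f"bins {l1} and {l2} overlap")
        for label, lo, hi in self.bins:
            if lo > hi or lo < 1:
                raise ValueError(f"bad bin {label}: [{lo}, {hi}]")

    def classify(self, length: int) -> str:
        for label, lo, hi in self.bins:
            if lo <= length <= hi:
                return label
        return UNCLASSIFIED


#: Wide brackets around the four canonical class sizes (~2040, ~220, ~1070,
#: ~510 nt); overridable in the pipeline config.
DEFAULT_LENGTH_BINS = LengthBins(
    (
        (PARASITE_ALPHA, 150, 350),
        (PARASITE_GAMMA, 400, 700),
        (PARASITE_BETA, 900, 1300),
        (HOST, 1800, 2300),
    )
)


def _normalise(seq: str, record_id: str, allow_gaps: bool) -> str:
    s = seq.upper().replace("U", "T")
    alphabet = _GAPPED_ALPHABET if allow_gaps else _ALPHABET
    bad = set(s) - alphabet
    if bad:
        raise ValueError(
            f"record {record_id!r}: unknown alphabet symbol(s) {sorted(bad)}"
        )
    if not s:
        raise ValueError(f"record {record_id!r}: empty sequence")
    return s


def _parse_metadata(description: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for token in description.split():
        if "=" in token:
            key, _, value = token.partition("=")
            out[key] = value
    return out


def read_sequences(path: str | Path, format: str = "fasta") -> list[ReadRecord]:
    """Parse FASTA/FASTQ/aligned-FASTA into :class:`ReadRecord` objects.

    ``aligned-fasta`` keeps gap characters so columns stay addressable;
    all records in an aligned file must share one padded length.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt not in {"fasta", "fastq", "aligned-fasta"}:
        raise ValueError(f"unsupported format {format!r}")
    aligned = fmt == "aligned-fasta"
    bio_fmt = "fasta" if aligned else fmt
    records: list[ReadRecord] = []
    for rec in SeqIO.parse(str(path), bio_fmt):
        meta = _parse_metadata(rec.description)
        records.append(
            ReadRecord(
                id=rec.id,
                sequence=_normalise(str(rec.seq), rec.id, allow_gaps=aligned),
                round=int(meta["round"]) if "round" in meta else None,
                passes=int(meta["passes"]) if "passes" in meta else None,
                class_label=meta.get("class"),
            )
        )
    if aligned and records:
        lengths = {len(r.sequence) for r in records}
        if len(lengths) > 1:
            raise ValueError(
                f"aligned-fasta {path} has unequal padded lengths {sorted(lengths)}"
            )
    return records


def write_sequences(records: Iterable[ReadRecord], path: str | Path) -> None:
    """Write records as FASTA with ``key=value`` annotation fields."""
    out = []
    for r in records:
        fields = []
        if r.round is not None:
            fields.append(f"round={r.round}")
        if r.class_label is not None:
            fields.append(f"class={r.class_label}")
        if r.passes is not None:
            fields.append(f"passes={r.passes}")
        out.append(
            SeqRecord(Seq(r.sequence), id=r.id, description=" ".join(fields))
        )
    SeqIO.write(out, str(path), "fasta")


DEFAULT_MIN_PASSES = {HOST: 5, "parasite": 10}


def _pass_threshold(class_label: str | None, thresholds: dict[str, int]) -> int:
    if class_label in thresholds:
        return thresholds[class_label]
    if class_label is not None and class_label.startswith("parasite"):
        return thresholds.get("parasite", 0)
    return thresholds.get("default", 0)


def filter_by_passes(
    reads: Sequence[ReadRecord],
    min_passes_by_class: dict[str, int] | None = None,
) -> list[ReadRecord]:
    """Keep reads whose CCS pass count meets the class threshold.

    Circular-consensus reads built from more passes over the molecule have
    fewer residual errors; the defaults require at least 5 passes for host
    reads and 10 for parasites. Reads without a pass count are kept, with a
    logged warning.
    """
    thresholds = dict(DEFAULT_MIN_PASSES if min_passes_by_class is None
                      else min_passes_by_class)
    for label, t in thresholds.items():
        if t < 0:
            raise ValueError(f"negative pass threshold for {label}: {t}")
    kept: list[ReadRecord] = []
    n_missing = 0
    for r in reads:
        if r.passes is None:
            n_missing += 1
            kept.append(r)
        elif r.passes >= _pass_threshold(r.class_label, thresholds):
            kept.append(r)
    if n_missing:
        logger.warning(
            "%d read(s) lack a pass count and were kept unfiltered", n_missing
        )
    return kept


def classify_by_length(
    read: ReadRecord, bins: LengthBins = DEFAULT_LENGTH_BINS
) -> str:
    """Class label for a read's (ungapped) length, or ``"unclassified"``."""
    return bins.classify(len(read))


def classify_reads(
    reads: Sequence[ReadRecord], bins: LengthBins = DEFAULT_LENGTH_BINS
) -> list[ReadRecord]:
    """Attach length-based class labels to every read."""
    return [replace(r, class_label=classify_by_length(r, bins)) for r in reads]
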