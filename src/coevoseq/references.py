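"""Reference sequences for the host and its deletion-derived parasite classes.

The host is a ~2040 nt self-replicating RNA encoding the replicase beta
subunit; each parasite class is the host with one large internal deletion
excised, keeping both termini (the replicase recognition ends) intact.
Default windows reproduce the canonical class sizes: parasite-alpha ~220 nt
(entire replicase gene deleted), parasite-beta ~1070 nt (3' half of the
gene), parasite-gamma ~510 nt (3' half plus part of the 5' region).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mutations import DeletionWindow

HOST = "host"
PARASITE_ALPHA = "parasite-alpha"
PARASITE_BETA = "parasite-beta"
PARASITE_GAMMA = "parasite-gamma"

DEFAULT_HOST_LENGTH = 2040

#: Default deletion windows (1-based inclusive host coordinates). Windows of
#: different classes may nest: a molecule carries exactly one of them, and
#: class identity is fixed by the recorded deletion event and by the distinct
#: product lengths (220 / 1070 / 510 nt).
DEFAULT_DELETION_WINDOWS: dict[str, DeletionWindow] = {
    PARASITE_ALPHA: DeletionWindow(101, 1920),   # product 220 nt
    PARASITE_BETA: DeletionWindow(971, 1940),    # product 1070 nt
    PARASITE_GAMMA: DeletionWindow(256, 1785),   # product 510 nt
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReferenceSet:
    """Host reference plus one derived reference per parasite class."""

    host: str
    windows: dict[str, DeletionWindow] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_windows(self.windows, len(self.host))

    @property
    def host_length(self) -> int:
        return len(self.host)

    @property
    def classes(self) -> list[str]:
        return [HOST, *self.windows]

    def sequence(self, class_label: str) -> str:
        """Reference sequence for a class (window excised for parasites)."""
        if class_label == HOST:
            return self.host
        w = self.window(class_label)
        return self.host[: w.start - 1] + self.host[w.end :]

    def window(self, class_label: str) -> DeletionWindow | None:
        if class_label == HOST:
            return None
        try:
            return self.windows[class_label]
        except KeyError:
            raise KeyError(f"unknown parasite class {class_label!r}") from None

    def retained(self, class_label: str, site: int) -> bool:
        """Whether a host-coordinate site survives in a class's reference."""
        w = self.window(class_label)
        return w is None or not w.contains(site)


def validate_windows(windows: dict[str, DeletionWindow], host_length: int) -> None:
    """Check that every window lies strictly inside the host reference.

    Both termini must remain intact (start >= 2, end <= length - 1), and no
    two classes may share an identical window, which would make class
    identity ambiguous. Nested or overlapping windows of *different* classes
    are allowed: product lengths, not intervals, separate the classes.
    """
    seen: dict[tuple[int, int], str] = {}
    lengths: dict[int, str] = {}
    for label, w in windows.items():
        if w.start < 2 or w.end > host_length - 1:
            raise ValueError(
                f"window {label} ({w.start}, {w.end}) must leave both termini "
                f"of the {host_length} nt host intact"
            )
        key = (w.start, w.end)
        if key in seen:
            raise ValueError(f"classes {seen[key]} and {label} share one window")
        seen[key] = label
        plen = host_length - len(w)
        if plen in lengths:
            raise ValueError(
                f"classes {lengths[plen]} and {label} both produce {plen} nt "
                "molecules; lengths must distinguish classes"
            )
        lengths[plen] = label


def generate_reference_set(
    host_length: int = DEFAULT_HOST_LENGTH,
    deletion_windows: dict[str, DeletionWindow] | None = None,
    seed: int | np.random.Generator | None = 0,
) -> ReferenceSet:
    """Generate a random host reference and its parasite-class derivatives.

    Parameters
    ----------
    host_length : int
        Length of the host reference in nt.
    deletion_windows : dict, optional
        Mapping class label -> :class:`DeletionWindow`. ``None`` uses the
        defaults when ``host_length`` matches the default host, otherwise an
        empty mapping (host only).
    seed : int, Generator or None
        Source of randomness for the host sequence.
    """
    if deletion_windows is None:
        deletion_windows = (
            dict(DEFAULT_DELETION_WINDOWS)
            if host_length == DEFAULT_HOST_LENGTH
            else {}
        )
    rng = np.random.default_rng(seed)
    host = "".join(rng.choice(_BASES, size=host_length))
    return ReferenceSet(host=host, windows=dict(deletion_windows))


def scaled_deletion_windows(host_length: int) -> dict[str, DeletionWindow]:
    """Deletion windows proportional to the defaults for a shorter host.

    Useful for simulation studies at reduced sequence length: window
    boundaries are scaled so the parasite/host length ratios match the
    canonical 220/1070/510 over 2040.
    """
    f = host_length / DEFAULT_HOST_LENGTH
    out: dict[str, DeletionWindow] = {}
    for label, w in DEFAULT_DELETION_WINDOWS.items():
        start = max(2, int(round(w.start * f)))
        end = min(host_length - 1, int(round(w.end * f)))
        out[label] = DeletionWindow(start, end)
    validate_windows(out, host_length)
    return out
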