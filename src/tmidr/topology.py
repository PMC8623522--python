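"""Per-residue membrane topology and the four-compartment partition.

A transmembrane protein is annotated per residue as inside (cytosolic,
``I``), outside (extracellular, ``O``), membrane (``M``) or re-entrant loop
(``L``). Non-membrane residues are further partitioned by which side they
are on and how far (in sequence positions) they are from the nearest
membrane residue: within ``PROXIMAL_DISTANCE`` (= 15) residues they are
*proximal*, beyond it *distant*. Re-entrant loops sit in the bilayer and
are treated as membrane for all downstream purposes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

#: Residues at most this many sequence positions from a membrane residue are
#: "proximal"; strictly farther ones are "distant".
PROXIMAL_DISTANCE = 15

TOPOLOGY_ALPHABET = "IOML"
_MEMBRANE_SYMBOLS = frozenset("ML")


class TopologyError(ValueError):
    """Invalid topology input (unknown symbol, length mismatch, no membrane)."""


class Category(IntEnum):
    """Compartment of a residue relative to the membrane."""

    EXTRA_DISTANT = 0
    EXTRA_PROXIMAL = 1
    INTRA_DISTANT = 2
    INTRA_PROXIMAL = 3
    MEMBRANE = 4


#: The four compartments that receive their own convolutional model.
NON_MEMBRANE_CATEGORIES = (
    Category.EXTRA_DISTANT,
    Category.EXTRA_PROXIMAL,
    Category.INTRA_DISTANT,
    Category.INTRA_PROXIMAL,
)


@dataclass(frozen=True)
class TopologyTrack:
    """Per-residue topology labels over the alphabet ``I/O/M/L``."""

    labels: str

    def __post_init__(self) -> None:
        bad = set(self.labels) - set(TOPOLOGY_ALPHABET)
        if bad:
            raise TopologyError(f"unknown topology symbol(s): {sorted(bad)}")
        if not any(c in _MEMBRANE_SYMBOLS for c in self.labels):
            raise TopologyError(
                "no membrane residue in topology; this tool handles "
                "transmembrane proteins only"
            )

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, key) -> "TopologyTrack | str":
        if isinstance(key, slice):
            return self.labels[key]
        return self.labels[key]

    @property
    def membrane_mask(self) -> np.ndarray:
        """Boolean array, True at membrane or re-entrant-loop residues."""
        arr = np.frombuffer(self.labels.encode(), dtype="S1")
        return (arr == b"M") | (arr == b"L")


def parse_topology(source, length: int | None = None) -> TopologyTrack:
    """Build a :class:`TopologyTrack` from a label string or a region list.

    Parameters
    ----------
    source
        Either a per-residue string over ``I/O/M/L``, or an iterable of
        ``(start, end, label)`` regions with 1-based closed coordinates.
        Regions may cover only the membrane segments; uncovered gaps are
        then assigned alternating sides starting with inside (``I``).
    length
        Required for region lists (total protein length); if given for a
        string it must match the string length.
    """
    if isinstance(source, str):
        if length is not None and length != len(source):
            raise TopologyError(
                f"topology length {len(source)} != sequence length {length}"
            )
        return TopologyTrack(source)

    if length is None:
        raise TopologyError("region-list topology requires the sequence length")
    labels = [None] * length
    for start, end, label in source:
        label = _normalise_region_label(label)
        if not (1 <= start <= end <= length):
            raise TopologyError(
                f"region {start}-{end} outside sequence of length {length}"
            )
        for i in range(start - 1, end):
            if labels[i] is not None:
                raise TopologyError(f"overlapping regions at position {i + 1}")
            labels[i] = label
    _fill_gaps_alternating(labels)
    return TopologyTrack("".join(labels))


def _normalise_region_label(label: str) -> str:
    label = label.strip().upper()
    aliases = {
        "TM": "M", "MEMBRANE": "M", "M": "M",
        "I": "I", "IN": "I", "INSIDE": "I",
        "O": "O", "OUT": "O", "OUTSIDE": "O",
        "L": "L", "REENTRANT": "L", "RE-ENTRANT": "L",
    }
    if label not in aliases:
        raise TopologyError(f"unknown region label {label!r}")
    return aliases[label]


def _fill_gaps_alternating(labels: list) -> None:
    """Assign I/O to unlabeled gaps, alternating sides across membrane runs."""
    side = "I"
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] is None:
            j = i
            while j < n and labels[j] is None:
                labels[j] = side
                j += 1
            i = j
        else:
            if labels[i] == "M":
                side = "O" if side == "I" else "I"
                while i < n and labels[i] == "M":
                    i += 1
            elif labels[i] in "IO":
                side = "O" if labels[i] == "I" else "I"
                i += 1
            else:
                i += 1


def membrane_distances(track: TopologyTrack) -> np.ndarray:
    """Distance of every residue to the nearest membrane residue (0 inside it).

    Two linear scans; distances are sequence-position counts.
    """
    n = len(track)
    mem = track.membrane_mask
    inf = n + 1
    dist = np.full(n, inf, dtype=np.int64)
    last = -inf
    for i in range(n):
        if mem[i]:
            last = i
        dist[i] = i - last
    last = 2 * inf
    for i in range(n - 1, -1, -1):
        if mem[i]:
            last = i
        dist[i] = min(dist[i], last - i)
    return dist


def membrane_distance(track: TopologyTrack, index: int) -> int:
    """Minimum sequence distance from ``index`` to any membrane residue."""
    if not 0 <= index < len(track):
        raise IndexError(f"index {index} out of range for track of length {len(track)}")
    return int(membrane_distances(track)[index])


def categorize(track: TopologyTrack) -> np.ndarray:
    """Assign each residue its :class:`Category`.

    Membrane and re-entrant residues map to ``MEMBRANE``; the rest split by
    side (inside/outside) and by distance: ``<= PROXIMAL_DISTANCE`` is
    proximal, strictly greater is distant.
    """
    dist = membrane_distances(track)
    out = np.empty(len(track), dtype=np.int64)
    for i, sym in enumerate(track.labels):
        if sym in _MEMBRANE_SYMBOLS:
            out[i] = Category.MEMBRANE
        elif sym == "O":
            out[i] = (
                Category.EXTRA_PROXIMAL
                if dist[i] <= PROXIMAL_DISTANCE
                else Category.EXTRA_DISTANT
            )
        else:
            out[i] = (
                Category.INTRA_PROXIMAL
                if dist[i] <= PROXIMAL_DISTANCE
                else Category.INTRA_DISTANT
            )
    return out


def category_onehot(categories: np.ndarray) -> np.ndarray:
    """(L, 4) one-hot of the four non-membrane compartments; membrane rows zero."""
    onehot = np.zeros((len(categories), 4))
    for j, cat in enumerate(NON_MEMBRANE_CATEGORIES):
        onehot[categories == cat, j] = 1.0
    return onehot
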