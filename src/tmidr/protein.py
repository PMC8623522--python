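"""Core annotated-protein container shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import TopologyTrack

#: Per-residue order/disorder label symbols.
DISORDERED, ORDERED, UNOBSERVED = "D", "O", "U"
LABEL_ALPHABET = frozenset("DOU")


def validate_labels(labels: str, length: int) -> str:
    bad = set(labels) - LABEL_ALPHABET
    if bad:
        raise ValueError(f"unknown label symbol(s): {sorted(bad)}")
    if len(labels) != length:
        raise ValueError(f"label length {len(labels)} != sequence length {length}")
    return labels


@dataclass
class AnnotatedProtein:
    """Sequence plus per-residue topology and (optionally) disorder labels."""

    id: str
    sequence: str
    topology: TopologyTrack
    labels: str | None = None
    rsa: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.topology) != len(self.sequence):
            raise ValueError(
                f"{self.id}: topology length {len(self.topology)} != "
                f"sequence length {len(self.sequence)}"
            )
        if self.labels is not None:
            validate_labels(self.labels, len(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)
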