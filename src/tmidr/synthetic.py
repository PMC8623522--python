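"""Synthetic transmembrane proteins with planted topology and disorder.

The generator emulates the architecture the predictor targets: alternating
inside/outside loops and tails separated by hydrophobic membrane segments,
with disorder planted per non-membrane segment (side-specific Bernoulli)
and carried by two signals the real feature channels would see — a
disorder-promoting residue composition (enriched P, E, S, Q, K, G versus
C, W, F, I, L, V, Y for ordered segments) and a higher surrogate solvent
accessibility. Labels equal the planted truth except for a configurable
noise rate. Everything is driven by one integer seed and reproduces
byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import AccessibilityTrack, pseudo_profile
from .protein import AnnotatedProtein
from .scales import AMINO_ACIDS
from .topology import TopologyTrack

_DISORDER_PROMOTING = "PESQKG"
_ORDER_PROMOTING = "CWFILVY"
_TM_PROMOTING = "ILVFAGWM"


def _weights(enriched: str, factor: float) -> np.ndarray:
    w = np.ones(20)
    for aa in enriched:
        w[AMINO_ACIDS.index(aa)] = factor
    return w / w.sum()


@dataclass
class SyntheticScenario:
    """Study conditions of the synthetic corpus (defaults are the standard
    scenario every test and example uses)."""

    n_proteins: int = 500
    tm_count_range: tuple = (1, 6)           # inclusive
    tm_length_range: tuple = (17, 25)        # inclusive
    loop_length_min: int = 5
    loop_length_mean: float = 30.0
    tail_length_min: int = 8
    tail_length_mean: float = 40.0
    p_disorder_inside: float = 0.45
    p_disorder_outside: float = 0.25
    disorder_enrichment: float = 5.0
    order_enrichment: float = 4.0
    label_noise: float = 0.02
    rsa_ordered_mean: float = 0.35
    rsa_disordered_mean: float = 0.65
    rsa_sd: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_disorder_inside, self.p_disorder_outside,
                  self.label_noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.loop_length_min < 1 or self.tail_length_min < 1:
            raise ValueError("segment lengths must be positive")

    @property
    def expected_disorder_rate(self) -> float:
        """Expected disordered fraction among non-membrane residues (sides
        are balanced by the alternating architecture)."""
        return 0.5 * (self.p_disorder_inside + self.p_disorder_outside)

    def disorder_weights(self) -> np.ndarray:
        return _weights(_DISORDER_PROMOTING, self.disorder_enrichment)

    def order_weights(self) -> np.ndarray:
        return _weights(_ORDER_PROMOTING, self.order_enrichment)

    def tm_weights(self) -> np.ndarray:
        return _weights(_TM_PROMOTING, 6.0)


def _sample_len(rng: np.random.Generator, minimum: int, mean: float) -> int:
    return int(minimum + rng.geometric(1.0 / (mean - minimum + 1)) - 1)


def _draw(rng: np.random.Generator, n: int, weights: np.ndarray) -> str:
    idx = rng.choice(20, size=n, p=weights)
    return "".join(AMINO_ACIDS[i] for i in idx)


def generate_protein(scenario: SyntheticScenario, rng: np.random.Generator,
                     pid: str = "synthetic") -> AnnotatedProtein:
    """One protein: tail - (TM - loop)* - TM - tail, sides alternating.

    Each non-membrane segment is disordered as a whole with the
    side-specific probability; disordered segments use the
    disorder-promoting composition, ordered ones the order-promoting
    composition, membrane segments the hydrophobic one. Membrane residues
    are labelled ordered (resolved in structures). Labels are then flipped
    at the configured noise rate; surrogate accessibility is sampled around
    a higher mean for (truly) disordered residues.
    """
    n_tm = int(rng.integers(scenario.tm_count_range[0],
                            scenario.tm_count_range[1] + 1))
    side = "I" if rng.random() < 0.5 else "O"
    seq_parts, topo_parts, lab_parts, truth = [], [], [], []

    def add_segment(kind: str, current_side: str) -> None:
        if kind == "tm":
            length = int(rng.integers(scenario.tm_length_range[0],
                                      scenario.tm_length_range[1] + 1))
            seq_parts.append(_draw(rng, length, scenario.tm_weights()))
            topo_parts.append("M" * length)
            lab_parts.append("O" * length)
            truth.extend([0] * length)
            return
        if kind == "tail":
            length = _sample_len(rng, scenario.tail_length_min,
                                 scenario.tail_length_mean)
        else:
            length = _sample_len(rng, scenario.loop_length_min,
                                 scenario.loop_length_mean)
        p_dis = (scenario.p_disorder_inside if current_side == "I"
                 else scenario.p_disorder_outside)
        disordered = rng.random() < p_dis
        weights = (scenario.disorder_weights() if disordered
                   else scenario.order_weights())
        seq_parts.append(_draw(rng, length, weights))
        topo_parts.append(current_side * length)
        lab_parts.append(("D" if disordered else "O") * length)
        truth.extend([1 if disordered else 0] * length)

    add_segment("tail", side)
    for k in range(n_tm):
        add_segment("tm", side)
        side = "O" if side == "I" else "I"
        add_segment("tail" if k == n_tm - 1 else "loop", side)

    sequence = "".join(seq_parts)
    labels = list("".join(lab_parts))
    truth_arr = np.array(truth, dtype=bool)
    flip = rng.random(len(labels)) < scenario.label_noise
    for i in np.where(flip)[0]:
        labels[i] = "O" if labels[i] == "D" else "D"
    rsa = np.where(
        truth_arr,
        rng.normal(scenario.rsa_disordered_mean, scenario.rsa_sd, len(labels)),
        rng.normal(scenario.rsa_ordered_mean, scenario.rsa_sd, len(labels)),
    )
    return AnnotatedProtein(
        id=pid,
        sequence=sequence,
        topology=TopologyTrack("".join(topo_parts)),
        labels="".join(labels),
        rsa=np.clip(rsa, 0.0, 1.0),
    )


@dataclass
class SyntheticCorpus:
    proteins: list
    profiles: dict = field(default_factory=dict)
    rsas: dict = field(default_factory=dict)
    scenario: SyntheticScenario | None = None


def generate_corpus(scenario: SyntheticScenario) -> SyntheticCorpus:
    """The full labelled corpus plus profile and accessibility surrogates."""
    rng = np.random.default_rng(scenario.seed)
    proteins, profiles, rsas = [], {}, {}
    for i in range(scenario.n_proteins):
        p = generate_protein(scenario, rng, pid=f"syn{i:05d}")
        proteins.append(p)
        profiles[p.id] = pseudo_profile(p.sequence)
        rsas[p.id] = AccessibilityTrack(p.rsa, source="external")
    return SyntheticCorpus(proteins, profiles, rsas, scenario)
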