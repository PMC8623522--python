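"""Training-set construction: consensus labels, fragments, balancing,
redundancy filtering and leakage-guarded splits.

The training unit is a *fragment*: every maximal disordered run is taken
together with up to 15 ordered residues of flank on each side, plus
randomly placed fully-ordered fragments for class balance. Redundancy is
reduced with a greedy 40%-identity clustering, and the independent test
split is repaired so that no test fragment shares >= 40% global sequence
identity with any training or validation fragment.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np

from .protein import DISORDERED, ORDERED, UNOBSERVED, AnnotatedProtein
from .topology import Category, categorize

#: Maximal ordered flank kept on each side of a disordered run.
FLANK_LENGTH = 15

#: Fragments at or above this global identity are considered redundant.
IDENTITY_THRESHOLD = 0.40

#: Consensus fraction of structural observations required for a label.
CONSENSUS_FRACTION = 0.90


# ---------------------------------------------------------------------------
# consensus labels


def consensus_labels(observations: list) -> str:
    """Merge per-residue observed/missing tracks into D/O/U labels.

    Each observation is a string over ``m`` (missing) / ``o`` (observed),
    case-insensitive. A residue is labelled disordered when >= 90% of the
    tracks mark it missing, ordered when >= 90% mark it observed, and
    unobserved otherwise. Order of the input tracks is immaterial.
    """
    if not observations:
        raise ValueError("need at least one observation track")
    tracks = [obs.lower() for obs in observations]
    n = len(tracks[0])
    if any(len(t) != n for t in tracks):
        raise ValueError("observation tracks differ in length")
    bad = set("".join(tracks)) - set("mo")
    if bad:
        raise ValueError(f"unknown observation symbol(s): {sorted(bad)}")
    k = len(tracks)
    missing = np.zeros(n)
    for t in tracks:
        missing += np.frombuffer(t.encode(), dtype="S1") == b"m"
    frac = missing / k
    out = np.full(n, UNOBSERVED, dtype="U1")
    out[frac >= CONSENSUS_FRACTION] = DISORDERED
    out[(1.0 - frac) >= CONSENSUS_FRACTION] = ORDERED
    return "".join(out)


# ---------------------------------------------------------------------------
# fragments


@dataclass
class Fragment:
    """Contiguous labelled subsequence; the unit of training and evaluation.

    Coordinates are 0-based half-open on the parent protein. ``categories``
    is computed on the *parent* topology so membrane distances are not
    distorted by the cut.
    """

    parent_id: str
    start: int
    end: int
    sequence: str
    topology: str
    labels: str
    categories: np.ndarray
    kind: str  # "idr_with_flanks" | "ordered_random"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("fragment requires 0 <= start < end")
        n = self.end - self.start
        if not (len(self.sequence) == len(self.topology) == len(self.labels)
                == len(self.categories) == n):
            raise ValueError("fragment slice lengths inconsistent")
        if self.kind == "idr_with_flanks" and DISORDERED not in self.labels:
            raise ValueError("idr_with_flanks fragment has no disordered residue")

    def __len__(self) -> int:
        return self.end - self.start


def _maximal_runs(labels: str, symbol: str) -> list:
    runs = []
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] == symbol:
            j = i
            while j < n and labels[j] == symbol:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _cut(protein: AnnotatedProtein, categories: np.ndarray,
         start: int, end: int, kind: str) -> Fragment:
    return Fragment(
        parent_id=protein.id,
        start=start,
        end=end,
        sequence=protein.sequence[start:end],
        topology=protein.topology.labels[start:end],
        labels=protein.labels[start:end],
        categories=categories[start:end],
        kind=kind,
    )


def select_fragments(
    protein: AnnotatedProtein,
    rng: np.random.Generator,
    flank: int = FLANK_LENGTH,
) -> list:
    """Cut one fragment per maximal disordered run plus random ordered ones.

    Flanks extend over ordered residues only, truncated at unobserved
    residues, protein ends, or ``flank`` residues. The number of ordered
    fragments matches the number of disordered ones (at least 1 for a fully
    ordered protein); their lengths are drawn from the empirical lengths of
    the disordered fragments and they are placed uniformly inside
    fully-ordered stretches.
    """
    if protein.labels is None:
        raise ValueError(f"{protein.id}: protein has no labels")
    categories = categorize(protein.topology)
    labels = protein.labels
    fragments = []
    for run_start, run_end in _maximal_runs(labels, DISORDERED):
        left = run_start
        while left > run_start - flank and left > 0 and labels[left - 1] == ORDERED:
            left -= 1
        right = run_end
        n = len(labels)
        while right < run_end + flank and right < n and labels[right] == ORDERED:
            right += 1
        fragments.append(_cut(protein, categories, left, right, "idr_with_flanks"))

    n_ordered = max(len(fragments), 1) if DISORDERED not in labels else len(fragments)
    if fragments:
        length_pool = [len(f) for f in fragments]
    else:
        length_pool = [2 * flank + 5]
    ordered_runs = _maximal_runs(labels, ORDERED)
    for _ in range(n_ordered):
        length = int(length_pool[rng.integers(len(length_pool))])
        candidates = [(s, e) for s, e in ordered_runs if e - s >= length]
        if not candidates:
            continue
        s, e = candidates[rng.integers(len(candidates))]
        start = int(s + rng.integers(e - s - length + 1))
        fragments.append(_cut(protein, categories, start, start + length,
                              "ordered_random"))
    return fragments


# ---------------------------------------------------------------------------
# class balancing per compartment


def balance_categories(
    fragments: list,
    tolerance: float = 0.10,
    rng: np.random.Generator | None = None,
) -> dict:
    """Downsample the majority class per compartment to the 10% tolerance.

    Returns ``{Category: (disordered, ordered)}`` where each side is a list
    of ``(fragment_index, position)`` residue addresses. Compartments
    missing one class entirely are dropped with a warning.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    pools = {cat: {DISORDERED: [], ORDERED: []} for cat in Category
             if cat != Category.MEMBRANE}
    for fi, frag in enumerate(fragments):
        for pos, (label, cat) in enumerate(zip(frag.labels, frag.categories)):
            if label == UNOBSERVED or cat == Category.MEMBRANE:
                continue
            pools[Category(cat)][label].append((fi, pos))
    out = {}
    for cat, pool in pools.items():
        n_d, n_o = len(pool[DISORDERED]), len(pool[ORDERED])
        if n_d == 0 and n_o == 0:
            continue  # compartment absent from these fragments
        if n_d == 0 or n_o == 0:
            warnings.warn(
                f"compartment {cat.name} has no "
                f"{'disordered' if n_d == 0 else 'ordered'} residues; excluded",
                stacklevel=2,
            )
            continue
        minority = min(n_d, n_o)
        target = min(max(n_d, n_o), int(np.floor(minority * (1 + tolerance))))
        d, o = pool[DISORDERED], pool[ORDERED]
        if n_d > target:
            d = [d[i] for i in rng.choice(n_d, size=target, replace=False)]
        if n_o > target:
            o = [o[i] for i in rng.choice(n_o, size=target, replace=False)]
        out[cat] = (d, o)
    return out


# ---------------------------------------------------------------------------
# identity clustering and splits

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def _identity_upper_bound(a: str, b: str) -> float:
    """Exact upper bound on global identity from shared composition.

    Identities cannot exceed the multiset intersection of the two
    compositions and alignment length cannot be below max(len).
    """
    ca, cb = Counter(a), Counter(b)
    shared = sum(min(ca[k], cb.get(k, 0)) for k in ca)
    return shared / max(len(a), len(b))


def _composition_counts(sequences: list) -> np.ndarray:
    """(n, 26) letter-count matrix for the vectorised prefilter."""
    counts = np.zeros((len(sequences), 26), dtype=np.int32)
    for i, seq in enumerate(sequences):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8) - ord("A")
        counts[i] = np.bincount(arr, minlength=26)
    return counts


def global_identity(a: str, b: str) -> float:
    """Identity fraction under a global unit-cost (edit-distance-optimal)
    alignment: matched columns / alignment columns."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches = columns = 0
    for num, op in _CIGAR_RE.findall(res["cigar"]):
        columns += int(num)
        if op == "=":
            matches += int(num)
    return matches / columns


def identity_cluster(sequences: list, threshold: float = IDENTITY_THRESHOLD):
    """Greedy longest-first clustering at >= ``threshold`` global identity.

    Each sequence joins the first cluster whose representative it matches at
    or above the threshold, otherwise founds a new cluster. Returns
    ``(clusters, representatives)`` as lists of original indices.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    order = sorted(range(len(sequences)), key=lambda i: -len(sequences[i]))
    reps: list = []
    clusters: list = []
    for i in order:
        seq = sequences[i]
        placed = False
        for ci, rep_i in enumerate(reps):
            rep = sequences[rep_i]
            if _identity_upper_bound(seq, rep) < threshold:
                continue
            if global_identity(seq, rep) >= threshold:
                clusters[ci].append(i)
                placed = True
                break
        if not placed:
            reps.append(i)
            clusters.append([i])
    return clusters, reps


@dataclass
class SplitAssignment:
    """Fragment index -> split name, with the seed that produced it."""

    assignment: dict
    seed: int

    def indices(self, split: str) -> list:
        return sorted(i for i, s in self.assignment.items() if s == split)


def split_fragments(
    fragments: list,
    ratios: tuple = (0.7, 0.15, 0.15),
    seed: int = 0,
    threshold: float = IDENTITY_THRESHOLD,
) -> SplitAssignment:
    """Seeded random train/validation/test split with a leakage repair pass.

    After the random assignment, any test fragment sharing >= ``threshold``
    identity with a train or validation fragment is moved to train.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(fragments)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    assignment = {}
    for k, i in enumerate(perm):
        if k < n_train:
            assignment[int(i)] = "train"
        elif k < n_train + n_val:
            assignment[int(i)] = "validation"
        else:
            assignment[int(i)] = "test"

    sequences = [f.sequence for f in fragments]
    counts = _composition_counts(sequences)
    lengths = np.array([len(s) for s in sequences])

    def _violates(i: int, pool: np.ndarray) -> bool:
        if pool.size == 0:
            return False
        # vectorised composition bound, then alignments only where needed
        shared = np.minimum(counts[i], counts[pool]).sum(axis=1)
        bound = shared / np.maximum(lengths[i], lengths[pool])
        for k in pool[bound >= threshold]:
            if global_identity(sequences[i], sequences[int(k)]) >= threshold:
                return True
        return False

    # incremental repair: every test fragment is compared against each pool
    # member at most once (new pool members re-trigger only the new pairs)
    pool = np.array([i for i, s in assignment.items()
                     if s in ("train", "validation")], dtype=np.int64)
    remaining = [i for i, s in assignment.items() if s == "test"]
    fresh = pool
    while fresh.size and remaining:
        moved = []
        for i in list(remaining):
            if _violates(i, fresh):
                assignment[i] = "train"
                remaining.remove(i)
                moved.append(i)
        fresh = np.array(moved, dtype=np.int64)
        pool = np.concatenate([pool, fresh])
    if n and not any(s == "test" for s in assignment.values()):
        raise ValueError(
            "identity guard emptied the test split: all fragments are "
            f"mutually similar at >= {threshold:.0%} identity"
        )
    return SplitAssignment(assignment, seed)
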