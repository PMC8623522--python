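"""Per-residue feature extraction: the 11 x 39 window matrix.

For every labelled non-membrane residue a window of +/-5 positions is cut
out and each of the 11 positions is described by 39 features:

==========  =====================================================
columns     content
==========  =====================================================
0-19        evolutionary profile (PSSM row, or substitution-matrix
            pseudo-profile when no PSSM is supplied)
20-28       nine amino-acid scale values (see :mod:`tmidr.scales`)
29-31       ProtParam descriptors of the +/-5 window around the
            *center* residue: molecular weight, isoelectric point,
            instability index (identical on all 11 rows)
32-35       one-hot compartment of the window position
36          relative solvent accessibility
37          low-complexity flag (SEG-style entropy scan)
38          validity indicator: 1 for real positions, 0 for padding
==========  =====================================================

Window positions that fall outside the sequence are all-zero padding rows
with validity 0; membrane positions are real rows (validity 1) and are
distinguishable by their zeroed compartment one-hot.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParamData import DIWV

from .scales import (
    AA_INDEX,
    AMINO_ACIDS,
    PKA_NEGATIVE,
    PKA_POSITIVE,
    RESIDUE_MASS,
    WATER_MASS,
    encode_sequence,
    scale_matrix,
)
from .topology import TopologyTrack, category_onehot, categorize

# ---------------------------------------------------------------------------
# profiles


@dataclass
class ProfileMatrix:
    """L x 20 position-specific score matrix, columns in AMINO_ACIDS order."""

    values: np.ndarray
    source: str = "external_pssm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError("profile must be an L x 20 matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile contains non-finite values")

    def __len__(self) -> int:
        return self.values.shape[0]


def _blosum62_rows() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    rows = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            rows[i, j] = m[a, b]
    return rows


_BLOSUM_ROWS = _blosum62_rows()
# affine rescale of the whole matrix to [0, 1]
_BLOSUM_SCALED = (_BLOSUM_ROWS - _BLOSUM_ROWS.min()) / (
    _BLOSUM_ROWS.max() - _BLOSUM_ROWS.min()
)


def pseudo_profile(sequence: str) -> ProfileMatrix:
    """Deterministic substitution-matrix fallback profile.

    Row *i* is the BLOSUM62 column of residue *i*, rescaled to [0, 1];
    unknown residues (``X``) get a zero row.
    """
    codes = encode_sequence(sequence)
    values = np.zeros((len(sequence), 20))
    known = codes >= 0
    values[known] = _BLOSUM_SCALED[codes[known]]
    return ProfileMatrix(values, source="substitution_fallback")


_PSSM_HEADER = (
    "Last position-specific scoring matrix computed, substitution scores..."
)


def write_pssm(sequence: str, profile: ProfileMatrix) -> str:
    """Serialise a profile in the PSI-BLAST ASCII matrix dialect."""
    if len(profile) != len(sequence):
        raise ValueError("profile/sequence length mismatch")
    buf = io.StringIO()
    buf.write("\n" + _PSSM_HEADER + "\n")
    buf.write(" " * 11 + "  ".join(AMINO_ACIDS) + "\n")
    for i, aa in enumerate(sequence):
        scores = " ".join(f"{v:6.2f}" for v in profile.values[i])
        buf.write(f"{i + 1:5d} {aa} {scores}\n")
    return buf.getvalue()


def read_pssm(text: str, sequence: str | None = None) -> ProfileMatrix:
    """Parse a PSI-BLAST ASCII PSSM (first 20-score block per position).

    If ``sequence`` is given, the residue column must agree with it.
    """
    rows = []
    residues = []
    for line in text.splitlines():
        parts = line.split()
        if len(parts) >= 22 and parts[0].isdigit() and len(parts[1]) == 1:
            pos = int(parts[0])
            if pos != len(rows) + 1:
                raise ValueError(f"PSSM positions not consecutive at {pos}")
            residues.append(parts[1])
            try:
                rows.append([float(v) for v in parts[2:22]])
            except ValueError as exc:
                raise ValueError(f"malformed PSSM score row at position {pos}") from exc
    if not rows:
        raise ValueError("no PSSM rows found")
    if sequence is not None:
        if len(rows) != len(sequence):
            raise ValueError(
                f"PSSM has {len(rows)} rows but sequence has {len(sequence)}"
            )
        for i, (aa, got) in enumerate(zip(sequence, residues)):
            if aa != got:
                raise ValueError(
                    f"PSSM residue {got!r} at position {i + 1} disagrees "
                    f"with sequence residue {aa!r}"
                )
    return ProfileMatrix(np.array(rows), source="external_pssm")


# ---------------------------------------------------------------------------
# accessibility


@dataclass
class AccessibilityTrack:
    """Per-residue relative solvent accessibility in [0, 1]."""

    rsa: np.ndarray
    source: str = "external"

    def __post_init__(self) -> None:
        self.rsa = np.clip(np.asarray(self.rsa, dtype=float), 0.0, 1.0)

    def __len__(self) -> int:
        return len(self.rsa)

    @classmethod
    def constant(cls, length: int, value: float = 0.5) -> "AccessibilityTrack":
        return cls(np.full(length, value), source="constant_fallback")


# ---------------------------------------------------------------------------
# low complexity (SEG-style two-threshold entropy scan)


@dataclass
class LowComplexityMask:
    mask: np.ndarray
    window: int
    k_trigger: float
    k_extension: float

    def __len__(self) -> int:
        return len(self.mask)


def _window_entropies(sequence: str, window: int) -> np.ndarray:
    """Shannon entropy (bits) of every length-``window`` window.

    For sequences shorter than the window a single whole-sequence window is
    used.
    """
    n = len(sequence)
    w = min(window, n)
    codes = encode_sequence(sequence)
    counts = np.zeros(21, dtype=np.int64)  # slot 20 = unknown
    for c in codes[:w]:
        counts[c if c >= 0 else 20] += 1
    entropies = np.empty(n - w + 1)

    def entropy(cnt: np.ndarray) -> float:
        f = cnt[cnt > 0] / w
        return float(-(f * np.log2(f)).sum())

    entropies[0] = entropy(counts)
    for i in range(1, n - w + 1):
        out_c = codes[i - 1] if codes[i - 1] >= 0 else 20
        in_c = codes[i + w - 1] if codes[i + w - 1] >= 0 else 20
        counts[out_c] -= 1
        counts[in_c] += 1
        entropies[i] = entropy(counts)
    return entropies


def seg_mask(
    sequence: str,
    window: int = 12,
    k_trigger: float = 2.2,
    k_extension: float = 2.5,
) -> LowComplexityMask:
    """Two-threshold low-complexity scan over windowed compositional entropy.

    Windows whose entropy K <= ``k_trigger`` seed regions; seeds extend
    through contiguous windows with K <= ``k_extension``; every residue
    covered by an extended run is masked.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    w = min(window, n)
    ent = _window_entropies(sequence, window)
    seeds = ent <= k_trigger
    extendable = ent <= k_extension
    mask = np.zeros(n, dtype=bool)
    i = 0
    m = len(ent)
    while i < m:
        if extendable[i]:
            j = i
            while j < m and extendable[j]:
                j += 1
            if seeds[i:j].any():
                mask[i : j - 1 + w] = True
            i = j
        else:
            i += 1
    return LowComplexityMask(mask, window=window, k_trigger=k_trigger,
                             k_extension=k_extension)


# ---------------------------------------------------------------------------
# ProtParam descriptors

_MASS_VEC = np.array([RESIDUE_MASS[aa] for aa in AMINO_ACIDS])
_DIWV_MAT = np.zeros((20, 20))
for _a in AMINO_ACIDS:
    for _b in AMINO_ACIDS:
        _DIWV_MAT[AA_INDEX[_a], AA_INDEX[_b]] = DIWV[_a][_b]

_POS_PKA = np.array([PKA_POSITIVE[k] for k in ("H", "K", "R", "Nterm")])
_NEG_PKA = np.array([PKA_NEGATIVE[k] for k in ("D", "E", "C", "Y", "Cterm")])
_POS_IDX = [AA_INDEX[a] for a in "HKR"]
_NEG_IDX = [AA_INDEX[a] for a in "DECY"]


def net_charge(counts: np.ndarray, ph: np.ndarray) -> np.ndarray:
    """Peptide net charge at ``ph`` given residue counts (..., 20).

    Henderson-Hasselbalch per ionizable group, including free termini
    (one each per peptide).
    """
    ph = np.asarray(ph, dtype=float)
    pos_counts = np.stack(
        [counts[..., i] for i in _POS_IDX] + [np.ones(counts.shape[:-1])], axis=-1
    )
    neg_counts = np.stack(
        [counts[..., i] for i in _NEG_IDX] + [np.ones(counts.shape[:-1])], axis=-1
    )
    pos = pos_counts / (1.0 + 10.0 ** (ph[..., None] - _POS_PKA))
    neg = neg_counts / (1.0 + 10.0 ** (_NEG_PKA - ph[..., None]))
    return pos.sum(axis=-1) - neg.sum(axis=-1)


def _bisect_pi(counts: np.ndarray, iters: int = 60) -> np.ndarray:
    """Vectorised bisection for the pH of zero net charge.

    Net charge is strictly decreasing in pH, so the root is unique; 60
    halvings of [0, 14] converge far below any reported precision.
    """
    lo = np.zeros(counts.shape[:-1])
    hi = np.full(counts.shape[:-1], 14.0)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        c = net_charge(counts, mid)
        lo = np.where(c > 0, mid, lo)
        hi = np.where(c > 0, hi, mid)
    return 0.5 * (lo + hi)


def protparam_features(window_sequence: str) -> tuple[float, float, float]:
    """(molecular weight Da, isoelectric point, instability index) of a peptide.

    Non-standard symbols (padding, ``X``) are skipped. MW uses average
    isotopic residue masses plus one water; pI is the bisection root of the
    net-charge curve; instability is the Guruprasad dipeptide-weight sum
    scaled by 10/len.
    """
    codes = encode_sequence(window_sequence)
    codes = codes[codes >= 0]
    if codes.size == 0:
        raise ValueError("window contains no standard residues")
    mw = float(_MASS_VEC[codes].sum() + WATER_MASS)
    counts = np.bincount(codes, minlength=20).astype(float)
    pi = float(_bisect_pi(counts))
    if codes.size >= 2:
        dipep = float(_DIWV_MAT[codes[:-1], codes[1:]].sum())
    else:
        dipep = 0.0
    instability = 10.0 / codes.size * dipep
    return mw, pi, instability


def window_protparam(sequence: str, half_width: int = 5) -> np.ndarray:
    """(L, 3) ProtParam descriptors of the +/-``half_width`` window at each
    position, vectorised via sliding counts and batched bisection."""
    n = len(sequence)
    codes = encode_sequence(sequence)
    onehot = np.zeros((n, 20))
    known = codes >= 0
    onehot[known, codes[known]] = 1.0
    # cumulative sums give windowed composition counts
    cum = np.vstack([np.zeros(20), np.cumsum(onehot, axis=0)])
    starts = np.maximum(np.arange(n) - half_width, 0)
    ends = np.minimum(np.arange(n) + half_width + 1, n)
    counts = cum[ends] - cum[starts]
    sizes = counts.sum(axis=1)
    sizes_safe = np.maximum(sizes, 1.0)

    mw = counts @ _MASS_VEC + WATER_MASS
    pi = _bisect_pi(counts)

    # dipeptide sums over each window via cumulative pair weights
    pair_w = np.zeros(n - 1 if n > 1 else 0)
    if n > 1:
        valid_pair = known[:-1] & known[1:]
        pair_w[valid_pair] = _DIWV_MAT[codes[:-1][valid_pair], codes[1:][valid_pair]]
    cpw = np.concatenate([[0.0], np.cumsum(pair_w)])
    dipep = cpw[np.maximum(ends - 1, starts)] - cpw[starts]
    instability = 10.0 / sizes_safe * dipep
    return np.column_stack([mw, pi, instability])


# ---------------------------------------------------------------------------
# schema and matrix assembly


@dataclass(frozen=True)
class FeatureSchema:
    """Versioned, named layout of the per-position feature vector."""

    half_width: int = 5
    version: str = "default-39-v1"
    columns: tuple = field(default_factory=lambda: _default_columns())

    @property
    def window_size(self) -> int:
        return 2 * self.half_width + 1

    @property
    def n_features(self) -> int:
        return len(self.columns)

    def schema_hash(self) -> str:
        payload = f"{self.version}|h={self.half_width}|" + ",".join(self.columns)
        return hashlib.sha1(payload.encode()).hexdigest()


def _default_columns() -> tuple:
    cols = [f"pssm_{aa}" for aa in AMINO_ACIDS]
    cols += [f"scale_{name}" for name in (
        "hydrophobicity", "polarity", "volume", "flexibility", "charge",
        "helix", "sheet", "coil", "aromaticity")]
    cols += ["protparam_mw", "protparam_pi", "protparam_instability"]
    cols += ["cat_extra_distant", "cat_extra_proximal",
             "cat_intra_distant", "cat_intra_proximal"]
    cols += ["rsa", "low_complexity", "valid"]
    return tuple(cols)


DEFAULT_SCHEMA = FeatureSchema()

_SCALE_MATRIX = scale_matrix()


def position_features_from_parts(
    sequence: str,
    categories: np.ndarray,
    profile: ProfileMatrix,
    rsa: AccessibilityTrack,
    lc: LowComplexityMask,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> np.ndarray:
    """(L, n_features) per-position rows from pre-computed compartments.

    Used for fragments, whose compartments come from the parent protein.
    ProtParam columns are left zero (filled per-center by the matrix
    builders).
    """
    n = len(sequence)
    for name, obj in (("category", categories), ("profile", profile),
                      ("rsa", rsa), ("low-complexity", lc)):
        if len(obj) != n:
            raise ValueError(f"{name} track length {len(obj)} != sequence length {n}")
    if schema.n_features != 39:
        raise ValueError(
            f"default builder expects a 39-column schema, got {schema.n_features}"
        )
    codes = encode_sequence(sequence)
    rows = np.zeros((n, schema.n_features))
    rows[:, 0:20] = profile.values
    known = codes >= 0
    rows[known, 20:29] = _SCALE_MATRIX[codes[known]]
    rows[:, 32:36] = category_onehot(np.asarray(categories))
    rows[:, 36] = rsa.rsa
    rows[:, 37] = lc.mask.astype(float)
    rows[:, 38] = 1.0
    return rows


def position_features(
    sequence: str,
    track: TopologyTrack,
    profile: ProfileMatrix,
    rsa: AccessibilityTrack,
    lc: LowComplexityMask,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> np.ndarray:
    """(L, n_features) per-position rows for a whole protein."""
    return position_features_from_parts(
        sequence, categorize(track), profile, rsa, lc, schema
    )


def feature_tensor_from_parts(
    sequence: str,
    categories: np.ndarray,
    profile: ProfileMatrix,
    rsa: AccessibilityTrack,
    lc: LowComplexityMask,
    centers: np.ndarray,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> np.ndarray:
    """Stack the (window, n_features) matrices of many centers.

    Returns an array of shape (len(centers), 2*h+1, n_features). Window
    positions outside the sequence are all-zero padding rows (validity 0).
    """
    base = position_features_from_parts(sequence, categories, profile, rsa,
                                        lc, schema)
    pp = window_protparam(sequence, schema.half_width)
    n = len(sequence)
    h = schema.half_width
    centers = np.asarray(centers, dtype=np.int64)
    if centers.size and (centers.min() < 0 or centers.max() >= n):
        raise IndexError("center outside sequence")
    # pad base rows with h zero-rows on both sides, then gather windows
    padded = np.zeros((n + 2 * h, schema.n_features))
    padded[h : h + n] = base
    idx = centers[:, None] + np.arange(2 * h + 1)[None, :]
    tensors = padded[idx]
    # ProtParam descriptors of the center window, on all valid rows
    valid = tensors[:, :, 38] > 0
    for k in range(3):
        tensors[:, :, 29 + k] = np.where(valid, pp[centers, k][:, None], 0.0)
    return tensors


def feature_tensor(
    sequence: str,
    track: TopologyTrack,
    profile: ProfileMatrix,
    rsa: AccessibilityTrack,
    lc: LowComplexityMask,
    centers: np.ndarray,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> np.ndarray:
    """Window feature tensors for centers of a whole protein."""
    return feature_tensor_from_parts(
        sequence, categorize(track), profile, rsa, lc, centers, schema
    )


def build_feature_matrix(
    sequence: str,
    track: TopologyTrack,
    profile: ProfileMatrix,
    rsa: AccessibilityTrack,
    lc: LowComplexityMask,
    center: int,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> np.ndarray:
    """The (11, 39) feature matrix of one center residue (default schema)."""
    return feature_tensor(sequence, track, profile, rsa, lc,
                          np.array([center]), schema)[0]
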