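"""Post-processing of score tracks: smoothing, rescaling, binary calls.

Two published output modes are supported:

* **specific** — the compartment-CNN track smoothed with a +/-4 moving
  average and thresholded at 0.65; best specificity.
* **sensitive** — the recurrent-smoother track smoothed with +/-7; best
  sensitivity.

Scores are additionally mapped through a piecewise-linear rescaling that
sends the decision cutoff (0.65) to a display value of 0.5, so a display
threshold of 0.5 reproduces the raw-cutoff call exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Raw-score decision cutoff.
CUTOFF = 0.65
#: Moving-average half-widths of the two modes.
SPECIFIC_HALF_WIDTH = 4
SENSITIVE_HALF_WIDTH = 7

MODES = ("specific", "sensitive")


def smooth(
    scores: np.ndarray,
    half_width: int,
    membrane_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Centered moving average, truncated at the track ends.

    Membrane residues are excluded from their neighbours' averages and are
    emitted as 0 themselves. ``half_width 0`` is the identity for
    non-membrane positions.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score track")
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    if membrane_mask is None:
        valid = np.ones_like(scores)
    else:
        valid = (~np.asarray(membrane_mask, dtype=bool)).astype(float)
    kernel = np.ones(2 * half_width + 1)
    # full convolution sliced to the centered window; robust to tracks
    # shorter than the kernel
    n = len(scores)
    num = np.convolve(scores * valid, kernel)[half_width : half_width + n]
    den = np.convolve(valid, kernel)[half_width : half_width + n]
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    out[valid == 0] = 0.0
    return out


def rescale(score, cutoff: float = CUTOFF):
    """Piecewise-linear display map: [0, c] -> [0, 0.5], [c, 1] -> [0.5, 1].

    Strictly increasing with ``rescale(c) == 0.5``, so thresholding the
    display score at 0.5 is identical to thresholding the raw score at the
    cutoff.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be strictly inside (0, 1)")
    s = np.asarray(score, dtype=float)
    lo = s / cutoff * 0.5
    hi = 0.5 + (s - cutoff) / (1.0 - cutoff) * 0.5
    out = np.where(s <= cutoff, lo, hi)
    return float(out) if np.isscalar(score) else out


def call_binary(smoothed, cutoff: float = CUTOFF) -> np.ndarray:
    """Disordered iff the smoothed score is at or above the cutoff."""
    return np.asarray(smoothed, dtype=float) >= cutoff


@dataclass
class PredictionTrack:
    """Per-residue scores and calls of one protein in one output mode."""

    mode: str
    raw: np.ndarray
    smoothed: np.ndarray
    display: np.ndarray
    calls: np.ndarray
    half_width: int
    cutoff: float

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        n = len(self.raw)
        if not (len(self.smoothed) == len(self.display) == len(self.calls) == n):
            raise ValueError("track lengths inconsistent")

    def __len__(self) -> int:
        return len(self.raw)


def make_track(
    raw: np.ndarray,
    mode: str,
    membrane_mask: np.ndarray | None = None,
    cutoff: float = CUTOFF,
    half_width: int | None = None,
) -> PredictionTrack:
    """Smooth, rescale and call a raw score track in the given mode."""
    if half_width is None:
        half_width = SPECIFIC_HALF_WIDTH if mode == "specific" else SENSITIVE_HALF_WIDTH
    smoothed = smooth(raw, half_width, membrane_mask)
    display = rescale(smoothed, cutoff)
    calls = call_binary(smoothed, cutoff)
    if membrane_mask is not None:
        calls = calls & ~np.asarray(membrane_mask, dtype=bool)
    return PredictionTrack(mode=mode, raw=np.asarray(raw, dtype=float),
                           smoothed=smoothed, display=display, calls=calls,
                           half_width=half_width, cutoff=cutoff)
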