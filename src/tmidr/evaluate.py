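"""Residue- and region-level evaluation.

Residue metrics follow the community disorder-assessment (CAID) suite:
sensitivity, specificity, balanced accuracy, Matthews correlation
coefficient and ROC AUC, with disordered as the positive class. Evaluation
can be restricted to the previously selected fragments, and regions are
counted as detected when at least 60% of their residues are called
disordered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .protein import DISORDERED, ORDERED
from .topology import Category

#: Fraction of residues of a region that must be called disordered for the
#: region to count as detected.
REGION_THRESHOLD = 0.60


@dataclass
class ConfusionCounts:
    """Binary confusion counts with disordered as the positive class."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def residue_metrics(counts: ConfusionCounts) -> dict:
    """Sensitivity, specificity, balanced accuracy and MCC.

    Metrics with a zero denominator are reported as ``nan`` (undefined),
    never silently as 0.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sens = tp / (tp + fn) if tp + fn else math.nan
    spec = tn / (tn + fp) if tn + fp else math.nan
    bal = (sens + spec) / 2.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else math.nan
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": bal,
        "mcc": mcc,
    }


def auc(scores, labels) -> float:
    """ROC AUC; equals the normalised Mann-Whitney U with ties counted half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def restrict_to_fragments(
    calls: dict,
    labels: dict,
    categories: dict,
    fragments: list,
) -> ConfusionCounts:
    """Confusion counts over labelled, non-membrane residues inside fragments.

    ``calls``, ``labels`` and ``categories`` map protein id to full-length
    per-residue tracks; ``fragments`` provide the evaluated coordinates.
    Residues labelled unobserved and membrane residues never enter the
    counts.
    """
    counts = ConfusionCounts()
    for frag in fragments:
        pid = frag.parent_id
        call = np.asarray(calls[pid], dtype=bool)
        lab = labels[pid]
        cat = np.asarray(categories[pid])
        if frag.end > len(call):
            raise ValueError(f"fragment {pid}:{frag.start}-{frag.end} outside sequence")
        for i in range(frag.start, frag.end):
            if cat[i] == Category.MEMBRANE:
                continue
            if lab[i] == DISORDERED:
                if call[i]:
                    counts.tp += 1
                else:
                    counts.fn += 1
            elif lab[i] == ORDERED:
                if call[i]:
                    counts.fp += 1
                else:
                    counts.tn += 1
    return counts


@dataclass
class RegionCall:
    protein_id: str
    start: int
    end: int
    fraction: float
    detected: bool


def region_detection(
    regions: list,
    calls: dict,
    threshold: float = REGION_THRESHOLD,
) -> tuple:
    """Region-level detection: a region counts when >= ``threshold`` of its
    residues are called disordered.

    ``regions`` is a list of ``(protein_id, start, end)`` with 0-based
    half-open coordinates; returns ``(region_calls, detection_rate)``.
    """
    if not regions:
        raise ValueError("no regions supplied")
    out = []
    for pid, start, end in regions:
        if end <= start:
            raise ValueError(f"zero-length region {pid}:{start}-{end}")
        call = np.asarray(calls[pid], dtype=bool)
        if end > len(call):
            raise ValueError(f"region {pid}:{start}-{end} outside sequence")
        frac = float(call[start:end].mean())
        out.append(RegionCall(pid, start, end, frac, frac >= threshold))
    rate = sum(r.detected for r in out) / len(out)
    return out, rate
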