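"""Pixelwise evaluation of a predicted mask against a reference mask.

Confusion counts are taken over the full image grid (not ROI-restricted);
Dice > 0.70 is conventionally read as excellent agreement for this kind
of segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, UndefinedMetricError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ContractError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.dtype != bool or truth.dtype != bool:
        raise ContractError("masks must be boolean")
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def dice(counts: ConfusionCounts) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|)."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        raise UndefinedMetricError("Dice undefined: both masks are empty")
    return 2.0 * counts.tp / denom

def precision_sensitivity_specificity(
    counts: ConfusionCounts,
) -> tuple[float | None, float | None, float | None]:
    """(tp/(tp+fp), tp/(tp+fn), tn/(tn+fp)); a zero denominator yields
    None for that component only."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    s = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    sp = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    return p, s, sp


def report(pred: np.ndarray, truth: np.ndarray) -> dict:
    """JSON-ready metric report; undefined metrics serialize as null."""
    c = confusion(pred, truth)
    try:
        d = dice(c)
    except UndefinedMetricError:
        d = None
    p, s, sp = precision_sensitivity_specificity(c)
    return {
        "dice": d,
        "precision": p,
        "sensitivity": s,
        "specificity": sp,
        "tp": c.tp,
        "fp": c.fp,
        "tn": c.tn,
        "fn": c.fn,
    }
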