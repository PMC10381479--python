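"""Dice similarity coefficient and segmentation comparison reports.

DSC = 2|S ∩ GT| / (|S| + |GT|) = 2·TP / (2·TP + FP + FN), where TP/FP/FN
count pixels that are foreground in both masks, only in the segmentation,
and only in the ground truth.  1 means identical masks, 0 disjoint ones.
The same report format serves both method-vs-truth scoring and the
inter-expert agreement protocol (two readers segmenting the same frames).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binarize import BinaryMask
from .errors import SchemaError, ShapeError


@dataclass(frozen=True)
class GrooveDice:
    groove_label: str
    dsc: float
    tp: int
    fp: int
    fn: int
    elapsed_a: float = 0.0
    elapsed_b: float = 0.0


@dataclass
class DiceReport:
    per_groove: list
    #: convention: two empty masks score DSC 1 (vacuous agreement)
    empty_pair_convention: str = "dsc=1 when both masks are empty"

    @property
    def mean_dsc(self) -> float:
        return float(np.mean([g.dsc for g in self.per_groove]))

    @property
    def elapsed_a(self) -> float:
        return float(sum(g.elapsed_a for g in self.per_groove))

    @property
    def elapsed_b(self) -> float:
        return float(sum(g.elapsed_b for g in self.per_groove))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "groove": g.groove_label,
                    "dsc": g.dsc,
                    "tp": g.tp,
                    "fp": g.fp,
                    "fn": g.fn,
                    "elapsed_a": g.elapsed_a,
                    "elapsed_b": g.elapsed_b,
                }
                for g in self.per_groove
            ]
        )
        return df


def _as_grid(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.grid
    return np.asarray(mask).astype(bool)


def dice(S, GT) -> tuple[float, int, int, int]:
    """Sørensen–Dice coefficient between two same-shape binary masks.

    Returns (dsc, tp, fp, fn).  Two empty masks score 1 by convention
    (vacuously perfect agreement).
    """
    s, gt = _as_grid(S), _as_grid(GT)
    if s.shape != gt.shape:
        raise ShapeError(f"mask shapes differ: {s.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(s & gt))
    fp = int(np.count_nonzero(s & ~gt))
    fn = int(np.count_nonzero(~s & gt))
    denom = 2 * tp + fp + fn
    dsc = 1.0 if denom == 0 else 2.0 * tp / denom
    return dsc, tp, fp, fn


def compare(results_a: Sequence, results_b) -> DiceReport:
    """Per-groove Dice report between two segmentations.

    ``results_a`` is a list of SegmentationResult; ``results_b`` is either
    another such list (e.g. a second expert) or a mapping of groove label
    to ground-truth mask.
    """
    masks_a = {r.groove_label: r for r in results_a}
    if len(masks_a) != len(results_a):
        raise SchemaError("duplicate groove labels in results_a")

    if isinstance(results_b, Mapping):
        masks_b = dict(results_b)
        elapsed_b = {k: 0.0 for k in masks_b}
    else:
        masks_b = {r.groove_label: r.mask for r in results_b}
        elapsed_b = {r.groove_label: getattr(r, "elapsed", 0.0) for r in results_b}
        if len(masks_b) != len(results_b):
            raise SchemaError("duplicate groove labels in results_b")

    if set(masks_a) != set(masks_b):
        raise SchemaError(
            f"groove labels do not match: {sorted(masks_a)} vs {sorted(masks_b)}"
        )

    per_groove = []
    for label in masks_a:  # insertion order of results_a
        res = masks_a[label]
        dsc, tp, fp, fn = dice(res.mask, masks_b[label])
        per_groove.append(
            GrooveDice(
                groove_label=label, dsc=dsc, tp=tp, fp=fp, fn=fn,
                elapsed_a=getattr(res, "elapsed", 0.0),
                elapsed_b=elapsed_b[label],
            )
        )
    return DiceReport(per_groove=per_groove)
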