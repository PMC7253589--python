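"""Evaluation measures: Dice similarity coefficient and ASSD.

DSC = 2|A∩M| / (|A| + |M|) measures volumetric overlap in [0, 1].
ASSD averages, symmetrically in both directions, the distance from each
border voxel of one mask to the nearest border voxel of the other,

    ASSD = ( sum_{m in B(M)} min_{a in B(A)} ||m - a||
           + sum_{a in B(A)} min_{m in B(M)} ||a - m|| )
           / (|B(M)| + |B(A)|),

in mm, using voxel-center Euclidean distances.  Border voxels are mask
voxels with at least one 6-connected neighbour outside the mask; voxels
on the array boundary count their out-of-array side as outside.  Both
conventions are stated because the choice affects comparability.

Undefined cells (empty masks) are reported as NaN, never as zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import AlignmentError

__all__ = ["dice", "border_voxels", "assd", "evaluate", "EvaluationReport"]

_CONN6 = ndimage.generate_binary_structure(3, 1)


def _check_pair(a, m):
    a = np.asarray(a, dtype=bool)
    m = np.asarray(m, dtype=bool)
    if a.shape != m.shape:
        raise AlignmentError(f"mask shapes differ: {a.shape} vs {m.shape}")
    return a, m


def dice(a, m) -> float:
    """2|A∩M| / (|A|+|M|); NaN if both masks are empty (undefined, not 0/0)."""
    a, m = _check_pair(a, m)
    denom = int(a.sum()) + int(m.sum())
    if denom == 0:
        return float("nan")
    return 2.0 * int(np.logical_and(a, m).sum()) / denom


def border_voxels(mask) -> np.ndarray:
    """Coordinates (n, 3) of mask voxels with a 6-connected outside neighbour."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.empty((0, 3), dtype=np.int64)
    interior = ndimage.binary_erosion(mask, structure=_CONN6, border_value=0)
    return np.argwhere(mask & ~interior)


def assd(a, m, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average symmetric surface distance in mm; NaN if either mask is empty."""
    a, m = _check_pair(a, m)
    if not a.any() or not m.any():
        return float("nan")
    spacing = np.asarray(spacing, dtype=float)
    ba = border_voxels(a) * spacing
    bm = border_voxels(m) * spacing
    d_m_to_a, _ = cKDTree(ba).query(bm, k=1)
    d_a_to_m, _ = cKDTree(bm).query(ba, k=1)
    return float((d_m_to_a.sum() + d_a_to_m.sum()) / (len(ba) + len(bm)))


@dataclasses.dataclass
class EvaluationReport:
    """Per-class, per-subject Dice/ASSD plus a mean (sd) summary."""

    per_subject: pd.DataFrame  # subject, class, dice, assd, status
    summary: pd.DataFrame      # class, dice_mean, dice_sd, assd_mean, assd_sd

    def to_csv(self, path):
        """Write the summary in the field's usual 'mean (sd)' table form."""
        rows = []
        for _, r in self.summary.iterrows():
            rows.append({
                "class": r["class"],
                "dice_pct": f"{100 * r.dice_mean:.1f} ({100 * r.dice_sd:.1f})"
                if np.isfinite(r.dice_mean) else "N/A",
                "assd_mm": f"{r.assd_mean:.2f} ({r.assd_sd:.2f})"
                if np.isfinite(r.assd_mean) else "N/A",
            })
        pd.DataFrame(rows).to_csv(path, index=False)


def evaluate(predictions, truths, class_table, spacing=(1.0, 1.0, 1.0)) -> EvaluationReport:
    """One-vs-rest Dice and ASSD per foreground class, across subjects.

    `predictions`/`truths`: LabelMap-like objects or integer arrays,
    one per subject.  Classes absent from a subject's truth are flagged
    'absent-from-truth' with NaN metrics, never silently zero.
    """
    if not isinstance(predictions, (list, tuple)):
        predictions = [predictions]
        truths = [truths]
    if len(predictions) != len(truths):
        raise ValueError("need one truth per prediction")
    rows = []
    for s, (pred, truth) in enumerate(zip(predictions, truths)):
        p = np.asarray(getattr(pred, "data", pred))
        t = np.asarray(getattr(truth, "data", truth))
        sp = getattr(truth, "spacing", spacing)
        if p.shape != t.shape:
            raise AlignmentError("prediction and truth shapes differ")
        for label in class_table.foreground_labels:
            pm, tm = p == label, t == label
            if not tm.any():
                rows.append({"subject": s, "class": class_table.class_names[label],
                             "dice": np.nan, "assd": np.nan,
                             "status": "absent-from-truth"})
                continue
            d = dice(pm, tm)
            sd = assd(pm, tm, sp)
            status = "ok" if np.isfinite(sd) else "assd-undefined"
            rows.append({"subject": s, "class": class_table.class_names[label],
                         "dice": d, "assd": sd, "status": status})
    per_subject = pd.DataFrame(rows)
    grouped = per_subject.groupby("class", sort=False)
    summary = grouped.agg(
        dice_mean=("dice", "mean"), dice_sd=("dice", "std"),
        assd_mean=("assd", "mean"), assd_sd=("assd", "std"),
    ).reset_index()
    return EvaluationReport(per_subject=per_subject, summary=summary)
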