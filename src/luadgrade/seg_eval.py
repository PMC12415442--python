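"""Pixel-level evaluation of predicted pattern masks against ground truth.

Per-class Dice (F1) overlap and the discrepant-pixel structure: for each
ground-truth pattern, the percentage breakdown of its misclassified pixels
over the other patterns (plus a background column for pixels the prediction
left unannotated inside the ground-truth tumor area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .patterns import DEFAULT_CODEBOOK, LabelMask, PATTERN_NAMES, PatternCodebook


@dataclass
class EvalReport:
    dice_by_class: dict[str, float]
    macro_dice: float
    weighted_dice: float
    discrepancy: pd.DataFrame  # rows: gt pattern; cols: patterns + background; row % of discrepant px
    support: dict[str, int]


def _confusion(
    gt: LabelMask, pred: LabelMask, codebook: PatternCodebook, ignore_code: int
) -> tuple[np.ndarray, list[int]]:
    """Joint (gt, pred) pixel tally over pixels where gt != ignore_code."""
    if gt.raster.shape != pred.raster.shape:
        raise ValueError(
            f"shape mismatch: gt {gt.raster.shape} vs pred {pred.raster.shape}"
        )
    g = gt.raster.ravel().astype(np.int64)
    p = pred.raster.ravel().astype(np.int64)
    keep = g != ignore_code
    g, p = g[keep], p[keep]
    codes = sorted(codebook.code_to_name) + [codebook.background_code]
    remap = {c: i for i, c in enumerate(codes)}
    k = len(codes)
    gi = np.vectorize(remap.get, otypes=[np.int64])(g) if g.size else g
    pi = np.vectorize(remap.get, otypes=[np.int64])(p) if p.size else p
    joint = np.bincount(gi * k + pi, minlength=k * k).reshape(k, k)
    return joint, codes


def evaluate_masks(
    gt: LabelMask,
    pred: LabelMask,
    codebook: PatternCodebook = DEFAULT_CODEBOOK,
    ignore_code: int | None = None,
) -> EvalReport:
    """Per-class Dice and the discrepancy matrix in a single report.

    Pixels where the ground truth equals ``ignore_code`` (default: the
    codebook's background code) are excluded: evaluation is confined to the
    annotated tumor area.  Dice_c = 2|GT_c ∩ PR_c| / (|GT_c| + |PR_c|);
    the macro mean is unweighted over classes present in the ground truth,
    and a support-weighted mean is reported alongside.  Discrepancy row c
    distributes the pixels with gt = c and pred != c over the predicted
    classes (in %); rows with no misclassified pixels are NaN.
    """
    if ignore_code is None:
        ignore_code = codebook.background_code
    joint, codes = _confusion(gt, pred, codebook, ignore_code)
    names = [codebook.code_to_name.get(c, "background") for c in codes]
    n_pat = len(codebook.code_to_name)

    gt_tot = joint.sum(axis=1)
    pr_tot = joint.sum(axis=0)
    dice, support = {}, {}
    for i in range(n_pat):
        name = names[i]
        support[name] = int(gt_tot[i])
        denom = gt_tot[i] + pr_tot[i]
        dice[name] = float(2.0 * joint[i, i] / denom) if denom > 0 else float("nan")

    present = [n for n in PATTERN_NAMES if support[n] > 0]
    macro = float(np.mean([dice[n] for n in present])) if present else float("nan")
    weighted = (
        float(
            np.average([dice[n] for n in present], weights=[support[n] for n in present])
        )
        if present
        else float("nan")
    )

    disc = np.full((n_pat, len(codes)), np.nan)
    for i in range(n_pat):
        wrong = joint[i].copy()
        wrong[i] = 0
        tot = wrong.sum()
        if tot > 0:
            disc[i] = 100.0 * wrong / tot
            disc[i, i] = 0.0
    discrepancy = pd.DataFrame(disc, index=names[:n_pat], columns=names)

    return EvalReport(
        dice_by_class=dice,
        macro_dice=macro,
        weighted_dice=weighted,
        discrepancy=discrepancy,
        support=support,
    )


def dice_per_class(
    gt: LabelMask,
    pred: LabelMask,
    codebook: PatternCodebook = DEFAULT_CODEBOOK,
    ignore_code: int | None = None,
) -> EvalReport:
    """Per-class Dice overlap report (see :func:`evaluate_masks`)."""
    return evaluate_masks(gt, pred, codebook, ignore_code)


def discrepancy_matrix(
    gt: LabelMask,
    pred: LabelMask,
    codebook: PatternCodebook = DEFAULT_CODEBOOK,
    ignore_code: int | None = None,
) -> pd.DataFrame:
    """Row-normalized % breakdown of misclassified pixels per gt pattern."""
    return evaluate_masks(gt, pred, codebook, ignore_code).discrepancy
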