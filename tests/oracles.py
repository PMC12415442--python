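"""Independent brute-force re-implementations used as test oracles.

Deliberately written table-first and without importing any luadgrade rule
engine, so that agreement between the two routes is informative.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np

PAT = ("lepidic", "acinar", "papillary", "micropapillary", "solid", "complex_glandular")
SEV = ("lepidic", "acinar", "papillary", "complex_glandular", "micropapillary", "solid")
T3 = {"lepidic": 1, "acinar": 2, "papillary": 2,
      "micropapillary": 3, "solid": 3, "complex_glandular": 3}
T4 = {"lepidic": 1, "acinar": 2, "papillary": 2,
      "complex_glandular": 3, "micropapillary": 4, "solid": 4}


def oracle_dom_sec(pct: Mapping[str, float], min_sec: float = 5.0):
    ranked = sorted(
        (p for p in PAT if pct.get(p, 0) > 0),
        key=lambda p: (-pct[p], -SEV.index(p)),
    )
    dom = ranked[0]
    for p in ranked[1:]:
        if pct[p] >= min_sec:
            return dom, p, False
    return dom, dom, True


def oracle_grade(pct: Mapping[str, float], system: str) -> str:
    """Grade label by direct transcription of each system's rule."""
    dom, sec, _ = oracle_dom_sec(pct)
    hg3 = pct.get("micropapillary", 0) + pct.get("solid", 0) + pct.get("complex_glandular", 0)
    hg2 = pct.get("micropapillary", 0) + pct.get("solid", 0)
    if system == "WHO":
        return f"G{T3[dom]}"
    if system == "IASLC":
        return "G3" if (T3[dom] < 3 and hg3 > 20) else f"G{T3[dom]}"
    if system == "IASLC_SIMPLIFIED":
        return "G3" if (T3[dom] < 3 and hg2 > 20) else f"G{T3[dom]}"
    if system == "IASLC_MODIFIED":
        return "G3" if (T3[dom] < 3 and hg3 > 50) else f"G{T3[dom]}"
    if system == "FOUR_TIER":
        return f"G{T4[dom]}"
    if system == "PROG_SCORE":
        return SCORE_LOOKUP[(T3[dom], T3[sec])]
    raise ValueError(system)


#: hand-built (dominant tier, secondary tier) -> prognostic group table
SCORE_LOOKUP = {
    (1, 1): "PG0",  # score 2, purely lepidic
    (1, 2): "PG1",  # 3a
    (2, 1): "PG2",  # 3b
    (2, 2): "PG3",  # score 4
    (1, 3): "PG3",
    (3, 1): "PG3",
    (2, 3): "PG4",  # score 5
    (3, 2): "PG4",
    (3, 3): "PG5",  # score 6
}


def simplex_grid(step: int = 5):
    """All 6-part percent compositions on a `step`%-grid summing to 100."""
    n = 100 // step
    for cuts in itertools.combinations(range(n + 5), 5):
        parts = np.diff((-1,) + cuts + (n + 5,)) - 1
        yield {p: float(step * k) for p, k in zip(PAT, parts)}


def oracle_kappa(a: Sequence[str], b: Sequence[str], weighting: str = "none",
                 categories: Sequence[str] = SEV) -> float:
    """Direct p_o / p_e kappa from the definition."""
    idx = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    if weighting == "none":
        w = 1.0 - np.eye(k)
    else:
        ii, jj = np.meshgrid(range(k), range(k), indexing="ij")
        w = np.abs(ii - jj) / (k - 1)
    n = len(a)
    obs = sum(w[idx[x], idx[y]] for x, y in zip(a, b)) / n
    pa = np.bincount([idx[x] for x in a], minlength=k) / n
    pb = np.bincount([idx[y] for y in b], minlength=k) / n
    exp = float(pa @ w @ pb)
    if exp == 0:
        return 1.0 if obs == 0 else 0.0
    return 1.0 - obs / exp


def oracle_seg_tally(gt: np.ndarray, pred: np.ndarray, codes=range(1, 7), ignore=0):
    """Pixel-by-pixel Dice + discrepancy tally with explicit loops."""
    inter = {c: 0 for c in codes}
    gt_n = {c: 0 for c in codes}
    pr_n = {c: 0 for c in codes}
    wrong = {c: {} for c in codes}
    for g, p in zip(gt.ravel().tolist(), pred.ravel().tolist()):
        if g == ignore:
            continue
        if g in gt_n:
            gt_n[g] += 1
        if p in pr_n:
            pr_n[p] += 1
        if g == p and g in inter:
            inter[g] += 1
        elif g in wrong:
            wrong[g][p] = wrong[g].get(p, 0) + 1
    dice = {
        c: (2 * inter[c] / (gt_n[c] + pr_n[c]) if gt_n[c] + pr_n[c] else float("nan"))
        for c in codes
    }
    disc = {}
    for c in codes:
        tot = sum(wrong[c].values())
        disc[c] = {k: 100.0 * v / tot for k, v in wrong[c].items()} if tot else None
    return dice, disc, gt_n
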