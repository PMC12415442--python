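"""Multi-rater agreement analysis for dominant-pattern calls.

Panels of pathologists (optionally plus the AI tool) each assign one
dominant growth pattern per tumor region (ROI).  This module provides
Cohen's kappa (unweighted and linear/equal-spacing weighted over a declared
category order), simple agreement, the pairwise-kappa matrix with per-rater
averages, majority voting with a consensus rule (default: at least 7 of 13
raters agreeing), and the leave-one-out comparison of a single rater against
the majority vote of the others.

The AI rater takes part in pairwise kappa comparisons but is always
excluded from majority-vote computations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .patterns import PATTERN_NAMES, SEVERITY_ORDER

MISSING = None  # sentinel for a missing rating


@dataclass
class RaterPanel:
    """Items x raters categorical matrix of dominant-pattern labels.

    ``ratings`` is a DataFrame indexed by item id with one column per
    rater; missing ratings are NaN/None.  ``ai_raters`` names columns that
    represent automated tools rather than pathologists.
    """

    ratings: pd.DataFrame
    ai_raters: frozenset[str] = frozenset()
    categories: Sequence[str] = SEVERITY_ORDER

    def __post_init__(self) -> None:
        if self.ratings.shape[1] < 2:
            raise ValueError("a rater panel needs at least 2 raters")
        if self.ratings.shape[0] < 1:
            raise ValueError("a rater panel needs at least 1 item")
        labels = set(self.ratings.stack().dropna().unique())
        unknown = labels - set(self.categories)
        if unknown:
            raise ValueError(f"unknown labels in panel: {sorted(unknown)}")

    @property
    def items(self) -> list:
        return list(self.ratings.index)

    @property
    def raters(self) -> list[str]:
        return list(self.ratings.columns)

    @property
    def pathologists(self) -> list[str]:
        return [r for r in self.raters if r not in self.ai_raters]


@dataclass
class VoteResult:
    item: object
    mv1: str | None
    mv2: str | None
    counts: dict[str, int]
    consensus: bool
    n_distinct: int
    tie: bool = False


def _paired(a: Sequence, b: Sequence) -> tuple[np.ndarray, np.ndarray]:
    a = pd.Series(list(a))
    b = pd.Series(list(b))
    if len(a) != len(b):
        raise ValueError("rating vectors differ in length")
    ok = a.notna() & b.notna()
    if not ok.any():
        raise ValueError("no overlapping (non-missing) ratings")
    return a[ok].to_numpy(), b[ok].to_numpy()


def _contingency(a: np.ndarray, b: np.ndarray, categories: Sequence[str]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    table = np.zeros((k, k))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    return table / table.sum()


def cohen_kappa(
    a: Sequence,
    b: Sequence,
    weighting: str = "none",
    categories: Sequence[str] = SEVERITY_ORDER,
) -> float:
    """Chance-corrected agreement between two label vectors.

    ``weighting="none"`` is classical Cohen's kappa; ``"equal"`` uses
    linearly (equally) spaced disagreement weights over the declared
    category order, giving partial credit to near-miss categories.

    When expected agreement is 1 (both raters use one shared category), the
    degenerate 0/0 is resolved to kappa = 1 for perfect agreement.
    """
    if weighting not in ("none", "equal"):
        raise ValueError("weighting must be 'none' or 'equal'")
    av, bv = _paired(a, b)
    used = sorted(set(av) | set(bv), key=list(categories).index)
    p = _contingency(av, bv, categories)
    k = len(categories)
    if weighting == "none":
        w = 1.0 - np.eye(k)
    else:
        ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
        w = np.abs(ii - jj) / max(k - 1, 1)
    row, col = p.sum(axis=1), p.sum(axis=0)
    expected = np.outer(row, col)
    do = float((w * p).sum())   # observed disagreement
    de = float((w * expected).sum())
    if de == 0.0:
        # both raters confined to one category: kappa 1 iff they agree
        return 1.0 if do == 0.0 and len(used) == 1 else 0.0
    return 1.0 - do / de


def simple_agreement(a: Sequence, b: Sequence) -> float:
    """Fraction of items with identical labels, in [0, 1]."""
    av, bv = _paired(a, b)
    return float(np.mean(av == bv))


def pairwise_kappa(
    panel: RaterPanel,
    weighting: str = "equal",
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Symmetric pairwise-kappa matrix and per-rater averages.

    Returns ``(matrix, avg, avg_vs_pathologists)``: per-rater averages
    exclude self; the second average restricts comparisons to pathologist
    partners, so an AI rater's score is comparable to the pathologists'.
    Raters with no usable ratings are dropped with a warning.
    """
    import warnings

    raters = [r for r in panel.raters if panel.ratings[r].notna().any()]
    dropped = set(panel.raters) - set(raters)
    if dropped:
        warnings.warn(f"raters with all-missing ratings excluded: {sorted(dropped)}")
    n = len(raters)
    mat = pd.DataFrame(np.eye(n), index=raters, columns=raters)
    for i in range(n):
        for j in range(i + 1, n):
            k = cohen_kappa(
                panel.ratings[raters[i]], panel.ratings[raters[j]],
                weighting=weighting, categories=panel.categories,
            )
            mat.iloc[i, j] = mat.iloc[j, i] = k
    avg = pd.Series(
        {r: (mat[r].sum() - 1.0) / (n - 1) for r in raters}, name="avg_kappa"
    )
    path_partners = [r for r in raters if r not in panel.ai_raters]
    avg_vs_path = pd.Series(
        {
            r: mat.loc[r, [p for p in path_partners if p != r]].mean()
            for r in raters
        },
        name="avg_kappa_vs_pathologists",
    )
    return mat, avg, avg_vs_path


def majority_vote(
    panel: RaterPanel,
    consensus_min: int | None = None,
) -> list[VoteResult]:
    """Per-item modal pattern over pathologist ratings with a consensus rule.

    AI raters never contribute to the vote.  Consensus is reached when the
    modal count is at least ``consensus_min`` (default: a strict majority of
    the panel's pathologists, i.e. 7 for 13).  Modal ties yield no
    consensus; mv1 is then chosen by higher clinical severity with the tie
    flagged.
    """
    voters = panel.pathologists
    if len(voters) < 2:
        raise ValueError("majority vote needs at least 2 non-AI raters")
    if consensus_min is None:
        consensus_min = len(voters) // 2 + 1
    if consensus_min > len(voters):
        raise ValueError("consensus_min exceeds the number of voting raters")
    severity = {c: i for i, c in enumerate(panel.categories)}
    out = []
    for item, row in panel.ratings[voters].iterrows():
        votes = row.dropna()
        counts = votes.value_counts().to_dict()
        if not counts:
            out.append(VoteResult(item, None, None, {}, False, 0))
            continue
        top = max(counts.values())
        modal = sorted((c for c, n in counts.items() if n == top),
                       key=lambda c: -severity[c])
        tie = len(modal) > 1
        mv1 = modal[0]
        rest = {c: n for c, n in counts.items() if c != mv1}
        mv2 = (max(rest, key=lambda c: (rest[c], severity[c])) if rest else None)
        consensus = (not tie) and top >= consensus_min
        out.append(VoteResult(item, mv1, mv2, counts, consensus, len(counts), tie))
    return out


def leave_one_out(
    panel: RaterPanel,
    target_rater: str,
    exclude: frozenset[str] | None = None,
    weighting: str = "equal",
    consensus_min: int | None = None,
) -> dict:
    """Compare one rater against the majority vote of the remaining raters.

    The target and any rater in ``exclude`` (by default all AI raters) are
    removed before voting; kappa and simple agreement are computed on items
    where the reduced vote reaches consensus.  Items without consensus are
    dropped and counted in the result.
    """
    exclude = exclude if exclude is not None else panel.ai_raters
    if target_rater in exclude:
        raise ValueError("target rater must not be in the exclusion set")
    keep = [r for r in panel.raters if r != target_rater and r not in exclude]
    if len(keep) < 2:
        raise ValueError("need at least 2 remaining raters for the reduced vote")
    reduced = RaterPanel(
        ratings=panel.ratings[keep], ai_raters=frozenset(), categories=panel.categories
    )
    votes = majority_vote(reduced, consensus_min=consensus_min)
    consensus_items = [v.item for v in votes if v.consensus]
    if not consensus_items:
        raise ValueError("no consensus items remain after leaving the target out")
    mv = pd.Series({v.item: v.mv1 for v in votes if v.consensus})
    target = panel.ratings.loc[consensus_items, target_rater]
    return {
        "target": target_rater,
        "kappa": cohen_kappa(target, mv, weighting=weighting, categories=panel.categories),
        "simple_agreement": simple_agreement(target, mv),
        "n_consensus_items": len(consensus_items),
        "n_dropped_no_consensus": len(votes) - len(consensus_items),
    }


def consensus_summary(votes: Sequence[VoteResult]) -> dict:
    """Counts of consensus vs no-consensus items, overall and per pattern."""
    by_pattern: dict[str, dict[str, int]] = {
        p: {"consensus": 0, "total": 0} for p in PATTERN_NAMES
    }
    n_cons = 0
    for v in votes:
        if v.mv1 is None:
            continue
        by_pattern[v.mv1]["total"] += 1
        if v.consensus:
            by_pattern[v.mv1]["consensus"] += 1
            n_cons += 1
    return {
        "n_items": len(votes),
        "n_consensus": n_cons,
        "n_no_consensus": len(votes) - n_cons,
        "by_pattern": by_pattern,
    }
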