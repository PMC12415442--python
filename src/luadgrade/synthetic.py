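"""Synthetic fixtures with known ground truth for every analysis module.

Three generators emulate the statistical structure of the study's inputs
without any real data:

* :func:`gen_mask_pair` — a blobby multi-class ground-truth label mask and
  a prediction derived from it by a known pixel-wise confusion matrix, for
  exercising segmentation metrics against an analytic truth.
* :func:`gen_rater_panel` — a panel of raters labelling items whose latent
  pattern is drawn from a prior, each rater filtered through their own
  confusion matrix; expected pairwise kappa has a closed form.
* :func:`gen_cohort` — case compositions tied to a latent prognostic group
  and survival times from a proportional-hazards model with independent
  censoring and mildly grade-correlated clinicopathological covariates.

All generators are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .agreement import RaterPanel
from .patterns import (
    DEFAULT_CODEBOOK,
    CaseComposition,
    LabelMask,
    PATTERN_NAMES,
    SEVERITY_ORDER,
    case_from_pct,
)
from .survival import SurvivalRecord

#: tier pairs (dominant, secondary) realising each prognostic group
_PG_TIER_PAIRS = {
    1: [(1, 2)],                # score 3a
    2: [(2, 1)],                # score 3b
    3: [(2, 2), (1, 3), (3, 1)],  # score 4
    4: [(2, 3), (3, 2)],        # score 5
    5: [(3, 3)],                # score 6
}
_TIER_MEMBERS = {
    1: ["lepidic"],
    2: ["acinar", "papillary"],
    3: ["micropapillary", "solid", "complex_glandular"],
}


def _neighbour_confusion(accuracy: float, order: Sequence[str] = SEVERITY_ORDER) -> np.ndarray:
    """Row-stochastic 6x6 matrix: ``accuracy`` on the diagonal, the
    remainder spread over the neighbouring categories in severity order
    (morphologically adjacent patterns are the likeliest confusions)."""
    k = len(order)
    m = np.zeros((k, k))
    for i in range(k):
        m[i, i] = accuracy
        nbrs = [j for j in (i - 1, i + 1) if 0 <= j < k]
        for j in nbrs:
            m[i, j] = (1.0 - accuracy) / len(nbrs)
    return m


@dataclass
class SimSpec:
    """Parameters of the synthetic study; defaults mirror the study's scale
    (13 raters x 283 items; 1000-case cohort in five prognostic groups)."""

    seed: int = 0
    # masks
    mask_size: int = 64
    n_blobs: int = 24
    background_frac: float = 0.15
    confusion: np.ndarray = field(default_factory=lambda: _neighbour_confusion(0.9))
    # rater panel
    n_items: int = 283
    n_raters: int = 13
    rater_accuracies: Sequence[float] | None = None  # default: spread 0.55..0.85
    item_prior: Sequence[float] = (0.10, 0.35, 0.12, 0.08, 0.20, 0.15)  # severity order
    # cohort
    n_cases: int = 1000
    group_probs: Sequence[float] = (0.2, 0.2, 0.2, 0.2, 0.2)  # PG1..PG5, balanced arms
    log_hr_step: float = 0.6
    baseline_hazard: float = np.log(2) / 60.0  # per month; median 60 mo in PG1
    censoring: float = 0.2
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=float)
        if self.confusion.shape != (6, 6) or not np.allclose(self.confusion.sum(axis=1), 1.0):
            raise ValueError("confusion must be a row-stochastic 6x6 matrix")
        if not (0.0 <= self.censoring < 1.0):
            raise ValueError("censoring must be in [0, 1)")
        if self.mask_size < 16:
            raise ValueError("mask_size must be at least 16")
        if not np.isclose(sum(self.item_prior), 1.0):
            raise ValueError("item_prior must sum to 1")


def gen_mask_pair(spec: SimSpec, rng: np.random.Generator | None = None) -> tuple[LabelMask, LabelMask, np.ndarray]:
    """Blobby ground-truth mask plus a confusion-corrupted prediction.

    Ground truth is built from nearest-seed (Voronoi) regions whose seeds
    carry random pattern codes (a fraction are background).  Each
    ground-truth pattern pixel is relabelled in the prediction according to
    the spec's confusion matrix; background pixels are left untouched.
    Returns (gt, pred, generating confusion matrix).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    s = spec.mask_size
    seeds = rng.uniform(0, s, size=(spec.n_blobs, 2))
    is_bg = rng.random(spec.n_blobs) < spec.background_frac
    seed_codes = rng.integers(1, 7, size=spec.n_blobs)
    seed_codes[is_bg] = 0
    yy, xx = np.mgrid[0:s, 0:s]
    _, nearest = cKDTree(seeds).query(np.column_stack([yy.ravel(), xx.ravel()]))
    gt = seed_codes[nearest].reshape(s, s).astype(np.uint8)

    pred = gt.copy()
    for code in range(1, 7):
        pix = gt == code
        n = int(pix.sum())
        if n:
            pred[pix] = rng.choice(np.arange(1, 7), size=n, p=spec.confusion[code - 1])
    return (
        LabelMask("gt", gt),
        LabelMask("pred", pred),
        spec.confusion.copy(),
    )


def _default_rater_confusions(spec: SimSpec) -> list[np.ndarray]:
    accs = (
        list(spec.rater_accuracies)
        if spec.rater_accuracies is not None
        else list(np.linspace(0.55, 0.85, spec.n_raters))
    )
    return [_neighbour_confusion(a) for a in accs]


def gen_rater_panel(
    spec: SimSpec,
) -> tuple[RaterPanel, pd.Series, list[np.ndarray]]:
    """Panel of raters labelling items with a latent true pattern.

    The latent pattern of each item is drawn from ``item_prior`` (over the
    severity order); each rater reports it through their own confusion
    matrix.  Returns (panel, latent truth, per-rater confusion matrices);
    the matrices allow closed-form expected kappas via
    :func:`expected_kappa`.
    """
    if spec.n_raters < 2:
        raise ValueError("need at least 2 raters")
    rng = np.random.default_rng(spec.seed)
    cats = list(SEVERITY_ORDER)
    confusions = _default_rater_confusions(spec)
    latent_idx = rng.choice(6, size=spec.n_items, p=np.asarray(spec.item_prior))
    items = [f"roi_{i:04d}" for i in range(spec.n_items)]
    data = {}
    for r, conf in enumerate(confusions):
        lab = np.empty(spec.n_items, dtype=object)
        for t in range(6):
            sel = latent_idx == t
            n = int(sel.sum())
            if n:
                lab[sel] = rng.choice(cats, size=n, p=conf[t])
        data[f"rater_{r + 1:02d}"] = lab
    panel = RaterPanel(ratings=pd.DataFrame(data, index=items))
    latent = pd.Series([cats[i] for i in latent_idx], index=items, name="latent")
    return panel, latent, confusions


def expected_kappa(
    prior: Sequence[float],
    conf_a: np.ndarray,
    conf_b: np.ndarray,
    weighting: str = "none",
) -> float:
    """Closed-form expected kappa between two raters with known confusion
    matrices over a shared latent-category prior."""
    pi = np.asarray(prior, dtype=float)
    joint = np.einsum("t,ti,tj->ij", pi, conf_a, conf_b)
    row, col = joint.sum(axis=1), joint.sum(axis=0)
    expected = np.outer(row, col)
    k = len(pi)
    if weighting == "none":
        w = 1.0 - np.eye(k)
    elif weighting == "equal":
        ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
        w = np.abs(ii - jj) / (k - 1)
    else:
        raise ValueError("weighting must be 'none' or 'equal'")
    return 1.0 - float((w * joint).sum()) / float((w * expected).sum())


def _sample_composition(rng: np.random.Generator, group: int) -> dict[str, float]:
    """Percent composition whose dominant/secondary tiers realise ``group``."""
    d_tier, s_tier = _PG_TIER_PAIRS[group][rng.integers(len(_PG_TIER_PAIRS[group]))]
    dom = _TIER_MEMBERS[d_tier][rng.integers(len(_TIER_MEMBERS[d_tier]))]
    sec_pool = [p for p in _TIER_MEMBERS[s_tier] if p != dom]
    sec = sec_pool[rng.integers(len(sec_pool))]
    while True:
        dom_share = rng.uniform(0.50, 0.70)
        sec_share = rng.uniform(0.15, min(0.30, dom_share - 0.05))
        rest = 1.0 - dom_share - sec_share
        others = [p for p in PATTERN_NAMES if p not in (dom, sec)]
        split = rng.dirichlet(np.ones(len(others)))
        shares = rest * split
        # keep the intended ordering: no bystander may rival the secondary
        if shares.max() < 0.9 * sec_share:
            pct = {dom: 100 * dom_share, sec: 100 * sec_share}
            pct.update({p: 100 * s for p, s in zip(others, shares)})
            return pct


def _censoring_rate_for(spec: SimSpec, hazards: np.ndarray) -> float:
    """Exponential censoring rate giving the target marginal censor fraction.

    With event time Exp(lam) and censor time Exp(mu), P(censored) =
    mu / (lam + mu); solve the mixture over the cohort's hazards for mu.
    """
    if spec.censoring == 0.0:
        return 0.0
    target = spec.censoring

    def f(mu: float) -> float:
        return float(np.mean(mu / (hazards + mu))) - target

    return brentq(f, 1e-9, 1e4)


def gen_cohort(
    spec: SimSpec,
) -> tuple[list[CaseComposition], list[SurvivalRecord], pd.Series]:
    """Cohort of cases with latent prognostic groups, compositions and
    proportional-hazards survival.

    Hazard for a case in group g is ``baseline_hazard * exp(log_hr_step *
    (g - 1))``; censoring is an independent exponential clock calibrated to
    the target marginal censoring fraction.  pT, pN and age are drawn with
    mild positive correlation to the latent group but carry no direct
    hazard effect.
    """
    if spec.n_cases < 10:
        raise ValueError("n_cases must be at least 10")
    rng = np.random.default_rng(spec.seed)
    groups = rng.choice(np.arange(1, 6), size=spec.n_cases, p=np.asarray(spec.group_probs))
    hazards = spec.baseline_hazard * np.exp(spec.log_hr_step * (groups - 1))
    mu = _censoring_rate_for(spec, hazards)

    event_t = rng.exponential(1.0 / hazards)
    censor_t = rng.exponential(1.0 / mu, size=spec.n_cases) if mu > 0 else np.full(spec.n_cases, np.inf)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)

    cohorts = np.array(["A", "B", "C", "D", "E"])[rng.integers(0, 5, spec.n_cases)]
    comps, records = [], []
    for i in range(spec.n_cases):
        g = int(groups[i])
        cid = f"case_{i:05d}"
        comps.append(case_from_pct(cid, _sample_composition(rng, g), DEFAULT_CODEBOOK))
        pT = 1 + int(rng.binomial(3, min(0.10 + 0.07 * (g - 1), 0.9)))
        pN = int(rng.binomial(2, min(0.08 + 0.05 * (g - 1), 0.9)))
        age = float(rng.normal(65.0 + 0.7 * (g - 1), 8.0))
        stage = "I" if (pT <= 2 and pN == 0) else ("II" if pN <= 1 else "III")
        records.append(
            SurvivalRecord(
                case_id=cid,
                endpoint=spec.endpoint,
                time=float(max(time[i], 1e-3)),
                event=int(event[i]),
                pT=pT,
                pN=pN,
                age=age,
                stage=stage,
                cohort=str(cohorts[i]),
            )
        )
    latent = pd.Series(groups, index=[r.case_id for r in records], name="latent_group")
    return comps, records, latent
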