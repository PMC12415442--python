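"""Rule engines for LUAD grading and prognostic scoring.

Six systems are implemented as explicit, provenance-carrying rules over a
case-level pattern composition:

* ``WHO`` — three tiers from the dominant pattern alone.
* ``IASLC`` — WHO base grade, upgraded to G3 when the summed abundance of
  high-grade patterns (micropapillary, solid, complex glandular) exceeds a
  threshold (default strictly > 20%).
* ``IASLC_SIMPLIFIED`` — IASLC with complex glandular removed from the
  upgrade sum (a dominant complex glandular pattern still grades G3).
* ``IASLC_MODIFIED`` — IASLC with the threshold raised to 50%.
* ``FOUR_TIER`` — dominant-pattern grading on four tiers, with complex
  glandular as an intermediate G3 between acinar/papillary and
  micropapillary/solid.
* ``PROG_SCORE`` — Gleason-style score: sum of the three-tier grades of the
  dominant and secondary pattern; score 3 split into 3a (1+2) and 3b (2+1);
  scores map to prognostic groups PG1..PG5 plus PG0 (score 2, purely
  lepidic, flagged as rarely relevant in routine diagnostics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .patterns import TIER3, TIER4, CaseComposition

HIGH_GRADE_PATTERNS = frozenset({"micropapillary", "solid", "complex_glandular"})

SYSTEMS = ("WHO", "IASLC", "IASLC_SIMPLIFIED", "IASLC_MODIFIED", "FOUR_TIER", "PROG_SCORE")

#: score -> prognostic group; score 3 is resolved via its 3a/3b sublabel
SCORE_GROUPS = {2: "PG0", "3a": "PG1", "3b": "PG2", 4: "PG3", 5: "PG4", 6: "PG5"}


@dataclass(frozen=True)
class GradingConfig:
    high_grade_set: frozenset[str] = HIGH_GRADE_PATTERNS
    high_grade_threshold_pct: float = 20.0  # strict greater-than
    tiers: int = 3
    min_secondary_pct: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.high_grade_threshold_pct <= 100.0):
            raise ValueError("threshold must lie in [0, 100]")
        if not self.high_grade_set:
            raise ValueError("high_grade_set must be non-empty")


@dataclass(frozen=True)
class GradeResult:
    system: str
    grade_label: str
    dominant: str
    secondary: str | None = None
    score: int | None = None
    score_sublabel: str | None = None
    base_grade: str | None = None
    upgraded: bool = False
    high_grade_pct: float = 0.0
    flags: tuple[str, ...] = field(default=())


def _require_dominant(comp: CaseComposition) -> str:
    if comp.dominant is None:
        raise ValueError(f"case {comp.case_id!r} has no resolved dominant pattern")
    return comp.dominant


def _high_grade_pct(comp: CaseComposition, patterns: Iterable[str]) -> float:
    return float(sum(comp.pct.get(p, 0.0) for p in patterns))


def grade_who(comp: CaseComposition) -> GradeResult:
    """Three-tier grade from the dominant pattern only."""
    dom = _require_dominant(comp)
    return GradeResult(
        system="WHO",
        grade_label=f"G{TIER3[dom]}",
        dominant=dom,
        secondary=comp.secondary,
        high_grade_pct=_high_grade_pct(comp, HIGH_GRADE_PATTERNS),
    )


def _graded_with_upgrade(comp: CaseComposition, cfg: GradingConfig, system: str) -> GradeResult:
    dom = _require_dominant(comp)
    base = f"G{TIER3[dom]}"
    hg = _high_grade_pct(comp, cfg.high_grade_set)
    if base in ("G1", "G2") and hg > cfg.high_grade_threshold_pct:
        return GradeResult(
            system=system,
            grade_label="G3",
            dominant=dom,
            secondary=comp.secondary,
            base_grade=base,
            upgraded=True,
            high_grade_pct=hg,
        )
    return GradeResult(
        system=system,
        grade_label=base,
        dominant=dom,
        secondary=comp.secondary,
        base_grade=base,
        upgraded=False,
        high_grade_pct=hg,
    )


def grade_iaslc(comp: CaseComposition, cfg: GradingConfig | None = None) -> GradeResult:
    """WHO base grade with G3 upgrade when high-grade patterns exceed 20%."""
    return _graded_with_upgrade(comp, cfg or GradingConfig(), "IASLC")


def grade_iaslc_simplified(comp: CaseComposition, cfg: GradingConfig | None = None) -> GradeResult:
    """IASLC variant excluding complex glandular from the upgrade sum."""
    base = cfg or GradingConfig()
    cfg2 = GradingConfig(
        high_grade_set=frozenset({"micropapillary", "solid"}),
        high_grade_threshold_pct=base.high_grade_threshold_pct,
        min_secondary_pct=base.min_secondary_pct,
    )
    return _graded_with_upgrade(comp, cfg2, "IASLC_SIMPLIFIED")


def grade_iaslc_modified(comp: CaseComposition, cfg: GradingConfig | None = None) -> GradeResult:
    """IASLC variant tolerating up to 50% non-dominant high-grade patterns."""
    base = cfg or GradingConfig()
    cfg2 = GradingConfig(
        high_grade_set=base.high_grade_set,
        high_grade_threshold_pct=50.0,
        min_secondary_pct=base.min_secondary_pct,
    )
    return _graded_with_upgrade(comp, cfg2, "IASLC_MODIFIED")


def grade_four_tier(comp: CaseComposition) -> GradeResult:
    """Four-tier dominant-pattern grade (complex glandular intermediate)."""
    dom = _require_dominant(comp)
    return GradeResult(
        system="FOUR_TIER",
        grade_label=f"G{TIER4[dom]}",
        dominant=dom,
        secondary=comp.secondary,
        high_grade_pct=_high_grade_pct(comp, HIGH_GRADE_PATTERNS),
    )


def score_prognostic(dominant: str, secondary: str, tiers: int = 3) -> GradeResult:
    """Gleason-style prognostic score: sum of dominant + secondary tiers.

    With ``tiers=3`` the score maps to prognostic groups (score 2 -> PG0,
    3a -> PG1, 3b -> PG2, 4 -> PG3, 5 -> PG4, 6 -> PG5).  ``tiers=4`` is the
    finer-grained variant; it returns the raw score without a group mapping,
    as no grouping is defined for it.
    """
    tier = TIER3 if tiers == 3 else TIER4
    if dominant not in tier or secondary not in tier:
        raise ValueError(f"unknown pattern: {dominant!r} / {secondary!r}")
    d, s = tier[dominant], tier[secondary]
    score = d + s
    sublabel = None
    flags: tuple[str, ...] = ()
    if tiers == 3:
        if (d, s) == (1, 2):
            sublabel = "3a"
        elif (d, s) == (2, 1):
            sublabel = "3b"
        label = SCORE_GROUPS[sublabel if sublabel else score]
        if label == "PG0":
            flags = ("purely_lepidic_score2",)
    else:
        label = f"S{score}"
        flags = ("four_tier_score_no_group_mapping",)
    return GradeResult(
        system="PROG_SCORE",
        grade_label=label,
        dominant=dominant,
        secondary=secondary,
        score=score,
        score_sublabel=sublabel,
        flags=flags,
    )


def grade_prognostic(comp: CaseComposition) -> GradeResult:
    """PROG_SCORE applied to a resolved case composition."""
    dom = _require_dominant(comp)
    sec = comp.secondary if comp.secondary is not None else dom
    res = score_prognostic(dom, sec)
    return GradeResult(
        system=res.system,
        grade_label=res.grade_label,
        dominant=dom,
        secondary=sec,
        score=res.score,
        score_sublabel=res.score_sublabel,
        high_grade_pct=_high_grade_pct(comp, HIGH_GRADE_PATTERNS),
        flags=res.flags + (("secondary_is_proxy",) if comp.secondary_is_proxy else ()),
    )


GRADERS = {
    "WHO": grade_who,
    "IASLC": grade_iaslc,
    "IASLC_SIMPLIFIED": grade_iaslc_simplified,
    "IASLC_MODIFIED": grade_iaslc_modified,
    "FOUR_TIER": grade_four_tier,
    "PROG_SCORE": grade_prognostic,
}


def grade_case(comp: CaseComposition, system: str) -> GradeResult:
    try:
        grader = GRADERS[system]
    except KeyError:
        raise ValueError(f"unknown grading system {system!r}; choose from {SYSTEMS}")
    return grader(comp)


def sweep_thresholds(
    cohort: Sequence[tuple[CaseComposition, "SurvivalRecord"]],
    thresholds: Sequence[float],
    system: str = "IASLC",
    endpoint: str = "OS",
) -> pd.DataFrame:
    """Systematically vary the high-grade upgrade threshold.

    For each threshold the cohort is re-graded with an IASLC-family rule at
    that cut-off and the resulting stratification is scored by a k-sample
    log-rank test and the concordance index of the grade order.  At
    threshold 100 no upgrade is possible and the grading degenerates to WHO.

    Returns one row per threshold: group sizes, log-rank chi-square and p,
    concordance index.
    """
    from lifelines.statistics import multivariate_logrank_test
    from lifelines.utils import concordance_index

    if system not in ("IASLC", "IASLC_SIMPLIFIED"):
        raise ValueError("threshold sweep applies to IASLC-family systems")
    hg_set = (
        HIGH_GRADE_PATTERNS
        if system == "IASLC"
        else frozenset({"micropapillary", "solid"})
    )
    missing = [r.case_id for _, r in cohort if r.endpoint != endpoint or r.time is None]
    if missing:
        raise ValueError(f"endpoint {endpoint} missing for cases: {missing}")

    times = np.array([r.time for _, r in cohort], dtype=float)
    events = np.array([r.event for _, r in cohort], dtype=int)
    rows = []
    for thr in thresholds:
        if not (0.0 <= thr <= 100.0):
            raise ValueError(f"threshold {thr} outside [0, 100]")
        cfg = GradingConfig(high_grade_set=hg_set, high_grade_threshold_pct=thr)
        grades = [_graded_with_upgrade(c, cfg, system).grade_label for c, _ in cohort]
        numeric = np.array([int(g[1]) for g in grades])
        sizes = {f"n_G{k}": int(np.sum(numeric == k)) for k in (1, 2, 3)}
        if len(set(grades)) >= 2:
            lr = multivariate_logrank_test(times, grades, events)
            stat, p = float(lr.test_statistic), float(lr.p_value)
        else:
            stat, p = float("nan"), float("nan")
        cidx = float(concordance_index(times, -numeric, events))
        rows.append({"threshold": float(thr), **sizes, "logrank_stat": stat, "logrank_p": p, "c_index": cidx})
    return pd.DataFrame(rows)
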