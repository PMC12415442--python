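"""Growth-pattern vocabulary and correction-weighted composition quantification.

Lung adenocarcinoma (LUAD) is graded from the architectural growth patterns
the tumor exhibits: lepidic, acinar, papillary, micropapillary, solid and
complex glandular (cribriform / fused glands).  This module defines the
pattern codebook (integer codes, grade tiers, severity order), converts
integer label masks into slide-level pattern compositions, and aggregates
slides into case-level compositions with a dominant / secondary pattern call.

Because the epithelial tumor component is denser in high-grade patterns than
in, e.g., lepidic areas, raw segmented pixel areas under-represent low-grade
patterns.  Pixel areas are therefore multiplied by pattern-specific
correction weights (derived from the tool's training distribution) before
percentages are formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

PATTERN_NAMES = (
    "lepidic",
    "acinar",
    "papillary",
    "micropapillary",
    "solid",
    "complex_glandular",
)

#: three-tier grade of each pattern (WHO/IASLC): G1 lepidic; G2 acinar,
#: papillary; G3 micropapillary, solid, complex glandular
TIER3 = {
    "lepidic": 1,
    "acinar": 2,
    "papillary": 2,
    "micropapillary": 3,
    "solid": 3,
    "complex_glandular": 3,
}

#: four-tier grade: complex glandular split out as an intermediate tier
#: between acinar/papillary and micropapillary/solid
TIER4 = {
    "lepidic": 1,
    "acinar": 2,
    "papillary": 2,
    "complex_glandular": 3,
    "micropapillary": 4,
    "solid": 4,
}

#: clinical severity order (ascending); used for deterministic tie-breaks
SEVERITY_ORDER = (
    "lepidic",
    "acinar",
    "papillary",
    "complex_glandular",
    "micropapillary",
    "solid",
)

#: correction multipliers on pattern pixel area
DEFAULT_WEIGHTS = {
    "lepidic": 1.41,
    "acinar": 1.35,
    "papillary": 1.06,
    "micropapillary": 1.14,
    "solid": 1.0,
    "complex_glandular": 1.10,
}


class InvalidCodeError(ValueError):
    """Raster contains a code absent from the codebook."""


class UnitMismatchError(ValueError):
    """Slides of one case mix physical and pixel units."""


@dataclass(frozen=True)
class PatternCodebook:
    """Maps integer raster codes to the six LUAD growth patterns.

    Parameters
    ----------
    code_to_name
        Mapping of raster code -> pattern name; exactly the six canonical
        patterns, codes unique and distinct from ``background_code``.
    background_code
        Code of non-tumor / unannotated pixels (default 0).
    severity_order
        Ascending clinical severity, used to break dominant-pattern ties
        toward the more aggressive pattern.
    """

    code_to_name: Mapping[int, str]
    background_code: int = 0
    severity_order: Sequence[str] = SEVERITY_ORDER

    def __post_init__(self) -> None:
        names = sorted(self.code_to_name.values())
        if names != sorted(PATTERN_NAMES):
            raise ValueError(
                f"codebook must contain exactly the six patterns {PATTERN_NAMES}, got {names}"
            )
        if self.background_code in self.code_to_name:
            raise ValueError("background_code collides with a pattern code")
        if sorted(self.severity_order) != sorted(PATTERN_NAMES):
            raise ValueError("severity_order must be a permutation of the six patterns")

    @property
    def name_to_code(self) -> dict[str, int]:
        return {v: k for k, v in self.code_to_name.items()}

    def severity_rank(self, name: str) -> int:
        return self.severity_order.index(name)

    def tier3(self, name: str) -> int:
        return TIER3[name]

    def tier4(self, name: str) -> int:
        return TIER4[name]


#: default coding: 0 background, then patterns in canonical order
DEFAULT_CODEBOOK = PatternCodebook(
    code_to_name={i + 1: n for i, n in enumerate(PATTERN_NAMES)},
    background_code=0,
)


@dataclass(frozen=True)
class CorrectionWeights:
    """Positive multipliers on pattern pixel area."""

    weight_by_pattern: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )

    def __post_init__(self) -> None:
        missing = set(PATTERN_NAMES) - set(self.weight_by_pattern)
        if missing:
            raise ValueError(f"weights missing for patterns: {sorted(missing)}")
        if any(w <= 0 for w in self.weight_by_pattern.values()):
            raise ValueError("all correction weights must be > 0")

    def __getitem__(self, name: str) -> float:
        return float(self.weight_by_pattern[name])

    @classmethod
    def unweighted(cls) -> "CorrectionWeights":
        """Identity weights: percentages become raw pixel fractions."""
        return cls({n: 1.0 for n in PATTERN_NAMES})


@dataclass
class LabelMask:
    """Single-channel integer raster of pattern codes plus background.

    ``mpp`` (microns per pixel) gives the physical scale; when present,
    weighted areas are reported in mm² (1 px = (mpp/1000)² mm²).
    """

    slide_id: str
    raster: np.ndarray
    mpp: float | None = None

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 2 or self.raster.size == 0:
            raise ValueError("raster must be a non-empty 2-D array")
        if self.mpp is not None and self.mpp <= 0:
            raise ValueError("mpp must be positive")


@dataclass
class SlideComposition:
    """Raw and correction-weighted pattern areas of one slide."""

    slide_id: str
    raw_pixels: dict[str, int]
    weighted_area: dict[str, float]
    pct: dict[str, float]
    background_pixels: int = 0
    mpp: float | None = None
    empty: bool = False  # true when the mask held no pattern pixels


@dataclass
class CaseComposition:
    """Area-pooled composition of all slides of one case."""

    case_id: str
    slide_ids: list[str]
    weighted_area: dict[str, float]
    pct: dict[str, float]
    dominant: str | None = None
    secondary: str | None = None
    secondary_is_proxy: bool = False
    empty: bool = False


def _pct_from_areas(area: Mapping[str, float]) -> dict[str, float]:
    total = sum(area.values())
    if total <= 0:
        return {n: 0.0 for n in PATTERN_NAMES}
    return {n: 100.0 * area[n] / total for n in PATTERN_NAMES}


def quantify_mask(
    mask: LabelMask,
    codebook: PatternCodebook = DEFAULT_CODEBOOK,
    weights: CorrectionWeights | None = None,
    apply_weights: bool = True,
) -> SlideComposition:
    """Convert a label mask into a correction-weighted slide composition.

    Background pixels are excluded from all totals.  Percentages are formed
    from the weighted areas (set ``apply_weights=False`` for raw-percent
    mode).  Raw pixel counts are preserved alongside.

    Raises
    ------
    InvalidCodeError
        If the raster contains a code not in the codebook.
    """
    if weights is None:
        weights = CorrectionWeights()
    counts = np.bincount(mask.raster.ravel().astype(np.int64))
    known = set(codebook.code_to_name) | {codebook.background_code}
    present = set(np.nonzero(counts)[0].tolist())
    bad = present - known
    if bad:
        raise InvalidCodeError(
            f"raster of slide {mask.slide_id!r} contains unknown code(s) {sorted(bad)}"
        )

    raw = {
        name: int(counts[code]) if code < len(counts) else 0
        for code, name in codebook.code_to_name.items()
    }
    background = (
        int(counts[codebook.background_code])
        if codebook.background_code < len(counts)
        else 0
    )

    px_area = 1.0 if mask.mpp is None else (mask.mpp / 1000.0) ** 2  # mm² per px
    weighted = {
        n: raw[n] * (weights[n] if apply_weights else 1.0) * px_area
        for n in PATTERN_NAMES
    }
    empty = sum(raw.values()) == 0
    return SlideComposition(
        slide_id=mask.slide_id,
        raw_pixels=raw,
        weighted_area=weighted,
        pct=_pct_from_areas(weighted),
        background_pixels=background,
        mpp=mask.mpp,
        empty=empty,
    )


def dominant_secondary(
    pct: Mapping[str, float],
    codebook: PatternCodebook = DEFAULT_CODEBOOK,
    min_secondary_pct: float = 5.0,
) -> tuple[str, str, bool]:
    """Resolve the dominant and secondary pattern from a percent composition.

    Dominant is the argmax of percentage, ties broken toward higher clinical
    severity.  Secondary is the next most abundant pattern with at least
    ``min_secondary_pct`` percent; if none qualifies, the Gleason convention
    applies (secondary := dominant) and the proxy flag is set.
    """
    items = [n for n in PATTERN_NAMES if pct.get(n, 0.0) > 0]
    if not items:
        raise ValueError("empty composition: no pattern has positive abundance")
    key = lambda n: (pct.get(n, 0.0), codebook.severity_rank(n))
    dominant = max(items, key=key)
    rest = [n for n in items if n != dominant and pct.get(n, 0.0) >= min_secondary_pct]
    if rest:
        return dominant, max(rest, key=key), False
    return dominant, dominant, True


def aggregate_case(
    compositions: Sequence[SlideComposition],
    case_id: str,
    codebook: PatternCodebook = DEFAULT_CODEBOOK,
    min_secondary_pct: float = 5.0,
) -> CaseComposition:
    """Pool slide compositions of one case by summing weighted areas.

    Percentages are recomputed from the pooled areas (area-weighted pooling,
    not a mean of slide percentages), so larger tumor areas dominate.  All
    slides must be in consistent units: either all carry an mpp (areas are
    mm²) or none does (areas are weighted pixels at one implicit scale).
    """
    if not compositions:
        raise ValueError("aggregate_case requires at least one slide composition")
    has_mpp = [c.mpp is not None for c in compositions]
    if any(has_mpp) and not all(has_mpp):
        raise UnitMismatchError(
            f"case {case_id!r} mixes slides with and without mpp; "
            "weighted areas are not in comparable units"
        )
    pooled = {
        n: float(sum(c.weighted_area[n] for c in compositions)) for n in PATTERN_NAMES
    }
    pct = _pct_from_areas(pooled)
    case = CaseComposition(
        case_id=case_id,
        slide_ids=[c.slide_id for c in compositions],
        weighted_area=pooled,
        pct=pct,
        empty=sum(pooled.values()) == 0,
    )
    if not case.empty:
        dom, sec, proxy = dominant_secondary(pct, codebook, min_secondary_pct)
        case.dominant, case.secondary, case.secondary_is_proxy = dom, sec, proxy
    return case


def case_from_pct(
    case_id: str,
    pct: Mapping[str, float],
    codebook: PatternCodebook = DEFAULT_CODEBOOK,
    min_secondary_pct: float = 5.0,
) -> CaseComposition:
    """Build a CaseComposition directly from a percent composition.

    Convenience for table-driven workflows where only percentages are known;
    weighted areas are set equal to the percentages.
    """
    full = {n: float(pct.get(n, 0.0)) for n in PATTERN_NAMES}
    total = sum(full.values())
    if total > 0:
        full = {n: 100.0 * v / total for n, v in full.items()}
    case = CaseComposition(
        case_id=case_id,
        slide_ids=[],
        weighted_area=dict(full),
        pct=full,
        empty=total <= 0,
    )
    if not case.empty:
        dom, sec, proxy = dominant_secondary(full, codebook, min_secondary_pct)
        case.dominant, case.secondary, case.secondary_is_proxy = dom, sec, proxy
    return case
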