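"""Readers and writers for masks, composition / rater / survival tables.

Masks are single-channel 8-bit PNG or TIFF rasters of codebook codes.
Tables are CSV/TSV via pandas.  Row-level validation problems are collected
and reported together with line numbers; a run aborts on them unless
``skip_bad`` is set.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .agreement import RaterPanel
from .patterns import (
    DEFAULT_CODEBOOK,
    DEFAULT_WEIGHTS,
    CaseComposition,
    CorrectionWeights,
    LabelMask,
    PATTERN_NAMES,
    PatternCodebook,
    case_from_pct,
)
from .survival import SurvivalRecord


class TableValidationError(ValueError):
    """One or more rows failed validation; message lists line numbers."""


def read_mask(path: str | Path, slide_id: str | None = None, mpp: float | None = None) -> LabelMask:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        raster = tifffile.imread(path)
    else:
        from PIL import Image

        raster = np.asarray(Image.open(path))
    if raster.ndim == 3:  # tolerate an accidental grayscale-as-RGB export
        if not (raster[..., 0] == raster[..., 1]).all():
            raise ValueError(f"{path} is multi-channel; expected a label raster")
        raster = raster[..., 0]
    return LabelMask(slide_id or path.stem, raster.astype(np.int64), mpp=mpp)


def write_mask(path: str | Path, mask: LabelMask) -> None:
    path = Path(path)
    arr = mask.raster.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr, mode="L").save(path)


def read_codebook(path: str | Path) -> PatternCodebook:
    """Codebook config: YAML with ``codes: {name: code}`` and optional
    ``background_code`` / ``severity_order``."""
    cfg = yaml.safe_load(Path(path).read_text())
    codes = {int(v): str(k) for k, v in cfg["codes"].items()}
    return PatternCodebook(
        code_to_name=codes,
        background_code=int(cfg.get("background_code", 0)),
        severity_order=tuple(cfg.get("severity_order", DEFAULT_CODEBOOK.severity_order)),
    )


def read_weights(path: str | Path) -> CorrectionWeights:
    cfg = yaml.safe_load(Path(path).read_text())
    return CorrectionWeights({str(k): float(v) for k, v in cfg.items()})


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def read_composition_table(
    path: str | Path,
    codebook: PatternCodebook = DEFAULT_CODEBOOK,
    weights: CorrectionWeights | None = None,
    skip_bad: bool = False,
    renorm_tolerance: float = 1.0,
) -> list[CaseComposition]:
    """Long-format composition CSV: case_id, [slide_id,] pattern, pixels|pct.

    Pixel counts are correction-weighted and pooled over slides per case;
    percent tables are renormalized when the per-case sum deviates from 100
    by at most ``renorm_tolerance`` (a warning is emitted), and rejected
    beyond it.
    """
    import warnings

    df = _read_table(path)
    required = {"case_id", "pattern"}
    if not required <= set(df.columns):
        raise TableValidationError(f"missing required columns: {sorted(required - set(df.columns))}")
    value_col = "pixels" if "pixels" in df.columns else "pct"
    if value_col not in df.columns:
        raise TableValidationError("need a 'pixels' or 'pct' column")
    if weights is None:
        weights = CorrectionWeights()

    errors = []
    for i, row in df.iterrows():
        if row["pattern"] not in PATTERN_NAMES:
            errors.append(f"line {i + 2}: unknown pattern {row['pattern']!r}")
        if not np.isfinite(pd.to_numeric(row[value_col], errors="coerce")):
            errors.append(f"line {i + 2}: malformed numeric {row[value_col]!r}")
    if errors and not skip_bad:
        raise TableValidationError("; ".join(errors))
    if errors:
        bad = df["pattern"].isin(PATTERN_NAMES) & pd.to_numeric(df[value_col], errors="coerce").notna()
        df = df[bad]
    df[value_col] = pd.to_numeric(df[value_col])

    cases = []
    for cid, sub in df.groupby("case_id", sort=True):
        agg = sub.groupby("pattern")[value_col].sum()
        if value_col == "pixels":
            area = {p: float(agg.get(p, 0.0)) * weights[p] for p in PATTERN_NAMES}
            total = sum(area.values())
            pct = {p: (100.0 * a / total if total else 0.0) for p, a in area.items()}
        else:
            pct = {p: float(agg.get(p, 0.0)) for p in PATTERN_NAMES}
            s = sum(pct.values())
            if abs(s - 100.0) > renorm_tolerance and s > 0:
                msg = f"case {cid!r}: pct sums to {s:.3f}, outside tolerance {renorm_tolerance}"
                if skip_bad:
                    warnings.warn(msg + "; skipped")
                    continue
                raise TableValidationError(msg)
            if s > 0 and abs(s - 100.0) > 1e-9:
                warnings.warn(f"case {cid!r}: pct sums to {s:.3f}; renormalized")
        cases.append(case_from_pct(str(cid), pct, codebook))
    return cases


def write_composition_table(path: str | Path, cases: Sequence[CaseComposition]) -> None:
    rows = [
        {"case_id": c.case_id, "pattern": p, "pct": c.pct[p], "weighted_area": c.weighted_area[p]}
        for c in cases
        for p in PATTERN_NAMES
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rater_table(
    path: str | Path,
    mapping: Mapping | None = None,
    codebook: PatternCodebook = DEFAULT_CODEBOOK,
) -> RaterPanel:
    """Wide rater CSV: first column item id, one column per rater.

    ``mapping`` adapts foreign layouts: keys ``item_col``, ``rater_cols``
    (list, default: all other columns), ``label_map`` (raw value ->
    canonical pattern name; integer codes resolved via the codebook),
    ``ai_raters``.
    """
    df = _read_table(path)
    mapping = dict(mapping or {})
    item_col = mapping.get("item_col", df.columns[0])
    rater_cols = mapping.get("rater_cols", [c for c in df.columns if c != item_col])
    label_map = {str(k): v for k, v in mapping.get("label_map", {}).items()}
    code_names = {str(k): v for k, v in codebook.code_to_name.items()}

    def canon(v):
        if pd.isna(v):
            return None
        s = str(v).strip()
        if s in label_map:
            return label_map[s]
        if s in code_names:
            return code_names[s]
        low = s.lower().replace(" ", "_")
        if low in PATTERN_NAMES:
            return low
        raise TableValidationError(f"unresolvable label {v!r} in rater table")

    ratings = df.set_index(item_col)[list(rater_cols)].map(canon)
    return RaterPanel(ratings=ratings, ai_raters=frozenset(mapping.get("ai_raters", ())))


def read_survival_table(path: str | Path, skip_bad: bool = False) -> list[SurvivalRecord]:
    """Survival CSV with columns case_id, endpoint, time, event and optional
    pT, pN, age, stage, cohort."""
    df = _read_table(path)
    records, errors = [], []
    for i, row in df.iterrows():
        try:
            records.append(
                SurvivalRecord(
                    case_id=str(row["case_id"]),
                    endpoint=str(row["endpoint"]),
                    time=float(row["time"]),
                    event=int(row["event"]),
                    pT=None if pd.isna(row.get("pT")) else int(row["pT"]),
                    pN=None if pd.isna(row.get("pN")) else int(row["pN"]),
                    age=None if pd.isna(row.get("age")) else float(row["age"]),
                    stage=None if pd.isna(row.get("stage")) else str(row["stage"]),
                    cohort="" if pd.isna(row.get("cohort")) else str(row["cohort"]),
                )
            )
        except (ValueError, KeyError, TypeError) as exc:
            errors.append(f"line {i + 2}: {exc}")
    if errors and not skip_bad:
        raise TableValidationError("; ".join(errors))
    return records


def write_survival_table(path: str | Path, records: Sequence[SurvivalRecord]) -> None:
    from .survival import records_to_frame

    records_to_frame(records).to_csv(path, index=False)


def config_digest(config: Mapping) -> str:
    """Stable short hash of a configuration mapping, embedded in reports."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_json_report(path: str | Path, payload: Mapping, config: Mapping | None = None) -> None:
    out = dict(payload)
    if config is not None:
        out["_config_digest"] = config_digest(config)
    Path(path).write_text(json.dumps(out, indent=2, default=str))
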