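"""File formats: annotation JSON, binary-mask PNG/TIFF, reports, rule tables.

Annotation files are JSON documents::

    {
      "image_id": "case-01",
      "height": 256, "width": 256,
      "source": "reference",            // or "marked"
      "pathologies": {
        "microaneurysm":  [{"contour": [[r, c], ...]}, ...],
        "hemorrhage":     [{"mask_file": "hemorrhage.png"}],
        "soft_exudate":   [],
        "hard_exudate":   []
      }
    }

All four pathology keys must be present. Contour records are rasterized,
sealed by the dilation/closing/hole-filling morphology and componentized;
mask-file records (8-bit single-channel PNG or TIFF, any nonzero pixel =
lesion, paths relative to the JSON file) are loaded and componentized as-is.
Reports serialize deterministically: identical inputs and config give
byte-identical JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from PIL import Image

from .feedback import FeedbackCategory, FeedbackReport, LesionRef, PathologyFeedback
from .geometry import (
    AnnotationSet,
    ImageGrid,
    Lesion,
    MorphologyConfig,
    PathologyClass,
    Source,
    close_and_fill,
    extract_lesions,
    lesions_to_mask,
    rasterize_contours,
)
from .grading import GRADE_LABELS, GradingRule, GradingRuleTable

__all__ = [
    "InputError",
    "ConfigError",
    "read_mask",
    "write_mask",
    "read_annotation",
    "write_annotation",
    "report_to_dict",
    "report_from_dict",
    "write_report_json",
    "read_report_json",
    "write_report_csv",
    "load_rule_table",
    "write_rule_table",
]


class InputError(ValueError):
    """Malformed or inconsistent user input (file, schema, coordinates)."""


class ConfigError(ValueError):
    """Invalid configuration (e.g. a malformed grading rule table)."""


# ---------------------------------------------------------------------------
# masks


def read_mask(path: str | Path) -> np.ndarray:
    """Load an 8-bit single-channel PNG/TIFF mask; nonzero = lesion."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"mask file not found: {path}")
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"))
    return arr > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit PNG/TIFF (255 = lesion)."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)


# ---------------------------------------------------------------------------
# annotation JSON


def _require(doc: dict, key: str, pointer: str, path: Path) -> Any:
    if key not in doc:
        raise InputError(f"{path}: missing {pointer}/{key}")
    return doc[key]


def read_annotation(
    path: str | Path, morphology: MorphologyConfig | None = None
) -> AnnotationSet:
    """Read an annotation JSON file into an :class:`AnnotationSet`.

    Contour records pass through the full sealing morphology; mask records
    are componentized directly. Lesions come out in canonical order.
    """
    path = Path(path)
    morphology = morphology or MorphologyConfig()
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise InputError(f"{path}: top-level document must be an object")

    image_id = _require(doc, "image_id", "", path)
    height = _require(doc, "height", "", path)
    width = _require(doc, "width", "", path)
    source_name = _require(doc, "source", "", path)
    pathologies = _require(doc, "pathologies", "", path)
    try:
        grid = ImageGrid(int(height), int(width))
        source = Source(source_name)
    except ValueError as exc:
        raise InputError(f"{path}: {exc}") from exc

    lesions: dict[PathologyClass, list[Lesion]] = {}
    for pathology in PathologyClass:
        key = pathology.value
        if key not in pathologies:
            raise InputError(f"{path}: missing /pathologies/{key}")
        records = pathologies[key]
        if not isinstance(records, list):
            raise InputError(f"{path}: /pathologies/{key} must be a list")

        union = np.zeros((grid.height, grid.width), dtype=bool)
        contours = []
        for i, record in enumerate(records):
            pointer = f"/pathologies/{key}/{i}"
            if not isinstance(record, dict) or not (
                ("contour" in record) ^ ("mask_file" in record)
            ):
                raise InputError(
                    f"{path}: {pointer} must contain exactly one of "
                    "'contour' or 'mask_file'"
                )
            if "contour" in record:
                contour = record["contour"]
                if not contour:
                    raise InputError(f"{path}: {pointer}/contour is empty")
                contours.append([(int(r), int(c)) for r, c in contour])
            else:
                mask_path = Path(record["mask_file"])
                if not mask_path.is_absolute():
                    mask_path = path.parent / mask_path
                mask = read_mask(mask_path)
                if mask.shape != (grid.height, grid.width):
                    raise InputError(
                        f"{path}: {pointer}/mask_file has shape "
                        f"{mask.shape}, expected {(grid.height, grid.width)}"
                    )
                union |= mask
        if contours:
            try:
                drawn = rasterize_contours(contours, grid)
            except ValueError as exc:
                raise InputError(f"{path}: /pathologies/{key}: {exc}") from exc
            union |= close_and_fill(drawn, morphology)
        lesions[pathology] = extract_lesions(union, pathology, morphology)

    return AnnotationSet(image_id=str(image_id), grid=grid, source=source, lesions=lesions)


def write_annotation(
    aset: AnnotationSet, json_path: str | Path, mask_dir: str | Path | None = None
) -> None:
    """Write an annotation set as JSON plus one mask PNG per pathology.

    Mask files land next to the JSON (or in ``mask_dir``) and are referenced
    relatively, so the directory relocates as a unit.
    """
    json_path = Path(json_path)
    mask_dir = Path(mask_dir) if mask_dir is not None else json_path.parent
    mask_dir.mkdir(parents=True, exist_ok=True)

    pathologies: dict[str, list[dict]] = {}
    for pathology in PathologyClass:
        items = aset.lesions[pathology]
        if not items:
            pathologies[pathology.value] = []
            continue
        mask = lesions_to_mask(items, aset.grid)
        name = f"{aset.image_id}_{aset.source.value}_{pathology.value}.png"
        write_mask(mask, mask_dir / name)
        rel = (mask_dir / name).relative_to(json_path.parent) if mask_dir != json_path.parent else Path(name)
        pathologies[pathology.value] = [{"mask_file": str(rel)}]

    doc = {
        "image_id": aset.image_id,
        "height": aset.grid.height,
        "width": aset.grid.width,
        "source": aset.source.value,
        "pathologies": pathologies,
    }
    json_path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# feedback reports


def report_to_dict(report: FeedbackReport) -> dict:
    """Deterministic, JSON-ready representation of a feedback report."""
    return {
        "image_id": report.image_id,
        "config": report.config,
        "pathologies": [
            {
                "pathology": p.value,
                "n_reference": fb.n_reference,
                "n_marked": fb.n_marked,
                "n_correct": fb.n_correct,
                "n_false": fb.n_false,
                "n_missed": fb.n_missed,
                "percent_found": fb.percent_found,
                "lesions": {
                    cat.value: [asdict(ref) | {"category": ref.category.value} for ref in refs]
                    for cat, refs in sorted(
                        fb.lesion_lists.items(), key=lambda kv: kv[0].value
                    )
                },
            }
            for p, fb in ((p, report.pathologies[p]) for p in PathologyClass)
        ],
    }


def report_from_dict(doc: dict) -> FeedbackReport:
    pathologies: dict[PathologyClass, PathologyFeedback] = {}
    for entry in doc["pathologies"]:
        pathology = PathologyClass(entry["pathology"])
        lists = {}
        for cat_name, refs in entry["lesions"].items():
            cat = FeedbackCategory(cat_name)
            lists[cat] = [
                LesionRef(
                    category=FeedbackCategory(r["category"]),
                    origin=r["origin"],
                    index=r["index"],
                    color=r["color"],
                    iou=r["iou"],
                    paired_with=r["paired_with"],
                )
                for r in refs
            ]
        pathologies[pathology] = PathologyFeedback(
            pathology=pathology,
            n_reference=entry["n_reference"],
            n_marked=entry["n_marked"],
            n_correct=entry["n_correct"],
            n_false=entry["n_false"],
            n_missed=entry["n_missed"],
            percent_found=entry["percent_found"],
            lesion_lists=lists,
        )
    return FeedbackReport(
        image_id=doc["image_id"], pathologies=pathologies, config=doc.get("config", {})
    )


def write_report_json(report: FeedbackReport, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n"
    )


def read_report_json(path: str | Path) -> FeedbackReport:
    return report_from_dict(json.loads(Path(path).read_text()))


def write_report_csv(report: FeedbackReport, path: str | Path) -> None:
    """Flat per-pathology CSV mirroring the report counts."""
    rows = [
        {
            "image_id": report.image_id,
            "pathology": p.value,
            "n_reference": fb.n_reference,
            "n_marked": fb.n_marked,
            "n_correct": fb.n_correct,
            "n_false": fb.n_false,
            "n_missed": fb.n_missed,
            "percent_found": fb.percent_found,
        }
        for p, fb in ((p, report.pathologies[p]) for p in PathologyClass)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# grading rule tables


def load_rule_table(path: str | Path) -> GradingRuleTable:
    """Load and validate a grading rule table from JSON.

    Schema: ``{"default_grade": 0, "rules": [{"name", "grade",
    "min_counts": {class: n}, "require_proliferative": bool,
    "only": [class, ...]}, ...]}``; rules apply first-match in file order.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"rule table not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
    try:
        rules = []
        for r in doc.get("rules", []):
            min_counts = {
                PathologyClass(k): int(v) for k, v in r.get("min_counts", {}).items()
            }
            only = r.get("only")
            rules.append(
                GradingRule(
                    name=str(r["name"]),
                    grade=int(r["grade"]),
                    min_counts=min_counts,
                    require_proliferative=bool(r.get("require_proliferative", False)),
                    only=frozenset(PathologyClass(p) for p in only)
                    if only is not None
                    else None,
                )
            )
        return GradingRuleTable(
            rules=tuple(rules), default_grade=int(doc.get("default_grade", 0))
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(f"{path}: invalid rule table ({exc})") from exc


def write_rule_table(table: GradingRuleTable, path: str | Path) -> None:
    doc = {
        "default_grade": table.default_grade,
        "rules": [
            {
                "name": r.name,
                "grade": r.grade,
                "min_counts": {p.value: n for p, n in sorted(
                    r.min_counts.items(), key=lambda kv: kv[0].value
                )},
                "require_proliferative": r.require_proliferative,
                **({"only": sorted(p.value for p in r.only)} if r.only is not None else {}),
            }
            for r in table.rules
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
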