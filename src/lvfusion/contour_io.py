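"""Versioned JSON contour interchange format.

The method consumes segmented contours, not images, so the interchange
format stores 2-D in-plane point lists together with an explicit plane frame
(origin + orthonormal axis_u/axis_v, DICOM-style) per contour — plane
membership is true by construction.  Units are millimetres throughout.
Unknown fields are preserved on round-trip; records that violate the schema
are reported together with their indices.

The published JSON schema ships with the package
(``lvfusion/schema/contour_file.schema.json``).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .chunks import ContourStack
from .errors import ContourFileError
from .geometry import ImagePlane, PlanarContour

SCHEMA_VERSION = "1.0"


class PlaneModel(BaseModel):
    model_config = ConfigDict(extra="allow")
    origin: list[float] = Field(min_length=3, max_length=3)
    axis_u: list[float] = Field(min_length=3, max_length=3)
    axis_v: list[float] = Field(min_length=3, max_length=3)


class ViewModel(BaseModel):
    model_config = ConfigDict(extra="allow")
    type: Literal["SAX", "LAX"]
    slice_index: int | None = None
    label: str | None = None


class ContourRecord(BaseModel):
    model_config = ConfigDict(extra="allow")
    plane: PlaneModel
    points: list[list[float]] = Field(min_length=3)
    surface: Literal["endocardium", "epicardium"]
    phase: Literal["ED", "ES"]
    view: ViewModel


class ContourFileModel(BaseModel):
    model_config = ConfigDict(extra="allow")
    schema_version: str
    subject_id: str
    slice_thickness_mm: float | None = None
    inter_slice_gap_mm: float | None = None
    contours: list[ContourRecord]


def contour_file_schema() -> dict:
    """The JSON schema the interchange format validates against."""
    with resources.files("lvfusion").joinpath(
        "schema/contour_file.schema.json"
    ).open("r", encoding="utf-8") as fh:
        return json.load(fh)


def _stack_key(record: ContourRecord) -> tuple[str, str]:
    return (record.phase, record.surface)


def read_contours(path: str | Path) -> dict[tuple[str, str], ContourStack]:
    """Read a contour file into typed stacks keyed by (phase, surface).

    Raises :class:`ContourFileError` listing every offending record on
    schema violations (including duplicated SAX slice indices).
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ContourFileError(f"{path}: not valid JSON: {exc}") from exc
    try:
        model = ContourFileModel.model_validate(raw)
    except ValidationError as exc:
        locs = sorted({str(e["loc"]) for e in exc.errors()})
        raise ContourFileError(
            f"{path}: schema violation at {', '.join(locs)}"
        ) from exc

    groups: dict[tuple[str, str], dict[str, list]] = {}
    problems: list[str] = []
    for idx, rec in enumerate(model.contours):
        key = _stack_key(rec)
        g = groups.setdefault(key, {"sax": [], "lax": []})
        plane = ImagePlane(np.array(rec.plane.origin), np.array(rec.plane.axis_u),
                           np.array(rec.plane.axis_v))
        if rec.view.type == "SAX":
            if rec.view.slice_index is None:
                problems.append(f"record {idx}: SAX contour without slice_index")
                continue
            contour = PlanarContour(plane, np.array(rec.points), surface=rec.surface,
                                    phase=rec.phase, slice_index=rec.view.slice_index)
            g["sax"].append((rec.view.slice_index, idx, contour))
        else:
            contour = PlanarContour(plane, np.array(rec.points), surface=rec.surface,
                                    phase=rec.phase)
            g["lax"].append((idx, contour, rec.view.label))

    stacks: dict[tuple[str, str], ContourStack] = {}
    for key, g in groups.items():
        indices = [i for i, _, _ in g["sax"]]
        dupes = {i for i in indices if indices.count(i) > 1}
        if dupes:
            offending = [rec_idx for i, rec_idx, _ in g["sax"] if i in dupes]
            problems.append(
                f"{key}: duplicated SAX slice_index {sorted(dupes)} "
                f"(records {offending})"
            )
            continue
        if len(g["lax"]) > 1:
            problems.append(f"{key}: more than one LAX contour per stack")
            continue
        sax = [c for _, _, c in sorted(g["sax"], key=lambda t: t[0])]
        lax = g["lax"][0][1] if g["lax"] else None
        if not sax:
            problems.append(f"{key}: no SAX contours")
            continue
        stacks[key] = ContourStack(
            sax=sax,
            lax=lax,
            slice_thickness=model.slice_thickness_mm,
            inter_slice_gap=model.inter_slice_gap_mm,
            metadata={"subject_id": model.subject_id},
        )
    if problems:
        raise ContourFileError(f"{path}: " + "; ".join(problems))
    return stacks


def write_contours(
    stacks: dict[tuple[str, str], ContourStack] | ContourStack,
    path: str | Path,
    subject_id: str = "anonymous",
    extra_fields: dict | None = None,
) -> None:
    """Serialize stacks to the JSON interchange format (deterministic output)."""
    if isinstance(stacks, ContourStack):
        stacks = {(stacks.phase_label(), stacks.surface_label()): stacks}
    records = []
    t = l = None
    for (_phase, _surface), stack in sorted(stacks.items()):
        t = stack.slice_thickness if t is None else t
        l = stack.inter_slice_gap if l is None else l
        for c in stack.sax:
            records.append(_record_dict(c, view={"type": "SAX",
                                                 "slice_index": c.slice_index}))
        if stack.lax is not None:
            label = stack.metadata.get("lax_label", "LAX")
            records.append(_record_dict(stack.lax, view={"type": "LAX", "label": label}))
    doc = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": subject_id,
        "units": "mm",
        "slice_thickness_mm": t,
        "inter_slice_gap_mm": l,
        "contours": records,
    }
    if extra_fields:
        doc.update(extra_fields)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True),
                          encoding="utf-8")


def _record_dict(contour: PlanarContour, view: dict) -> dict:
    return {
        "plane": {
            "origin": contour.plane.origin.tolist(),
            "axis_u": contour.plane.axis_u.tolist(),
            "axis_v": contour.plane.axis_v.tolist(),
        },
        "points": np.asarray(contour.points).tolist(),
        "surface": contour.surface,
        "phase": contour.phase,
        "view": view,
    }
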