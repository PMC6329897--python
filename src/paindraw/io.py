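"""On-disk formats: drawing sessions, templates, cohorts, NIfTI export.

Formats
-------
Template directory::

    template/
      manifest.json          {"format": "paindraw-template/1", "sex_variant": ...,
                              "views": {"front": {"outline": ..., "regions": ...,
                                                  "height": ..., "width": ...}, ...}}
      front_outline.png      8-bit grayscale, 255 inside the outline
      front_regions.png      8-bit grayscale, gray value = region label 0..19
      ...

Session directory (one drawing)::

    S001/patient/
      manifest.json          {"format": "paindraw-session/1", "subject_id": ...,
                              "role": ..., "layers": [{"descriptor": ...,
                              "intensity": ..., "depth": ..., "files": {...}}]}
      layer00_front.png      8-bit grayscale; gray g > 0 marks a drawn pixel and
      ...                    encodes the layer's VAS intensity as g / 255 * 10

Views absent from a layer's ``files`` map are empty in that layer.  The PNG
gray value is authoritative for intensity on read (the manifest repeats it
for readability); one write/read cycle quantizes intensity to 8 bits and is
idempotent afterwards.

Cohort directory::

    cohort/
      template/...
      sessions/S001/patient/..., sessions/S001/doctor/...
      ratings.csv            subject_id, understanding_rating, decision_rating,
                             nrs_intensity (empty cell = missing)
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image

from .model import (
    BodyTemplate,
    CohortRecord,
    PainDrawing,
    SymptomLayer,
    PAIN_DESCRIPTORS,
    DimensionError,
    validate_drawing,
)
from .stats import AverageMap
from .simulate import RatingModel, SimulationConfig

TEMPLATE_FORMAT = "paindraw-template/1"
SESSION_FORMAT = "paindraw-session/1"


class MissingFileError(FileNotFoundError):
    """A file referenced by a manifest does not exist."""


class UnknownDescriptorError(ValueError):
    """A layer descriptor outside the pain vocabulary, in strict mode."""


class FormatError(ValueError):
    """Unrecognized manifest format tag or malformed manifest."""


def _read_gray(path: Path) -> np.ndarray:
    if not path.exists():
        raise MissingFileError(str(path))
    return np.asarray(Image.open(path).convert("L"))


def _write_gray(arr: np.ndarray, path: Path) -> None:
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


def intensity_to_gray(intensity: float) -> int:
    """VAS [0, 10] -> 8-bit gray (linear)."""
    return int(round(intensity / 10.0 * 255.0))


def gray_to_intensity(gray: int) -> float:
    """8-bit gray -> VAS [0, 10] (linear)."""
    return gray / 255.0 * 10.0


# ---------------------------------------------------------------------------
# Template


def write_template(template: BodyTemplate, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    views = {}
    for view in template.views:
        h, w = template.shape(view)
        outline_f = f"{view}_outline.png"
        regions_f = f"{view}_regions.png"
        _write_gray(template.outline[view].astype(np.uint8) * 255, path / outline_f)
        _write_gray(template.region_labels[view], path / regions_f)
        views[view] = {"outline": outline_f, "regions": regions_f,
                       "height": h, "width": w}
    manifest = {"format": TEMPLATE_FORMAT, "sex_variant": template.sex_variant,
                "views": views}
    mpath = path / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_template(path: Union[str, Path]) -> BodyTemplate:
    path = Path(path)
    mpath = path / "manifest.json" if path.is_dir() else path
    if not mpath.exists():
        raise MissingFileError(str(mpath))
    manifest = json.loads(mpath.read_text())
    if manifest.get("format") != TEMPLATE_FORMAT:
        raise FormatError(f"unrecognized template format {manifest.get('format')!r}")
    base = mpath.parent
    outline, regions = {}, {}
    for view, entry in manifest["views"].items():
        o = _read_gray(base / entry["outline"]) > 127
        r = _read_gray(base / entry["regions"]).astype(np.int32)
        if o.shape != (entry["height"], entry["width"]):
            raise DimensionError(
                f"view {view!r}: outline {o.shape} != manifest "
                f"({entry['height']}, {entry['width']})"
            )
        outline[view] = o
        regions[view] = r
    return BodyTemplate(outline=outline, region_labels=regions,
                        sex_variant=manifest.get("sex_variant", "neutral"))


# ---------------------------------------------------------------------------
# Sessions


def write_session(
    drawing: PainDrawing, template: BodyTemplate, path: Union[str, Path]
) -> Path:
    """Write one drawing session; returns the manifest path.

    The drawing is strict-validated first; a layer with no drawn pixel in any
    view is rejected.  Nothing is written on failure.
    """
    validate_drawing(drawing, template, mode="strict")
    for i, layer in enumerate(drawing.layers):
        if layer.pixels() == 0:
            raise ValueError(f"layer {i} ({layer.descriptor!r}) is empty")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, layer in enumerate(drawing.layers):
        gray = intensity_to_gray(layer.intensity)
        files = {}
        for view, mask in layer.masks.items():
            if not mask.any():
                continue
            fname = f"layer{i:02d}_{view}.png"
            _write_gray(mask.astype(np.uint8) * gray, path / fname)
            files[view] = fname
        entries.append(
            {
                "descriptor": layer.descriptor,
                "intensity": layer.intensity,
                "depth": layer.depth,
                "files": files,
            }
        )
    manifest = {
        "format": SESSION_FORMAT,
        "subject_id": drawing.subject_id,
        "role": drawing.role,
        "layers": entries,
    }
    mpath = path / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_session(
    path: Union[str, Path],
    template: BodyTemplate,
    strict_descriptors: bool = False,
) -> PainDrawing:
    """Read a session directory back into a :class:`PainDrawing`.

    Layer intensity is decoded from the PNG gray values (maximum over views);
    the manifest's ``intensity`` field is informational.  With
    ``strict_descriptors`` a descriptor outside the pain vocabulary raises
    :class:`UnknownDescriptorError` instead of being kept as a non-pain
    finding layer.
    """
    path = Path(path)
    mpath = path / "manifest.json" if path.is_dir() else path
    if not mpath.exists():
        raise MissingFileError(str(mpath))
    manifest = json.loads(mpath.read_text())
    if manifest.get("format") != SESSION_FORMAT:
        raise FormatError(f"unrecognized session format {manifest.get('format')!r}")
    base = mpath.parent
    layers = []
    for entry in manifest["layers"]:
        desc = entry["descriptor"]
        if strict_descriptors and desc not in PAIN_DESCRIPTORS:
            raise UnknownDescriptorError(desc)
        masks = {v: np.zeros(template.shape(v), dtype=bool) for v in template.views}
        peak = 0
        for view, fname in entry["files"].items():
            arr = _read_gray(base / fname)
            if view not in masks:
                raise DimensionError(f"layer drawn on unknown view {view!r}")
            if arr.shape != template.shape(view):
                raise DimensionError(
                    f"{fname}: {arr.shape} != template {template.shape(view)}"
                )
            masks[view] = arr > 0
            if arr.max() > peak:
                peak = int(arr.max())
        layers.append(
            SymptomLayer(
                descriptor=desc,
                intensity=gray_to_intensity(peak),
                masks=masks,
                depth=entry.get("depth", "unspecified"),
            )
        )
    return PainDrawing(
        subject_id=manifest["subject_id"], role=manifest["role"], layers=tuple(layers)
    )


# ---------------------------------------------------------------------------
# Cohorts


def write_cohort(
    template: BodyTemplate,
    records: Sequence[CohortRecord],
    path: Union[str, Path],
) -> Path:
    path = Path(path)
    write_template(template, path / "template")
    for rec in records:
        sdir = path / "sessions" / rec.subject_id
        write_session(rec.patient_drawing, template, sdir / "patient")
        write_session(rec.doctor_drawing, template, sdir / "doctor")
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "understanding_rating": r.understanding_rating,
                "decision_rating": r.decision_rating,
                "nrs_intensity": r.nrs_intensity,
            }
            for r in records
        ]
    ).to_csv(path / "ratings.csv", index=False)
    return path


def read_cohort(path: Union[str, Path]) -> tuple[BodyTemplate, list[CohortRecord]]:
    path = Path(path)
    template = read_template(path / "template")
    ratings = pd.read_csv(path / "ratings.csv").set_index("subject_id")
    records = []
    for sdir in sorted((path / "sessions").iterdir()):
        if not sdir.is_dir():
            continue
        pat = read_session(sdir / "patient", template)
        doc = read_session(sdir / "doctor", template)
        row = ratings.loc[sdir.name] if sdir.name in ratings.index else None

        def _val(col):
            if row is None or pd.isna(row[col]):
                return None
            return int(row[col])

        records.append(
            CohortRecord(
                patient_drawing=pat,
                doctor_drawing=doc,
                understanding_rating=_val("understanding_rating"),
                decision_rating=_val("decision_rating"),
                nrs_intensity=_val("nrs_intensity"),
            )
        )
    return template, records


# ---------------------------------------------------------------------------
# NIfTI export / average-map PNGs


def export_nifti(
    obj: Union[Sequence[PainDrawing], AverageMap],
    template: BodyTemplate,
    path: Union[str, Path],
) -> list[Path]:
    """Export merged drawings (or an average map) as one NIfTI volume per view.

    For a list of n drawings each view yields an (H, W, n) volume of merged
    intensity maps; for an :class:`AverageMap`, an (H, W) volume of the
    thresholded mean.  Returns the written file paths.
    """
    import nibabel as nib

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    if isinstance(obj, AverageMap):
        stacks = {v: obj.thresholded_mean[v] for v in obj.thresholded_mean}
    else:
        drawings = list(obj)
        if not drawings:
            raise ValueError("no drawings to export")
        maps = [d.pain_map(template) for d in drawings]
        stacks = {
            v: np.stack([m[v] for m in maps], axis=-1) for v in template.views
        }
    for view, vol in stacks.items():
        img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine=np.eye(4))
        out = path / f"{view}.nii.gz"
        nib.save(img, out)
        written.append(out)
    return written


def write_average_pngs(avg: AverageMap, path: Union[str, Path]) -> list[Path]:
    """Average map as one grayscale PNG per view (VAS 0-10 -> gray 0-255)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for view, arr in avg.thresholded_mean.items():
        out = path / f"average_{view}.png"
        _write_gray(np.round(arr / 10.0 * 255.0), out)
        written.append(out)
    return written


# ---------------------------------------------------------------------------
# Simulation config files


def load_config(path: Union[str, Path]) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a flat JSON file.

    Rating models are nested objects under ``understanding_model`` /
    ``decision_model``; ``template_size`` is a two-element list.
    """
    raw = json.loads(Path(path).read_text())
    for key in ("understanding_model", "decision_model"):
        if key in raw:
            raw[key] = RatingModel(**raw[key])
    if "template_size" in raw:
        raw["template_size"] = tuple(raw["template_size"])
    if "cluster_radius_frac" in raw:
        raw["cluster_radius_frac"] = tuple(raw["cluster_radius_frac"])
    return SimulationConfig(**raw)


def save_config(config: SimulationConfig, path: Union[str, Path]) -> Path:
    d = dataclasses.asdict(config)
    path = Path(path)
    path.write_text(json.dumps(d, indent=1))
    return path
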