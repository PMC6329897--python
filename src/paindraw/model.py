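"""Core data types for multi-view body-map symptom drawings.

A drawing session lives on a :class:`BodyTemplate` — four independent raster
canvases (front, back, left, right), each with a binary body-outline mask and
an integer label map partitioning the outline into the 19 body regions of the
widespread pain index (WPI).  A subject draws one or more
:class:`SymptomLayer` s (one sensation each, with a descriptor, a single VAS
intensity in [0, 10], and a perceived depth); a :class:`PainDrawing` bundles
the layers of one subject-role (patient or doctor) and exposes the
max-intensity merged map used by all downstream analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

#: Canonical view names, in display order.
VIEWS: tuple[str, ...] = ("front", "back", "left", "right")

#: The 17 pain/paresthesia descriptors offered to patients.
PAIN_DESCRIPTORS: tuple[str, ...] = (
    "stinging",
    "burning",
    "pressing",
    "tugging",
    "radiating",
    "dull",
    "cramping",
    "tingling",
    "shooting",
    "electric",
    "heavy",
    "tender",
    "throbbing",
    "pricking",
    "numb",
    "hot",
    "cold",
)

#: Number of WPI body regions.
N_REGIONS = 19


class TemplateError(ValueError):
    """A body template violates its invariants."""


class DimensionError(ValueError):
    """Raster dimensions do not match the template."""


class OutOfOutlineError(ValueError):
    """Drawn pixels fall outside the body outline (strict validation)."""

    def __init__(self, counts: Mapping[str, int]):
        self.counts = dict(counts)
        views = ", ".join(f"{v}: {c}" for v, c in self.counts.items() if c)
        super().__init__(f"drawn pixels outside the body outline ({views})")


def _as_bool(arr: np.ndarray) -> np.ndarray:
    return np.asarray(arr, dtype=bool)


@dataclass(frozen=True)
class BodyTemplate:
    """Drawing canvas: per-view outline masks and 19-region label maps.

    Parameters
    ----------
    outline
        view name -> boolean raster, ``True`` inside the body outline.
    region_labels
        view name -> integer raster, 0 = unassigned, 1..19 = WPI region.
    sex_variant
        free tag ("female", "male", "neutral", ...); carried as metadata only.
    """

    outline: Mapping[str, np.ndarray]
    region_labels: Mapping[str, np.ndarray]
    sex_variant: str = "neutral"

    def __post_init__(self):
        object.__setattr__(
            self, "outline", {v: _as_bool(m) for v, m in self.outline.items()}
        )
        object.__setattr__(
            self,
            "region_labels",
            {v: np.asarray(m, dtype=np.int32) for v, m in self.region_labels.items()},
        )
        self.validate()

    @property
    def views(self) -> tuple[str, ...]:
        return tuple(self.outline.keys())

    def shape(self, view: str) -> tuple[int, int]:
        return self.outline[view].shape

    def outline_pixels(self, view: str) -> int:
        return int(self.outline[view].sum())

    def validate(self) -> None:
        if set(self.outline) != set(self.region_labels):
            raise TemplateError("outline and region_labels cover different views")
        if not self.outline:
            raise TemplateError("template has no views")
        seen: set[int] = set()
        for view, mask in self.outline.items():
            labels = self.region_labels[view]
            if labels.shape != mask.shape:
                raise TemplateError(f"label/outline shape mismatch in view {view!r}")
            if not mask.any():
                raise TemplateError(f"empty outline mask in view {view!r}")
            if labels.min() < 0 or labels.max() > N_REGIONS:
                raise TemplateError(f"region labels outside 0..{N_REGIONS} in {view!r}")
            if np.any((labels > 0) & ~mask):
                raise TemplateError(f"region label outside outline in view {view!r}")
            seen |= set(np.unique(labels[labels > 0]).tolist())
        if seen != set(range(1, N_REGIONS + 1)):
            missing = sorted(set(range(1, N_REGIONS + 1)) - seen)
            raise TemplateError(f"regions missing from template: {missing}")


@dataclass(frozen=True)
class SymptomLayer:
    """One drawn sensation: per-view binary masks plus its metadata.

    ``descriptor`` is normally one of :data:`PAIN_DESCRIPTORS`; other labels
    (doctors' clinical findings such as "allodynia" or "erythema") are stored
    but excluded from the pain analyses — see :meth:`is_pain`.
    """

    descriptor: str
    intensity: float
    masks: Mapping[str, np.ndarray]
    depth: str = "unspecified"

    def __post_init__(self):
        if not 0.0 <= self.intensity <= 10.0:
            raise ValueError(f"intensity {self.intensity} outside [0, 10]")
        object.__setattr__(
            self, "masks", {v: _as_bool(m) for v, m in self.masks.items()}
        )

    @property
    def is_pain(self) -> bool:
        """Whether this layer enters the pain analysis."""
        return self.descriptor in PAIN_DESCRIPTORS

    def pixels(self) -> int:
        return int(sum(m.sum() for m in self.masks.values()))


def merge_layers(
    layers: Sequence[SymptomLayer], template: BodyTemplate
) -> dict[str, np.ndarray]:
    """Merge symptom layers into a per-view max-intensity map.

    Each pixel of the result carries the maximum VAS intensity over all
    layers drawn there, 0 where nothing was drawn.  Commutative and
    associative over layers; an all-empty layer is a no-op.
    """
    merged = {v: np.zeros(template.shape(v), dtype=float) for v in template.views}
    for layer in layers:
        for view, mask in layer.masks.items():
            if view not in merged:
                raise DimensionError(f"layer drawn on unknown view {view!r}")
            if mask.shape != merged[view].shape:
                raise DimensionError(
                    f"layer mask {mask.shape} != template {merged[view].shape} "
                    f"in view {view!r}"
                )
            np.maximum(merged[view], np.where(mask, layer.intensity, 0.0), out=merged[view])
    return merged


@dataclass(frozen=True)
class PainDrawing:
    """An ordered stack of symptom layers drawn by one subject-role."""

    subject_id: str
    role: str  # "patient" | "doctor"
    layers: tuple[SymptomLayer, ...]

    def __post_init__(self):
        if self.role not in ("patient", "doctor"):
            raise ValueError(f"role must be 'patient' or 'doctor', got {self.role!r}")
        if not self.layers:
            raise ValueError("a drawing needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def pain_layers(self) -> tuple[SymptomLayer, ...]:
        """Layers that enter the pain analysis (pain/paresthesia descriptors)."""
        return tuple(l for l in self.layers if l.is_pain)

    def merged_map(self, template: BodyTemplate) -> dict[str, np.ndarray]:
        """Max-intensity merge over all layers."""
        return merge_layers(self.layers, template)

    def pain_map(self, template: BodyTemplate) -> dict[str, np.ndarray]:
        """Max-intensity merge over pain layers only (analysis map)."""
        return merge_layers(self.pain_layers, template)


def validate_drawing(
    drawing: PainDrawing,
    template: BodyTemplate,
    mode: str = "strict",
) -> tuple[PainDrawing, dict[str, int]]:
    """Check (or enforce) that every drawn pixel lies inside the outline.

    The capture app restricts strokes to the body outline, but sessions from
    other sources may not.  ``mode="strict"`` raises
    :class:`OutOfOutlineError` if any drawn pixel falls outside;
    ``mode="clip"`` zeroes offending pixels.

    Returns
    -------
    (drawing, clipped)
        The (possibly clipped) drawing and the per-view count of pixels that
        were outside the outline.
    """
    if mode not in ("strict", "clip"):
        raise ValueError(f"mode must be 'strict' or 'clip', got {mode!r}")
    counts = {v: 0 for v in template.views}
    new_layers = []
    any_outside = False
    for layer in drawing.layers:
        new_masks = {}
        for view, mask in layer.masks.items():
            if view not in counts:
                raise DimensionError(f"layer drawn on unknown view {view!r}")
            if mask.shape != template.shape(view):
                raise DimensionError(
                    f"mask {mask.shape} != template {template.shape(view)} in {view!r}"
                )
            outside = mask & ~template.outline[view]
            n = int(outside.sum())
            counts[view] += n
            if n:
                any_outside = True
                new_masks[view] = mask & template.outline[view]
            else:
                new_masks[view] = mask
        new_layers.append(dataclasses.replace(layer, masks=new_masks))
    if any_outside and mode == "strict":
        raise OutOfOutlineError(counts)
    if not any_outside:
        return drawing, counts
    return dataclasses.replace(drawing, layers=tuple(new_layers)), counts


@dataclass
class CohortRecord:
    """Paired patient/doctor drawings with the doctor's post-reveal ratings.

    ``understanding_rating`` and ``decision_rating`` are the doctor's
    11-point Likert answers (0 = "not at all", 10 = "very much") to how much
    seeing the patient's drawing improved their understanding of the case and
    influenced their clinical decision; ``nrs_intensity`` is the patient's
    current pain on the 0-10 numeric rating scale.
    """

    patient_drawing: PainDrawing
    doctor_drawing: PainDrawing
    understanding_rating: Optional[int] = None
    decision_rating: Optional[int] = None
    nrs_intensity: Optional[int] = None

    def __post_init__(self):
        for name in ("understanding_rating", "decision_rating", "nrs_intensity"):
            v = getattr(self, name)
            if v is not None:
                v = int(v)
                if not 0 <= v <= 10:
                    raise ValueError(f"{name}={v} outside 0..10")
                setattr(self, name, v)

    @property
    def subject_id(self) -> str:
        return self.patient_drawing.subject_id
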