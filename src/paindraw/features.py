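"""Per-drawing feature extraction.

The eight quantities computed from each drawing: pain extent (percent of the
template's body surface, per view and whole drawing, unthresholded and at a
VAS >= 6 severity threshold), number of pain clusters (connected components,
same two variants), number of body views used, number of distinct symptom
descriptors, mean VAS intensity per symptom, and the widespread pain index
(number of nonempty WPI body regions, 0-19).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .model import BodyTemplate, PainDrawing, N_REGIONS

#: Default VAS severity threshold ("larger or equal to 6").
SEVERE_THRESHOLD = 6.0


def _binarize(merged: np.ndarray, threshold: Optional[float]) -> np.ndarray:
    if threshold is None:
        return merged > 0
    return merged >= threshold


def pain_extent(
    drawing: PainDrawing,
    template: BodyTemplate,
    threshold: Optional[float] = None,
) -> tuple[dict[str, float], float]:
    """Drawn surface as percent of the body outline.

    Per view: 100 * (qualifying pixels) / (outline pixels of that view).
    Whole drawing: 100 * (total qualifying pixels) / (total outline pixels).
    ``threshold=None`` counts any nonzero pixel; otherwise pixels with merged
    intensity >= threshold count.
    """
    merged = drawing.pain_map(template)
    per_view: dict[str, float] = {}
    tot_drawn = 0
    tot_outline = 0
    for view in template.views:
        n_out = template.outline_pixels(view)
        if n_out == 0:
            raise ZeroDivisionError(f"empty outline mask in view {view!r}")
        n_drawn = int(_binarize(merged[view], threshold).sum())
        per_view[view] = 100.0 * n_drawn / n_out
        tot_drawn += n_drawn
        tot_outline += n_out
    return per_view, 100.0 * tot_drawn / tot_outline


def count_clusters(
    drawing: PainDrawing,
    template: BodyTemplate,
    threshold: Optional[float] = None,
    connectivity: int = 8,
    per_view: bool = False,
):
    """Number of pain clusters: connected components of the binarized map.

    Views are independent canvases, so the whole-drawing count is the sum of
    per-view component counts.  ``connectivity`` is 4 (edge neighbours) or 8
    (edge + diagonal, the default — stylus strokes produce diagonal chains).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    skc = 1 if connectivity == 4 else 2
    merged = drawing.pain_map(template)
    counts = {}
    for view in template.views:
        mask = _binarize(merged[view], threshold)
        _, n = measure.label(mask, connectivity=skc, return_num=True)
        counts[view] = int(n)
    if per_view:
        return counts
    return sum(counts.values())


def widespread_pain_index(drawing: PainDrawing, template: BodyTemplate) -> int:
    """Count of WPI body regions (1..19) containing >= 1 drawn pixel, any view."""
    merged = drawing.pain_map(template)
    hit: set[int] = set()
    for view in template.views:
        labels = template.region_labels[view][merged[view] > 0]
        hit |= set(np.unique(labels[labels > 0]).tolist())
    return len(hit)


@dataclass(frozen=True)
class DrawingFeatures:
    """The feature vector extracted from one drawing."""

    extent_pct: float
    extent_pct_per_view: dict[str, float]
    extent_pct_thr: float
    extent_pct_thr_per_view: dict[str, float]
    n_clusters: int
    n_clusters_thr: int
    n_views_used: int
    n_descriptors: int
    mean_intensity: float
    wpi: int

    def __post_init__(self):
        assert 0.0 <= self.extent_pct_thr <= self.extent_pct <= 100.0
        assert 0 <= self.wpi <= N_REGIONS
        # nothing drawn => no nonempty region (the converse needs full label
        # coverage of the outline, which user templates may not have)
        if self.extent_pct == 0.0:
            assert self.wpi == 0


def extract_features(
    drawing: PainDrawing,
    template: BodyTemplate,
    threshold: float = SEVERE_THRESHOLD,
    connectivity: int = 8,
) -> DrawingFeatures:
    """Extract the full feature vector from one validated drawing.

    ``mean_intensity`` is the mean of the per-symptom VAS ratings (the app
    collects one rating per symptom layer), not a pixel-weighted mean.
    """
    ext_pv, ext = pain_extent(drawing, template, threshold=None)
    ext_thr_pv, ext_thr = pain_extent(drawing, template, threshold=threshold)
    pain_layers = drawing.pain_layers
    merged = drawing.pain_map(template)
    n_views = sum(1 for v in template.views if (merged[v] > 0).any())
    intensities = [l.intensity for l in pain_layers]
    return DrawingFeatures(
        extent_pct=ext,
        extent_pct_per_view=ext_pv,
        extent_pct_thr=ext_thr,
        extent_pct_thr_per_view=ext_thr_pv,
        n_clusters=count_clusters(drawing, template, None, connectivity),
        n_clusters_thr=count_clusters(drawing, template, threshold, connectivity),
        n_views_used=n_views,
        n_descriptors=len({l.descriptor for l in pain_layers}),
        mean_intensity=float(np.mean(intensities)) if intensities else float("nan"),
        wpi=widespread_pain_index(drawing, template),
    )


FEATURE_COLUMNS = [
    "extent_pct",
    "extent_pct_thr",
    "n_clusters",
    "n_clusters_thr",
    "n_views_used",
    "n_descriptors",
    "mean_intensity",
    "wpi",
]


def features_table(
    drawings: Sequence[PainDrawing],
    template: BodyTemplate,
    threshold: float = SEVERE_THRESHOLD,
    connectivity: int = 8,
) -> pd.DataFrame:
    """One row per drawing: subject, role, the 8 scalar features, and the
    per-view extents; ``threshold`` recorded as metadata column."""
    rows = []
    for d in drawings:
        f = extract_features(d, template, threshold, connectivity)
        row: dict = {"subject_id": d.subject_id, "role": d.role}
        row.update({c: getattr(f, c) for c in FEATURE_COLUMNS})
        for v, x in f.extent_pct_per_view.items():
            row[f"extent_pct_{v}"] = x
        row["threshold"] = threshold
        rows.append(row)
    return pd.DataFrame(rows)
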