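"""Patient-doctor agreement: Jaccard overlap and ICC(3,1).

The Jaccard index is computed per body view on the binarized (any nonzero
pixel) merged maps and averaged over views, excluding views that are empty in
both drawings; intensity plays no role beyond binarization.

The intraclass correlation is ICC(3,1) in the Shrout-Fleiss classification:
two-way mixed model, single rater, consistency.  With between-subject mean
square BMS and residual mean square EMS from the two-way ANOVA of an
n-subject x k-rater table,

    ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) EMS)

and the 95% CI follows from the F bounds F_obs = BMS/EMS with
(n-1, (n-1)(k-1)) degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import BodyTemplate, CohortRecord, PainDrawing, DimensionError
from .features import features_table, SEVERE_THRESHOLD


class InsufficientSubjectsError(ValueError):
    """Fewer subjects than the statistic requires."""


class MissingDataError(ValueError):
    """The rating table contains missing cells."""


def jaccard_index(
    a: PainDrawing, b: PainDrawing, template: BodyTemplate
) -> tuple[dict[str, float], float]:
    """Per-view Jaccard |A∩B|/|A∪B| of the binarized maps, and their mean.

    Views empty in both drawings carry no information about overlap and are
    excluded (reported as NaN); if every view is both-empty the mean itself
    is NaN.
    """
    ma = a.pain_map(template)
    mb = b.pain_map(template)
    per_view: dict[str, float] = {}
    vals = []
    for view in template.views:
        if ma[view].shape != mb[view].shape:
            raise DimensionError(f"drawings disagree on shape of view {view!r}")
        A = ma[view] > 0
        B = mb[view] > 0
        union = int((A | B).sum())
        if union == 0:
            per_view[view] = float("nan")
            continue
        j = int((A & B).sum()) / union
        per_view[view] = j
        vals.append(j)
    return per_view, (float(np.mean(vals)) if vals else float("nan"))


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    confidence: float = 0.95

    def __post_init__(self):
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            assert self.ci_low <= self.estimate <= self.ci_high


def icc31(
    ratings: np.ndarray, confidence: float = 0.95
) -> ICCResult:
    """ICC(3,1) with Shrout-Fleiss exact F-based confidence interval.

    Parameters
    ----------
    ratings
        (n_subjects, k_raters) table; here k = 2 (patient, doctor).

    Notes
    -----
    Degenerate input with no variance at all (every cell identical) makes
    the ANOVA ratio 0/0; by convention the estimate is 0 with a missing CI,
    since zero subject variance means no measurable consistency.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an (n, k>=2) table")
    if np.isnan(x).any():
        raise MissingDataError("rating table contains missing cells")
    n, k = x.shape
    if n < 3:
        raise InsufficientSubjectsError(f"need >= 3 subjects, got {n}")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    df_rows = n - 1
    df_err = (n - 1) * (k - 1)
    bms = ss_rows / df_rows
    ems = max(ss_err, 0.0) / df_err  # ss_err can round tiny-negative

    tiny = 1e-12 * max(ss_total, 1.0)
    if bms <= tiny and ems <= tiny:
        warnings.warn("degenerate rating table (zero variance); ICC set to 0")
        return ICCResult(0.0, float("nan"), float("nan"), n, confidence)
    if ems <= tiny:
        # perfect consistency: CI collapses
        return ICCResult(1.0, 1.0, 1.0, n, confidence)

    est = (bms - ems) / (bms + (k - 1) * ems)
    alpha = 1.0 - confidence
    f_obs = bms / ems
    fl = f_obs / sps.f.ppf(1 - alpha / 2, df_rows, df_err)
    fu = f_obs * sps.f.ppf(1 - alpha / 2, df_err, df_rows)
    lo = (fl - 1) / (fl + k - 1)
    hi = (fu - 1) / (fu + k - 1)
    return ICCResult(float(est), float(lo), float(hi), n, confidence)


@dataclass
class SimilarityResult:
    """Cohort-level agreement summary (the report mirrors Table-3 structure)."""

    per_subject_jaccard: dict[str, float]
    cohort_jaccard_mean: float
    cohort_jaccard_sd: float
    icc_extent: dict[str, Optional[ICCResult]]  # "whole" + one key per view
    icc_clusters: dict[str, Optional[ICCResult]]
    patient_features: pd.DataFrame = field(repr=False, default=None)
    doctor_features: pd.DataFrame = field(repr=False, default=None)


def _paired_icc(pat: np.ndarray, doc: np.ndarray) -> ICCResult:
    return icc31(np.column_stack([pat, doc]))


def compare_cohort(
    records: Sequence[CohortRecord],
    template: BodyTemplate,
    threshold: float = SEVERE_THRESHOLD,
) -> SimilarityResult:
    """Full agreement analysis of a paired cohort.

    Whole-drawing ICCs use per-subject totals (whole-drawing extent percent;
    summed cluster count).  Per-view ICCs use the per-view extent / cluster
    values of all subjects, but a view is dropped (None) when fewer than 3
    subjects have a nonempty pair there, since its ICC would rest on
    structurally empty 0-0 pairs only.
    """
    if len(records) < 3:
        raise InsufficientSubjectsError(f"need >= 3 records, got {len(records)}")

    pat = features_table([r.patient_drawing for r in records], template, threshold)
    doc = features_table([r.doctor_drawing for r in records], template, threshold)

    per_subject: dict[str, float] = {}
    for r in records:
        _, j = jaccard_index(r.patient_drawing, r.doctor_drawing, template)
        per_subject[r.subject_id] = j
    jvals = np.array([v for v in per_subject.values() if not np.isnan(v)])
    j_mean = float(jvals.mean()) if jvals.size else float("nan")
    j_sd = float(jvals.std(ddof=1)) if jvals.size > 1 else float("nan")

    from .features import count_clusters  # per-view cluster counts

    icc_extent: dict[str, Optional[ICCResult]] = {
        "whole": _paired_icc(pat["extent_pct"].values, doc["extent_pct"].values)
    }
    icc_clusters: dict[str, Optional[ICCResult]] = {
        "whole": _paired_icc(pat["n_clusters"].values, doc["n_clusters"].values)
    }
    pat_cl = [
        count_clusters(r.patient_drawing, template, None, per_view=True)
        for r in records
    ]
    doc_cl = [
        count_clusters(r.doctor_drawing, template, None, per_view=True)
        for r in records
    ]
    for view in template.views:
        pe = pat[f"extent_pct_{view}"].values
        de = doc[f"extent_pct_{view}"].values
        nonempty = int(np.sum((pe > 0) | (de > 0)))
        if nonempty < 3:
            icc_extent[view] = None
            icc_clusters[view] = None
            continue
        icc_extent[view] = _paired_icc(pe, de)
        icc_clusters[view] = _paired_icc(
            np.array([c[view] for c in pat_cl], dtype=float),
            np.array([c[view] for c in doc_cl], dtype=float),
        )

    return SimilarityResult(
        per_subject_jaccard=per_subject,
        cohort_jaccard_mean=j_mean,
        cohort_jaccard_sd=j_sd,
        icc_extent=icc_extent,
        icc_clusters=icc_clusters,
        patient_features=pat,
        doctor_features=doc,
    )


def similarity_report(result: SimilarityResult) -> pd.DataFrame:
    """Flat table of the agreement summary (one row per statistic)."""
    rows = [
        {
            "analysis": "jaccard",
            "scope": "mean_over_views",
            "estimate": result.cohort_jaccard_mean,
            "sd": result.cohort_jaccard_sd,
            "ci_low": np.nan,
            "ci_high": np.nan,
        }
    ]
    for name, table in (("icc_extent", result.icc_extent),
                        ("icc_clusters", result.icc_clusters)):
        for scope, icc in table.items():
            rows.append(
                {
                    "analysis": name,
                    "scope": scope,
                    "estimate": icc.estimate if icc else np.nan,
                    "sd": np.nan,
                    "ci_low": icc.ci_low if icc else np.nan,
                    "ci_high": icc.ci_high if icc else np.nan,
                }
            )
    return pd.DataFrame(rows)
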