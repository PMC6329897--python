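"""Cohort-level statistics: average pain-distribution maps, rating t-tests,
paired feature comparisons, and the exploratory rating-feature correlations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import BodyTemplate, CohortRecord, PainDrawing
from .features import FEATURE_COLUMNS


class DegenerateVarianceError(ValueError):
    """Sample variance is zero; the t statistic is undefined."""


@dataclass
class AverageMap:
    """Pixel-wise cohort summary of merged drawings for one role.

    ``support`` is the fraction of subjects with a nonzero pixel there;
    ``thresholded_mean`` keeps the mean intensity only where at least
    ``ceil(support_threshold * n_subjects)`` subjects drew (the map shown in
    cohort figures; e.g. threshold 0.10 with 47 subjects keeps pixels drawn
    by >= 5 of them).
    """

    mean_intensity: dict[str, np.ndarray]
    support: dict[str, np.ndarray]
    thresholded_mean: dict[str, np.ndarray]
    support_threshold: float
    n_subjects: int

    @property
    def min_subjects(self) -> int:
        return math.ceil(self.support_threshold * self.n_subjects)


def average_distribution(
    drawings: Sequence[PainDrawing],
    template: BodyTemplate,
    support_threshold: float = 0.10,
) -> AverageMap:
    """Pixel-wise mean of merged maps over subjects, with a support threshold.

    A pixel survives thresholding iff the number of subjects with a nonzero
    pixel there is at least ``ceil(support_threshold * n)``.
    """
    if not drawings:
        raise ValueError("need at least one drawing")
    if not 0.0 <= support_threshold <= 1.0:
        raise ValueError("support_threshold must be in [0, 1]")
    n = len(drawings)
    need = math.ceil(support_threshold * n)
    mean_i: dict[str, np.ndarray] = {}
    support: dict[str, np.ndarray] = {}
    thr_mean: dict[str, np.ndarray] = {}
    maps = [d.pain_map(template) for d in drawings]
    for view in template.views:
        stack = np.stack([m[view] for m in maps])
        mean_i[view] = stack.mean(axis=0)
        counts = (stack > 0).sum(axis=0)
        support[view] = counts / n
        thr_mean[view] = np.where(counts >= need, mean_i[view], 0.0)
    return AverageMap(mean_i, support, thr_mean, support_threshold, n)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    sidedness: str  # "one" | "two"
    estimate: float  # mean (one-sample) or mean difference (paired)
    n: int

    def __post_init__(self):
        assert 0.0 <= self.p_value <= 1.0
        assert self.df == self.n - 1


def one_sample_t_onesided(values: Sequence[float], mu0: float = 0.0) -> TestResult:
    """One-sided one-sample t-test of mean > mu0 (upper tail)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    if np.ptp(x) == 0:
        raise DegenerateVarianceError("all values identical")
    res = sps.ttest_1samp(x, popmean=mu0, alternative="greater")
    return TestResult(
        statistic=float(res.statistic),
        df=x.size - 1,
        p_value=float(res.pvalue),
        sidedness="one",
        estimate=float(x.mean()),
        n=x.size,
    )


def paired_t_twosided(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired t-test on the differences x - y."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.shape} vs {ya.shape}")
    if xa.size < 2:
        raise ValueError("need n >= 2")
    d = xa - ya
    if np.ptp(d) == 0:
        raise DegenerateVarianceError("all paired differences identical")
    res = sps.ttest_rel(xa, ya)
    return TestResult(
        statistic=float(res.statistic),
        df=xa.size - 1,
        p_value=float(res.pvalue),
        sidedness="two",
        estimate=float(d.mean()),
        n=xa.size,
    )


def paired_feature_tests(
    patient: pd.DataFrame,
    doctor: pd.DataFrame,
    columns: Sequence[str] = tuple(FEATURE_COLUMNS),
) -> pd.DataFrame:
    """Two-sided paired t-tests patient vs doctor for each feature column."""
    pat = patient.set_index("subject_id")
    doc = doctor.set_index("subject_id")
    common = pat.index.intersection(doc.index)
    rows = []
    for col in columns:
        x = pat.loc[common, col].astype(float)
        y = doc.loc[common, col].astype(float)
        row = {
            "feature": col,
            "patient_mean": x.mean(),
            "patient_sd": x.std(ddof=1),
            "doctor_mean": y.mean(),
            "doctor_sd": y.std(ddof=1),
            "n": len(common),
        }
        try:
            t = paired_t_twosided(x.values, y.values)
            row.update(t_statistic=t.statistic, p_value=t.p_value)
        except DegenerateVarianceError:
            row.update(t_statistic=np.nan, p_value=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CorrelationTable:
    """Feature x rating cross-correlation grid (r, two-sided p, n per cell).

    p-values are raw (uncorrected): the analysis is exploratory.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    method: str = "pearson"
    mode: str = "raw"


def feature_rating_correlations(
    features: pd.DataFrame,
    ratings: pd.DataFrame,
    doctor_features: Optional[pd.DataFrame] = None,
    mode: str = "raw",
    method: str = "pearson",
    feature_columns: Sequence[str] = tuple(FEATURE_COLUMNS),
) -> CorrelationTable:
    """Cross-correlate drawing features with the doctors' ratings.

    ``mode="raw"`` uses the patient-drawing features directly;
    ``mode="abs_difference"`` uses |patient - doctor| per subject and feature
    (how far apart the two drawings are on that quantity).  Rating columns
    are every non-``subject_id`` column of ``ratings``.
    """
    if mode not in ("raw", "abs_difference"):
        raise ValueError(f"unknown mode {mode!r}")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    feat = features.set_index("subject_id")[list(feature_columns)].astype(float)
    if mode == "abs_difference":
        if doctor_features is None:
            raise ValueError("abs_difference mode requires doctor_features")
        doc = doctor_features.set_index("subject_id")[list(feature_columns)].astype(float)
        feat = (feat - doc.loc[feat.index]).abs()
    rat = ratings.set_index("subject_id") if "subject_id" in ratings else ratings
    rat = rat.astype(float)
    common = feat.index.intersection(rat.index)
    if len(common) < 3:
        raise ValueError("need >= 3 complete subjects")
    feat = feat.loc[common]
    rat = rat.loc[common]
    corr = sps.pearsonr if method == "pearson" else sps.spearmanr
    r = pd.DataFrame(index=feature_columns, columns=rat.columns, dtype=float)
    p = pd.DataFrame(index=feature_columns, columns=rat.columns, dtype=float)
    for fc in feature_columns:
        for rc in rat.columns:
            x = feat[fc].values
            y = rat[rc].values
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"constant column in ({fc}, {rc}); cell left missing")
                continue
            res = corr(x, y)
            r.loc[fc, rc] = float(res.statistic)
            p.loc[fc, rc] = float(res.pvalue)
    return CorrelationTable(r=r, p=p, n=len(common), method=method, mode=mode)
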