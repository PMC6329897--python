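"""Synthetic body templates and paired patient/doctor drawing cohorts.

Clinical pain-drawing datasets of this kind are rarely shareable, so every
pipeline stage is validated against a generator with controllable structure:

* a 4-view geometric humanoid template with a deterministic 19-region
  partition (regions are horizontal/vertical bands, not anatomy — sufficient
  to exercise region masking);
* patients who draw a Poisson-distributed number of elliptical pain blobs
  with per-blob descriptor and VAS intensity;
* doctors who reproduce the patient's blobs imperfectly: they miss some,
  relocate some entirely, jitter and dilate the rest (doctors' clusters are
  coarser and larger), and merge adjacent clusters into one — so doctors
  draw fewer, larger clusters than patients;
* doctors' post-reveal 0-10 ratings generated from the patient's realized
  pain extent and widespread pain index through a linear-Gaussian model with
  controllable feature-rating correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from skimage import draw as skdraw

from .model import (
    VIEWS,
    PAIN_DESCRIPTORS,
    BodyTemplate,
    CohortRecord,
    PainDrawing,
    SymptomLayer,
    TemplateError,
)

# Observed descriptor usage frequencies (patients / doctors), used as sampling
# weights so synthetic cohorts have a realistic descriptor mix.
_PATIENT_DESCRIPTOR_WEIGHTS = (22, 18, 16, 15, 13, 10, 11, 10, 5, 4, 7, 6, 7, 4, 4, 4, 1)
_DOCTOR_DESCRIPTOR_WEIGHTS = (28, 16, 15, 11, 6, 7, 5, 4, 8, 7, 1, 2, 1, 2, 1, 1, 1)

SeedLike = Union[int, np.random.SeedSequence]


# ---------------------------------------------------------------------------
# Template


def _silhouette(h: int, w: int, profile: bool) -> np.ndarray:
    """Blocky humanoid silhouette (head/neck/torso/arms/legs) spanning
    rows ~0.02h..0.97h so every horizontal band of the region partition is
    nonempty."""
    m = np.zeros((h, w), dtype=bool)

    def rect(r0, r1, c0, c1):
        m[int(r0 * h): int(r1 * h), int(c0 * w): int(c1 * w)] = True

    # head
    rr, cc = skdraw.ellipse(
        0.09 * h, 0.5 * w, 0.07 * h, (0.09 if profile else 0.10) * w, shape=(h, w)
    )
    m[rr, cc] = True
    if profile:
        rect(0.14, 0.20, 0.45, 0.58)  # neck
        rect(0.18, 0.53, 0.38, 0.66)  # trunk
        rect(0.22, 0.56, 0.46, 0.58)  # arm (against trunk)
        rect(0.52, 0.97, 0.40, 0.62)  # leg
    else:
        rect(0.14, 0.20, 0.44, 0.56)  # neck
        rect(0.18, 0.53, 0.30, 0.70)  # torso
        rect(0.20, 0.56, 0.18, 0.29)  # left arm
        rect(0.20, 0.56, 0.71, 0.82)  # right arm
        rect(0.52, 0.97, 0.32, 0.49)  # left leg
        rect(0.52, 0.97, 0.51, 0.68)  # right leg
    return m


def _band_labels(outline: np.ndarray, labels: Sequence[int]) -> np.ndarray:
    """Partition the outline into len(labels) horizontal bands."""
    h = outline.shape[0]
    edges = np.linspace(0, h, len(labels) + 1)
    out = np.zeros(outline.shape, dtype=np.int32)
    rows = np.arange(h)
    band = np.clip(np.searchsorted(edges, rows, side="right") - 1, 0, len(labels) - 1)
    lab = np.asarray(labels, dtype=np.int32)[band]
    out[outline] = np.broadcast_to(lab[:, None], outline.shape)[outline]
    return out


def make_template(
    size: tuple[int, int] = (256, 128),
    seed: int = 0,
    sex_variant: str = "neutral",
) -> BodyTemplate:
    """Build the 4-view synthetic humanoid template.

    ``size`` is (height, width) in pixels per view; at least 40x40 so that
    all 19 region bands contain pixels.  Deterministic given ``seed``
    (the geometry itself is seed-independent).
    """
    h, w = size
    if h < 40 or w < 40:
        raise TemplateError(f"size {size} too small to place 19 regions (min 40x40)")
    outline = {
        "front": _silhouette(h, w, profile=False),
        "back": _silhouette(h, w, profile=False),
        "left": _silhouette(h, w, profile=True),
        "right": _silhouette(h, w, profile=True),
    }
    region_labels = {
        "front": _band_labels(outline["front"], list(range(1, 11))),
        "back": _band_labels(outline["back"], list(range(11, 20))),
        "left": _band_labels(outline["left"], list(range(1, 20))),
        "right": _band_labels(outline["right"], list(range(19, 0, -1))),
    }
    return BodyTemplate(outline=outline, region_labels=region_labels,
                        sex_variant=sex_variant)


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class RatingModel:
    """Linear-Gaussian model for a 0-10 integer rating.

    rating = clip(round(mean + sd * (w_extent * z_e + w_wpi * z_w + w_n * eta)))

    where z_e, z_w are the patient's extent percent and WPI standardized by
    the frozen location/scale constants below, eta ~ N(0,1), and w_n is set
    so the latent variance is sd^2 given the extent-WPI correlation
    ``ew_corr``.  With unit-variance weights the generating latent-extent
    correlation is w_extent + w_wpi * ew_corr, independent of the
    standardization constants.
    """

    mean: float = 4.8
    sd: float = 2.6
    # equal extent/WPI weights giving a generating latent-extent correlation
    # of w * (1 + ew_corr) ~= 0.45
    w_extent: float = 0.243
    w_wpi: float = 0.243
    # population stats of patient features under the default generator
    # (estimated once from a large simulated sample; see estimate_feature_stats)
    extent_loc: float = 5.9
    extent_scale: float = 3.4
    wpi_loc: float = 7.9
    wpi_scale: float = 3.5
    ew_corr: float = 0.85

    @property
    def w_noise(self) -> float:
        struct = (
            self.w_extent**2
            + self.w_wpi**2
            + 2 * self.w_extent * self.w_wpi * self.ew_corr
        )
        return math.sqrt(max(0.0, 1.0 - struct))

    @property
    def extent_correlation(self) -> float:
        """Generating correlation between the latent rating and extent."""
        return self.w_extent + self.w_wpi * self.ew_corr

    @classmethod
    def with_extent_correlation(
        cls,
        rho: float,
        mean: float = 4.8,
        sd: float = 2.6,
        extent_loc: float = 5.9,
        extent_scale: float = 3.4,
    ) -> "RatingModel":
        """Model whose latent rating correlates with extent at exactly rho
        (WPI weight zero).

        The correlation holds only if ``extent_loc``/``extent_scale`` are the
        true population mean/sd of extent under the generator configuration
        in use (the noise term is scaled against them); estimate them with
        :func:`estimate_feature_stats` when deviating from the default
        configuration or template size.
        """
        return cls(mean=mean, sd=sd, w_extent=rho, w_wpi=0.0,
                   extent_loc=extent_loc, extent_scale=extent_scale)

    def sample(self, rng: np.random.Generator, extent_pct: float, wpi: float) -> int:
        z_e = (extent_pct - self.extent_loc) / self.extent_scale
        z_w = (wpi - self.wpi_loc) / self.wpi_scale
        latent = self.mean + self.sd * (
            self.w_extent * z_e + self.w_wpi * z_w + self.w_noise * rng.normal()
        )
        return int(np.clip(round(latent), 0, 10))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic paired cohort.

    Defaults emulate the clinical setting the pipeline was built for:
    47 subjects, patient cluster counts averaging ~3.6, severe mean VAS
    (~7.2 +- 2.2), doctors drawing fewer/larger clusters, and understanding
    ratings correlating ~0.45 with drawn extent.
    """

    n_subjects: int = 47
    template_size: tuple[int, int] = (256, 128)
    cluster_count_mean: float = 3.63
    cluster_radius_frac: tuple[float, float] = (0.04, 0.09)  # of view height
    intensity_mean: float = 7.19
    intensity_sd: float = 2.17
    doctor_agreement: float = 0.75
    doctor_cluster_merging: float = 0.7
    doctor_miss_rate: float = 0.2
    doctor_dilation: float = 1.25
    doctor_dilation_jitter: float = 0.03  # per-pair lognormal sd on dilation
    doctor_jitter_frac: float = 0.7  # sd of centre jitter, in blob radii
    doctor_merging_concentration: float = 1.0  # Beta concentration of per-pair style
    doctor_intensity_noise: float = 1.0  # sd of doctors' VAS reproduction error
    doctor_extra_cluster_rate: float = 0.8  # Poisson mean of spurious small clusters
    understanding_model: RatingModel = field(default_factory=RatingModel)
    decision_model: RatingModel = field(
        default_factory=lambda: RatingModel(mean=2.7, sd=1.2, w_extent=0.12, w_wpi=0.12)
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("doctor_agreement", "doctor_cluster_merging", "doctor_miss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.doctor_dilation <= 0:
            raise ValueError("doctor_dilation must be positive")


# ---------------------------------------------------------------------------
# Blobs


@dataclass(frozen=True)
class _Blob:
    view: str
    r: float
    c: float
    radius: float
    ax_ratio: float  # semi-axis anisotropy
    theta: float
    sat_angle: float  # satellite lobe direction (boundary irregularity)
    descriptor: str
    intensity: float

    def area(self) -> float:
        return math.pi * self.radius**2

    def render(self, shape: tuple[int, int], outline: np.ndarray) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        a = self.radius * self.ax_ratio
        b = self.radius / self.ax_ratio
        rr, cc = skdraw.ellipse(self.r, self.c, a, b, shape=shape, rotation=self.theta)
        mask[rr, cc] = True
        # satellite lobe makes the boundary irregular (non-elliptical)
        sr = self.r + 0.8 * self.radius * math.sin(self.sat_angle)
        sc = self.c + 0.8 * self.radius * math.cos(self.sat_angle)
        rr, cc = skdraw.ellipse(sr, sc, 0.55 * a, 0.55 * b, shape=shape,
                                rotation=self.theta)
        mask[rr, cc] = True
        mask &= outline
        # a stroke cannot jump a canvas gap: keep one connected component
        # (the one containing the centre, else the largest)
        from skimage import measure

        lab, n = measure.label(mask, connectivity=2, return_num=True)
        if n > 1:
            ri, ci = int(round(self.r)), int(round(self.c))
            if 0 <= ri < shape[0] and 0 <= ci < shape[1] and lab[ri, ci] > 0:
                keep = lab[ri, ci]
            else:
                keep = 1 + np.argmax(np.bincount(lab[lab > 0])[1:])
            mask = lab == keep
        return mask


def _outline_coords(template: BodyTemplate) -> dict[str, np.ndarray]:
    return {v: np.argwhere(template.outline[v]) for v in template.views}


def _nearest_inside(coords: np.ndarray, r: float, c: float) -> tuple[float, float]:
    d = (coords[:, 0] - r) ** 2 + (coords[:, 1] - c) ** 2
    i = int(np.argmin(d))
    return float(coords[i, 0]), float(coords[i, 1])


def _random_blob(
    rng: np.random.Generator,
    template: BodyTemplate,
    coords: dict[str, np.ndarray],
    config: SimulationConfig,
    weights: np.ndarray,
) -> _Blob:
    view = VIEWS[rng.integers(len(VIEWS))]
    pts = coords[view]
    r, c = pts[rng.integers(len(pts))]
    h = template.shape(view)[0]
    lo, hi = config.cluster_radius_frac
    return _Blob(
        view=view,
        r=float(r),
        c=float(c),
        radius=float(rng.uniform(lo, hi) * h),
        ax_ratio=float(rng.uniform(0.8, 1.25)),
        theta=float(rng.uniform(0, math.pi)),
        sat_angle=float(rng.uniform(0, 2 * math.pi)),
        descriptor=PAIN_DESCRIPTORS[rng.choice(len(PAIN_DESCRIPTORS), p=weights)],
        intensity=float(np.clip(rng.normal(config.intensity_mean, config.intensity_sd),
                                0.5, 10.0)),
    )


def _doctor_blobs(
    rng: np.random.Generator,
    patient: Sequence[_Blob],
    template: BodyTemplate,
    coords: dict[str, np.ndarray],
    config: SimulationConfig,
    weights: np.ndarray,
) -> list[_Blob]:
    # per-pair "style": this doctor's granularity and coarseness
    m = config.doctor_cluster_merging
    conc = config.doctor_merging_concentration
    if conc > 0 and 0.0 < m < 1.0:
        merge_p = float(rng.beta(conc * m, conc * (1.0 - m)))
    else:
        merge_p = m
    dilation = config.doctor_dilation
    if config.doctor_dilation_jitter > 0:
        dilation *= math.exp(rng.normal(0, config.doctor_dilation_jitter))

    out: list[_Blob] = []
    for blob in patient:
        if rng.random() < config.doctor_miss_rate:
            continue
        if rng.random() < config.doctor_agreement:
            # reproduce near the true location, coarser and larger
            jit = config.doctor_jitter_frac * blob.radius
            r = blob.r + rng.normal(0, jit)
            c = blob.c + rng.normal(0, jit)
            if not _inside(template, blob.view, r, c):
                r, c = _nearest_inside(coords[blob.view], r, c)
            new = replace(
                blob,
                r=r,
                c=c,
                radius=blob.radius * dilation,
                intensity=float(
                    np.clip(
                        blob.intensity + rng.normal(0, config.doctor_intensity_noise)
                        if config.doctor_intensity_noise > 0
                        else blob.intensity,
                        0.5,
                        10.0,
                    )
                ),
            )
        else:
            # doctor conceptualizes this symptom somewhere else entirely
            new = _random_blob(rng, template, coords, config, weights)
            new = replace(new, radius=new.radius * dilation)
        if rng.random() >= 0.7:  # doctors relabel sensations at times
            new = replace(
                new,
                descriptor=PAIN_DESCRIPTORS[rng.choice(len(PAIN_DESCRIPTORS), p=weights)],
            )
        out.append(new)
    # spurious clusters of the doctor's own (suspected but undrawn symptoms)
    for _ in range(rng.poisson(config.doctor_extra_cluster_rate)):
        extra = _random_blob(rng, template, coords, config, weights)
        out.append(replace(extra, radius=0.6 * extra.radius))

    if not out:  # a doctor always draws something after the consultation
        src = patient[rng.integers(len(patient))]
        out.append(replace(src, radius=src.radius * dilation))

    # merge adjacent clusters within a view: fewer, larger doctor clusters
    merged: list[_Blob] = []
    for blob in out:
        same_view = [i for i, b in enumerate(merged) if b.view == blob.view]
        if same_view and rng.random() < merge_p:
            i = same_view[int(np.argmin([
                (merged[j].r - blob.r) ** 2 + (merged[j].c - blob.c) ** 2
                for j in same_view
            ]))]
            other = merged[i]
            wa, wb = other.area(), blob.area()
            r = (other.r * wa + blob.r * wb) / (wa + wb)
            c = (other.c * wa + blob.c * wb) / (wa + wb)
            if not _inside(template, blob.view, r, c):
                r, c = _nearest_inside(coords[blob.view], r, c)
            merged[i] = replace(
                other,
                r=r,
                c=c,
                radius=math.sqrt(other.radius**2 + blob.radius**2),
                intensity=max(other.intensity, blob.intensity),
            )
        else:
            merged.append(blob)
    return merged


def _inside(template: BodyTemplate, view: str, r: float, c: float) -> bool:
    h, w = template.shape(view)
    ri, ci = int(round(r)), int(round(c))
    return 0 <= ri < h and 0 <= ci < w and bool(template.outline[view][ri, ci])


def _blobs_to_drawing(
    blobs: Sequence[_Blob],
    subject_id: str,
    role: str,
    template: BodyTemplate,
) -> PainDrawing:
    layers = []
    for blob in blobs:
        mask = blob.render(template.shape(blob.view), template.outline[blob.view])
        if not mask.any():
            continue
        masks = {v: np.zeros(template.shape(v), dtype=bool) for v in template.views}
        masks[blob.view] = mask
        layers.append(
            SymptomLayer(
                descriptor=blob.descriptor,
                intensity=blob.intensity,
                masks=masks,
                depth="deep",
            )
        )
    if not layers:  # degenerate render (blob fully off-outline); draw a point
        v = blobs[0].view if blobs else template.views[0]
        masks = {u: np.zeros(template.shape(u), dtype=bool) for u in template.views}
        pt = np.argwhere(template.outline[v])[0]
        masks[v][pt[0], pt[1]] = True
        layers.append(SymptomLayer("dull", 5.0, masks))
    return PainDrawing(subject_id=subject_id, role=role, layers=tuple(layers))


# ---------------------------------------------------------------------------
# Cohort simulation


def simulate_pair(
    template: BodyTemplate,
    config: SimulationConfig,
    seed: SeedLike,
    subject_id: str = "S001",
    _coords: Optional[dict[str, np.ndarray]] = None,
) -> CohortRecord:
    """One paired patient/doctor record, deterministic given ``seed``."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    coords = _coords if _coords is not None else _outline_coords(template)
    wp = np.asarray(_PATIENT_DESCRIPTOR_WEIGHTS, dtype=float)
    wp /= wp.sum()
    wd = np.asarray(_DOCTOR_DESCRIPTOR_WEIGHTS, dtype=float)
    wd /= wd.sum()

    n_blobs = max(1, int(rng.poisson(config.cluster_count_mean)))
    patient_blobs = [
        _random_blob(rng, template, coords, config, wp) for _ in range(n_blobs)
    ]
    doctor_blobs = _doctor_blobs(rng, patient_blobs, template, coords, config, wd)

    patient = _blobs_to_drawing(patient_blobs, subject_id, "patient", template)
    doctor = _blobs_to_drawing(doctor_blobs, subject_id, "doctor", template)

    # ratings depend on the patient's realized extent and WPI
    from .features import pain_extent, widespread_pain_index

    _, extent = pain_extent(patient, template)
    wpi = widespread_pain_index(patient, template)
    understanding = config.understanding_model.sample(rng, extent, wpi)
    decision = config.decision_model.sample(rng, extent, wpi)
    nrs = int(np.clip(round(rng.normal(6.4, 2.2)), 0, 10))

    return CohortRecord(
        patient_drawing=patient,
        doctor_drawing=doctor,
        understanding_rating=understanding,
        decision_rating=decision,
        nrs_intensity=nrs,
    )


def simulate_cohort(
    config: SimulationConfig,
    template: Optional[BodyTemplate] = None,
) -> tuple[BodyTemplate, list[CohortRecord]]:
    """Simulate ``config.n_subjects`` independent pairs.

    Per-subject random streams are derived from ``config.seed`` by subject
    index, so subject i's record does not change when ``n_subjects`` does.
    """
    if template is None:
        template = make_template(config.template_size, seed=config.seed)
    coords = _outline_coords(template)
    records = []
    for i in range(config.n_subjects):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
        records.append(
            simulate_pair(template, config, ss, subject_id=f"S{i + 1:03d}",
                          _coords=coords)
        )
    return template, records


def estimate_feature_stats(
    config: SimulationConfig,
    n: int = 1000,
    seed: int = 12345,
    template: Optional[BodyTemplate] = None,
) -> dict[str, float]:
    """Population statistics of patient extent/WPI under a config (for
    calibrating rating-model standardization constants)."""
    from .features import pain_extent, widespread_pain_index

    if template is None:
        template = make_template(config.template_size, seed=config.seed)
    coords = _outline_coords(template)
    ext, wpi = [], []
    for i in range(n):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        rec = simulate_pair(template, config, ss, subject_id=f"C{i:04d}",
                            _coords=coords)
        _, e = pain_extent(rec.patient_drawing, template)
        ext.append(e)
        wpi.append(widespread_pain_index(rec.patient_drawing, template))
    ext = np.asarray(ext)
    wpi = np.asarray(wpi, dtype=float)
    return {
        "extent_mean": float(ext.mean()),
        "extent_sd": float(ext.std(ddof=1)),
        "wpi_mean": float(wpi.mean()),
        "wpi_sd": float(wpi.std(ddof=1)),
        "extent_wpi_corr": float(np.corrcoef(ext, wpi)[0, 1]),
    }
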