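"""Seeded two-class synthetic cohorts of tumor-like textured ROI images.

No imaging data accompany the original study, so pipeline-level tests and
the scaled-down analogues of its headline numbers run on this generator.
Each subject image is a Gaussian random field (white noise smoothed at a
correlation length, rescaled to a contrast amplitude) on top of a base gray
level, plus additive white noise, multiplied by a soft elliptical "tumor"
support and quantised to 8 bits.  Class differences are controlled by a
single ``effect`` scalar interpolating the negative-class texture
parameters toward the positive-class ones (``effect = 0`` means identical
classes).

Default conditions: cohorts of 7 positive vs 15 negative subjects on 64x64
images; the negative class sits at base intensity 120 with contrast 12,
correlation length 3 px and noise SD 6; between-subject base-intensity
jitter has SD 4 gray levels and the default positive-class offset is 4 gray
levels, so ``effect`` reads approximately as the class separation in
between-subject SD units.

A feature-level generator bypasses the imaging step entirely and plants a
mean shift on a designated feature subset, for unit-testing the screening
and discriminant stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .features import FeatureTable, feature_names
from .image import GrayImage

__all__ = [
    "ClassTextureParams",
    "SyntheticCohortConfig",
    "generate_image",
    "generate_cohort",
    "generate_feature_cohort",
    "DEFAULT_SHIFTED_FEATURES",
]

#: Features that receive the planted class shift in feature-level cohorts —
#: the four variables of the reference worked-example model.
DEFAULT_SHIFTED_FEATURES = ("db2dec2sd", "bior33dec1max", "bior33dec3mn", "sym5dec2mn")

#: Between-subject SD of the per-subject base-intensity offset (gray levels).
SUBJECT_JITTER_SD = 4.0


@dataclass(frozen=True)
class ClassTextureParams:
    """Texture parameters of one diagnostic class (gray-level units)."""

    base_intensity: float = 120.0
    contrast: float = 12.0
    correlation_length: float = 3.0
    noise_sd: float = 6.0

    def __post_init__(self) -> None:
        if not (0 < self.base_intensity < 255):
            raise ValueError("base_intensity must lie in (0, 255)")
        for name in ("contrast", "correlation_length", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _interpolate(neg: ClassTextureParams, pos: ClassTextureParams,
                 effect: float) -> ClassTextureParams:
    return ClassTextureParams(
        base_intensity=neg.base_intensity + effect * (pos.base_intensity - neg.base_intensity),
        contrast=neg.contrast + effect * (pos.contrast - neg.contrast),
        correlation_length=neg.correlation_length
        + effect * (pos.correlation_length - neg.correlation_length),
        noise_sd=neg.noise_sd + effect * (pos.noise_sd - neg.noise_sd),
    )


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    ``effect`` interpolates (and extrapolates) the negative-class parameters
    toward ``params_pos``; with the defaults the positive class differs by
    ``effect * 4`` gray levels of base intensity, i.e. ``effect`` is the
    class shift in units of the between-subject jitter SD.
    """

    n_pos: int = 7
    n_neg: int = 15
    image_size: int = 64
    params_neg: ClassTextureParams = field(default_factory=ClassTextureParams)
    params_pos: ClassTextureParams = field(
        default_factory=lambda: ClassTextureParams(base_intensity=124.0))
    effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 3 or self.n_neg < 3:
            raise ValueError("need >= 3 subjects per class")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")

    def effective_params_pos(self) -> ClassTextureParams:
        return _interpolate(self.params_neg, self.params_pos, self.effect)


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    """Child generator for one subject.

    Seeding mixes the cohort seed with the subject index through
    ``numpy.random.SeedSequence(entropy=(seed, index))``, which is
    deterministic and platform-independent.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, index)))


def _render(params: ClassTextureParams, size: int,
            rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Float image plus the fraction of pixels clipped at 0 or 255."""
    field_ = rng.standard_normal((size, size))
    if params.correlation_length > 0:
        field_ = gaussian_filter(field_, sigma=params.correlation_length, mode="reflect")
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd * params.contrast
    img = params.base_intensity + field_ + rng.standard_normal((size, size)) * params.noise_sd
    # soft elliptical tumor support
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    r = np.sqrt(((yy - cy) / (0.44 * size)) ** 2 + ((xx - cx) / (0.36 * size)) ** 2)
    support = expit((1.0 - r) / 0.06)
    img = img * support
    clipped = float(np.mean((img < 0) | (img > 255)))
    return np.clip(img, 0, 255), clipped


def generate_image(params: ClassTextureParams, size: int = 64,
                   seed: int | np.random.Generator = 0,
                   subject_id: str = "") -> GrayImage:
    """One deterministic synthetic ROI image for given texture parameters."""
    if size < 16:
        raise ValueError("size must be >= 16")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img, _ = _render(params, size, rng)
    return GrayImage(pixels=np.rint(img).astype(np.uint8), subject_id=subject_id)


def clipping_fraction(params: ClassTextureParams, size: int = 64, seed: int = 0) -> float:
    """Fraction of pixels clipped during quantisation (diagnostic)."""
    img, clipped = _render(params, size, np.random.default_rng(seed))
    return clipped


def generate_cohort(config: SyntheticCohortConfig) -> tuple[list[GrayImage], np.ndarray]:
    """Images and labels for one cohort (positives first).

    Each subject gets an independent child seed and a per-subject
    base-intensity offset drawn with SD :data:`SUBJECT_JITTER_SD`.
    """
    params_pos = config.effective_params_pos()
    images: list[GrayImage] = []
    labels = np.concatenate([np.ones(config.n_pos, int), np.zeros(config.n_neg, int)])
    for i, lab in enumerate(labels):
        rng = _subject_rng(config.seed, i)
        base = params_pos if lab == 1 else config.params_neg
        jitter = rng.standard_normal() * SUBJECT_JITTER_SD
        subj_params = replace(
            base,
            base_intensity=float(np.clip(base.base_intensity + jitter, 1, 254)),
        )
        sid = f"{'pos' if lab else 'neg'}{i:02d}"
        images.append(generate_image(subj_params, config.image_size, rng, subject_id=sid))
    return images, labels


def generate_feature_cohort(config: SyntheticCohortConfig,
                            shifted_features=DEFAULT_SHIFTED_FEATURES,
                            rho: float = 0.2) -> FeatureTable:
    """Feature-level cohort with a planted class shift (no imaging).

    All 120 features are unit-variance within class with exchangeable
    within-subject correlation ``rho``; the ``shifted_features`` get a
    positive-class mean shift of ``config.effect`` within-class SD units.
    The remaining features are null.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    names = feature_names()
    unknown = [f for f in shifted_features if f not in names]
    if unknown:
        raise KeyError(f"unknown shifted features: {unknown}")
    labels = np.concatenate([np.ones(config.n_pos, int), np.zeros(config.n_neg, int)])
    rows = []
    ids = []
    shift = np.array([config.effect if f in shifted_features else 0.0 for f in names])
    a, b = np.sqrt(rho), np.sqrt(1 - rho)
    for i, lab in enumerate(labels):
        rng = _subject_rng(config.seed, i)
        z = rng.standard_normal()
        eps = rng.standard_normal(len(names))
        x = a * z + b * eps + lab * shift
        rows.append({"label": int(lab), **dict(zip(names, x))})
        ids.append(f"{'pos' if lab else 'neg'}{i:02d}")
    df = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"))
    return FeatureTable(df)
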