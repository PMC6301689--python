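"""Partial-volume-corrected calcium volume scoring.

For each detected lesion the intensities of its calcification region and
surrounding background shell are pooled and modelled as a two-component
univariate Gaussian mixture fitted by expectation-maximization. The fitted
background component defines a per-lesion threshold

    threshold = mu_B + FWHM_B / 2 = mu_B + sqrt(2 ln 2) * sigma_B,

i.e. the background mean plus half the full width at half maximum of the
background distribution. Every calcification voxel above this threshold is
considered to partially contain calcium; its fractional content is the
intensity rescaled between the minimum and maximum of the scored voxels,

    pvc_i = (x_i - x_min) / (x_max - x_min),

and the corrected volume score is the sum of the fractions times the voxel
volume. The conventional clinical volume score (voxel count of the 130 HU
component times voxel volume) is reported alongside for comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .config import RunConfig
from .segmentation import LesionSegmentation, segment_lesions
from .volume import CTVolume

__all__ = [
    "GaussianMixtureEstimate",
    "LesionScore",
    "ScanResult",
    "DegenerateIntensitiesError",
    "fit_two_gaussian_em",
    "lesion_threshold",
    "partial_content",
    "score_lesion",
    "score_scan",
]

logger = logging.getLogger(__name__)

#: sqrt(2 ln 2); the Gaussian FWHM is 2*sqrt(2 ln 2)*sigma =~ 2.3548*sigma.
SQRT_2LN2 = math.sqrt(2.0 * math.log(2.0))

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class DegenerateIntensitiesError(ValueError):
    """The intensity sample cannot support a two-component mixture."""


@dataclass
class GaussianMixtureEstimate:
    """Two-component univariate Gaussian mixture (background/foreground).

    Components are ordered so that ``mu_F >= mu_B``; the lower-mean component
    is interpreted as the lesion background. ``degenerate`` flags component
    collapse (a standard deviation clamped at the floor) or coinciding means.
    """

    mu_B: float
    sigma_B: float
    mu_F: float
    sigma_F: float
    weight_B: float = 0.5
    weight_F: float = 0.5
    n_iterations: int = 0
    converged: bool = False
    log_likelihood: float = float("nan")
    degenerate: bool = False

    @property
    def fwhm_B(self) -> float:
        """Full width at half maximum of the background component (HU)."""
        return 2.0 * SQRT_2LN2 * self.sigma_B


def lesion_threshold(mu_B: float, sigma_B: float) -> float:
    """Per-lesion separation threshold: mu_B + FWHM_B/2 = mu_B + sqrt(2 ln 2)*sigma_B."""
    if sigma_B < 0:
        raise ValueError("sigma_B must be non-negative")
    return mu_B + SQRT_2LN2 * sigma_B


def partial_content(x_i, x_min: float, x_max: float):
    """Fractional calcium content of voxels by linear intensity rescaling.

    ``x_max == x_min`` is the single-intensity-lesion case: every voxel
    already exceeded the detection threshold, so the content is taken as 1.
    """
    if x_max < x_min:
        raise ValueError("x_max must be >= x_min")
    x_i = np.asarray(x_i, dtype=float)
    if x_max == x_min:
        out = np.ones_like(x_i)
    else:
        out = (x_i - x_min) / (x_max - x_min)
    return float(out) if out.ndim == 0 else out


def _log_component(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sigma) ** 2 - math.log(sigma) - _LOG_SQRT_2PI


def fit_two_gaussian_em(
    intensities,
    init: GaussianMixtureEstimate | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    sigma_floor: float = 0.5,
) -> GaussianMixtureEstimate:
    """Fit a two-component Gaussian mixture to 1D intensities by EM.

    Standard E-step responsibilities / M-step weighted moments in double
    precision, with the per-observation likelihood evaluated via log-sum-exp.
    Iteration stops when the log-likelihood gain drops below ``tol`` or after
    ``max_iter`` iterations. Component standard deviations are clamped at
    ``sigma_floor`` (HU); a clamped fit is flagged ``degenerate`` rather than
    rejected. Without an explicit ``init``, components are initialized from
    the moments of the lower and upper halves of the sorted sample.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateIntensitiesError(
            "need at least two distinct intensity values to fit a two-component mixture"
        )
    if init is None:
        xs = np.sort(x)
        half = xs.size // 2
        lo, hi = xs[:half], xs[half:]
        init = GaussianMixtureEstimate(
            mu_B=float(lo.mean()),
            sigma_B=float(lo.std()),
            mu_F=float(hi.mean()),
            sigma_F=float(hi.std()),
            weight_B=half / xs.size,
            weight_F=1.0 - half / xs.size,
        )
    mu = np.array([init.mu_B, init.mu_F], dtype=float)
    sigma = np.maximum([init.sigma_B, init.sigma_F], sigma_floor).astype(float)
    w = np.array([init.weight_B, init.weight_F], dtype=float)
    w = w / w.sum()

    prev_ll = -np.inf
    ll = prev_ll
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_joint = np.stack(
            [np.log(w[k]) + _log_component(x, mu[k], sigma[k]) for k in range(2)]
        )
        log_norm = logsumexp(log_joint, axis=0)
        ll = float(log_norm.sum())
        resp = np.exp(log_joint - log_norm)
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / x.size
        mu = resp @ x / nk
        var = (resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk
        sigma = np.maximum(np.sqrt(var), sigma_floor)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll

    order = np.argsort(mu)  # background = lower mean
    b, f = order[0], order[1]
    degenerate = bool(
        np.any(sigma <= sigma_floor + 1e-12) or (mu[f] - mu[b]) < max(sigma[b], sigma[f]) * 1e-3
    )
    return GaussianMixtureEstimate(
        mu_B=float(mu[b]),
        sigma_B=float(sigma[b]),
        mu_F=float(mu[f]),
        sigma_F=float(sigma[f]),
        weight_B=float(w[b]),
        weight_F=float(w[f]),
        n_iterations=n_iter,
        converged=converged,
        log_likelihood=ll,
        degenerate=degenerate,
    )


@dataclass
class LesionScore:
    """Scores and intermediate estimates for one lesion."""

    label_id: int
    mixture: GaussianMixtureEstimate | None
    threshold_hu: float
    x_min_hu: float
    x_max_hu: float
    n_voxels: int
    ccs_volume_mm3: float
    pvc_volume_mm3: float
    scored_mask: np.ndarray | None = None
    pvc_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    status: str = "ok"

    def pvc_map(self) -> np.ndarray:
        """Full-volume map of per-voxel calcium fractions (zero elsewhere)."""
        if self.scored_mask is None:
            raise ValueError("no scored voxel set available")
        out = np.zeros(self.scored_mask.shape, dtype=float)
        out[self.scored_mask] = self.pvc_values
        return out


def score_lesion(
    volume: CTVolume, seg: LesionSegmentation, config: RunConfig | None = None
) -> LesionScore:
    """Score one segmented lesion: mixture fit, threshold, volume scores.

    The mixture is fitted on the pooled intensities of the calcification mask
    and its background shell, initialized from the sample moments of the two
    masks (an informative, deterministic start). The clinical score counts
    only initial-mask voxels; the corrected score sums calcium fractions over
    the calcification voxels above the fitted threshold.
    """
    cfg = config or RunConfig()
    hu = volume.intensities
    calc = seg.calcification_mask
    bg = seg.background_mask
    vox = volume.voxel_volume_mm3
    ccs = float(seg.initial_mask.sum()) * vox

    pooled = np.concatenate([hu[calc], hu[bg]]).astype(float)
    init = None
    if bg.any() and calc.any():
        init = GaussianMixtureEstimate(
            mu_B=float(hu[bg].mean()),
            sigma_B=float(hu[bg].std()),
            mu_F=float(hu[calc].mean()),
            sigma_F=float(hu[calc].std()),
            weight_B=float(bg.sum() / (bg.sum() + calc.sum())),
            weight_F=float(calc.sum() / (bg.sum() + calc.sum())),
        )
    mix = fit_two_gaussian_em(
        pooled, init=init, tol=cfg.em_tol, max_iter=cfg.em_max_iter,
        sigma_floor=cfg.em_sigma_floor_hu,
    )
    threshold = lesion_threshold(mix.mu_B, mix.sigma_B)

    scored_mask = calc & (hu > threshold)
    if not scored_mask.any():
        logger.warning(
            "lesion %d: threshold %.1f HU exceeds every lesion intensity; "
            "corrected volume set to 0", seg.label_id, threshold,
        )
        return LesionScore(
            label_id=seg.label_id, mixture=mix, threshold_hu=threshold,
            x_min_hu=float("nan"), x_max_hu=float("nan"), n_voxels=0,
            ccs_volume_mm3=ccs, pvc_volume_mm3=0.0, scored_mask=scored_mask,
            status="empty_scored_set",
        )

    scored = hu[scored_mask].astype(float)
    x_max = float(scored.max())
    if cfg.xmin_mode == "supra_threshold":
        x_min = float(scored.min())
    elif cfg.xmin_mode == "literal_lesion_min":
        x_min = float(hu[calc].min())
    else:  # "threshold"
        x_min = float(threshold)
    pvc = partial_content(scored, x_min, x_max)
    pvc = np.atleast_1d(pvc)
    status = "ok"
    if x_max == x_min:
        status = "single_intensity"
        logger.info("lesion %d: single-intensity lesion, fractions set to 1", seg.label_id)
    return LesionScore(
        label_id=seg.label_id, mixture=mix, threshold_hu=threshold,
        x_min_hu=x_min, x_max_hu=x_max, n_voxels=int(scored_mask.sum()),
        ccs_volume_mm3=ccs, pvc_volume_mm3=float(pvc.sum() * vox),
        scored_mask=scored_mask, pvc_values=pvc, status=status,
    )


@dataclass
class ScanResult:
    """All per-lesion segmentations and scores of one volume."""

    segmentations: list[LesionSegmentation]
    scores: list[LesionScore]

    @property
    def total_ccs_mm3(self) -> float:
        return float(sum(s.ccs_volume_mm3 for s in self.scores))

    @property
    def total_pvc_mm3(self) -> float:
        return float(sum(s.pvc_volume_mm3 for s in self.scores))


def score_scan(volume: CTVolume, config: RunConfig | None = None) -> ScanResult:
    """Detect, segment and score every lesion in a volume.

    Per-lesion failures (e.g. a degenerate intensity sample) are recorded in
    the lesion's ``status`` without aborting the scan; a degenerate lesion
    falls back to whole-voxel content (corrected volume equals the clinical
    volume) since each of its voxels exceeded the detection threshold.
    """
    cfg = config or RunConfig()
    segs = segment_lesions(
        volume,
        detection_threshold_hu=cfg.detection_threshold_hu,
        extension_threshold_hu=cfg.extension_threshold_hu,
        min_voxels=cfg.min_lesion_voxels,
    )
    scores = []
    for seg in segs:
        try:
            scores.append(score_lesion(volume, seg, cfg))
        except DegenerateIntensitiesError:
            ccs = float(seg.initial_mask.sum()) * volume.voxel_volume_mm3
            scores.append(
                LesionScore(
                    label_id=seg.label_id, mixture=None, threshold_hu=float("nan"),
                    x_min_hu=float("nan"), x_max_hu=float("nan"),
                    n_voxels=int(seg.initial_mask.sum()), ccs_volume_mm3=ccs,
                    pvc_volume_mm3=ccs, status="degenerate_intensities",
                )
            )
    return ScanResult(segmentations=segs, scores=scores)
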