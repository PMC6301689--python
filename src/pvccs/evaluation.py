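"""Evaluation machinery: ratios, repeatability summaries, agreement statistics.

Covers the quantities used to characterize calcium-scoring performance on
simulated phantoms (measured/true volume ratios, median and range over
repeated acquisitions) and agreement between paired reconstructions of one
acquisition (min-max scaling, Bland-Altman bias with 95% limits of
agreement, and the two-way random-effects absolute-agreement single-measure
intraclass correlation, ICC(2,1)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .config import RunConfig
from .phantom_sim import (
    GroundTruth,
    KernelConfig,
    SHARP_KERNEL,
    SOFT_KERNEL,
    JITTER_ROTATION_DEG,
    JITTER_TRANSLATION_MM,
    make_ceora_spec,
    make_random_spec,
    make_sati_spec,
    simulate_acquisition,
    simulate_paired_reconstructions,
)
from .pvc_scoring import ScanResult, score_scan

__all__ = [
    "AgreementStats",
    "volume_ratio",
    "median_range",
    "minmax_scale_volumes",
    "bland_altman",
    "icc_agreement",
    "match_scores_to_inserts",
    "run_phantom_experiment",
    "summarize_phantom_report",
    "run_kernel_agreement_experiment",
    "kernel_agreement_stats",
]


@dataclass
class AgreementStats:
    """Paired-measurement agreement summary.

    ``bias`` is the mean paired difference and ``loa_low``/``loa_high`` the
    95% limits of agreement (bias +/- 1.96 x SD of the differences, sample
    SD). ICC fields are filled by :func:`icc_agreement` and ``None`` when
    only a Bland-Altman analysis was run.
    """

    bias: float
    loa_low: float
    loa_high: float
    n_pairs: int
    icc: float | None = None
    icc_ci_low: float | None = None
    icc_ci_high: float | None = None


def volume_ratio(measured_mm3: float, reference_mm3: float) -> float:
    """Measured over reference volume; the reference must be positive."""
    if reference_mm3 <= 0:
        raise ValueError("reference volume must be strictly positive")
    return measured_mm3 / reference_mm3


def median_range(values) -> tuple[float, float, float]:
    """Sample median (mean of the middle two for even n), min and max."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("median_range of an empty sequence is undefined")
    return float(np.median(v)), float(v.min()), float(v.max())


def minmax_scale_volumes(volumes, reference_set) -> np.ndarray:
    """Scale volumes by the maximum of the reference set (soft-kernel scores).

    Division by a positive scalar, so ranks are preserved and the largest
    reference volume maps to exactly 1.
    """
    ref = np.asarray(list(reference_set), dtype=float)
    if ref.size == 0 or ref.max() <= 0:
        raise ValueError("reference set must contain a positive volume")
    return np.asarray(list(volumes), dtype=float) / ref.max()


def bland_altman(a, b) -> AgreementStats:
    """Bland-Altman agreement of paired measurements (differences a - b).

    By convention ``a`` holds the soft-kernel and ``b`` the sharp-kernel
    scores, so a method that scores higher on sharp reconstructions shows a
    negative bias.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    if a.size < 2:
        raise ValueError("Bland-Altman analysis needs at least two pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n_pairs=a.size
    )


def _icc2_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Row/column/error mean squares of the two-way ANOVA on an n x k table."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_agreement(a, b) -> AgreementStats:
    """ICC(2,1) with a 95% CI for paired measurements, plus Bland-Altman.

    Two-way random-effects, absolute-agreement, single-measurement intraclass
    correlation: paired reconstructions act as two "raters" of one underlying
    calcium volume, and absolute agreement (not mere consistency) is what
    reproducibility requires. From the mean-squares decomposition,
    ``ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``; the
    confidence interval uses the standard F-distribution method with
    Satterthwaite degrees of freedom (McGraw & Wong case 2A).
    """
    from scipy.stats import f as f_dist

    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    n = a.size
    if n < 5:
        raise ValueError("ICC with a meaningful CI needs at least 5 pairs")
    if np.var(np.concatenate([a, b])) == 0:
        raise ValueError("ICC is undefined for zero total variance")
    k = 2
    msr, msc, mse = _icc2_mean_squares(np.column_stack([a, b]))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    ba = bland_altman(a, b)
    if mse == 0.0 and msc == 0.0:  # perfect agreement: CI collapses
        return dc_replace(ba, icc=1.0, icc_ci_low=1.0, icc_ci_high=1.0)
    alpha = 0.05
    num = k * icc / (n * (1.0 - icc)) * msc + (1.0 + k * icc * (n - 1) / (n * (1.0 - icc))) * mse
    va = k * icc / (n * (1.0 - icc)) * msc
    vb = (1.0 + k * icc * (n - 1) / (n * (1.0 - icc))) * mse
    v = num**2 / (va**2 / (k - 1) + vb**2 / ((n - 1) * (k - 1)))
    f_l = f_dist.ppf(1 - alpha / 2, n - 1, v)
    f_u = f_dist.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return dc_replace(ba, icc=float(icc), icc_ci_low=float(lower), icc_ci_high=float(upper))


# ---------------------------------------------------------------------------
# phantom experiment harnesses
# ---------------------------------------------------------------------------

def match_scores_to_inserts(result: ScanResult, gt: GroundTruth) -> pd.DataFrame:
    """Attribute per-lesion scores to ground-truth inserts by mask overlap.

    Each detected lesion is assigned to the insert whose fractional-occupancy
    map overlaps its initial segmentation most; lesions overlapping no insert
    (pure noise components) are dropped. Undetected inserts appear with zero
    scores.
    """
    n = len(gt.inserts)
    ccs = np.zeros(n)
    pvc = np.zeros(n)
    for seg, score in zip(result.segmentations, result.scores):
        overlaps = np.array([float(occ[seg.initial_mask].sum()) for occ in gt.occupancy])
        if overlaps.size == 0 or overlaps.max() <= 0:
            continue
        j = int(overlaps.argmax())
        ccs[j] += score.ccs_volume_mm3
        pvc[j] += score.pvc_volume_mm3
    return pd.DataFrame(
        {
            "insert_id": [ins.insert_id for ins in gt.inserts],
            "size": [ins.size_label for ins in gt.inserts],
            "density_mg_cm3": [ins.ha_density_mg_cm3 for ins in gt.inserts],
            "true_mm3": gt.true_volumes_mm3,
            "detected": ccs > 0,
            "ccs_mm3": ccs,
            "pvc_mm3": pvc,
        }
    )


def _derived_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2**31))


def run_phantom_experiment(
    preset: str = "ceora",
    ring: str = "none",
    velocity_mm_s: float = 0.0,
    repeats: int = 5,
    seed: int = 0,
    config: RunConfig | None = None,
    reposition: bool = True,
) -> pd.DataFrame:
    """Simulate repeated phantom acquisitions and score each with both methods.

    Each repeat repositions the phantom slightly (sub-voxel translation plus
    a small rotation, as between physical repeat scans) unless ``reposition``
    is false, and uses an independent noise realization. Returns a tidy frame
    with one row per (repeat, insert): true volume, detection flag, clinical
    and corrected volume scores.
    """
    if preset == "ceora":
        base = make_ceora_spec(ring=ring)
    elif preset == "sati":
        base = make_sati_spec(velocity_mm_s=velocity_mm_s)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    if reposition:
        base = dc_replace(
            base,
            jitter_translation_mm=JITTER_TRANSLATION_MM,
            jitter_rotation_deg=JITTER_ROTATION_DEG,
        )
    children = np.random.SeedSequence(seed).spawn(repeats)
    frames = []
    for r, child in enumerate(children):
        spec = dc_replace(base, seed=_derived_seed(child))
        volume, gt = simulate_acquisition(spec)
        result = score_scan(volume, config)
        df = match_scores_to_inserts(result, gt)
        df.insert(0, "repeat", r)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def summarize_phantom_report(df: pd.DataFrame) -> pd.DataFrame:
    """Per-density median (range) of total detected volumes over repeats.

    Mirrors the layout of repeatability tables: per HA density, the total
    clinical and corrected volume summed over that density's detected
    inserts, summarized as median, min and max over the repeated scans.
    """
    totals = (
        df.groupby(["density_mg_cm3", "repeat"])[["ccs_mm3", "pvc_mm3"]].sum().reset_index()
    )
    rows = []
    for density, grp in totals.groupby("density_mg_cm3"):
        row = {"density_mg_cm3": density}
        for method in ("ccs", "pvc"):
            med, lo, hi = median_range(grp[f"{method}_mm3"])
            row[f"{method}_median_mm3"] = med
            row[f"{method}_min_mm3"] = lo
            row[f"{method}_max_mm3"] = hi
        rows.append(row)
    return pd.DataFrame(rows).sort_values("density_mg_cm3", ascending=False, ignore_index=True)


def run_kernel_agreement_experiment(
    n_pairs: int = 50,
    seed: int = 0,
    sharp: KernelConfig = SHARP_KERNEL,
    soft: KernelConfig = SOFT_KERNEL,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Score paired sharp/soft reconstructions of randomized phantoms.

    Each pair shares one simulated acquisition (geometry and motion) and
    differs only in the reconstruction-kernel surrogate (PSF width and noise
    level). Returns one row per pair with the total clinical and corrected
    volume scores under each kernel.
    """
    children = np.random.SeedSequence(seed).spawn(n_pairs)
    rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        spec = make_random_spec(rng, seed=_derived_seed(child.spawn(1)[0]))
        volumes, _ = simulate_paired_reconstructions(
            spec, {"sharp": sharp, "soft": soft}
        )
        row = {"pair": i}
        for kernel, vol in volumes.items():
            result = score_scan(vol, config)
            row[f"{kernel}_ccs_mm3"] = result.total_ccs_mm3
            row[f"{kernel}_pvc_mm3"] = result.total_pvc_mm3
        rows.append(row)
    return pd.DataFrame(rows)


def kernel_agreement_stats(pairs: pd.DataFrame) -> dict[str, AgreementStats]:
    """Agreement between kernels per scoring method on min-max-scaled volumes.

    Volumes are scaled per method by the maximum soft-kernel volume of that
    method (clinical and corrected scores live on different absolute scales),
    then summarized with Bland-Altman (soft - sharp) and ICC(2,1).
    """
    out = {}
    for method in ("ccs", "pvc"):
        soft = pairs[f"soft_{method}_mm3"].to_numpy(dtype=float)
        sharp = pairs[f"sharp_{method}_mm3"].to_numpy(dtype=float)
        a = minmax_scale_volumes(soft, soft)
        b = minmax_scale_volumes(sharp, soft)
        out[method] = icc_agreement(a, b)
    return out
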