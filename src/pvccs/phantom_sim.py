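"""Digital CT phantom simulation for calcium-scoring experiments.

This module generates synthetic CT volumes that emulate two physical
calcium-scoring phantoms at desk scale:

* a thorax phantom carrying nine cylindrical hydroxyapatite (HA) inserts
  (three sizes x three densities), optionally wrapped in extension rings
  that emulate patient girth, and
* a motion-capable phantom whose artificial arteries carry circular-segment
  (half-cylinder-like) inserts in a 50 HU blood-equivalent background,
  translated in the transverse plane at a configurable velocity.

Image formation is modelled entirely in the image domain:

1. analytic rasterization of the inserts on a grid supersampled in all axes,
2. HU assignment via an affine HA-density-to-HU calibration,
3. transverse box blur for motion (kernel width = velocity x exposure time),
4. isotropic in-plane Gaussian blur standing in for the scanner/reconstruction
   point spread function,
5. block averaging down to the reconstruction grid -- this step produces the
   partial volume effect the scoring method corrects for, and
6. additive i.i.d. Gaussian noise.

No projection-domain physics (sinograms, filtered backprojection, beam
hardening, spectral effects) is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .volume import CTVolume

__all__ = [
    "InsertSpec",
    "PhantomSpec",
    "GroundTruth",
    "KernelConfig",
    "SimulationSizeError",
    "cylinder_volume",
    "segment_volume",
    "ha_to_hu",
    "simulate_acquisition",
    "simulate_paired_reconstructions",
    "make_ceora_spec",
    "make_sati_spec",
    "make_random_spec",
]

#: Default affine HA-density -> HU calibration (slope HU per mg/cm^3, offset HU).
#: The slope places 200/400/800 mg/cm^3 inserts at 320/640/1280 HU, within
#: realistic 120 kVp ranges and all above the 130 HU detection threshold
#: before blurring.
DEFAULT_CALIBRATION: tuple[float, float] = (1.6, 0.0)

#: Noise level (HU) per extension-ring configuration. Rings are geometrically
#: irrelevant to the insert signal; a larger girth mainly degrades photon
#: statistics, so rings are modelled purely as increased image noise.
RING_NOISE_HU: dict[str, float] = {"none": 10.0, "M": 15.0, "L": 20.0}

#: Amplitude of the sub-voxel repositioning between repeated acquisitions
#: (translation per axis in mm, rotation about the scan axis in degrees).
#: Emulates the slight translation/rotation of the phantom between scans.
JITTER_TRANSLATION_MM: tuple[float, float, float] = (0.2, 0.2, 1.5)
JITTER_ROTATION_DEG: float = 2.0

#: Hard cap on the supersampled grid size (voxels) to keep memory bounded.
MAX_SUPERSAMPLED_VOXELS: int = 2**28


class SimulationSizeError(RuntimeError):
    """Supersampled grid would exceed the configured memory budget."""


# ---------------------------------------------------------------------------
# analytic insert geometry
# ---------------------------------------------------------------------------

def cylinder_volume(diameter_mm: float, length_mm: float) -> float:
    """Analytic volume of a cylinder, pi*(d/2)^2 * L, in mm^3."""
    if diameter_mm < 0 or length_mm < 0:
        raise ValueError("cylinder dimensions must be non-negative")
    return math.pi * (diameter_mm / 2.0) ** 2 * length_mm


def segment_volume(radius_mm: float, cap_height_mm: float, length_mm: float) -> float:
    """Analytic volume of a circular-segment prism in mm^3.

    The cross section is the circular segment of a circle of radius ``R``
    cut by a chord at height ``h`` from the rim:
    ``A = R^2 * acos((R - h)/R) - (R - h) * sqrt(2Rh - h^2)``.
    ``h = 2R`` gives the full circle, ``h = R`` the half disc.
    """
    R, h = radius_mm, cap_height_mm
    if R < 0 or length_mm < 0:
        raise ValueError("segment dimensions must be non-negative")
    if not 0 <= h <= 2 * R:
        raise ValueError(f"cap height {h} must lie in [0, 2R] = [0, {2 * R}]")
    if R == 0 or h == 0:
        return 0.0
    area = R * R * math.acos((R - h) / R) - (R - h) * math.sqrt(2 * R * h - h * h)
    return area * length_mm


def ha_to_hu(
    ha_density_mg_cm3: float, calibration: tuple[float, float] = DEFAULT_CALIBRATION
) -> float:
    """Map hydroxyapatite density (mg/cm^3) to Hounsfield units.

    Affine model ``HU = slope * rho + offset``; scanners are calibrated so
    that CT numbers scale approximately linearly with mineral density at a
    fixed tube voltage.
    """
    if ha_density_mg_cm3 < 0:
        raise ValueError("HA density must be non-negative")
    slope, offset = calibration
    return slope * ha_density_mg_cm3 + offset


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertSpec:
    """One calcification insert.

    ``cylinder`` inserts use ``diameter_mm``; ``circular_segment`` inserts
    use ``radius_mm`` + ``cap_height_mm`` and may be rotated about the scan
    axis by ``rotation_deg`` (the cap normal direction in the x-y plane).
    Both shapes extrude along z (inserts are oriented parallel to the CT
    scanning direction).
    """

    shape: Literal["cylinder", "circular_segment"]
    length_mm: float
    ha_density_mg_cm3: float
    center_mm: tuple[float, float, float]
    diameter_mm: float | None = None
    radius_mm: float | None = None
    cap_height_mm: float | None = None
    rotation_deg: float = 0.0
    axis: str = "z"
    insert_id: str = ""
    size_label: str = ""

    def __post_init__(self) -> None:
        if self.axis != "z":
            raise ValueError("only z-oriented inserts are supported")
        if self.length_mm <= 0:
            raise ValueError("length must be strictly positive")
        if self.ha_density_mg_cm3 <= 0:
            raise ValueError("HA density must be strictly positive")
        if self.shape == "cylinder":
            if self.diameter_mm is None or self.diameter_mm <= 0:
                raise ValueError("cylinder requires strictly positive diameter_mm")
        elif self.shape == "circular_segment":
            if self.radius_mm is None or self.radius_mm <= 0:
                raise ValueError("circular_segment requires strictly positive radius_mm")
            if self.cap_height_mm is None or self.cap_height_mm <= 0:
                raise ValueError("circular_segment requires strictly positive cap_height_mm")
            if self.cap_height_mm > 2 * self.radius_mm:
                raise ValueError("cap_height_mm must not exceed 2 * radius_mm")
        else:
            raise ValueError(f"unknown insert shape {self.shape!r}")

    @property
    def true_volume_mm3(self) -> float:
        """Analytic ground-truth volume of the insert."""
        if self.shape == "cylinder":
            return cylinder_volume(self.diameter_mm, self.length_mm)
        return segment_volume(self.radius_mm, self.cap_height_mm, self.length_mm)

    @property
    def radial_extent_mm(self) -> float:
        return self.diameter_mm / 2.0 if self.shape == "cylinder" else self.radius_mm


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of one virtual phantom acquisition.

    The reconstruction grid is derived from ``fov_mm``: in-plane voxels of
    ``in_plane_spacing_mm`` and slices of ``slice_thickness_mm`` spaced by
    ``slice_increment_mm`` (overlapping slices when increment < thickness).
    ``supersampling_factor`` controls the resolution of the internal analytic
    raster in all three axes.
    """

    inserts: tuple[InsertSpec, ...]
    background_hu: float = 0.0
    fov_mm: tuple[float, float, float] = (32.0, 32.0, 9.0)
    in_plane_spacing_mm: float = 0.4
    slice_thickness_mm: float = 3.0
    slice_increment_mm: float = 3.0
    supersampling_factor: int = 8
    psf_sigma_mm: float = 0.6
    noise_sigma_hu: float = 10.0
    motion_velocity_mm_s: float = 0.0
    # effective temporal aperture of one reconstructed slice: roughly half a
    # 0.4 s gantry rotation (half-scan reconstruction), so a moving insert is
    # smeared over velocity * 0.2 s in the transverse plane
    exposure_time_s: float = 0.2
    jitter_translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    jitter_rotation_deg: float = 0.0
    calibration: tuple[float, float] = DEFAULT_CALIBRATION
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "inserts", tuple(self.inserts))
        if self.in_plane_spacing_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("voxel spacing must be strictly positive")
        if not 0 < self.slice_increment_mm <= self.slice_thickness_mm:
            raise ValueError("slice increment must be in (0, slice_thickness]")
        if self.noise_sigma_hu < 0:
            raise ValueError("noise_sigma_hu must be non-negative")
        if self.motion_velocity_mm_s < 0 or self.exposure_time_s < 0:
            raise ValueError("motion velocity and exposure time must be non-negative")
        f = self.supersampling_factor
        if f < 1 or int(f) != f:
            raise ValueError("supersampling_factor must be an integer >= 1")
        inc_ss = f * self.slice_increment_mm / self.slice_thickness_mm
        if abs(inc_ss - round(inc_ss)) > 1e-9:
            raise ValueError(
                "supersampling_factor * increment / thickness must be an integer "
                "so reconstructed slices align with the supersampled z grid"
            )

    # -- grid geometry -----------------------------------------------------

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """Reconstruction grid (nx, ny, n_slices)."""
        nx = int(round(self.fov_mm[0] / self.in_plane_spacing_mm))
        ny = int(round(self.fov_mm[1] / self.in_plane_spacing_mm))
        ns = int(round((self.fov_mm[2] - self.slice_thickness_mm) / self.slice_increment_mm)) + 1
        if nx < 1 or ny < 1 or ns < 1:
            raise ValueError("field of view too small for the requested grid")
        return nx, ny, ns

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        """Reconstruction voxel spacing; z spacing is the slice increment."""
        return (self.in_plane_spacing_mm, self.in_plane_spacing_mm, self.slice_increment_mm)

    @property
    def _inc_ss(self) -> int:
        """Slice increment expressed in supersampled z steps."""
        f = self.supersampling_factor
        return int(round(f * self.slice_increment_mm / self.slice_thickness_mm))

    @property
    def supersampled_shape(self) -> tuple[int, int, int]:
        nx, ny, ns = self.grid_shape
        f = self.supersampling_factor
        return nx * f, ny * f, (ns - 1) * self._inc_ss + f


@dataclass
class GroundTruth:
    """True geometry of an acquisition: analytic volumes and occupancy maps.

    ``occupancy`` holds, per insert, the fraction of each reconstruction
    voxel covered by the (unblurred, unmoved) insert, obtained by
    supersampled rasterization. Summing an occupancy map times the voxel
    volume converges to the analytic volume as the supersampling factor
    grows (<= 1% relative error at factor 8 for contiguous slice grids).
    """

    inserts: tuple[InsertSpec, ...]
    true_volumes_mm3: np.ndarray
    occupancy: list[np.ndarray]
    voxel_volume_mm3: float

    def occupancy_volume_mm3(self, index: int) -> float:
        """Raster-estimated volume of one insert (occupancy sum x voxel volume)."""
        return float(self.occupancy[index].sum() * self.voxel_volume_mm3)


@dataclass(frozen=True)
class KernelConfig:
    """Image-domain surrogate for a reconstruction kernel.

    Sharp kernels trade a narrow PSF for more noise; soft kernels the
    reverse. Paired reconstructions of one acquisition share the same
    noiseless master raster and differ only in blur and noise.
    """

    psf_sigma_mm: float
    noise_sigma_hu: float


#: Default sharp/soft reconstruction-kernel surrogates.
SHARP_KERNEL = KernelConfig(psf_sigma_mm=0.35, noise_sigma_hu=18.0)
SOFT_KERNEL = KernelConfig(psf_sigma_mm=0.9, noise_sigma_hu=7.0)


# ---------------------------------------------------------------------------
# rasterization machinery
# ---------------------------------------------------------------------------

def _edge_ramp(signed_distance_mm: np.ndarray, pixel_mm: float) -> np.ndarray:
    """Approximate pixel coverage by a boundary: linear ramp one pixel wide.

    ``signed_distance_mm`` is positive inside the shape. Anti-aliases the
    rasterization so occupancy sums converge to analytic volumes much faster
    than binary center-in-shape sampling.
    """
    return np.clip(signed_distance_mm / pixel_mm + 0.5, 0.0, 1.0)


def _insert_occupancy(
    ins: InsertSpec,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    pixel_mm: float,
    dz_mm: float,
) -> np.ndarray:
    """Fractional occupancy of an insert at broadcastable voxel-center coords.

    In-plane coverage uses sub-pixel edge ramps; along z the overlap of each
    voxel's slab with the insert's extent is exact (inserts extrude along z).
    """
    cx, cy, cz = ins.center_mm
    z0, z1 = cz - ins.length_mm / 2.0, cz + ins.length_mm / 2.0
    zfrac = np.clip(
        (np.minimum(z + dz_mm / 2.0, z1) - np.maximum(z - dz_mm / 2.0, z0)) / dz_mm, 0.0, 1.0
    )
    dx, dy = x - cx, y - cy
    rho = np.sqrt(dx * dx + dy * dy)
    if ins.shape == "cylinder":
        inplane = _edge_ramp(ins.diameter_mm / 2.0 - rho, pixel_mm)
    else:
        R, h = ins.radius_mm, ins.cap_height_mm
        theta = math.radians(ins.rotation_deg)
        proj = dx * math.cos(theta) + dy * math.sin(theta)
        inplane = _edge_ramp(R - rho, pixel_mm) * _edge_ramp(proj - (R - h), pixel_mm)
    return (inplane * zfrac).astype(np.float32)


def _jittered_inserts(spec: PhantomSpec, rng: np.random.Generator) -> tuple[InsertSpec, ...]:
    """Apply the seed-controlled rigid repositioning to all inserts.

    The rotation is about the center of the field of view in the transverse
    plane; the translation is drawn per axis. Zero amplitudes reproduce the
    nominal geometry exactly (the draws still consume RNG state so the noise
    stream is independent of the jitter configuration).
    """
    t = rng.uniform(-1.0, 1.0, size=3) * np.asarray(spec.jitter_translation_mm)
    theta = math.radians(rng.uniform(-1.0, 1.0) * spec.jitter_rotation_deg)
    cx0, cy0 = spec.fov_mm[0] / 2.0, spec.fov_mm[1] / 2.0
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    out = []
    for ins in spec.inserts:
        x, y, z = ins.center_mm
        rx, ry = x - cx0, y - cy0
        nx = cx0 + cos_t * rx - sin_t * ry + t[0]
        ny = cy0 + sin_t * rx + cos_t * ry + t[1]
        out.append(
            replace(
                ins,
                center_mm=(nx, ny, z + t[2]),
                rotation_deg=ins.rotation_deg + math.degrees(theta),
            )
        )
    return tuple(out)


def _bbox_slices(ins: InsertSpec, spec: PhantomSpec) -> tuple[slice, slice, slice]:
    """Supersampled-grid bounding box of an insert, clipped to the grid."""
    nxs, nys, nzs = spec.supersampled_shape
    f = spec.supersampling_factor
    dxs = spec.in_plane_spacing_mm / f
    dzs = spec.slice_thickness_mm / f
    cx, cy, cz = ins.center_mm
    r = ins.radial_extent_mm + max(0.3, dxs)
    hl = ins.length_mm / 2.0 + max(0.3, dzs)

    def rng(lo: float, hi: float, step: float, n: int) -> slice:
        i0 = max(0, int(math.floor(lo / step)))
        i1 = min(n, int(math.ceil(hi / step)) + 1)
        return slice(i0, max(i1, i0))

    return (
        rng(cx - r, cx + r, dxs, nxs),
        rng(cy - r, cy + r, dxs, nys),
        rng(cz - hl, cz + hl, dzs, nzs),
    )


def _ss_coords(sl: tuple[slice, slice, slice], spec: PhantomSpec):
    f = spec.supersampling_factor
    dxs = spec.in_plane_spacing_mm / f
    dzs = spec.slice_thickness_mm / f
    x = (np.arange(sl[0].start, sl[0].stop) + 0.5) * dxs
    y = (np.arange(sl[1].start, sl[1].stop) + 0.5) * dxs
    z = (np.arange(sl[2].start, sl[2].stop) + 0.5) * dzs
    return x[:, None, None], y[None, :, None], z[None, None, :]


def _rasterize_master(spec: PhantomSpec, inserts: Sequence[InsertSpec]) -> np.ndarray:
    """Supersampled HU raster with motion blur applied (no PSF, no noise)."""
    nxs, nys, nzs = spec.supersampled_shape
    if nxs * nys * nzs > MAX_SUPERSAMPLED_VOXELS:
        raise SimulationSizeError(
            f"supersampled grid {nxs}x{nys}x{nzs} exceeds the "
            f"{MAX_SUPERSAMPLED_VOXELS}-voxel budget; reduce the field of "
            "view or the supersampling factor"
        )
    hu = np.full((nxs, nys, nzs), spec.background_hu, dtype=np.float32)
    f = spec.supersampling_factor
    dxs = spec.in_plane_spacing_mm / f
    dzs = spec.slice_thickness_mm / f
    for ins in inserts:
        sl = _bbox_slices(ins, spec)
        x, y, z = _ss_coords(sl, spec)
        occ = _insert_occupancy(ins, x, y, z, dxs, dzs)
        excess = ha_to_hu(ins.ha_density_mg_cm3, spec.calibration) - spec.background_hu
        hu[sl] += excess * occ
    if spec.motion_velocity_mm_s > 0 and spec.exposure_time_s > 0:
        dxs = spec.in_plane_spacing_mm / spec.supersampling_factor
        width = int(round(spec.motion_velocity_mm_s * spec.exposure_time_s / dxs))
        if width >= 2:
            ndimage.uniform_filter1d(hu, size=width, axis=0, mode="nearest", output=hu)
    return hu


def _reconstruct(
    hu_ss: np.ndarray, spec: PhantomSpec, psf_sigma_mm: float
) -> np.ndarray:
    """In-plane Gaussian PSF then block averaging to the reconstruction grid."""
    f = spec.supersampling_factor
    if psf_sigma_mm > 0:
        sigma_vox = psf_sigma_mm / (spec.in_plane_spacing_mm / f)
        hu_ss = ndimage.gaussian_filter(hu_ss, sigma=(sigma_vox, sigma_vox, 0), mode="nearest")
    return _downsample(hu_ss, spec)


def _downsample(arr_ss: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Block-average the supersampled grid down to the reconstruction grid.

    In-plane axes are averaged in contiguous f x f blocks; each output slice
    averages an f-sample window of the supersampled z axis centred on the
    slice, with consecutive windows offset by the slice increment (windows
    overlap when increment < thickness).
    """
    nx, ny, ns = spec.grid_shape
    f = spec.supersampling_factor
    inc = spec._inc_ss
    a = arr_ss.reshape(nx, f, ny, f, arr_ss.shape[2]).mean(axis=(1, 3))
    out = np.empty((nx, ny, ns), dtype=arr_ss.dtype)
    for k in range(ns):
        out[:, :, k] = a[:, :, k * inc : k * inc + f].mean(axis=2)
    return out


def _occupancy_map(ins: InsertSpec, spec: PhantomSpec) -> np.ndarray:
    """Fractional occupancy of one insert on the reconstruction grid."""
    nx, ny, ns = spec.grid_shape
    f = spec.supersampling_factor
    inc = spec._inc_ss
    sl = _bbox_slices(ins, spec)
    # widen the in-plane bounding box to whole reconstruction blocks
    i0, i1 = sl[0].start // f, min(nx, -(-sl[0].stop // f))
    j0, j1 = sl[1].start // f, min(ny, -(-sl[1].stop // f))
    # z: reconstruction slices whose window intersects the bbox
    k0 = max(0, (sl[2].start - f + 1 + inc - 1) // inc) if inc else 0
    k0 = max(0, min(ns - 1, k0))
    k1 = min(ns, sl[2].stop // inc + 1)
    out = np.zeros((nx, ny, ns), dtype=np.float32)
    if i1 <= i0 or j1 <= j0 or k1 <= k0:
        return out
    zsl = slice(k0 * inc, (k1 - 1) * inc + f)
    sub = (slice(i0 * f, i1 * f), slice(j0 * f, j1 * f), zsl)
    x, y, z = _ss_coords(sub, spec)
    dxs = spec.in_plane_spacing_mm / f
    dzs = spec.slice_thickness_mm / f
    occ = _insert_occupancy(ins, x, y, z, dxs, dzs)
    a = occ.reshape(i1 - i0, f, j1 - j0, f, occ.shape[2]).mean(axis=(1, 3))
    for k in range(k0, k1):
        lo = k * inc - zsl.start
        out[i0:i1, j0:j1, k] = a[:, :, lo : lo + f].mean(axis=2)
    return out


def _ground_truth(spec: PhantomSpec, inserts: Sequence[InsertSpec]) -> GroundTruth:
    dx, dy, dz = spec.spacing_mm
    return GroundTruth(
        inserts=tuple(inserts),
        true_volumes_mm3=np.array([ins.true_volume_mm3 for ins in inserts]),
        occupancy=[_occupancy_map(ins, spec) for ins in inserts],
        voxel_volume_mm3=dx * dy * dz,
    )


# ---------------------------------------------------------------------------
# acquisition pipelines
# ---------------------------------------------------------------------------

def _seed_streams(spec: PhantomSpec, n_noise: int = 1):
    children = np.random.SeedSequence(spec.seed).spawn(1 + n_noise)
    rng_jitter = np.random.default_rng(children[0])
    rng_noise = [np.random.default_rng(c) for c in children[1:]]
    return rng_jitter, rng_noise


def simulate_acquisition(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Simulate one CT acquisition of a phantom.

    Returns the reconstructed volume and the ground truth (analytic insert
    volumes plus fractional-occupancy maps of the jittered geometry). All
    randomness -- sub-voxel repositioning and image noise -- derives from
    ``spec.seed``; identical specs yield bit-identical volumes.
    """
    rng_jitter, (rng_noise,) = _seed_streams(spec)
    inserts = _jittered_inserts(spec, rng_jitter)
    hu_ss = _rasterize_master(spec, inserts)
    recon = _reconstruct(hu_ss, spec, spec.psf_sigma_mm)
    if spec.noise_sigma_hu > 0:
        recon = recon + rng_noise.normal(0.0, spec.noise_sigma_hu, recon.shape).astype(np.float32)
    volume = CTVolume(recon.astype(np.float32), spec.spacing_mm)
    return volume, _ground_truth(spec, inserts)


def simulate_paired_reconstructions(
    spec: PhantomSpec, kernels: Mapping[str, KernelConfig] | None = None
) -> tuple[dict[str, CTVolume], GroundTruth]:
    """Reconstruct one simulated acquisition with several kernel surrogates.

    All reconstructions share one noiseless master raster (geometry, motion),
    mirroring paired sharp/soft reconstructions of a single physical
    acquisition; each kernel then applies its own PSF and noise realization.
    """
    if kernels is None:
        kernels = {"sharp": SHARP_KERNEL, "soft": SOFT_KERNEL}
    rng_jitter, noise_rngs = _seed_streams(spec, n_noise=len(kernels))
    inserts = _jittered_inserts(spec, rng_jitter)
    hu_ss = _rasterize_master(spec, inserts)
    volumes: dict[str, CTVolume] = {}
    for (name, kern), rng in zip(kernels.items(), noise_rngs):
        recon = _reconstruct(hu_ss, spec, kern.psf_sigma_mm)
        if kern.noise_sigma_hu > 0:
            recon = recon + rng.normal(0.0, kern.noise_sigma_hu, recon.shape).astype(np.float32)
        volumes[name] = CTVolume(recon.astype(np.float32), spec.spacing_mm)
    return volumes, _ground_truth(spec, inserts)


# ---------------------------------------------------------------------------
# phantom presets
# ---------------------------------------------------------------------------

#: (label, diameter mm, length mm) of the cylindrical inserts.
CEORA_SIZES = (("large", 5.0, 5.0), ("medium", 3.0, 3.0), ("small", 1.0, 1.0))
#: (label, cap height mm, z center mm, rotation deg) of the segment inserts.
SATI_SIZES = (("large", 2.0, 7.5, 0.0), ("medium", 1.0, 22.5, 60.0), ("small", 0.5, 37.5, -60.0))
SATI_SEGMENT_RADIUS_MM = 2.0
SATI_SEGMENT_LENGTH_MM = 10.0
HA_DENSITIES = (800.0, 400.0, 200.0)


def make_ceora_spec(ring: str = "none", seed: int = 0, **overrides) -> PhantomSpec:
    """Replica spec of the cylindrical-insert thorax phantom.

    Nine cylinders (large 98.2, medium 21.2, small 0.8 mm^3; each at 800,
    400 and 200 mg/cm^3) on a 3x3 transverse layout, axes parallel to z,
    scanned at 3 mm slice thickness and increment. ``ring`` selects the
    extension-ring configuration, which only scales the noise level.
    """
    if ring not in RING_NOISE_HU:
        raise ValueError(f"ring must be one of {sorted(RING_NOISE_HU)}, got {ring!r}")
    positions = (6.0, 16.0, 26.0)
    inserts = []
    for density, y in zip(HA_DENSITIES, positions):
        for (label, diameter, length), x in zip(CEORA_SIZES, positions):
            inserts.append(
                InsertSpec(
                    shape="cylinder",
                    diameter_mm=diameter,
                    length_mm=length,
                    ha_density_mg_cm3=density,
                    center_mm=(x, y, 4.5),
                    insert_id=f"{label}_{int(density)}",
                    size_label=label,
                )
            )
    defaults = dict(
        inserts=tuple(inserts),
        background_hu=35.0,
        fov_mm=(32.0, 32.0, 9.0),
        noise_sigma_hu=RING_NOISE_HU[ring],
        seed=seed,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def make_sati_spec(velocity_mm_s: float = 0.0, seed: int = 0, **overrides) -> PhantomSpec:
    """Replica spec of the motion phantom with circular-segment inserts.

    Three artificial arteries (one per HA density) run parallel to z in a
    50 HU blood-equivalent background; each carries three segment inserts
    (large 62.8, medium 24.6, small 9.1 mm^3) stacked along z and mutually
    rotated +/-60 degrees about the artery axis. The segment radius of
    2.0 mm is inferred: it reproduces all three nominal volumes exactly.
    Motion translates the arteries in the transverse plane at
    ``velocity_mm_s`` (0, 10 or 30 mm/s in the replica protocol).
    """
    if velocity_mm_s < 0:
        raise ValueError("velocity must be non-negative")
    artery_y = (6.0, 18.0, 30.0)
    inserts = []
    for density, y in zip(HA_DENSITIES, artery_y):
        for label, cap, zc, rot in SATI_SIZES:
            inserts.append(
                InsertSpec(
                    shape="circular_segment",
                    radius_mm=SATI_SEGMENT_RADIUS_MM,
                    cap_height_mm=cap,
                    length_mm=SATI_SEGMENT_LENGTH_MM,
                    ha_density_mg_cm3=density,
                    center_mm=(16.0, y, zc),
                    rotation_deg=rot,
                    insert_id=f"{label}_{int(density)}",
                    size_label=label,
                )
            )
    defaults = dict(
        inserts=tuple(inserts),
        background_hu=50.0,
        fov_mm=(32.0, 36.0, 45.0),
        noise_sigma_hu=10.0,
        motion_velocity_mm_s=velocity_mm_s,
        seed=seed,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def make_random_spec(rng: np.random.Generator, seed: int = 0, **overrides) -> PhantomSpec:
    """Random single-cylinder phantom for paired-reconstruction experiments.

    Diameter, length, density and position vary between draws so a set of
    such phantoms spans a wide range of true calcium volumes, as needed for
    agreement statistics across paired reconstructions.
    """
    diameter = float(rng.uniform(2.5, 6.0))
    length = float(rng.uniform(2.0, 6.0))
    density = float(rng.choice([200.0, 400.0, 800.0]))
    center = (
        12.0 + float(rng.uniform(-2.0, 2.0)),
        12.0 + float(rng.uniform(-2.0, 2.0)),
        4.5 + float(rng.uniform(-1.0, 1.0)),
    )
    insert = InsertSpec(
        shape="cylinder",
        diameter_mm=diameter,
        length_mm=length,
        ha_density_mg_cm3=density,
        center_mm=center,
        insert_id=f"cyl_{int(density)}",
        size_label="random",
    )
    defaults = dict(
        inserts=(insert,),
        background_hu=35.0,
        fov_mm=(24.0, 24.0, 9.0),
        seed=seed,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)
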