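"""Seeded whole-body-like PET phantom simulator.

Generates paired AC/NAC phantoms: an SUV-valued activity map with an
elliptical body, very hot clearance organs (kidney and bladder analogs,
uptake well above 100 SUV so the clipping threshold is exercised), a
bone-analog high-attenuation region, and ellipsoidal lesions; a linear
attenuation-coefficient map at 511 keV; and the multiplicative
photon-attenuation relationship between the AC and NAC images plus PSF
blur and Poisson count noise.

Attenuation physics: for an annihilation at voxel ``x`` both photons
must escape along the same line of response, so the detected fraction is
``exp(-integral of mu over the FULL line through x)``.  The per-voxel
attenuation factor is the average of that survival probability over
``n_angles`` in-plane line orientations equally spaced in [0, pi).

Phantoms are slice-based: a volume is a stack of slices sharing one body
geometry, matching a 2-D slice-trained translation model.  Single-slice
(2-D) phantoms are first-class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .volume import PETVolume

__all__ = [
    "PhantomSpec",
    "LesionMask",
    "PhantomSample",
    "make_phantom",
    "attenuation_factors",
    "simulate_pair",
    "generate_sample",
]

LOCATIONS = ("lymph_node", "bone", "prostate")


@dataclass
class PhantomSpec:
    """Parameters of one phantom realization.

    mu_* are linear attenuation coefficients in 1/cm at 511 keV
    (soft tissue ~0.096, cortical-bone analog ~0.17, air ~0).
    count_scale is the expected number of detected counts per SUV unit
    per voxel and controls the Poisson noise level; psf_fwhm is the
    Gaussian point-spread/post-filter FWHM in mm.
    """

    grid_shape: tuple[int, int, int] = (1, 64, 64)
    voxel_size: tuple[float, float, float] = (3.27, 2.73, 2.73)
    n_lesions: int = 3
    lesion_suv_range: tuple[float, float] = (4.0, 30.0)
    organ_suv_range: tuple[float, float] = (120.0, 250.0)
    background_suv: float = 1.0
    mu_tissue: float = 0.096
    mu_bone: float = 0.17
    mu_air: float = 0.0
    psf_fwhm: float = 4.1
    count_scale: float = 2000.0
    n_angles: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(g) <= 0 for g in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        for name in ("mu_tissue", "mu_bone", "mu_air"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.organ_suv_range[1] <= 100.0:
            raise ValueError(
                "organ_suv_range upper bound must exceed 100 SUV "
                "(clearance organs must exercise the clipping threshold)"
            )
        if self.count_scale <= 0:
            raise ValueError("count_scale must be > 0")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")


@dataclass
class LesionMask:
    mask: np.ndarray  # boolean, phantom grid
    location: str     # one of LOCATIONS


@dataclass
class PhantomSample:
    """One phantom realization; PET pair filled in by :func:`simulate_pair`."""

    activity: np.ndarray            # SUV
    mu_map: np.ndarray              # 1/cm
    hu_map: np.ndarray              # Hounsfield units, affine in mu
    lesion_masks: list = field(default_factory=list)
    ac_pet: PETVolume | None = None
    nac_pet: PETVolume | None = None
    attenuation: np.ndarray | None = None
    spec: PhantomSpec | None = None


def _ellipsoid(zz, yy, xx, center, radii) -> np.ndarray:
    cz, cy, cx = center
    rz, ry, rx = radii
    return ((zz - cz) / max(rz, 1e-9)) ** 2 + ((yy - cy) / ry) ** 2 + (
        (xx - cx) / rx
    ) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> PhantomSample:
    """Build activity / mu / HU maps and lesion masks (no PET yet).

    Deterministic for a fixed ``spec.seed``.  Lesions are placed in one
    of three habitats — soft tissue (lymph-node analog), the bone-analog
    region, or the prostate-analog region between bladder and spine —
    disjoint from each other and from the clearance organs.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.grid_shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )

    # elliptical body cylinder, slightly jittered semi-axes
    by, bx = ny / 2.0, nx / 2.0
    ry = 0.5 * ny * rng.uniform(0.78, 0.88)
    rx = 0.5 * nx * rng.uniform(0.80, 0.90)
    body = ((yy - by) / ry) ** 2 + ((xx - bx) / rx) ** 2 <= 1.0

    activity = np.where(body, spec.background_suv, 0.0)
    mu = np.where(body, spec.mu_tissue, spec.mu_air)

    # bone analog: posterior spine cylinder
    spine_c = (nz / 2.0, by + 0.45 * ry, bx)
    spine_r = (nz, 0.16 * ry, 0.12 * rx)
    spine = _ellipsoid(zz, yy, xx, spine_c, spine_r) & body
    mu[spine] = spec.mu_bone

    organs = np.zeros_like(body)

    def place_organ(center, radii):
        m = _ellipsoid(zz, yy, xx, center, radii) & body
        activity[m] = rng.uniform(*spec.organ_suv_range)
        return m

    # two kidney analogs flanking the spine, one bladder analog anterior
    for sx in (-1.0, 1.0):
        c = (nz / 2.0, by + 0.18 * ry + rng.normal(0, 0.02 * ry),
             bx + sx * (0.42 * rx + rng.normal(0, 0.02 * rx)))
        organs |= place_organ(c, (nz, 0.14 * ry, 0.13 * rx))
    bladder_c = (nz / 2.0, by - 0.48 * ry + rng.normal(0, 0.02 * ry), bx)
    organs |= place_organ(bladder_c, (nz, 0.16 * ry, 0.17 * rx))

    # prostate-analog habitat: between bladder and spine
    prostate_region = _ellipsoid(
        zz, yy, xx, (nz / 2.0, by - 0.18 * ry, bx), (nz, 0.16 * ry, 0.16 * rx)
    ) & body & ~organs

    habitats = {
        "bone": spine,
        "prostate": prostate_region,
        "lymph_node": body & ~(spine | prostate_region | organs),
    }
    radius_range = {
        "bone": (1.0, 2.0),
        "prostate": (1.0, 2.2),
        "lymph_node": (1.5, 3.5),
    }

    masks: list[LesionMask] = []
    taken = organs.copy()
    for _ in range(spec.n_lesions):
        loc = LOCATIONS[rng.integers(0, len(LOCATIONS))]
        habitat = habitats[loc]
        idx = np.flatnonzero(habitat & ~taken)
        placed = False
        for _attempt in range(200):
            if idx.size == 0:
                break
            flat = idx[rng.integers(0, idx.size)]
            _, cy, cx = np.unravel_index(flat, habitat.shape)
            r = (
                max(nz / 2.0, 0.6),
                rng.uniform(*radius_range[loc]),
                rng.uniform(*radius_range[loc]),
            )
            m = _ellipsoid(zz, yy, xx, (nz / 2.0, float(cy), float(cx)), r)
            if not m.any():
                continue
            if not (m <= habitat).all():
                continue
            if (m & taken).any():
                continue
            activity[m] = rng.uniform(*spec.lesion_suv_range)
            taken |= m
            masks.append(LesionMask(mask=m, location=loc))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a {loc!r} lesion after 200 attempts: "
                "habitat too small or already occupied (disjointness constraint)"
            )

    # HU affine in mu: air -> -1000 HU, soft tissue (water analog) -> 0 HU
    denom = spec.mu_tissue - spec.mu_air
    if denom > 0:
        hu = -1000.0 + 1000.0 * (mu - spec.mu_air) / denom
    else:  # degenerate (vacuum phantom): everything reads as air
        hu = np.full_like(mu, -1000.0)

    return PhantomSample(
        activity=activity, mu_map=mu, hu_map=hu, lesion_masks=masks, spec=spec
    )


def attenuation_factors(
    mu_map: np.ndarray,
    n_angles: int = 8,
    voxel_size: tuple[float, float, float] = (3.27, 2.73, 2.73),
    step: float | None = None,
) -> np.ndarray:
    """Per-voxel photon-pair survival fraction, averaged over line angles.

    For each voxel center the line integral of mu runs over the full line
    through the voxel (both annihilation photons), marched at sample
    points ``t = +/-(k + 1/2) * h`` with step ``h`` at most half the
    smallest in-plane voxel size, using bilinear interpolation of mu
    (zero outside the grid).  Lines are in-plane; each slice of a 3-D
    stack is treated independently, matching a per-slice acquisition.

    Returns an array of the same shape with values in (0, 1].
    """
    mu = np.asarray(mu_map, dtype=np.float64)
    squeeze = mu.ndim == 2
    if squeeze:
        mu = mu[np.newaxis]
    if mu.ndim != 3:
        raise ValueError("mu_map must be 2-D or 3-D")
    if np.any(mu < 0):
        raise ValueError("mu_map must be non-negative")
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    sy, sx = float(voxel_size[-2]), float(voxel_size[-1])
    h = step if step is not None else 0.5 * min(sy, sx)
    if h <= 0:
        raise ValueError("step must be positive")

    nz, ny, nx = mu.shape
    # physical in-plane coordinates of voxel centers (mm)
    ys = np.arange(ny) * sy
    xs = np.arange(nx) * sx
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    pts = np.stack([yy.ravel(), xx.ravel()])  # (2, N)
    n_pts = pts.shape[1]

    diag = np.hypot(ny * sy, nx * sx)
    n_steps = int(np.ceil(diag / h)) + 1
    # symmetric midpoint offsets along the line, both photon directions
    t = (np.arange(n_steps) + 0.5) * h
    t = np.concatenate([-t[::-1], t])  # (2*n_steps,)

    angles = np.pi * np.arange(n_angles) / n_angles
    out = np.empty_like(mu)
    for k in range(nz):
        integ = np.zeros((n_angles, n_pts))
        for a, th in enumerate(angles):
            d = np.array([np.sin(th), np.cos(th)])  # (dy, dx) in mm
            sample_y = (pts[0][None, :] + t[:, None] * d[0]) / sy
            sample_x = (pts[1][None, :] + t[:, None] * d[1]) / sx
            # grid-constant: bilinear blending with mu=0 outside the grid
            vals = map_coordinates(
                mu[k],
                [sample_y.ravel(), sample_x.ravel()],
                order=1,
                mode="grid-constant",
                cval=0.0,
            ).reshape(sample_y.shape)
            integ[a] = vals.sum(axis=0) * (h / 10.0)  # mm -> cm
        out[k] = np.exp(-integ).mean(axis=0).reshape(ny, nx)
    return out[0] if squeeze else out


def simulate_pair(
    sample: PhantomSample,
    spec: PhantomSpec | None = None,
    noise: bool = True,
) -> tuple[PETVolume, PETVolume]:
    """Produce the (AC, NAC) PET pair for a phantom.

    AC: PSF-blurred activity with Poisson noise at ``count_scale``
    expected counts per SUV, converted back to SUV.  NAC: the activity
    multiplied by the per-voxel attenuation factor before blurring, with
    an independent noise draw.  Negative values are clamped at zero.
    """
    spec = spec or sample.spec
    if spec is None:
        raise ValueError("need a PhantomSpec (sample.spec is unset)")
    if sample.activity is None or sample.mu_map is None:
        raise ValueError("sample must carry activity and mu_map")

    if sample.attenuation is None:
        sample.attenuation = attenuation_factors(
            sample.mu_map, n_angles=spec.n_angles, voxel_size=spec.voxel_size
        )
    A = sample.attenuation

    sigma_vox = [
        (spec.psf_fwhm / 2.3548200450309493) / s for s in spec.voxel_size
    ]
    if spec.grid_shape[0] == 1:
        sigma_vox[0] = 0.0  # single slice: no through-plane blur

    ac_clean = gaussian_filter(sample.activity, sigma=sigma_vox)
    nac_clean = gaussian_filter(sample.activity * A, sigma=sigma_vox)

    if noise:
        rng_ac = np.random.default_rng([spec.seed, 101])
        rng_nac = np.random.default_rng([spec.seed, 202])
        ac_img = rng_ac.poisson(np.maximum(ac_clean, 0) * spec.count_scale) / spec.count_scale
        nac_img = rng_nac.poisson(np.maximum(nac_clean, 0) * spec.count_scale) / spec.count_scale
    else:
        ac_img, nac_img = ac_clean, nac_clean

    ac_img = np.maximum(ac_img, 0.0).astype(np.float64)
    nac_img = np.maximum(nac_img, 0.0).astype(np.float64)

    ac = PETVolume(ac_img, spacing=spec.voxel_size, value_space="SUV")
    nac = PETVolume(nac_img, spacing=spec.voxel_size, value_space="SUV")
    sample.ac_pet, sample.nac_pet = ac, nac
    return ac, nac


def generate_sample(spec: PhantomSpec, noise: bool = True) -> PhantomSample:
    """Convenience: phantom geometry plus its simulated PET pair."""
    sample = make_phantom(spec)
    simulate_pair(sample, spec, noise=noise)
    return sample
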