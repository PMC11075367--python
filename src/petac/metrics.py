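"""Scan-level image-quality metrics comparing generated and reference PET.

Conventions (the field reports these in several ways; ours are):

* NMSE — squared error relative to reference energy, in percent:
  ``100 * sum((gen - ref)^2) / sum(ref^2)`` over all voxels.
* MAE — mean absolute error in percent of the clipped 100-SUV dynamic
  range, i.e. computed on (0, 1)-scaled volumes and multiplied by 100.
* PSNR — ``10 * log10(data_range^2 / MSE)`` in dB, data range 1.0 in
  scaled space; identical inputs yield an infinite-PSNR sentinel
  (``math.inf``) rather than an exception.
* SSIM — local-window structural similarity with a Gaussian window
  (sigma 1.5, truncated at 3.5 sigma), K1=0.01, K2=0.03, data range
  1.0, population (filter-weighted) covariances, averaged over the
  window-valid interior.  Volume SSIM is the mean over axial slices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume import PETVolume

__all__ = ["ScanMetrics", "nmse", "mae", "psnr", "ssim", "evaluate_scan",
           "summarize_cohort"]


@dataclass
class ScanMetrics:
    nmse: float   # %
    mae: float    # %
    psnr: float   # dB (math.inf when identical)
    ssim: float   # unitless, <= 1

    def __post_init__(self) -> None:
        if self.nmse < 0 or self.mae < 0:
            raise ValueError("nmse and mae must be non-negative")
        if self.ssim > 1 + 1e-12:
            raise ValueError("ssim cannot exceed 1")


def _arrays(gen, ref) -> tuple[np.ndarray, np.ndarray]:
    g = gen.voxels if isinstance(gen, PETVolume) else np.asarray(gen, dtype=np.float64)
    r = ref.voxels if isinstance(ref, PETVolume) else np.asarray(ref, dtype=np.float64)
    if g.shape != r.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {r.shape}")
    return g.astype(np.float64), r.astype(np.float64)


def nmse(gen, ref) -> float:
    """Normalized mean squared error in percent of reference energy."""
    g, r = _arrays(gen, ref)
    denom = float(np.sum(r ** 2))
    if denom == 0.0:
        raise ValueError("reference volume is all zero; NMSE undefined")
    return 100.0 * float(np.sum((g - r) ** 2)) / denom


def mae(gen_scaled, ref_scaled) -> float:
    """Mean absolute error in percent of the scaled (0, 1) range."""
    g, r = _arrays(gen_scaled, ref_scaled)
    return 100.0 * float(np.mean(np.abs(g - r)))


def psnr(gen_scaled, ref_scaled, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; inf for identical inputs."""
    g, r = _arrays(gen_scaled, ref_scaled)
    mse = float(np.mean((g - r) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(data_range ** 2 / mse)


_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5
_K1, _K2 = 0.01, 0.03


def _ssim_2d(x: np.ndarray, y: np.ndarray, data_range: float) -> float:
    win_radius = int(_SSIM_TRUNCATE * _SSIM_SIGMA + 0.5)
    win_size = 2 * win_radius + 1
    if min(x.shape) < win_size:
        raise ValueError(
            f"image {x.shape} smaller than the {win_size}x{win_size} SSIM window"
        )

    def f(a):
        return gaussian_filter(a, _SSIM_SIGMA, truncate=_SSIM_TRUNCATE)

    ux, uy = f(x), f(y)
    uxx, uyy, uxy = f(x * x), f(y * y), f(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cxy = uxy - ux * uy

    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * cxy + c2)) / (
        (ux ** 2 + uy ** 2 + c1) * (vx + vy + c2)
    )
    pad = win_radius
    return float(s[pad:-pad, pad:-pad].mean())


def ssim(gen_scaled, ref_scaled, data_range: float = 1.0) -> float:
    """Structural similarity; 2-D slices directly, 3-D as slice mean."""
    g, r = _arrays(gen_scaled, ref_scaled)
    if g.ndim == 2:
        return _ssim_2d(g, r, data_range)
    if g.ndim == 3:
        return float(np.mean([_ssim_2d(gs, rs, data_range)
                              for gs, rs in zip(g, r)]))
    raise ValueError("ssim expects 2-D or 3-D input")


def evaluate_scan(gen_scaled, ref_scaled) -> ScanMetrics:
    """All four metrics for one scan, on (0, 1)-scaled volumes."""
    return ScanMetrics(
        nmse=nmse(gen_scaled, ref_scaled),
        mae=mae(gen_scaled, ref_scaled),
        psnr=psnr(gen_scaled, ref_scaled),
        ssim=ssim(gen_scaled, ref_scaled),
    )


def summarize_cohort(scans: list[ScanMetrics]) -> pd.DataFrame:
    """Median and (min, max) range per metric over a cohort of scans."""
    if len(scans) == 0:
        raise ValueError("no scans to summarize")
    df = pd.DataFrame([s.__dict__ for s in scans])
    out = pd.DataFrame(
        {
            "median": df.median(),
            "min": df.min(),
            "max": df.max(),
        }
    )
    out.index.name = "metric"
    return out
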