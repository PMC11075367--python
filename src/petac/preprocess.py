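"""SUV conversion and the two intensity-normalization strategies.

Strategy V1 converts a volume to SUV, clips at 100 and scales to (0, 1).
Strategy V2 additionally standardizes the NAC histogram with a Nyul
piecewise-linear landmark map (fitted on the training NAC-SUV images)
before the clip/scale step.  The AC target is always V1-style: only the
NAC input is histogram-standardized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .volume import PETVolume

F18_HALF_LIFE_S = 6586.2
SUV_CLIP = 100.0


@dataclass
class AcquisitionMeta:
    """Everything needed for a body-weight SUV conversion.

    injected_dose is in Bq, patient_weight in grams, times in seconds on
    any common clock, half_life in seconds (default fluorine-18).
    """

    injected_dose: float
    patient_weight: float
    injection_time: float
    scan_time: float
    half_life: float = F18_HALF_LIFE_S

    def __post_init__(self) -> None:
        for name in ("injected_dose", "patient_weight", "injection_time",
                     "scan_time", "half_life"):
            if getattr(self, name) is None:
                raise ValueError(f"missing acquisition field: {name}")
        if self.injected_dose <= 0:
            raise ValueError("injected_dose must be > 0")
        if self.patient_weight <= 0:
            raise ValueError("patient_weight must be > 0")
        if self.scan_time < self.injection_time:
            raise ValueError("scan_time must be >= injection_time")
        if self.half_life <= 0:
            raise ValueError("half_life must be > 0")

    @property
    def decayed_dose(self) -> float:
        """Injected dose decay-corrected to scan time, in Bq."""
        dt = self.scan_time - self.injection_time
        return self.injected_dose * 2.0 ** (-dt / self.half_life)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AcquisitionMeta":
        d = json.loads(text)
        try:
            return cls(**d)
        except TypeError as exc:  # missing key -> name it
            missing = {"injected_dose", "patient_weight", "injection_time",
                       "scan_time"} - set(d)
            if missing:
                raise ValueError(f"missing acquisition field(s): {sorted(missing)}") from exc
            raise


def suv_convert(volume: PETVolume, meta: AcquisitionMeta) -> PETVolume:
    """Convert an activity-concentration volume (Bq/mL) to body-weight SUV.

    SUV(x) = c(x) / (D_decayed / w) with D_decayed = D * 2^(-dt / T_half),
    assuming 1 g/mL tissue density so weight in grams plays the role of a
    distribution volume in mL.
    """
    if volume.value_space != "counts":
        raise ValueError(f"expected value_space 'counts', got {volume.value_space!r}")
    suv = volume.voxels * (meta.patient_weight / meta.decayed_dose)
    return volume.with_voxels(suv, value_space="SUV")


def clip_scale(volume: PETVolume, clip: float = SUV_CLIP) -> PETVolume:
    """Clip SUVs to an upper threshold (default 100) and scale to [0, 1].

    The inverse map back to SUV is multiplication by the threshold.
    """
    if volume.value_space != "SUV":
        raise ValueError(f"expected value_space 'SUV', got {volume.value_space!r}")
    out = np.clip(volume.voxels, 0.0, clip) / clip
    return volume.with_voxels(out, value_space="scaled")


def unscale(volume: PETVolume, clip: float = SUV_CLIP) -> PETVolume:
    """Map a scaled volume back to SUV (multiplication by the clip value)."""
    if volume.value_space != "scaled":
        raise ValueError(f"expected value_space 'scaled', got {volume.value_space!r}")
    return volume.with_voxels(volume.voxels * clip, value_space="SUV")


# ---------------------------------------------------------------------------
# Nyul histogram standardization
# ---------------------------------------------------------------------------

@dataclass
class NyulModel:
    """Learned standard-histogram landmarks for piecewise-linear mapping.

    Landmarks are percentiles of the foreground (positive-voxel) intensity
    distribution taken at ``n_landmarks`` equally spaced percentile points
    from ``pct_low`` to ``pct_high`` inclusive; ``standard_landmarks`` is
    their element-wise mean over the training images.
    """

    n_landmarks: int = 20
    pct_low: float = 80.0
    pct_high: float = 99.0
    standard_landmarks: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.n_landmarks < 2:
            raise ValueError("n_landmarks must be >= 2")
        if not (0 <= self.pct_low < self.pct_high <= 100):
            raise ValueError("need 0 <= pct_low < pct_high <= 100")
        if self.standard_landmarks is not None:
            lm = np.asarray(self.standard_landmarks, dtype=np.float64)
            if lm.shape != (self.n_landmarks,):
                raise ValueError("standard_landmarks length must equal n_landmarks")
            if not np.all(np.diff(lm) > 0):
                raise ValueError("standard_landmarks must be strictly increasing")
            self.standard_landmarks = lm

    @property
    def percentile_grid(self) -> np.ndarray:
        """The percentile points, e.g. [80, 81, ..., 99] at the defaults."""
        return np.linspace(self.pct_low, self.pct_high, self.n_landmarks)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_landmarks": self.n_landmarks,
                "pct_low": self.pct_low,
                "pct_high": self.pct_high,
                "standard_landmarks": list(self.standard_landmarks),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NyulModel":
        d = json.loads(text)
        return cls(
            n_landmarks=d["n_landmarks"],
            pct_low=d["pct_low"],
            pct_high=d["pct_high"],
            standard_landmarks=np.asarray(d["standard_landmarks"]),
        )


def image_landmarks(volume: PETVolume | np.ndarray, model: NyulModel) -> np.ndarray:
    """Foreground percentile landmarks of one image on the model's grid.

    Foreground = voxels > 0, because the air background dominates the
    whole-body histogram.  Percentiles use linear interpolation between
    order statistics.
    """
    vox = volume.voxels if isinstance(volume, PETVolume) else np.asarray(volume)
    fg = vox[vox > 0]
    if fg.size < model.n_landmarks:
        raise ValueError(
            f"image has {fg.size} positive voxels; need >= {model.n_landmarks}"
        )
    lm = np.percentile(fg, model.percentile_grid)
    return lm


def nyul_fit(
    training_volumes: list,
    n_landmarks: int = 20,
    pct_low: float = 80.0,
    pct_high: float = 99.0,
) -> NyulModel:
    """Fit the standard histogram: mean landmarks over the training images."""
    if len(training_volumes) == 0:
        raise ValueError("need at least one training volume")
    model = NyulModel(n_landmarks=n_landmarks, pct_low=pct_low, pct_high=pct_high)
    marks = []
    for vol in training_volumes:
        lm = image_landmarks(vol, model)
        if not np.all(np.diff(lm) > 0):
            raise ValueError(
                "degenerate landmarks (non-increasing percentiles); "
                "is the image (near-)constant over its foreground?"
            )
        marks.append(lm)
    std = np.mean(marks, axis=0)
    return NyulModel(
        n_landmarks=n_landmarks,
        pct_low=pct_low,
        pct_high=pct_high,
        standard_landmarks=std,
    )


def _piecewise_map(values: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Monotone piecewise-linear map sending src landmarks to dst landmarks.

    Linear between adjacent landmarks.  Below the first landmark the map
    is anchored through the origin — zero activity is zero in every
    intensity space, and this keeps mapped foreground values positive so
    the foreground set is invariant under the transform.  Above the last
    landmark the end segment's slope extrapolates.
    """
    out = np.interp(values, src, dst)
    lo = values < src[0]
    if np.any(lo):
        if src[0] > 0 and dst[0] > 0:
            out[lo] = values[lo] * (dst[0] / src[0])
        else:
            s = (dst[1] - dst[0]) / (src[1] - src[0])
            out[lo] = dst[0] + s * (values[lo] - src[0])
    hi = values > src[-1]
    if np.any(hi):
        s = (dst[-1] - dst[-2]) / (src[-1] - src[-2])
        out[hi] = dst[-1] + s * (values[hi] - src[-1])
    return out


def nyul_apply(volume: PETVolume, model: NyulModel) -> PETVolume:
    """Standardize one image onto the model's standard histogram.

    The image's own foreground landmarks are mapped onto the standard
    landmarks by a monotone piecewise-linear intensity transform.
    """
    if model.standard_landmarks is None:
        raise ValueError("NyulModel is not fitted")
    src = image_landmarks(volume, model)
    if not np.all(np.diff(src) > 0):
        raise ValueError("image landmarks are non-increasing; cannot standardize")
    vox = volume.voxels
    fg = vox > 0  # air background is left untouched
    out = np.zeros_like(vox)
    mapped = _piecewise_map(vox[fg], src, model.standard_landmarks)
    out[fg] = np.maximum(mapped, 0.0)  # SUV space is >= 0
    return volume.with_voxels(out)


def preprocess_pair(
    nac: PETVolume,
    ac: PETVolume | None,
    strategy: str = "v1",
    nyul: NyulModel | None = None,
) -> tuple[PETVolume, PETVolume | None]:
    """Apply a normalization strategy to a (NAC, AC) SUV pair.

    V1: clip/scale both.  V2: Nyul-standardize the NAC first, then
    clip/scale; the AC target is always V1-style.
    """
    if strategy not in ("v1", "v2"):
        raise ValueError(f"strategy must be 'v1' or 'v2', got {strategy!r}")
    if strategy == "v2":
        if nyul is None:
            raise ValueError("strategy v2 requires a fitted NyulModel")
        nac = nyul_apply(nac, nyul)
    nac_s = clip_scale(nac)
    ac_s = clip_scale(ac) if ac is not None else None
    return nac_s, ac_s
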