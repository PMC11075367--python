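"""NIfTI I/O, study bundles, CT resampling, and difference-map rendering.

Volumes are stored as ``.nii`` / ``.nii.gz`` with a diagonal affine
built from the voxel spacing; acquisition metadata travels in a JSON
sidecar next to the NAC volume.  In memory, slice index is axis 0 and
the NIfTI file axes are (x, y, slice), so arrays are transposed on the
way in and out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .preprocess import AcquisitionMeta
from .volume import PETVolume

__all__ = ["StudyBundle", "save_volume", "load_volume", "load_study",
           "save_study", "resample_ct_to_pet", "render_difference_map"]


@dataclass
class StudyBundle:
    study_id: str
    nac: PETVolume
    ac: PETVolume | None = None
    meta: AcquisitionMeta | None = None
    masks: list = field(default_factory=list)       # (bool array, location) pairs
    ct_hu: PETVolume | None = None

    def __post_init__(self) -> None:
        if self.ac is not None and not self.nac.same_grid(self.ac):
            raise ValueError(
                "NAC/AC grid mismatch: "
                f"shapes {self.nac.shape} vs {self.ac.shape}, "
                f"spacings {self.nac.spacing} vs {self.ac.spacing}"
            )


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    aff[:3, 3] = [origin[2], origin[1], origin[0]]
    return aff


def save_volume(volume: PETVolume, path) -> None:
    """Write a volume as NIfTI; voxel array stored (x, y, slice)."""
    data = np.ascontiguousarray(volume.voxels.transpose(2, 1, 0))
    img = nib.Nifti1Image(data, _affine(volume.spacing, volume.origin))
    img.header.set_xyzt_units("mm")
    img.header["descrip"] = f"value_space={volume.value_space}".encode()
    nib.save(img, str(path))


def load_volume(path, value_space: str | None = None) -> PETVolume:
    """Load a NIfTI volume; slice axis becomes axis 0.

    The value space is read from the header description when present,
    else taken from ``value_space`` (default SUV).
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 2:
        data = data[:, :, np.newaxis]
    vox = data.transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    if value_space is None:
        desc = bytes(img.header["descrip"]).decode(errors="ignore")
        value_space = desc.split("value_space=")[-1].strip("\x00 ") if "value_space=" in desc else "SUV"
    return PETVolume(vox, spacing=spacing, value_space=value_space, origin=origin)


def load_study(
    study_id: str,
    nac_path,
    ac_path=None,
    sidecar_path=None,
    mask_paths: dict | None = None,
    ct_path=None,
    require_meta: bool = False,
) -> StudyBundle:
    """Load the volumes and sidecar of one study onto a common grid."""
    nac = load_volume(nac_path)
    ac = load_volume(ac_path) if ac_path else None
    meta = None
    if sidecar_path is not None and Path(sidecar_path).exists():
        meta = AcquisitionMeta.from_json(Path(sidecar_path).read_text())
    elif require_meta:
        raise FileNotFoundError(
            f"SUV conversion requested but sidecar {sidecar_path} is missing"
        )
    masks = []
    for location, p in (mask_paths or {}).items():
        mv = load_volume(p)
        masks.append((mv.voxels > 0.5, location))
    ct = load_volume(ct_path, value_space="SUV") if ct_path else None
    return StudyBundle(study_id=study_id, nac=nac, ac=ac, meta=meta,
                       masks=masks, ct_hu=ct)


def save_study(bundle: StudyBundle, out_dir) -> dict:
    """Write a bundle's volumes, masks and sidecar; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    nac_p = out / f"{bundle.study_id}_nac.nii.gz"
    save_volume(bundle.nac, nac_p)
    paths["nac"] = nac_p
    if bundle.ac is not None:
        ac_p = out / f"{bundle.study_id}_ac.nii.gz"
        save_volume(bundle.ac, ac_p)
        paths["ac"] = ac_p
    if bundle.meta is not None:
        sc = out / f"{bundle.study_id}_meta.json"
        sc.write_text(bundle.meta.to_json())
        paths["sidecar"] = sc
    for i, (mask, location) in enumerate(bundle.masks):
        mp = out / f"{bundle.study_id}_lesion{i:02d}_{location}.nii.gz"
        save_volume(
            PETVolume(mask.astype(np.float64), spacing=bundle.nac.spacing),
            mp,
        )
        paths[f"mask{i}"] = mp
    return paths


def resample_ct_to_pet(ct_hu: PETVolume, pet: PETVolume) -> PETVolume:
    """Linearly interpolate a HU volume onto the PET grid.

    Out-of-field voxels are set to -1000 HU (air).  Both volumes are
    assumed axis-aligned; their world frames are related through origin
    and spacing only.
    """
    # PET voxel centers in world mm, converted to CT voxel indices
    coords = []
    for ax in range(3):
        w = pet.origin[ax] + np.arange(pet.shape[ax]) * pet.spacing[ax]
        coords.append((w - ct_hu.origin[ax]) / ct_hu.spacing[ax])
    for ax in range(3):
        if coords[ax][-1] < 0 or coords[ax][0] > ct_hu.shape[ax] - 1:
            raise ValueError("CT and PET fields of view do not overlap")
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    out = map_coordinates(
        ct_hu.voxels, [zz, yy, xx], order=1, mode="constant", cval=-1000.0
    )
    return PETVolume(out, spacing=pet.spacing, origin=pet.origin,
                     value_space=ct_hu.value_space)


def render_difference_map(gen: PETVolume, ac: PETVolume, out_path,
                          vmax: float | None = None) -> None:
    """Save a coronal mid-plane AC-minus-generated difference image.

    Red encodes underestimation by the generated image (AC - Gen > 0),
    blue overestimation, on a symmetric diverging scale.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g, a = gen.voxels, ac.voxels
    if g.shape != a.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {a.shape}")
    diff = a - g  # positive = underestimation
    coronal = diff[:, diff.shape[1] // 2, :]
    if vmax is None:
        vmax = float(np.max(np.abs(coronal))) or 1.0
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(coronal, cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   origin="lower", aspect=ac.spacing[0] / ac.spacing[2])
    ax.set_title("AC − generated (SUV)")
    ax.axis("off")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
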