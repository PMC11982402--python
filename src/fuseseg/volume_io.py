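"""Reading, writing and pairing of PET/CT/mask volumes.

Volumes live on pre-registered common grids; NIfTI affine handling is reduced
to voxel-spacing extraction, and inputs on different grids are rejected rather
than resampled (silent resampling would change the evaluation surface).
Arrays are indexed ``(z, y, x)`` for rank 3 and ``(y, x)`` for rank 2.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .exceptions import RegistrationError, ValidationError

__all__ = ["Modality", "ImageVolume", "SamplePair", "read_volume", "write_volume", "validate_pair"]

SPACING_RTOL = 1e-4
MASK_THRESHOLD = 0.5  # tolerates lossy-compressed label files


class Modality(str, enum.Enum):
    PET = "PET"
    CT = "CT"
    MASK = "MASK"


@dataclass
class ImageVolume:
    """A scalar grid (2-D or 3-D) with voxel spacing in millimetres."""

    data: np.ndarray
    spacing: tuple[float, ...]
    modality: Modality
    id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.modality = Modality(self.modality)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.data.ndim not in (2, 3):
            raise ValidationError(f"volume rank must be 2 or 3, got {self.data.ndim}")
        if len(self.spacing) != self.data.ndim:
            raise ValidationError(
                f"spacing has {len(self.spacing)} entries for a rank-{self.data.ndim} volume")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if self.modality is Modality.MASK:
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError(f"mask values must be 0/1, found {vals[:10]}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class SamplePair:
    """Co-registered PET + CT (+ optional ground-truth mask) for one case."""

    pet: ImageVolume
    ct: ImageVolume
    mask: ImageVolume | None = None
    center: str = ""
    patient: str = ""

    def __post_init__(self):
        if self.pet.modality is not Modality.PET or self.ct.modality is not Modality.CT:
            raise ValidationError("SamplePair requires pet.modality==PET and ct.modality==CT")

    @property
    def id(self) -> str:
        return self.patient


def _spacing_from_nifti(img) -> tuple[float, ...]:
    zooms = img.header.get_zooms()
    ndim = len(img.shape)
    return tuple(float(z) for z in zooms[:ndim])


def read_volume(path, modality: Modality | str) -> ImageVolume:
    """Read a NIfTI (or PNG slice) volume; masks are binarized at 0.5."""
    modality = Modality(modality)
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix.lower() == ".png":
        img = Image.open(path)
        arr = np.asarray(img, dtype=np.float32)
        if arr.ndim == 3:  # collapse RGB to grayscale
            arr = arr.mean(axis=-1)
        scale = 255.0 if img.mode in ("L", "P", "RGB") else 65535.0
        data = arr / scale
        meta = {"source": "png", "read_scale": scale}
        spacing = (1.0, 1.0)
    else:
        try:
            img = nib.load(str(path))
        except Exception as e:  # unreadable / not NIfTI
            raise IOError(f"cannot read NIfTI file {path}: {e}") from e
        data = np.asanyarray(img.dataobj).astype(np.float32)
        data = np.squeeze(data)
        if data.ndim not in (2, 3):
            raise ValidationError(f"{path}: expected rank 2 or 3, got {data.ndim}")
        spacing = _spacing_from_nifti(img)[: data.ndim]
        meta = {"source": "nifti"}
    if modality is Modality.MASK:
        if not np.isfinite(data).all():
            raise ValidationError(f"{path}: mask contains non-finite values")
        data = (data > MASK_THRESHOLD).astype(np.uint8)
    return ImageVolume(data=data, spacing=spacing, modality=modality,
                       id=path.name, meta=meta)


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume as NIfTI; float32 payloads round-trip bit-exactly."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    affine = np.eye(4)
    for i, s in enumerate(vol.spacing):
        affine[i, i] = s
    if vol.modality is Modality.MASK:
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float32)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing + (1.0,) * (len(img.header.get_zooms()) - len(vol.spacing)))
    nib.save(img, str(path))


def validate_pair(pet: ImageVolume, ct: ImageVolume,
                  mask: ImageVolume | None = None,
                  center: str = "", patient: str = "") -> SamplePair:
    """Check co-registration (identical shape, spacing within rtol) and pair up."""
    vols = [("pet", pet), ("ct", ct)] + ([("mask", mask)] if mask is not None else [])
    ref_name, ref = vols[0]
    for name, v in vols[1:]:
        if v.shape != ref.shape:
            raise RegistrationError(
                f"{name} shape {v.shape} does not match {ref_name} shape {ref.shape}")
        if not np.allclose(v.spacing, ref.spacing, rtol=SPACING_RTOL, atol=0.0):
            raise RegistrationError(
                f"{name} spacing {v.spacing} does not match {ref_name} spacing {ref.spacing}")
    return SamplePair(pet=pet, ct=ct, mask=mask, center=center, patient=patient)
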