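"""Synthetic co-registered PET-CT phantoms with ground-truth tumor masks.

The generator emulates, at desk scale, the structure that makes anatomy-guided
fusion worthwhile in head-and-neck PET-CT:

* **CT** shows an air background (-1000 HU), a soft-tissue body ellipse
  (~40 HU), a dense bone-like structure (~700 HU), and crisp-edged tumor
  ellipsoids at a modest contrast above soft tissue — plus *distractor*
  structures at exactly the tumor's HU, so density alone cannot identify
  tumors.
* **PET** shows low body uptake with hot tumor blobs, blurred by a Gaussian
  point-spread proxy so tumor boundaries are fuzzy, plus *confounder* hot
  spots with no CT correlate (excluded from the mask), bounding the precision
  of any PET-only segmenter.
* **Mask** is exactly the union of the unblurred tumor ellipsoids.

Identical spec + seed always reproduces bit-identical samples. Multi-center
datasets apply deterministic per-center noise jitter, mimicking inter-scanner
variation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, replace as dc_replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import GenerationError
from .volume_io import ImageVolume, Modality, SamplePair, read_volume, write_volume

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "center_jitter",
           "write_dataset", "load_dataset"]

AIR_HU = -1000.0
BODY_HU = 40.0
BONE_HU = 700.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic PET-CT sample.

    Units: HU for CT quantities, arbitrary uptake units for PET (body
    baseline 1.0), voxels for radii and blur sigma.
    """

    shape: tuple[int, ...] = (64, 64)
    spacing: tuple[float, ...] = (1.0, 1.0)
    n_tumors: int = 1
    tumor_radius_range: tuple[float, float] = (3.0, 6.0)
    tumor_ct_contrast: float = 60.0
    pet_tumor_intensity: float = 5.0
    pet_blur_sigma: float = 2.5
    n_confounders: int = 3
    n_ct_distractors: int = 2
    body_uptake: float = 1.0
    noise_sd_ct: float = 15.0
    noise_sd_pet: float = 0.4
    seed: int = 0
    center: str = "C0"

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        lo, hi = self.tumor_radius_range
        if lo > hi:
            raise GenerationError(f"tumor_radius_range min {lo} > max {hi}")
        if min(self.noise_sd_ct, self.noise_sd_pet, self.pet_blur_sigma) < 0:
            raise GenerationError("noise sds and blur sigma must be >= 0")
        if len(self.spacing) != len(self.shape):
            raise GenerationError("spacing and shape rank mismatch")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def default_3d(cls, seed: int = 0, center: str = "C0") -> "PhantomSpec":
        """Desk-scale 3-D conditions: 32³ grid with geometry scaled so the
        body comfortably hosts one tumor, one distractor and one confounder."""
        return cls(shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0),
                   tumor_radius_range=(2.5, 4.5), n_confounders=1,
                   n_ct_distractors=1, seed=seed, center=center)


def _ellipsoid(shape: tuple[int, ...], center: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Boolean rasterization: voxel centers with sum(((i-c)/a)^2) <= 1."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return q <= 1.0


def _body_geometry(shape):
    c = np.array(shape, dtype=float) / 2.0 - 0.5
    axes = np.array(shape, dtype=float) * 0.42
    return c, axes


def _inside_body(center: np.ndarray, radius: float, body_c, body_axes) -> bool:
    margin = body_axes - radius - 1.0
    if (margin <= 0).any():
        return False
    return float(np.sum(((center - body_c) / margin) ** 2)) <= 1.0


def _place_blobs(rng, n, radius_range, shape, body_c, body_axes, occupied,
                 max_attempts: int = 1000):
    """Rejection-sample non-overlapping ellipsoid blobs inside the body."""
    blobs = []
    lo, hi = radius_range
    nd = len(shape)
    for _ in range(n):
        for attempt in range(max_attempts):
            axes = rng.uniform(lo, hi, size=nd)
            rmax = float(axes.max())
            margin = body_axes - rmax - 1.0
            if (margin <= 0).any():
                raise GenerationError(
                    f"blob radius {rmax:.1f} cannot fit inside body semi-axes "
                    f"{tuple(body_axes)}")
            # uniform draw inside the feasible center ellipsoid
            z = rng.normal(size=nd)
            z /= np.linalg.norm(z)
            center = body_c + z * margin * rng.random() ** (1.0 / nd)
            if not _inside_body(center, rmax, body_c, body_axes):
                continue
            clash = any(np.linalg.norm(center - oc) < rmax + orad + 1.0
                        for oc, orad in occupied)
            if clash:
                continue
            blobs.append((center, axes))
            occupied.append((center, rmax))
            break
        else:
            raise GenerationError(
                f"could not place blob after {max_attempts} attempts "
                f"(shape {shape}, radii {radius_range})")
    return blobs


def generate_phantom(spec: PhantomSpec) -> SamplePair:
    """Generate one co-registered PET-CT-mask triplet from a spec."""
    shape = spec.shape
    rng = np.random.default_rng(spec.seed)
    body_c, body_axes = _body_geometry(shape)
    if spec.tumor_radius_range[1] + 2.0 >= float(body_axes.min()):
        raise GenerationError(
            f"tumors up to radius {spec.tumor_radius_range[1]} cannot fit inside "
            f"a body of semi-axes {tuple(body_axes)}")

    body = _ellipsoid(shape, body_c, body_axes)
    # dense bone-like structure, offset from center along the first axis
    bone_c = body_c + np.array([0.22 * s for s in shape]) * np.eye(len(shape))[0]
    bone_axes = np.maximum(np.array(shape, dtype=float) * 0.06, 1.5)
    bone = _ellipsoid(shape, bone_c, bone_axes) & body

    occupied: list[tuple[np.ndarray, float]] = [(bone_c, float(bone_axes.max()))]
    tumors = _place_blobs(rng, spec.n_tumors, spec.tumor_radius_range,
                          shape, body_c, body_axes, occupied)
    distractors = _place_blobs(rng, spec.n_ct_distractors, spec.tumor_radius_range,
                               shape, body_c, body_axes, occupied)
    confounders = _place_blobs(rng, spec.n_confounders, spec.tumor_radius_range,
                               shape, body_c, body_axes, occupied)

    mask = np.zeros(shape, dtype=bool)
    for c, a in tumors:
        mask |= _ellipsoid(shape, c, a)

    # --- CT: crisp anatomy ------------------------------------------------
    ct = np.full(shape, AIR_HU, dtype=np.float64)
    ct[body] = BODY_HU
    ct[bone] = BONE_HU
    for c, a in distractors:
        ct[_ellipsoid(shape, c, a)] = BODY_HU + spec.tumor_ct_contrast
    ct[mask] = BODY_HU + spec.tumor_ct_contrast
    if spec.noise_sd_ct > 0:
        ct += rng.normal(0.0, spec.noise_sd_ct, size=shape)

    # --- PET: metabolic signal, blurred -----------------------------------
    pet = np.zeros(shape, dtype=np.float64)
    pet[body] = spec.body_uptake
    for c, a in tumors:
        pet[_ellipsoid(shape, c, a)] += spec.pet_tumor_intensity
    for c, a in confounders:
        pet[_ellipsoid(shape, c, a)] += spec.pet_tumor_intensity
    if spec.pet_blur_sigma > 0:
        pet = ndimage.gaussian_filter(pet, sigma=spec.pet_blur_sigma)
    if spec.noise_sd_pet > 0:
        pet += rng.normal(0.0, spec.noise_sd_pet, size=shape)
    pet = np.maximum(pet, 0.0)  # uptake is non-negative

    pid = f"{spec.center}_s{spec.seed}"
    meta = {
        "spec_digest": spec.digest(),
        "seed": spec.seed,
        "tumors": [(c.tolist(), a.tolist()) for c, a in tumors],
        "confounders": [(c.tolist(), a.tolist()) for c, a in confounders],
    }
    return SamplePair(
        pet=ImageVolume(pet.astype(np.float32), spec.spacing, Modality.PET, id=f"{pid}_pet", meta=dict(meta)),
        ct=ImageVolume(ct.astype(np.float32), spec.spacing, Modality.CT, id=f"{pid}_ct", meta=dict(meta)),
        mask=ImageVolume(mask.astype(np.uint8), spec.spacing, Modality.MASK, id=f"{pid}_mask", meta=dict(meta)),
        center=spec.center,
        patient=pid,
    )


# deterministic per-center jitter factors (noise scaling across scanners)
_CT_NOISE_SCALES = (0.6, 1.0, 1.5, 0.8, 1.25)
_PET_NOISE_SCALES = (1.0, 0.7, 1.4, 0.9, 1.2)


def center_jitter(center_index: int) -> tuple[float, float]:
    """(CT noise scale, PET noise scale) applied to a center's samples."""
    return (_CT_NOISE_SCALES[center_index % len(_CT_NOISE_SCALES)],
            _PET_NOISE_SCALES[center_index % len(_PET_NOISE_SCALES)])


def generate_dataset(base_spec: PhantomSpec, n_per_center: int,
                     centers: list[str], seed: int = 0) -> list[SamplePair]:
    """Deterministic multi-center dataset with per-center noise jitter."""
    if n_per_center < 1 or not centers:
        raise GenerationError("need n_per_center >= 1 and at least one center")
    samples = []
    for ci, center in enumerate(centers):
        ct_scale, pet_scale = center_jitter(ci)
        for si in range(n_per_center):
            sample_seed = (seed * 1_000_003 + ci * 10_007 + si) % (2**31 - 1)
            spec = dc_replace(
                base_spec,
                seed=sample_seed,
                center=center,
                noise_sd_ct=base_spec.noise_sd_ct * ct_scale,
                noise_sd_pet=base_spec.noise_sd_pet * pet_scale,
            )
            s = generate_phantom(spec)
            s.patient = f"{center}_{si:03d}"
            samples.append(s)
    return samples


def write_dataset(samples: list[SamplePair], out_dir) -> Path:
    """Write a NIfTI tree (pet/ct/mask per sample) plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for s in samples:
        for vol, tag in ((s.pet, "pet"), (s.ct, "ct"), (s.mask, "mask")):
            if vol is None:
                continue
            write_volume(vol, out_dir / f"{tag}_{s.patient}.nii.gz")
        manifest.append({
            "id": s.patient,
            "center": s.center,
            "seed": s.pet.meta.get("seed"),
            "spec_digest": s.pet.meta.get("spec_digest"),
        })
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def load_dataset(in_dir) -> list[SamplePair]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    samples = []
    for entry in manifest:
        pid = entry["id"]
        pet = read_volume(in_dir / f"pet_{pid}.nii.gz", Modality.PET)
        ct = read_volume(in_dir / f"ct_{pid}.nii.gz", Modality.CT)
        mask_path = in_dir / f"mask_{pid}.nii.gz"
        mask = read_volume(mask_path, Modality.MASK) if mask_path.exists() else None
        samples.append(SamplePair(pet=pet, ct=ct, mask=mask,
                                  center=entry["center"], patient=pid))
    return samples
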