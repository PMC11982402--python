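"""Modality normalization, augmentation, and dataset splitting.

CT is clipped to [-1024, 1024] HU and mapped linearly onto [-1, 1]; PET is
z-scored per volume over all voxels. Augmentation applies the same seeded
spatial transform (horizontal/vertical flips, axial-plane rotation) to PET,
CT and mask. Two splitting protocols are provided: leave-one-center-out and
a seeded random 80/20 split.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, DegenerateInputError, ValidationError
from .volume_io import ImageVolume, Modality, SamplePair

__all__ = [
    "HU_CLIP",
    "SplitStrategy",
    "SplitPlan",
    "clip_and_scale_ct",
    "zscore_pet",
    "flip_h",
    "flip_v",
    "rotate90",
    "augment",
    "make_split",
    "save_split",
    "load_split",
]

HU_CLIP = 1024.0


def clip_and_scale_ct(ct: ImageVolume) -> ImageVolume:
    """Clip CT to [-1024, 1024] HU, then divide by 1024 to land in [-1, 1]."""
    if ct.modality is not Modality.CT:
        raise ValidationError(f"clip_and_scale_ct expects CT, got {ct.modality}")
    if not np.isfinite(ct.data).all():
        raise ValidationError("CT volume contains non-finite values")
    data = np.clip(ct.data, -HU_CLIP, HU_CLIP) / HU_CLIP
    return ImageVolume(data=data.astype(np.float32), spacing=ct.spacing,
                       modality=Modality.CT, id=ct.id, meta={**ct.meta, "ct_scaled": True})


def zscore_pet(pet: ImageVolume) -> ImageVolume:
    """Standardize a PET volume to zero mean, unit sd over all voxels."""
    if pet.modality is not Modality.PET:
        raise ValidationError(f"zscore_pet expects PET, got {pet.modality}")
    if not np.isfinite(pet.data).all():
        raise ValidationError("PET volume contains non-finite values")
    x = pet.data.astype(np.float64)
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("constant PET volume: z-score undefined (sd == 0)")
    z = (x - x.mean()) / sd
    return ImageVolume(data=z.astype(np.float32), spacing=pet.spacing,
                       modality=Modality.PET, id=pet.id, meta={**pet.meta, "pet_zscored": True})


# ---------------------------------------------------------------------------
# augmentation: flips and axial-plane right-angle rotation
# ---------------------------------------------------------------------------
# the horizontal axis is the last array axis (x), the vertical axis the
# second-to-last (y); rotations act in the (y, x) plane, so 3-D volumes rotate
# slice-wise about z.

def flip_h(a: np.ndarray) -> np.ndarray:
    return np.flip(a, axis=-1)


def flip_v(a: np.ndarray) -> np.ndarray:
    return np.flip(a, axis=-2)


def rotate90(a: np.ndarray, k: int = 1) -> np.ndarray:
    return np.rot90(a, k=k, axes=(-2, -1))


def _apply(sample: SamplePair, fn) -> SamplePair:
    def tr(vol: ImageVolume | None) -> ImageVolume | None:
        if vol is None:
            return None
        return ImageVolume(data=np.ascontiguousarray(fn(vol.data)), spacing=vol.spacing,
                           modality=vol.modality, id=vol.id, meta=dict(vol.meta))

    return SamplePair(pet=tr(sample.pet), ct=tr(sample.ct), mask=tr(sample.mask),
                      center=sample.center, patient=sample.patient)


def augment(sample: SamplePair, seed: int,
            enabled: tuple[str, ...] = ("hflip", "vflip", "rotate")) -> SamplePair:
    """Apply one seeded random spatial transform jointly to PET, CT and mask.

    Each enabled flip fires with probability 1/2; rotation draws a multiple
    of 90 degrees uniformly from {0, 90, 180, 270}. Identical seeds yield
    bit-identical outputs.
    """
    unknown = set(enabled) - {"hflip", "vflip", "rotate"}
    if unknown:
        raise ConfigurationError(f"unknown augmentation ops: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = sample
    if "hflip" in enabled and rng.random() < 0.5:
        out = _apply(out, flip_h)
    if "vflip" in enabled and rng.random() < 0.5:
        out = _apply(out, flip_v)
    if "rotate" in enabled:
        k = int(rng.integers(0, 4))
        if k:
            out = _apply(out, lambda a: rotate90(a, k))
    return out


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

class SplitStrategy(str, enum.Enum):
    LEAVE_ONE_CENTER = "LEAVE_ONE_CENTER"
    RANDOM_80_20 = "RANDOM_80_20"


@dataclass
class SplitPlan:
    folds: list[tuple[tuple[str, ...], tuple[str, ...]]]  # (train ids, test ids)
    strategy: SplitStrategy
    seed: int

    def __post_init__(self):
        all_ids = None
        for train, test in self.folds:
            if set(train) & set(test):
                raise ConfigurationError("train and test ids overlap within a fold")
            ids = set(train) | set(test)
            if all_ids is None:
                all_ids = ids
            elif ids != all_ids:
                raise ConfigurationError("folds do not cover the same id universe")


def make_split(samples: list[SamplePair], strategy: SplitStrategy | str,
               seed: int = 0) -> SplitPlan:
    """Build a leave-one-center-out or seeded random 80/20 split plan."""
    strategy = SplitStrategy(strategy)
    if len(samples) < 2:
        raise ConfigurationError("need at least 2 samples to split")
    ids = [s.patient for s in samples]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("sample (patient) ids must be unique")
    if strategy is SplitStrategy.LEAVE_ONE_CENTER:
        centers: dict[str, list[str]] = {}
        for s in samples:
            centers.setdefault(s.center, []).append(s.patient)
        if len(centers) < 2:
            raise ConfigurationError(
                f"leave-one-center split needs >=2 centers, found {len(centers)}")
        folds = []
        for c in sorted(centers):
            test = tuple(centers[c])
            train = tuple(i for i in ids if i not in set(test))
            folds.append((train, test))
    else:
        rng = np.random.default_rng(seed)
        order = [ids[i] for i in rng.permutation(len(ids))]
        n_test = int(round(0.2 * len(ids)))
        n_test = max(1, n_test)
        test = tuple(order[:n_test])
        train = tuple(order[n_test:])
        folds = [(train, test)]
    return SplitPlan(folds=folds, strategy=strategy, seed=seed)


def save_split(plan: SplitPlan, samples: list[SamplePair], path) -> None:
    """Serialize a plan as TSV: one row per (sample, fold) with its role."""
    center_of = {s.patient: s.center for s in samples}
    lines = ["id\tcenter\tfold\trole"]
    for f, (train, test) in enumerate(plan.folds):
        for i in train:
            lines.append(f"{i}\t{center_of.get(i, '')}\t{f}\ttrain")
        for i in test:
            lines.append(f"{i}\t{center_of.get(i, '')}\t{f}\ttest")
    Path(path).write_text("\n".join(lines) + "\n")


def load_split(path, strategy: SplitStrategy | str = SplitStrategy.RANDOM_80_20,
               seed: int = 0) -> SplitPlan:
    rows = Path(path).read_text().strip().splitlines()[1:]
    folds_d: dict[int, tuple[list[str], list[str]]] = {}
    for row in rows:
        i, _center, f, role = row.split("\t")
        tr, te = folds_d.setdefault(int(f), ([], []))
        (tr if role == "train" else te).append(i)
    folds = [(tuple(folds_d[f][0]), tuple(folds_d[f][1])) for f in sorted(folds_d)]
    return SplitPlan(folds=folds, strategy=SplitStrategy(strategy), seed=seed)
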