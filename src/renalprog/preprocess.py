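"""CT volume preparation for the tumor-grading network.

A whole-abdomen CT scan plus its kidney/tumor segmentation is turned into a
fixed-size two-channel sample: channel 0 is the z-scored image crop around a
kidney, channel 1 the binary tumor mask.  The pipeline order is

    extract kidney region -> reorient to RAS -> resize -> normalize -> concatenate

Masks always travel through the same spatial operators as the image, with
nearest-neighbor interpolation so the label set is preserved exactly.

Label convention (KiTS-style, remappable): 0 background, 1 kidney, 2 tumor,
3 cyst.  Voxel indices are 0-based and bounding boxes half-open ``[lo, hi)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as _sk_resize

KIDNEY_LABEL = 1
TUMOR_LABEL = 2
CYST_LABEL = 3

_VALID_AXIS_CODES = set("RLAPSI")


@dataclass
class Volume3D:
    """A scalar 3D image with voxel spacing (mm) and an orientation code."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str = "RAS"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a 3D array with all extents >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        _check_orientation(self.orientation)

    @property
    def shape(self):
        return self.voxels.shape


@dataclass
class SegMask:
    """Integer label volume aligned voxel-for-voxel with a :class:`Volume3D`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str = "RAS"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a 3D array")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            self.voxels = np.rint(self.voxels).astype(np.int16)
        _check_orientation(self.orientation)

    @property
    def shape(self):
        return self.voxels.shape


@dataclass
class PreparedSample:
    """Two-channel fixed-size network input: (image, binary tumor mask)."""

    channels: np.ndarray  # (2, D, H, W)
    grade: int
    patient_id: str = ""

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 4 or self.channels.shape[0] != 2:
            raise ValueError("channels must have shape (2, D, H, W)")
        if self.grade not in (1, 2, 3, 4):
            raise ValueError(f"ISUP grade must be in 1..4, got {self.grade}")
        mask = self.channels[1]
        if not np.isin(mask, (0.0, 1.0)).all():
            raise ValueError("tumor channel must be binary")

    @property
    def shape(self):
        return self.channels.shape[1:]


def _check_orientation(code: str) -> None:
    axis_of = {"R": 0, "L": 0, "A": 1, "P": 1, "S": 2, "I": 2}
    if (len(code) != 3 or any(c not in _VALID_AXIS_CODES for c in code)
            or len({axis_of[c] for c in code}) != 3):
        raise ValueError(f"invalid orientation code {code!r}")


def extract_kidney_region(volume: Volume3D, mask: SegMask,
                          side_policy: str = "with-tumor", margin: int = 0,
                          region_labels: tuple[int, ...] = (KIDNEY_LABEL, TUMOR_LABEL),
                          ) -> list[tuple[Volume3D, SegMask]]:
    """Crop the image and mask to per-kidney bounding boxes.

    Connected components of the kidney+tumor region are found and each is
    cropped to its axis-aligned bounding box (plus ``margin`` voxels, clamped
    to the volume).  ``side_policy`` selects which kidneys are returned:
    ``"both-separately"`` all of them, ``"left"``/``"right"`` by anatomical
    side (assuming the first axis points Right as in RAS), and the default
    ``"with-tumor"`` only kidneys whose box contains tumor voxels (all of
    them if no kidney does).
    """
    if volume.shape != mask.shape:
        raise ValueError("mask/volume shape mismatch")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    region = np.isin(mask.voxels, region_labels)
    if not region.any():
        raise ValueError("empty segmentation: mask contains no kidney voxels")
    labeled, n_comp = ndimage.label(region)
    crops, centroids, has_tumor = [], [], []
    for comp in range(1, n_comp + 1):
        idx = np.argwhere(labeled == comp)
        lo = np.maximum(idx.min(axis=0) - margin, 0)
        hi = np.minimum(idx.max(axis=0) + 1 + margin, volume.shape)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        crops.append((
            Volume3D(volume.voxels[sl].copy(), volume.spacing, volume.orientation),
            SegMask(mask.voxels[sl].copy(), mask.spacing, mask.orientation),
        ))
        centroids.append(idx.mean(axis=0))
        has_tumor.append(bool((mask.voxels[sl] == TUMOR_LABEL).any()))
    if side_policy == "both-separately":
        return crops
    if side_policy == "with-tumor":
        picked = [c for c, t in zip(crops, has_tumor) if t]
        return picked if picked else crops
    if side_policy in ("left", "right"):
        xs = [c[0] for c in centroids]
        i = int(np.argmin(xs)) if side_policy == "left" else int(np.argmax(xs))
        return [crops[i]]
    raise ValueError(f"unknown side_policy {side_policy!r}")


def _reorient(voxels: np.ndarray, spacing, src: str, dst: str = "RAS"):
    _check_orientation(src)
    src_ornt = nib.orientations.axcodes2ornt(tuple(src))
    dst_ornt = nib.orientations.axcodes2ornt(tuple(dst))
    transform = nib.orientations.ornt_transform(src_ornt, dst_ornt)
    out = nib.orientations.apply_orientation(voxels, transform)
    perm = transform[:, 0].astype(int)
    new_spacing = tuple(float(spacing[p]) for p in perm)
    return out, new_spacing


def reorient_to_ras(volume: Volume3D) -> Volume3D:
    """Permute/flip axes so the volume is in Right-Anterior-Superior order."""
    vox, sp = _reorient(volume.voxels, volume.spacing, volume.orientation)
    return Volume3D(vox, sp, "RAS")


def reorient_mask_to_ras(mask: SegMask) -> SegMask:
    vox, sp = _reorient(mask.voxels, mask.spacing, mask.orientation)
    return SegMask(vox, sp, "RAS")


def resize_volume(volume: Volume3D, target: tuple[int, int, int],
                  order: int = 1) -> Volume3D:
    """Resample to ``target`` shape (trilinear by default)."""
    if any(t < 1 for t in target):
        raise ValueError("target extents must be >= 1")
    out = _sk_resize(volume.voxels.astype(np.float64), target, order=order,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    scale = [s * o / t for s, o, t in zip(volume.spacing, volume.shape, target)]
    return Volume3D(out, tuple(scale), volume.orientation)


def resize_mask(mask: SegMask, target: tuple[int, int, int]) -> SegMask:
    """Nearest-neighbor resample; the label set is preserved exactly."""
    if any(t < 1 for t in target):
        raise ValueError("target extents must be >= 1")
    out = _sk_resize(mask.voxels, target, order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    scale = [s * o / t for s, o, t in zip(mask.spacing, mask.shape, target)]
    return SegMask(out.astype(mask.voxels.dtype), tuple(scale), mask.orientation)


def normalize_intensity(volume: Volume3D) -> Volume3D:
    """Z-score the intensities (population standard deviation, ddof=0)."""
    v = volume.voxels.astype(np.float64)
    if v.size < 2:
        raise ValueError("volume must have more than one voxel")
    sd = v.std()
    if sd == 0:
        raise ValueError("zero intensity variance: cannot normalize")
    return Volume3D((v - v.mean()) / sd, volume.spacing, volume.orientation)


def concatenate_tumor_channel(image: Volume3D, tumor_mask: SegMask, grade: int,
                              patient_id: str = "",
                              tumor_label: int = TUMOR_LABEL) -> PreparedSample:
    """Stack the image with the binarized tumor mask on the channel axis."""
    if image.shape != tumor_mask.shape:
        raise ValueError("image/mask shape mismatch")
    binary = (tumor_mask.voxels == tumor_label).astype(np.float32)
    channels = np.stack([image.voxels.astype(np.float32), binary])
    return PreparedSample(channels, grade, patient_id)


def prepare_sample(volume: Volume3D, mask: SegMask, grade: int,
                   patient_id: str = "",
                   target: tuple[int, int, int] = (128, 128, 128),
                   side_policy: str = "with-tumor",
                   margin: int = 0) -> list[PreparedSample]:
    """Full preparation pipeline; one sample per selected kidney."""
    volume = reorient_to_ras(volume)
    mask = reorient_mask_to_ras(mask)
    samples = []
    for vol_c, mask_c in extract_kidney_region(volume, mask, side_policy, margin):
        vol_r = resize_volume(vol_c, target)
        mask_r = resize_mask(mask_c, target)
        vol_n = normalize_intensity(vol_r)
        samples.append(concatenate_tumor_channel(vol_n, mask_r, grade, patient_id))
    return samples


# ---------------------------------------------------------------------------
# NIfTI and clinical-table I/O

def load_nifti_volume(path: str | Path) -> Volume3D:
    img = nib.load(str(path))
    orientation = "".join(nib.aff2axcodes(img.affine))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(np.asarray(img.get_fdata()), spacing, orientation)


def load_nifti_mask(path: str | Path) -> SegMask:
    img = nib.load(str(path))
    orientation = "".join(nib.aff2axcodes(img.affine))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.rint(np.asarray(img.get_fdata())).astype(np.int16)
    return SegMask(data, spacing, orientation)


def _affine_for(orientation: str, spacing) -> np.ndarray:
    ornt = nib.orientations.axcodes2ornt(tuple(orientation))
    aff = np.zeros((4, 4))
    aff[3, 3] = 1.0
    for axis, (out_axis, flip) in enumerate(ornt):
        aff[int(out_axis), axis] = flip * spacing[axis]
    return aff


def save_nifti(obj: Volume3D | SegMask, path: str | Path) -> None:
    data = obj.voxels
    if isinstance(obj, SegMask):
        data = data.astype(np.int16)
    img = nib.Nifti1Image(data, _affine_for(obj.orientation, obj.spacing))
    nib.save(img, str(path))


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the KiTS-style clinical JSON into a tidy frame.

    Expected per-case keys: ``case_id``, ``tumor_isup_grade`` (1-4),
    ``vital_status`` (1 death, 0 censored) and ``vital_days_after_surgery``.
    """
    records = json.loads(Path(path).read_text())
    rows = []
    for rec in records:
        rows.append({
            "patient_id": str(rec["case_id"]),
            "grade": int(rec["tumor_isup_grade"]),
            "event": int(rec["vital_status"]),
            "duration_days": float(rec["vital_days_after_surgery"]),
        })
    df = pd.DataFrame(rows)
    if ((df["grade"] < 1) | (df["grade"] > 4)).any():
        raise ValueError("ISUP grades must be in 1..4")
    if (df["duration_days"] < 0).any():
        raise ValueError("durations must be non-negative")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    records = [{
        "case_id": str(r.patient_id),
        "tumor_isup_grade": int(r.grade),
        "vital_status": int(r.event),
        "vital_days_after_surgery": float(r.duration_days),
    } for r in df.itertuples()]
    Path(path).write_text(json.dumps(records, indent=1))
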