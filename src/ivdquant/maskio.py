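"""Reading, writing and post-processing of images and 14-class label masks.

The sagittal lumbar scene is annotated with 14 anatomical classes:
background, the five lumbar vertebral bodies (L1..L5), the five lumbar
discs (L1/L2..L5/S1), the sacrum, the presacral fat pad and the
cerebrospinal-fluid (CSF) band in the spinal canal.

Coordinate convention used throughout the package: 0-based ``(row, col)``
pixel indices, row increasing inferiorly (down the image).  By default the
anterior side of the patient is the low-column side.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image
from scipy.ndimage import binary_opening
from skimage.measure import label as _cc_label

log = logging.getLogger(__name__)

__all__ = [
    "ClassMap",
    "LabelMask",
    "BinaryRegion",
    "DEFAULT_CLASS_MAP",
    "MaskFormatError",
    "MaskValidationError",
    "AbsentStructureError",
    "read_image",
    "read_label_mask",
    "write_image",
    "write_label_mask",
    "clean_mask",
    "extract_structure",
]


class MaskFormatError(ValueError):
    """Unreadable or unsupported image format."""


class MaskValidationError(ValueError):
    """Label mask contains pixel values outside the class map."""


class AbsentStructureError(KeyError):
    """A requested anatomical class has no pixels in the mask."""


# Anatomical roles of the 14 classes.
ROLES = (
    ["background"]
    + [f"VB_L{i}" for i in range(1, 6)]
    + ["DISC_L1L2", "DISC_L2L3", "DISC_L3L4", "DISC_L4L5", "DISC_L5S1"]
    + ["SACRUM", "PRESACRAL_FAT", "CSF"]
)


@dataclass(frozen=True)
class ClassMap:
    """Mapping of integer class id to anatomical role (exactly 14 entries)."""

    id_to_role: Mapping[int, str]

    def __post_init__(self):
        ids = list(self.id_to_role)
        if len(ids) != 14 or len(set(ids)) != 14:
            raise ValueError("class map must have exactly 14 unique ids")
        if self.id_to_role.get(0) != "background":
            raise ValueError("class id 0 must be background")
        missing = set(ROLES) - set(self.id_to_role.values())
        if missing:
            raise ValueError(f"class map missing roles: {sorted(missing)}")

    def id_of(self, role: str) -> int:
        for cid, r in self.id_to_role.items():
            if r == role:
                return cid
        raise KeyError(role)

    @property
    def ids(self) -> list[int]:
        return sorted(self.id_to_role)

    @property
    def vertebra_ids(self) -> list[int]:
        return [self.id_of(f"VB_L{i}") for i in range(1, 6)]

    @property
    def disc_ids(self) -> list[int]:
        return [self.id_of(r) for r in
                ("DISC_L1L2", "DISC_L2L3", "DISC_L3L4", "DISC_L4L5", "DISC_L5S1")]

    @classmethod
    def from_json(cls, path) -> "ClassMap":
        with open(path) as fh:
            raw = json.load(fh)
        return cls({int(k): v for k, v in raw.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({str(k): v for k, v in self.id_to_role.items()}, fh, indent=1)


#: Canonical ids: 0 background, 1-5 VB L1..L5 (superior to inferior),
#: 6-10 discs L1/L2..L5/S1, 11 sacrum, 12 presacral fat, 13 CSF.
DEFAULT_CLASS_MAP = ClassMap({i: role for i, role in enumerate(ROLES)})


@dataclass
class LabelMask:
    """Integer label image together with its class map and optional spacing."""

    pixels: np.ndarray
    class_map: ClassMap = DEFAULT_CLASS_MAP
    spacing_mm: tuple[float, float] | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or not np.issubdtype(self.pixels.dtype, np.integer):
            raise MaskValidationError("label mask must be a 2-D integer grid")
        bad = np.setdiff1d(np.unique(self.pixels), self.class_map.ids)
        if bad.size:
            raise MaskValidationError(
                f"mask contains undeclared class ids: {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def present_ids(self) -> list[int]:
        return np.unique(self.pixels).tolist()


@dataclass
class BinaryRegion:
    """Boolean pixel grid of one anatomical class."""

    pixels: np.ndarray
    class_id: int

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def coords(self) -> np.ndarray:
        """(n, 2) array of (row, col) coordinates of region pixels."""
        return np.argwhere(self.pixels)


def _load_png(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:  # pragma: no cover - PIL error text varies
        raise MaskFormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        # accept RGB(A) only when all channels agree (gray stored as RGB)
        rgb = arr[..., :3]
        if not (rgb[..., 0] == rgb[..., 1]).all() or not (rgb[..., 0] == rgb[..., 2]).all():
            raise MaskFormatError(
                f"{path} is true-colour RGB; convert to grayscale explicitly")
        arr = rgb[..., 0]
    return arr


def _load_nifti(path: Path, slice_index: int | None) -> np.ndarray:
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj)
    vol = np.squeeze(vol)
    if vol.ndim == 2:
        return vol
    if vol.ndim != 3:
        raise MaskFormatError(f"{path}: expected 2-D or 3-D NIfTI, got {vol.ndim}-D")
    # the sagittal stack axis is taken as the smallest dimension
    axis = int(np.argmin(vol.shape))
    idx = vol.shape[axis] // 2 if slice_index is None else slice_index
    return np.take(vol, idx, axis=axis)


def read_image(path, slice_index: int | None = None) -> np.ndarray:
    """Read a grayscale intensity image (PNG or NIfTI) as a 2-D float array.

    Intensities are preserved as stored (16-bit PNGs are *not* rescaled to
    255).  Multi-slice NIfTI volumes return the middle sagittal slice by
    default; pass ``slice_index`` to select another.
    """
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        arr = _load_nifti(path, slice_index)
    else:
        arr = _load_png(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise MaskFormatError(f"{path}: expected a single 2-D slice")
    if (arr < 0).any():
        raise MaskFormatError(f"{path}: negative intensities are not supported")
    return arr


def read_label_mask(path, class_map: ClassMap = DEFAULT_CLASS_MAP,
                    spacing_mm: tuple[float, float] | None = None) -> LabelMask:
    """Read an integer label mask and validate it against ``class_map``."""
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        arr = _load_nifti(path, None)
    else:
        arr = _load_png(path)
    arr = np.asarray(arr)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise MaskValidationError(f"{path}: mask pixels are not integer-valued")
        arr = np.round(arr).astype(np.int64)
    return LabelMask(arr.astype(np.int64), class_map, spacing_mm)


def write_image(image: np.ndarray, path) -> None:
    """Write an intensity image as 8- or 16-bit grayscale PNG."""
    image = np.asarray(image)
    if image.max(initial=0) <= 255:
        Image.fromarray(np.round(image).astype(np.uint8)).save(path)
    else:
        Image.fromarray(np.round(image).astype(np.uint16)).save(path)


def write_label_mask(mask: LabelMask, path) -> None:
    """Write a label mask as an 8-bit PNG with the canonical ids."""
    Image.fromarray(mask.pixels.astype(np.uint8)).save(path)


def clean_mask(mask: LabelMask, radius: int = 1) -> LabelMask:
    """Remove segmentation burrs by class-wise morphological opening.

    Each class is opened (erosion then dilation) with a square structuring
    element of side ``2·radius + 1``, which removes islands and edge
    protrusions up to ``radius`` pixels (a cross/disk element of the same
    radius regrows 1-px spurs on flat edges and was therefore not used).
    Openings are subsets of the original class regions, so classes stay
    disjoint when recomposed; pixels removed from every class become
    background.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    se = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    out = np.zeros_like(mask.pixels)
    for cid in mask.present_ids():
        if cid == 0:
            continue
        opened = binary_opening(mask.pixels == cid, structure=se)
        out[opened] = cid
    return LabelMask(out, mask.class_map, mask.spacing_mm)


def extract_structure(mask: LabelMask, class_id: int) -> BinaryRegion:
    """Return the binary region of one class, keeping the largest component.

    Fragmented predictions (more than one connected component) keep only the
    largest component; a warning is logged since downstream geometry assumes
    one structure per class.
    """
    if class_id not in mask.class_map.ids:
        raise KeyError(f"class id {class_id} not in class map")
    binary = mask.pixels == class_id
    if not binary.any():
        role = mask.class_map.id_to_role[class_id]
        raise AbsentStructureError(f"class {class_id} ({role}) absent from mask")
    labels, n = _cc_label(binary, connectivity=2, return_num=True)
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1
        log.warning("class %d fragmented into %d components; keeping largest "
                    "(%d px of %d)", class_id, n, sizes.max(), sizes.sum())
        warnings.warn(f"class {class_id} fragmented; largest component kept",
                      stacklevel=2)
        binary = labels == keep
    return BinaryRegion(binary, class_id)
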