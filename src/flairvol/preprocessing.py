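"""Volume ingestion and ROI-cropping preprocessing.

The preprocessing chain mirrors what is done to clinical FLAIR data before
classification: load the volume (NIfTI file or DICOM series), strip non-brain
tissue so the background is exactly zero, find the per-slice non-zero
bounding boxes, take their union over all slices (and, in dataset mode, over
all training volumes) to obtain the maximal ROI (MROI), and crop every slice
to that box without resampling, preserving voxel positional relationships.
On the clinical acquisition geometry (256x256 in-plane, 66 slices) the MROI
with corner vertices (49,60) and (207,200) reduces volumes to 159x141x66.

Skull stripping delegates to an external BET executable (fractional
intensity threshold 0.5) when one is configured; otherwise an internal
fallback is used: Otsu threshold scaled by the fractional threshold, largest
connected component, morphological closing and hole filling.
"""

from __future__ import annotations

import json
import logging
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pydicom
from scipy import ndimage
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)


@dataclass
class VolumeImage:
    """A 3D scalar voxel grid (rows, cols, slices) with spacing metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_order: str = "RCS"  # rows, columns, slices

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned inclusive bounding box: in-plane (row, col) plus slices."""

    row: tuple[int, int]
    col: tuple[int, int]
    slices: tuple[int, int]

    def __post_init__(self):
        for name in ("row", "col", "slices"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"invalid {name} range ({lo}, {hi})")

    @property
    def extents(self) -> tuple[int, int, int]:
        """Inclusive extents: (49,207) spans 207-49+1 = 159 indices."""
        return (
            self.row[1] - self.row[0] + 1,
            self.col[1] - self.col[0] + 1,
            self.slices[1] - self.slices[0] + 1,
        )

    @classmethod
    def from_vertices(cls, vertices: Iterable[tuple[int, int]], n_slices: int) -> "RoiBox":
        """Box from in-plane corner vertices (duplicates allowed), all slices kept."""
        vs = list(vertices)
        rows = [v[0] for v in vs]
        cols = [v[1] for v in vs]
        return cls((min(rows), max(rows)), (min(cols), max(cols)), (0, n_slices - 1))

    def to_dict(self) -> dict:
        return {"row": list(self.row), "col": list(self.col), "slices": list(self.slices)}

    @classmethod
    def from_dict(cls, d: dict) -> "RoiBox":
        return cls(tuple(d["row"]), tuple(d["col"]), tuple(d["slices"]))


def load_volume(path) -> VolumeImage:
    """Load a NIfTI file or a DICOM series directory as a canonical volume.

    DICOM slices are sorted by their position along the slice normal (image
    orientation cross product), falling back to InstanceNumber, so shuffled
    file order yields the identical volume.  Mixed-series directories and
    non-3D NIfTI images are rejected.
    """
    path = Path(path)
    if path.is_dir():
        return _load_dicom_series(path)
    img = nib.load(path)
    if img.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI image, got {img.ndim}D shape {img.shape}")
    data = np.asarray(img.dataobj, dtype=np.float32)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(data=data, spacing=zooms)


def _load_dicom_series(directory: Path) -> VolumeImage:
    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", ".ima", ""))
    if not files:
        raise ValueError(f"no DICOM files found in {directory}")
    datasets = [pydicom.dcmread(str(p)) for p in files]
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1:
        raise ValueError(f"directory {directory} mixes {len(uids)} DICOM series")
    ds0 = datasets[0]
    try:
        iop = np.array(ds0.ImageOrientationPatient, dtype=float)
        normal = np.cross(iop[:3], iop[3:])
        datasets.sort(key=lambda ds: float(np.dot(normal, np.array(ds.ImagePositionPatient, dtype=float))))
        positions = [float(np.dot(normal, np.array(ds.ImagePositionPatient, dtype=float))) for ds in datasets]
        dz = float(np.median(np.diff(positions))) if len(positions) > 1 else 1.0
    except (AttributeError, TypeError):
        datasets.sort(key=lambda ds: int(ds.InstanceNumber))
        dz = float(getattr(ds0, "SliceThickness", 1.0))
    data = np.stack([ds.pixel_array.astype(np.float32) for ds in datasets], axis=-1)
    ps = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    return VolumeImage(data=data, spacing=(float(ps[0]), float(ps[1]), abs(dz) or 1.0))


def save_volume(vol: VolumeImage, path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def strip_nonbrain(
    vol: VolumeImage,
    frac_threshold: float = 0.5,
    bet_path: str | None = None,
) -> VolumeImage:
    """Zero out non-brain voxels.

    With ``bet_path`` set, the volume is handed to the external BET
    executable with fractional intensity ``frac_threshold`` (0.5 by default).
    Otherwise the internal fallback runs: Otsu threshold on positive voxels
    scaled by ``frac_threshold/0.5``, largest connected component,
    morphological closing, hole filling.
    """
    data = np.asarray(vol.data, dtype=np.float32)
    if (data < 0).any():
        raise ValueError("strip_nonbrain expects nonnegative intensities")
    if not (data > 0).any():
        raise ValueError("no brain tissue found: volume is all zero")
    if bet_path is not None:
        return _strip_with_bet(vol, frac_threshold, bet_path)

    positive = data[data > 0]
    if np.unique(positive).size == 1:
        mask = data > 0
    else:
        thr = threshold_otsu(positive) * (frac_threshold / 0.5)
        mask = data > thr
        if not mask.any():
            mask = data > 0
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    # pad before closing so the zero border cannot erode true brain voxels
    pad = 3
    padded = np.pad(mask, pad)
    closed = ndimage.binary_closing(
        padded, structure=ndimage.generate_binary_structure(3, 1), iterations=2
    )
    mask = closed[pad:-pad, pad:-pad, pad:-pad]
    mask = ndimage.binary_fill_holes(mask)
    out = np.where(mask, data, 0.0).astype(np.float32)
    return replace(vol, data=out)


def _strip_with_bet(vol: VolumeImage, frac_threshold: float, bet_path: str) -> VolumeImage:
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.nii.gz"
        outp = Path(tmp) / "out.nii.gz"
        save_volume(vol, inp)
        subprocess.run([bet_path, str(inp), str(outp), "-f", str(frac_threshold)], check=True)
        stripped = load_volume(outp)
    return replace(vol, data=stripped.data)


def slice_roi(slice_2d: np.ndarray) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Tightest inclusive box around non-zero entries of a 2D slice, or None."""
    slice_2d = np.asarray(slice_2d)
    if slice_2d.ndim != 2:
        raise ValueError(f"slice must be 2D, got shape {slice_2d.shape}")
    rows = np.flatnonzero(np.any(slice_2d != 0, axis=1))
    if rows.size == 0:
        return None
    cols = np.flatnonzero(np.any(slice_2d != 0, axis=0))
    return (int(rows[0]), int(rows[-1])), (int(cols[0]), int(cols[-1]))


def max_roi(vol: VolumeImage | np.ndarray) -> RoiBox:
    """Union of all per-slice ROIs: the maximal in-plane ROI (MROI).

    Equivalently the tightest in-plane box covering every slice's non-zero
    region; the slice axis is never cropped.
    """
    data = vol.data if isinstance(vol, VolumeImage) else np.asarray(vol)
    if data.ndim != 3:
        raise ValueError(f"volume must be 3D, got shape {data.shape}")
    nz = data != 0
    rows = np.flatnonzero(nz.any(axis=(1, 2)))
    if rows.size == 0:
        raise ValueError("all-zero volume has no ROI")
    cols = np.flatnonzero(nz.any(axis=(0, 2)))
    return RoiBox(
        (int(rows[0]), int(rows[-1])),
        (int(cols[0]), int(cols[-1])),
        (0, data.shape[2] - 1),
    )


def union_rois(boxes: Sequence[RoiBox]) -> RoiBox:
    """Per-axis min-of-mins / max-of-maxes union of ROI boxes."""
    if not boxes:
        raise ValueError("no boxes to unite")
    return RoiBox(
        (min(b.row[0] for b in boxes), max(b.row[1] for b in boxes)),
        (min(b.col[0] for b in boxes), max(b.col[1] for b in boxes)),
        (min(b.slices[0] for b in boxes), max(b.slices[1] for b in boxes)),
    )


def dataset_max_roi(volumes: Iterable[VolumeImage | np.ndarray]) -> RoiBox:
    """MROI over a whole dataset: union of every volume's MROI."""
    return union_rois([max_roi(v) for v in volumes])


def crop(vol: VolumeImage, box: RoiBox) -> VolumeImage:
    """Crop to an inclusive box without resampling; positions are preserved."""
    data = vol.data
    m, n, l = data.shape
    if box.row[1] >= m or box.col[1] >= n or box.slices[1] >= l:
        raise ValueError(f"box {box} exceeds volume extents {data.shape}")
    out = data[
        box.row[0] : box.row[1] + 1,
        box.col[0] : box.col[1] + 1,
        box.slices[0] : box.slices[1] + 1,
    ]
    return replace(vol, data=out.copy())


def normalize_volume(vol: VolumeImage) -> VolumeImage:
    """Min-max scale intensities to [0,1] over brain (non-zero) voxels.

    Background stays exactly zero.  This is a model-input conditioning step
    needed for stable training; it is applied after cropping.
    """
    data = np.asarray(vol.data, dtype=np.float32)
    brain = data != 0
    if not brain.any():
        raise ValueError("cannot normalize an all-zero volume")
    lo = float(data[brain].min())
    hi = float(data[brain].max())
    if hi == lo:
        out = np.where(brain, 1.0, 0.0).astype(np.float32)
    else:
        out = np.where(brain, (data - lo) / (hi - lo), 0.0).astype(np.float32)
    return replace(vol, data=out)


def preprocess_dataset(
    volumes: Sequence[VolumeImage],
    frac_threshold: float = 0.5,
    bet_path: str | None = None,
    box: RoiBox | None = None,
    normalize: bool = True,
) -> tuple[list[VolumeImage], RoiBox]:
    """Strip, compute the dataset MROI (unless given), crop and normalize."""
    stripped = [strip_nonbrain(v, frac_threshold, bet_path) for v in volumes]
    if box is None:
        box = dataset_max_roi(stripped)
    out = [crop(v, box) for v in stripped]
    if normalize:
        out = [normalize_volume(v) for v in out]
    return out, box


def write_sidecar(path, box: RoiBox, params: dict) -> None:
    """JSON sidecar recording the ROI box and preprocessing parameters."""
    with open(path, "w") as fh:
        json.dump({"roi_box": box.to_dict(), "parameters": params}, fh, indent=2, sort_keys=True)
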