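"""Multi-channel MR image I/O and per-pixel feature extraction.

A case consists of four co-registered 2-D Dixon channels (fat, water,
in-phase, opposed-phase).  Each pixel inside a rectangular region of
interest contributes a six-dimensional feature vector: the four channel
intensities after a fixed 3x3 smoothing kernel, plus its physical
(x, y) position in millimetres.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "CHANNEL_NAMES",
    "LABEL_PALETTE",
    "SMOOTHING_KERNEL",
    "MRVolumeSet",
    "ROI",
    "FeatureTable",
    "load_volume_set",
    "smooth_channel",
    "extract_features",
    "write_label_mask",
    "read_label_mask",
]

CHANNEL_NAMES = ("fat", "water", "ip", "op")

#: Normalised 3x3 low-pass kernel applied to every channel before sampling.
#: Entries sum to 1 so constant regions are preserved exactly.
SMOOTHING_KERNEL = np.array(
    [[0.1, 0.1, 0.1],
     [0.1, 0.2, 0.1],
     [0.1, 0.1, 0.1]]
)

# integer-scaled form used internally: correlating with tenths and dividing
# once keeps constant regions bit-exact instead of accumulating 0.1-rounding
_SMOOTHING_KERNEL_X10 = np.array(
    [[1.0, 1.0, 1.0],
     [1.0, 2.0, 1.0],
     [1.0, 1.0, 1.0]]
)

#: Fixed integer palette used for label masks on disk.
LABEL_PALETTE = {"other": 0, "liver": 1, "kidney": 2, "ignore": 255}
_PALETTE_INV = {v: k for k, v in LABEL_PALETTE.items()}

FEATURE_COLUMNS = ("fat_s", "water_s", "ip_s", "op_s", "x", "y")


class VolumeValidationError(ValueError):
    """A channel set failed structural validation."""


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, 0-based, half-open pixel bounds."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 3 or self.width < 3:
            raise ValueError("ROI must be at least 3x3")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")

    def validate_for(self, shape: tuple[int, int]) -> None:
        if self.row0 + self.height > shape[0] or self.col0 + self.width > shape[1]:
            raise ValueError(f"ROI {self} exceeds image shape {shape}")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )

    @property
    def area(self) -> int:
        return self.height * self.width


@dataclass
class MRVolumeSet:
    """Four co-registered 2-D MR channels plus physical pixel spacing."""

    channels: dict[str, np.ndarray]
    pixel_spacing: tuple[float, float]
    case_id: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CHANNEL_NAMES if c not in self.channels]
        if missing:
            raise VolumeValidationError(f"missing channel: {', '.join(missing)}")
        extra = set(self.channels) - set(CHANNEL_NAMES)
        if extra:
            raise VolumeValidationError(f"unexpected channels: {sorted(extra)}")
        shapes = {c: np.asarray(img).shape for c, img in self.channels.items()}
        ref = shapes[CHANNEL_NAMES[0]]
        if any(len(s) != 2 for s in shapes.values()):
            raise VolumeValidationError(f"channels must be 2-D, got shapes {shapes}")
        if any(s != ref for s in shapes.values()):
            raise VolumeValidationError(f"channel shape mismatch: {shapes}")
        if not (self.pixel_spacing[0] > 0 and self.pixel_spacing[1] > 0):
            raise VolumeValidationError(
                f"pixel spacing must be positive, got {self.pixel_spacing}"
            )
        self.channels = {
            c: np.asarray(img, dtype=float) for c, img in self.channels.items()
        }

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[CHANNEL_NAMES[0]].shape


@dataclass
class FeatureTable:
    """n x 6 per-pixel features with optional tissue labels.

    Columns are (fat_s, water_s, ip_s, op_s, x, y): the four smoothed
    channel intensities and the physical pixel coordinates in mm.
    """

    X: np.ndarray
    labels: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != 6:
            raise ValueError(f"feature matrix must be n x 6, got {self.X.shape}")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (self.X.shape[0],):
                raise ValueError("label vector length does not match feature rows")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        labels = None if self.labels is None else self.labels[idx]
        return FeatureTable(self.X[idx], labels, dict(self.provenance))

    def restrict_labels(self, keep: Sequence[str]) -> "FeatureTable":
        if self.labels is None:
            raise ValueError("table has no labels")
        mask = np.isin(self.labels.astype(str), list(keep))
        return self.subset(np.flatnonzero(mask))

    def label_counts(self) -> dict[str, int]:
        if self.labels is None:
            return {}
        values, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))

    def to_csv(self, path: str | Path) -> None:
        header = list(FEATURE_COLUMNS)
        if self.labels is not None:
            header.append("label")
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            for i in range(self.n):
                row = [repr(float(v)) for v in self.X[i]]
                if self.labels is not None:
                    row.append(str(self.labels[i]))
                writer.writerow(row)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            has_labels = header == list(FEATURE_COLUMNS) + ["label"]
            if not has_labels and header != list(FEATURE_COLUMNS):
                raise ValueError(f"unrecognised feature CSV header: {header}")
            X, labels = [], []
            for row in reader:
                X.append([float(v) for v in row[:6]])
                if has_labels:
                    labels.append(row[6])
        return cls(np.asarray(X), np.asarray(labels, dtype=object) if has_labels else None)


def _read_image(path: str | Path, slice_index: int | None = None) -> np.ndarray:
    """Read one grayscale image as a float 2-D array (no rescaling)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        try:
            img = nib.load(str(path))
        except Exception as exc:  # pragma: no cover - nibabel error text varies
            raise VolumeValidationError(f"unreadable file {path}: {exc}") from exc
        data = np.asanyarray(img.dataobj)
        data = np.squeeze(data)
        if data.ndim == 3:
            if slice_index is None:
                raise VolumeValidationError(
                    f"{path} is a multi-slice volume; a slice index is required"
                )
            data = data[:, :, slice_index]
        if data.ndim != 2:
            raise VolumeValidationError(f"{path}: expected a 2-D slice, got {data.shape}")
        return np.asarray(data, dtype=float)
    if name.endswith((".png", ".tif", ".tiff")):
        from PIL import Image

        try:
            with Image.open(path) as im:
                arr = np.asarray(im)
        except Exception as exc:
            raise VolumeValidationError(f"unreadable file {path}: {exc}") from exc
        if arr.ndim != 2:
            raise VolumeValidationError(f"{path}: expected grayscale, got shape {arr.shape}")
        return arr.astype(float)
    raise VolumeValidationError(f"unsupported image format: {path}")


def load_volume_set(
    paths: Mapping[str, str | Path],
    pixel_spacing: tuple[float, float],
    case_id: str = "",
    slice_index: int | None = None,
) -> MRVolumeSet:
    """Load and validate the four Dixon channel images for one case.

    Parameters
    ----------
    paths
        Map from channel name (``fat``, ``water``, ``ip``, ``op``) to an
        image file (NIfTI-1 single slice, or 8/16-bit grayscale PNG/TIFF).
    pixel_spacing
        Physical (row_mm, col_mm) pixel spacing.
    slice_index
        Required when a NIfTI file holds more than one slice.
    """
    missing = [c for c in CHANNEL_NAMES if c not in paths]
    if missing:
        raise VolumeValidationError(f"missing channel: {', '.join(missing)}")
    channels = {c: _read_image(paths[c], slice_index) for c in CHANNEL_NAMES}
    return MRVolumeSet(channels, tuple(pixel_spacing), case_id=case_id)


def smooth_channel(image: np.ndarray) -> np.ndarray:
    """Correlate a channel with the fixed 3x3 smoothing kernel.

    Borders use replicate-edge padding so the output shape equals the
    input shape and no artificial zero intensities are introduced.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError(f"image must be 2-D and at least 3x3, got {image.shape}")
    return ndimage.correlate(image, _SMOOTHING_KERNEL_X10, mode="nearest") / 10.0


def extract_features(
    vol: MRVolumeSet,
    roi: ROI,
    mask: np.ndarray | None = None,
) -> FeatureTable:
    """Assemble the six-dimensional per-pixel feature table for one ROI.

    One row per non-ignored ROI pixel, in row-major order.  Columns 1-4
    are the smoothed channel intensities at the pixel; columns 5-6 are the
    physical coordinates x = col * col_mm and y = row * row_mm.  If a
    label mask is given (integer palette or string array), labels are
    copied and pixels marked ``ignore`` are dropped.
    """
    roi.validate_for(vol.shape)
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != vol.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match channels {vol.shape}"
            )

    smoothed = [smooth_channel(vol.channels[c])[roi.slices] for c in CHANNEL_NAMES]
    rows, cols = np.mgrid[roi.row0:roi.row0 + roi.height, roi.col0:roi.col0 + roi.width]
    row_mm, col_mm = vol.pixel_spacing
    x = cols * col_mm
    y = rows * row_mm
    X = np.stack([s.ravel() for s in smoothed] + [x.ravel(), y.ravel()], axis=1)

    labels = None
    if mask is not None:
        sub = mask[roi.slices].ravel()
        if sub.dtype.kind in "iu":
            names = np.array([_PALETTE_INV.get(int(v)) for v in sub], dtype=object)
            if any(v is None for v in names):
                bad = sorted({int(v) for v in sub if int(v) not in _PALETTE_INV})
                raise ValueError(f"mask contains values outside the palette: {bad}")
        else:
            names = sub.astype(object)
            bad = set(map(str, names)) - set(LABEL_PALETTE)
            if bad:
                raise ValueError(f"mask contains unknown labels: {sorted(bad)}")
        keep = np.array([str(v) != "ignore" for v in names])
        if not keep.any():
            raise ValueError("ROI is empty after masking")
        X = X[keep]
        labels = names[keep]

    return FeatureTable(
        X, labels, provenance={"case_id": vol.case_id, "roi": roi}
    )


def write_label_mask(
    labels: Sequence[str],
    roi: ROI,
    shape: tuple[int, int],
    path: str | Path,
) -> None:
    """Write per-pixel predictions as an indexed mask image.

    Palette: other=0, liver=1, kidney=2; everything outside the ROI is
    written as ignore=255.  Output format follows the file extension
    (indexed PNG, or NIfTI).
    """
    labels = list(labels)
    if len(labels) != roi.area:
        raise ValueError(
            f"got {len(labels)} labels for an ROI of {roi.area} pixels"
        )
    roi.validate_for(shape)
    bad = set(labels) - set(LABEL_PALETTE)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    full = np.full(shape, LABEL_PALETTE["ignore"], dtype=np.uint8)
    block = np.array([LABEL_PALETTE[v] for v in labels], dtype=np.uint8)
    full[roi.slices] = block.reshape(roi.height, roi.width)

    path = Path(path)
    if path.name.lower().endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(full.astype(np.uint8), np.eye(4)), str(path))
        return
    from PIL import Image

    im = Image.fromarray(full, mode="P")
    palette = [0] * 768
    for value, rgb in ((0, (40, 40, 40)), (1, (200, 60, 60)),
                       (2, (60, 120, 220)), (255, (0, 0, 0))):
        palette[3 * value:3 * value + 3] = list(rgb)
    im.putpalette(palette)
    im.save(path)


def read_label_mask(path: str | Path) -> np.ndarray:
    """Read a label mask written by :func:`write_label_mask` (integer array)."""
    path = Path(path)
    if path.name.lower().endswith((".nii", ".nii.gz")):
        import nibabel as nib

        return np.asanyarray(nib.load(str(path)).dataobj).astype(np.uint8)
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im).astype(np.uint8)
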