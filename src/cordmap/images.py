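"""Image containers and NIfTI-1 I/O.

``ImageStack`` is the common currency of all fitters: a 3D or 4D magnitude
array with an affine.  Reading and writing go through nibabel; data are
stored float64 in memory and written float32 (maps) or float64 (stacks)
as requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


class ImageFormatError(ValueError):
    """Malformed or inconsistent image input."""


@dataclass
class ImageStack:
    """4D magnitude image: spatial axes (x, y, z) plus a volume axis."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:
            self.data = self.data[..., None]
        if self.data.ndim != 4:
            raise ImageFormatError(f"expected 3D/4D data, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]


def read_image(path) -> ImageStack:
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # nibabel raises several header error types
        raise ImageFormatError(f"cannot read NIfTI image {path}: {exc}") from exc
    return ImageStack(data, np.asarray(img.affine))


def write_image(stack: ImageStack | np.ndarray, path, affine: np.ndarray | None = None,
                dtype=np.float64) -> Path:
    if not isinstance(stack, ImageStack):
        stack = ImageStack(np.asarray(stack), affine if affine is not None else np.eye(4))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(stack.data.astype(dtype), stack.affine)
    nib.save(img, str(path))
    return path


def read_labels(path) -> np.ndarray:
    """Integer ROI label volume (3D)."""
    stack = read_image(path)
    labels = stack.data[..., 0]
    rounded = np.rint(labels)
    if not np.allclose(labels, rounded):
        raise ImageFormatError(f"label image {path} contains non-integer values")
    return rounded.astype(int)


def write_labels(labels: np.ndarray, path, affine: np.ndarray | None = None) -> Path:
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = labels[..., None]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(labels.astype(np.int16),
                          affine if affine is not None else np.eye(4))
    nib.save(img, str(path))
    return path
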