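"""Reading, writing, validating and normalising 3D brain volumes.

Volumes are NIfTI-1 (single-file ``.nii`` or ``.nii.gz``), 3D scalar only.
An optional JSON sidecar next to each image carries acquisition metadata
(``contrast``, ``age_tag``, ``normalized``) that NIfTI has no standard slot
for.  Inputs are assumed skull-stripped and spatially pre-aligned; no
resampling or reorientation is performed here.

Intensity normalisation maps each volume affinely into [-1, 1], the range
the translation networks produce through their final tanh.  Exact-zero
voxels are treated as stripped-skull background: they are excluded from the
min/max computation and pinned to -1, so that a large empty background
cannot compress the usable contrast range of the brain itself.  See
:func:`normalize_intensity` for the precise rules and escape hatch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .errors import InputError, UnsupportedContentError

__all__ = [
    "Volume",
    "LabelMap",
    "read_volume",
    "write_volume",
    "read_label_map",
    "write_label_map",
    "normalize_intensity",
]

_CONTRASTS = ("T1w", "T2w", "synthetic")


@dataclass
class Volume:
    """One 3D scalar image with voxel spacing and acquisition tags.

    Parameters
    ----------
    data : ndarray, shape (D, H, W)
        Voxel intensities.
    spacing : tuple of 3 floats
        Voxel size along each axis, in mm.
    contrast : {"T1w", "T2w", "synthetic"}
    age_tag : str
        Free-form timepoint label, e.g. ``"6m"`` or ``"12m"``.
    normalized : bool
        True once the data has been mapped into [-1, 1].
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    contrast: str = "synthetic"
    age_tag: str = ""
    normalized: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise InputError(
                f"Volume data must be 3D with axes >= 1, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or not all(
            math.isfinite(s) and s > 0 for s in self.spacing
        ):
            raise InputError(f"spacing must be 3 positive finite values, got {self.spacing}")
        if self.contrast not in _CONTRASTS:
            raise InputError(f"contrast must be one of {_CONTRASTS}, got {self.contrast!r}")
        if self.normalized:
            finite = self.data[np.isfinite(self.data)]
            if finite.size and (finite.min() < -1.0 - 1e-6 or finite.max() > 1.0 + 1e-6):
                raise InputError("normalized Volume has values outside [-1, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, **kw) -> "Volume":
        return replace(self, data=data, **kw)


@dataclass
class LabelMap:
    """Integer segmentation aligned to a :class:`Volume`; label 0 = background."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InputError(f"LabelMap data must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise InputError(f"LabelMap data must be integer, got dtype {self.data.dtype}")
        if self.data.min() < 0:
            raise InputError("LabelMap contains negative labels")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.label_names = {int(k): str(v) for k, v in dict(self.label_names).items()}
        if 0 in self.label_names:
            raise InputError("label 0 is reserved for background")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels_present(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.data) if v != 0)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_volume(path, contrast: str | None = None, age_tag: str | None = None) -> Volume:
    """Load a 3D NIfTI-1 scalar image as a :class:`Volume`.

    Contrast / age tags come from an optional JSON sidecar, unless overridden
    by the keyword arguments.  4D or non-scalar files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise UnsupportedContentError(
            f"{path} holds a {data.ndim}D image; only 3D scalar volumes are supported"
        )
    if not np.issubdtype(data.dtype, np.number):
        raise UnsupportedContentError(f"{path} holds non-scalar data ({data.dtype})")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Volume(
        data=np.asarray(data, dtype=np.float32)
        if np.issubdtype(data.dtype, np.floating)
        else np.asarray(data, dtype=np.float32),
        spacing=spacing,
        contrast=contrast or meta.get("contrast", "synthetic"),
        age_tag=age_tag if age_tag is not None else meta.get("age_tag", ""),
        normalized=bool(meta.get("normalized", False)),
    )


def write_volume(v: Volume, path) -> Path:
    """Write ``v`` as NIfTI-1 (float32) plus a JSON metadata sidecar.

    The affine is diagonal in the voxel spacing (volumes are assumed
    pre-aligned, so no rotation component is stored).  Returns ``path``.
    """
    path = Path(path)
    affine = np.diag(list(v.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), affine)
    img.header.set_zooms(v.spacing)
    try:
        nib.save(img, str(path))
    except OSError as e:  # unwritable destination
        raise InputError(f"cannot write {path}: {e}") from e
    _sidecar_path(path).write_text(
        json.dumps(
            {"contrast": v.contrast, "age_tag": v.age_tag, "normalized": v.normalized},
            indent=0,
        )
    )
    return path


def read_label_map(path) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise UnsupportedContentError(f"{path}: label maps must be 3D")
    names = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        names = {int(k): v for k, v in json.loads(sidecar.read_text()).get("label_names", {}).items()}
    return LabelMap(
        data=np.asarray(np.rint(data), dtype=np.int16),
        spacing=tuple(float(z) for z in img.header.get_zooms()[:3]),
        label_names=names,
    )


def write_label_map(m: LabelMap, path) -> Path:
    path = Path(path)
    affine = np.diag(list(m.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(m.data, dtype=np.int16), affine)
    img.header.set_zooms(m.spacing)
    nib.save(img, str(path))
    _sidecar_path(path).write_text(
        json.dumps({"label_names": {str(k): v for k, v in m.label_names.items()}})
    )
    return path


def normalize_intensity(v: Volume, exclude_background: bool = True) -> Volume:
    """Affinely map a volume's intensities into [-1, 1].

    With ``exclude_background=True`` (default, intended for skull-stripped
    images with an exact-zero exterior) the affine map ``a*x + b`` is fitted
    so the smallest/largest *nonzero* intensity maps to -1/+1; zero voxels
    are pinned to -1 and the result is clipped to [-1, 1].  If the volume
    contains negative intensities the background rule is disabled (zero is
    then an interior intensity, not an exterior mask value) and the map is
    fitted over all finite voxels, preserving monotonicity.

    Constant-valued volumes map to all zeros (range midpoint).  Already
    normalised volumes are returned unchanged, making the operation
    idempotent.  All-NaN input raises :class:`InputError`.
    """
    if v.normalized:
        return v.with_data(v.data.copy())
    data = np.asarray(v.data, dtype=np.float64)
    finite = np.isfinite(data)
    if not finite.any():
        raise InputError("cannot normalize an all-NaN volume")
    use_background = exclude_background and not (data[finite] < 0).any()
    if use_background:
        support = finite & (data != 0)
        if not support.any():  # all-zero volume: constant case
            support = finite
    else:
        support = finite
    lo = data[support].min()
    hi = data[support].max()
    if hi == lo:
        out = np.zeros_like(data)
    else:
        a = 2.0 / (hi - lo)
        b = -1.0 - a * lo
        out = a * data + b
        out = np.clip(out, -1.0, 1.0)
        if use_background:
            out[finite & (data == 0)] = -1.0
    out[~finite] = 0.0
    return v.with_data(out.astype(np.float32), normalized=True)
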