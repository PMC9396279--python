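"""NIfTI volume I/O and the patch-geometry preprocessing pipeline.

Volumes use axis order (slice, row, col), 0-based indices and half-open
windows throughout.  Preprocessing mirrors the standard multi-contrast
brain-MR recipe: a central in-plane crop to discard the empty boundary,
four overlapping corner-anchored square patches per slice (the overlap is
averaged when stitching back), per-volume linear intensity scaling to
[-1, 1], and 3-slice stacks for axial-context tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


class GeometryError(ValueError):
    """Raised when crop/patch geometry cannot be satisfied."""


@dataclass
class Volume:
    """A 3-D intensity grid with modality label and geometry metadata."""

    data: np.ndarray                    # (slices, rows, cols) float
    modality: str = ""
    case_id: str = ""
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise GeometryError(f"volume must be 3-D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclass
class PatchRecord:
    """A 2-D patch (or 3-slice stack) with full stitch-back provenance."""

    pixels: np.ndarray                  # (H, W) or (3, H, W)
    case_id: str = ""
    modality: str = ""
    slice_index: int = 0
    crop_offset: tuple[int, int] = (0, 0)   # (row, col) inside the cropped plane

    @property
    def patch_shape(self) -> tuple[int, int]:
        return tuple(self.pixels.shape[-2:])


@dataclass(frozen=True)
class ScaleParams:
    """Parameters of the linear [vmin, vmax] → [-1, 1] intensity map."""

    vmin: float
    vmax: float

    @property
    def degenerate(self) -> bool:
        return self.vmax == self.vmin


def load_volume(path: str | Path, modality: str = "", case_id: str = "") -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    return Volume(data=data, modality=modality, case_id=case_id,
                  affine=np.asarray(img.affine))


def save_volume(vol: Volume, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), str(path))


def central_crop(vol: Volume, crop_shape: tuple[int, int]) -> Volume:
    """Centered in-plane crop; odd margins round the leading margin down."""
    _, H, W = vol.shape
    ch, cw = crop_shape
    if ch > H or cw > W:
        raise GeometryError(f"crop {crop_shape} exceeds slice shape {(H, W)}")
    r0 = (H - ch) // 2
    c0 = (W - cw) // 2
    return Volume(vol.data[:, r0:r0 + ch, c0:c0 + cw],
                  modality=vol.modality, case_id=vol.case_id, affine=vol.affine)


def patch_offsets(plane_shape: tuple[int, int],
                  patch_shape: tuple[int, int]) -> list[tuple[int, int]]:
    """Corner-anchored offsets: rows {0, H-p}, cols {0, W-p}, de-duplicated.

    For a 160×180 plane and 128×128 patches this is
    (0,0), (0,52), (32,0), (32,52) — four overlapping blocks whose union
    covers the plane.
    """
    H, W = plane_shape
    ph, pw = patch_shape
    if ph > H or pw > W:
        raise GeometryError(f"patch {patch_shape} exceeds plane {plane_shape}")
    rows = sorted({0, H - ph})
    cols = sorted({0, W - pw})
    return [(r, c) for r in rows for c in cols]


def extract_patches(vol: Volume, patch_shape: tuple[int, int] = (128, 128)
                    ) -> list[PatchRecord]:
    """Per slice, the corner-anchored overlapping patches with provenance."""
    offsets = patch_offsets(vol.shape[1:], patch_shape)
    ph, pw = patch_shape
    records = []
    for k in range(vol.shape[0]):
        for (r, c) in offsets:
            records.append(PatchRecord(
                pixels=vol.data[k, r:r + ph, c:c + pw].copy(),
                case_id=vol.case_id, modality=vol.modality,
                slice_index=k, crop_offset=(r, c)))
    return records


def stitch_patches(patches: list[PatchRecord],
                   plane_shape: tuple[int, int]) -> np.ndarray:
    """Reassemble one plane, averaging wherever patches overlap.

    Uses only each record's ``crop_offset`` provenance.  Raises if the
    patches do not cover the whole plane.
    """
    acc = np.zeros(plane_shape, dtype=np.float64)
    cnt = np.zeros(plane_shape, dtype=np.float64)
    for p in patches:
        ph, pw = p.patch_shape
        r, c = p.crop_offset
        if r + ph > plane_shape[0] or c + pw > plane_shape[1]:
            raise GeometryError(
                f"patch at {p.crop_offset} of size {p.patch_shape} "
                f"exceeds plane {plane_shape}")
        acc[r:r + ph, c:c + pw] += p.pixels.reshape(ph, pw)
        cnt[r:r + ph, c:c + pw] += 1.0
    if (cnt == 0).any():
        rows, cols = np.nonzero(cnt == 0)
        raise GeometryError(
            f"incomplete coverage: {rows.size} uncovered pixels, first at "
            f"({rows[0]}, {cols[0]})")
    return acc / cnt


def stitch_volume(patches: list[PatchRecord], shape: tuple[int, int, int],
                  modality: str = "", case_id: str = "") -> Volume:
    """Stitch per-slice patch groups back into a full volume."""
    d, H, W = shape
    data = np.zeros(shape, dtype=np.float64)
    by_slice: dict[int, list[PatchRecord]] = {}
    for p in patches:
        by_slice.setdefault(p.slice_index, []).append(p)
    for k in range(d):
        if k not in by_slice:
            raise GeometryError(f"no patches for slice {k}")
        data[k] = stitch_patches(by_slice[k], (H, W))
    return Volume(data, modality=modality, case_id=case_id)


def _scale_array(data: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    if vmax == vmin:
        return np.zeros_like(data)
    return 2.0 * (data - vmin) / (vmax - vmin) - 1.0


def scale_intensity(vol: Volume, mode: str = "volume",
                    fixed_range: tuple[float, float] | None = None
                    ) -> tuple[Volume, ScaleParams | list[ScaleParams]]:
    """Linear map of [min, max] onto [-1, 1].

    mode="volume" (default): one min/max per volume, returns one
    :class:`ScaleParams`.  mode="slice": independent per-slice scaling,
    returns one ScaleParams per slice.  mode="fixed": use ``fixed_range``
    (e.g. a dataset-wide range) for every voxel.  A constant volume (or
    slice) maps to all zeros — the range midpoint — so background-only
    inputs pass through instead of erroring.
    """
    if not np.isfinite(vol.data).all():
        raise ValueError("volume contains non-finite values")
    if mode == "volume":
        params = ScaleParams(float(vol.data.min()), float(vol.data.max()))
        scaled = _scale_array(vol.data, params.vmin, params.vmax)
    elif mode == "slice":
        params = [ScaleParams(float(s.min()), float(s.max()))
                  for s in vol.data]
        scaled = np.stack([_scale_array(s, p.vmin, p.vmax)
                           for s, p in zip(vol.data, params)])
    elif mode == "fixed":
        if fixed_range is None:
            raise ValueError("mode='fixed' requires fixed_range=(vmin, vmax)")
        params = ScaleParams(float(fixed_range[0]), float(fixed_range[1]))
        scaled = _scale_array(vol.data, params.vmin, params.vmax)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return (Volume(scaled, modality=vol.modality, case_id=vol.case_id,
                   affine=vol.affine), params)


def unscale_intensity(data: np.ndarray, params: ScaleParams) -> np.ndarray:
    """Invert :func:`scale_intensity` on an array of scaled intensities."""
    if params.degenerate:
        return np.full_like(np.asarray(data, dtype=np.float64), params.vmin)
    return (np.asarray(data, dtype=np.float64) + 1.0) / 2.0 \
        * (params.vmax - params.vmin) + params.vmin


def slice_triplets(vol: Volume) -> list[PatchRecord]:
    """3-adjacent-slice stacks (k-1, k, k+1) for every slice k.

    Boundary slices are edge-replicated, so a depth-D volume yields exactly
    D stacks with slice_index 0..D-1.
    """
    d = vol.shape[0]
    if d < 3:
        raise GeometryError(f"need depth >= 3 for slice triplets, got {d}")
    records = []
    for k in range(d):
        idx = [max(k - 1, 0), k, min(k + 1, d - 1)]
        records.append(PatchRecord(
            pixels=vol.data[idx].copy(),
            case_id=vol.case_id, modality=vol.modality,
            slice_index=k, crop_offset=(0, 0)))
    return records
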