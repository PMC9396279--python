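"""Synthetic co-registered multimodal MR phantoms.

Real training data for cross-modality synthesis are co-registered multi-contrast
brain volumes (e.g. BraTS-style T1/T2/FLAIR at 240×240×155).  The phantoms here
stand in for such data while keeping the source→target mapping known exactly:

* shared anatomy: a composite of smooth 3-D Gaussian blobs, identical across
  modalities (perfect co-registration by construction);
* modality contrast: each "modality" applies its own monotone intensity
  transfer (gain and gamma) to the shared anatomy, mimicking how different MR
  contrasts re-weight the same tissue;
* axial continuity: blobs are 3-D, so adjacent slices are correlated, and a
  smooth monotone gain profile along the slice axis (a coil-sensitivity-like
  modulation) makes the slice position recoverable from image content;
* zero background: a margin of exactly-zero voxels on every face, like the
  empty border of a skull-stripped acquisition;
* known target: the target modality is a fixed deterministic function of the
  two source modalities ("mean" for exact linear oracles, "blend" for a smooth
  nonlinear default), so recovery is verifiable.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .mri_io import Volume, save_volume


class PhantomConfigError(ValueError):
    """Raised for phantom specs that cannot be realised."""


#: per-modality monotone intensity transfer: value = gain * anatomy ** gamma
DEFAULT_CONTRAST = {
    "source1": {"gain": 1.0, "gamma": 1.0},
    "source2": {"gain": 0.8, "gamma": 1.6},
}

#: smooth axial gain range (slice 0 → last slice), shared by all modalities
AXIAL_GAIN = (0.7, 1.3)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and contrast parameters of one synthetic case.

    The default geometry (16 slices of 160×180) matches the in-plane size of
    the centrally-cropped region used by the preprocessing pipeline, so patch
    extraction is exercised at its native geometry.  ``tiny()`` gives a
    64×64 profile for fast runs.
    """

    shape: tuple[int, int, int] = (16, 160, 180)  # (slices, rows, cols)
    n_blobs: int = 8
    background_margin: int = 8
    contrast_params: dict = field(default_factory=lambda: dict(DEFAULT_CONTRAST))
    target_rule: str = "blend"
    seed: int = 0

    @staticmethod
    def tiny(seed: int = 0, target_rule: str = "blend") -> "PhantomSpec":
        return PhantomSpec(shape=(12, 64, 64), n_blobs=5, background_margin=4,
                           target_rule=target_rule, seed=seed)

    def validate(self) -> None:
        d, h, w = self.shape
        if min(d, h, w) <= 0:
            raise PhantomConfigError(f"non-positive shape {self.shape}")
        if self.background_margin < 0:
            raise PhantomConfigError("negative background margin")
        if self.n_blobs < 0:
            raise PhantomConfigError("negative n_blobs")
        m = self.background_margin
        if self.n_blobs > 0 and (h - 2 * m < 2 or w - 2 * m < 2 or d < 1):
            raise PhantomConfigError(
                f"shape {self.shape} cannot hold margin {m} plus a blob")


TARGET_RULES = {
    # exact linear rule for closed-form oracles
    "mean": lambda s1, s2: 0.5 * (s1 + s2),
    # smooth nonlinear default; vanishes when both sources vanish, so the
    # zero background is preserved in the target
    "blend": lambda s1, s2: 0.5 * (s1 + s2) + 0.4 * s1 * s2,
}


def _anatomy(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Shared blob composite in [0, 1], zero on the background margin."""
    d, h, w = spec.shape
    m = spec.background_margin
    vol = np.zeros(spec.shape, dtype=np.float64)
    if spec.n_blobs == 0:
        return vol
    zz, yy, xx = np.meshgrid(np.arange(d), np.arange(h), np.arange(w),
                             indexing="ij")
    for _ in range(spec.n_blobs):
        cz = rng.uniform(0.15 * d, 0.85 * d)
        cy = rng.uniform(m + 0.1 * (h - 2 * m), h - m - 0.1 * (h - 2 * m))
        cx = rng.uniform(m + 0.1 * (w - 2 * m), w - m - 0.1 * (w - 2 * m))
        sz = rng.uniform(0.1 * d, 0.3 * d)
        sy = rng.uniform(0.06 * (h - 2 * m), 0.22 * (h - 2 * m)) + 1.0
        sx = rng.uniform(0.06 * (w - 2 * m), 0.22 * (w - 2 * m)) + 1.0
        amp = rng.uniform(0.4, 1.0)
        vol += amp * np.exp(-((zz - cz) ** 2 / (2 * sz ** 2)
                              + (yy - cy) ** 2 / (2 * sy ** 2)
                              + (xx - cx) ** 2 / (2 * sx ** 2)))
    vmax = vol.max()
    if vmax > 0:
        vol /= vmax
    # shared axial landmark: a centred smooth ellipse whose in-plane extent
    # grows monotonically with slice position — the phantom analogue of
    # anatomy whose cross-section changes systematically with axial level,
    # which is what makes a slice's position readable from its content
    cy, cx = h / 2.0, w / 2.0
    frac = np.arange(d)[:, None, None] / max(d - 1, 1)
    ry = (0.06 + 0.20 * frac) * (h - 2 * m) / 2.0
    rx = (0.06 + 0.20 * frac) * (w - 2 * m) / 2.0
    landmark = 0.7 * np.exp(-(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2))
    vol = np.maximum(vol, landmark)
    # coil-sensitivity-like monotone gain along the slice axis: makes the
    # slice index recoverable from content (axial 3-D structure)
    lo, hi = AXIAL_GAIN
    gain = np.linspace(lo, hi, d)[:, None, None]
    vol = vol * gain
    # exact-zero in-plane background margin (the empty border of a
    # skull-stripped slice); the slice axis keeps content everywhere so the
    # axial structure stays informative
    if m > 0:
        mask = np.zeros(spec.shape, dtype=bool)
        mask[:, m:h - m, m:w - m] = True
        vol = np.where(mask, vol, 0.0)
    # suppress numerically-tiny tails so "background" is exactly 0
    vol[vol < 1e-4] = 0.0
    return vol


def generate_case(spec: PhantomSpec, case_id: str = "case_0000"
                  ) -> tuple[Volume, Volume, Volume]:
    """Generate one co-registered (source1, source2, target) triple.

    The two sources are monotone contrast transforms of a shared anatomy;
    the target is ``TARGET_RULES[spec.target_rule]`` applied voxel-wise to
    the sources.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    if spec.target_rule not in TARGET_RULES:
        raise PhantomConfigError(f"unknown target_rule {spec.target_rule!r}")
    rng = np.random.default_rng(spec.seed)
    anatomy = _anatomy(spec, rng)
    sources = {}
    for name in ("source1", "source2"):
        p = spec.contrast_params[name]
        sources[name] = p["gain"] * anatomy ** p["gamma"]
    target = TARGET_RULES[spec.target_rule](sources["source1"], sources["source2"])
    return (
        Volume(sources["source1"], modality="source1", case_id=case_id),
        Volume(sources["source2"], modality="source2", case_id=case_id),
        Volume(target, modality="target", case_id=case_id),
    )


def generate_dataset(spec: PhantomSpec, n_cases: int,
                     out_dir: str | Path | None = None) -> list[tuple[Volume, Volume, Volume]]:
    """Generate ``n_cases`` independent cases (seeds spec.seed, spec.seed+1, ...).

    If ``out_dir`` is given, each volume is also written as NIfTI
    (``<case>_<modality>.nii.gz``) so downstream stages can treat phantoms
    exactly like external data.
    """
    cases = []
    for i in range(n_cases):
        case_id = f"case_{i:04d}"
        triple = generate_case(replace(spec, seed=spec.seed + i), case_id=case_id)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            for vol in triple:
                save_volume(vol, out_dir / f"{case_id}_{vol.modality}.nii.gz")
        cases.append(triple)
    return cases


@dataclass(frozen=True)
class MaskSpec:
    """A stack of binary inpainting masks inside one patch."""

    masks: np.ndarray          # (n, H, W) bool; True = masked
    patch_shape: tuple[int, int]

    @property
    def combined(self) -> np.ndarray:
        """Union of all masks, (H, W) bool."""
        if self.masks.shape[0] == 0:
            return np.zeros(self.patch_shape, dtype=bool)
        return self.masks.any(axis=0)

    @property
    def masked_fraction(self) -> float:
        return float(self.combined.mean())


def sample_masks(patch_shape: tuple[int, int], n_masks: int = 4,
                 mask_size: tuple[int, int] = (32, 32), seed: int = 0,
                 allow_overlap: bool = False, max_tries: int = 10_000) -> MaskSpec:
    """Uniform-random placement of ``n_masks`` rectangular masks in a patch.

    Masks lie fully inside the patch and by default are mutually
    non-overlapping (rejection sampling).  With the default geometry
    (128×128 patch, four 32×32 masks) exactly a quarter of the patch is
    masked.
    """
    H, W = patch_shape
    mh, mw = mask_size
    if n_masks == 0:
        return MaskSpec(masks=np.zeros((0, H, W), dtype=bool),
                        patch_shape=(H, W))
    if mh > H or mw > W:
        raise PhantomConfigError(f"mask {mask_size} larger than patch {patch_shape}")
    if n_masks * mh * mw > H * W:
        raise PhantomConfigError(
            f"{n_masks} masks of {mask_size} cannot fit in patch {patch_shape}")
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_masks, H, W), dtype=bool)
    placed: list[tuple[int, int]] = []
    for k in range(n_masks):
        for attempt in range(max_tries):
            r = int(rng.integers(0, H - mh + 1))
            c = int(rng.integers(0, W - mw + 1))
            if allow_overlap or all(
                r + mh <= pr or pr + mh <= r or c + mw <= pc or pc + mw <= c
                for pr, pc in placed
            ):
                placed.append((r, c))
                masks[k, r:r + mh, c:c + mw] = True
                break
        else:
            raise PhantomConfigError(
                f"could not place {n_masks} non-overlapping {mask_size} masks "
                f"in {patch_shape} after {max_tries} tries")
    return MaskSpec(masks=masks, patch_shape=(H, W))
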