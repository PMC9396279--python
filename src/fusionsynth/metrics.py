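"""Image-fidelity metrics: MSE, PSNR and SSIM.

Two PSNR conventions are provided.  The default (``mode="peak"``) takes the
peak as the maximum intensity over *both* images,

    PSNR = 10 log10( max²(y, g) / MSE ),

which makes the value invariant to a joint positive rescaling of the pair.
``mode="standard"`` uses a fixed data range instead (the usual definition).
SSIM likewise has a global-statistics form (single means/variances/covariance
over the whole image) and a Gaussian-windowed mean-SSIM alternate for
comparability with common practice.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from skimage.metrics import structural_similarity as _skimage_ssim


@dataclass(frozen=True)
class MetricsRecord:
    """MSE / PSNR / SSIM for one synthesized-vs-truth pair."""

    mse: float
    psnr: float                 # dB; +inf when the images are identical
    ssim: float
    n: int                      # number of pixels compared

    def to_json(self) -> str:
        d = asdict(self)
        if math.isinf(d["psnr"]):
            d["psnr"] = "Infinity"
        return json.dumps(d)


def _check_pair(y, g):
    y = np.asarray(y, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if y.shape != g.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {g.shape}")
    return y, g


def mse(y, g) -> float:
    """Mean squared difference, 1/N ||y - g||²."""
    y, g = _check_pair(y, g)
    return float(np.mean((y - g) ** 2))


def psnr(y, g, mode: str = "peak", data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB.

    mode="peak": peak² = (max intensity over both images)².
    mode="standard": peak = ``data_range`` (defaults to max-min over both).
    Identical images return +inf.
    """
    y, g = _check_pair(y, g)
    err = mse(y, g)
    if err == 0.0:
        return float("inf")
    if mode == "peak":
        peak = float(max(y.max(), g.max()))
    elif mode == "standard":
        peak = float(data_range if data_range is not None
                     else max(y.max(), g.max()) - min(y.min(), g.min()))
    else:
        raise ValueError(f"unknown PSNR mode {mode!r}")
    return float(10.0 * np.log10(peak ** 2 / err))


def ssim(y, g, mode: str = "global", data_range: float | None = None) -> float:
    """Structural similarity.

    mode="global": the single-statistics formula
        (2 μ_y μ_g + c1)(2 σ_yg + c2) / ((μ_y² + μ_g² + c1)(σ_y² + σ_g² + c2))
    with c1 = (0.01 L)², c2 = (0.03 L)², L = data range over both images.
    mode="windowed": 11×11 Gaussian-weighted mean SSIM (scikit-image).
    """
    y, g = _check_pair(y, g)
    L = float(data_range) if data_range is not None else \
        float(max(y.max(), g.max()) - min(y.min(), g.min()))
    if L == 0.0:
        L = 1.0  # pair of equal constants; SSIM is 1 regardless of L
    if mode == "windowed":
        return float(_skimage_ssim(y, g, data_range=L, gaussian_weights=True,
                                   sigma=1.5, use_sample_covariance=False))
    if mode != "global":
        raise ValueError(f"unknown SSIM mode {mode!r}")
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    mu_y, mu_g = y.mean(), g.mean()
    var_y = y.var()
    var_g = g.var()
    cov = ((y - mu_y) * (g - mu_g)).mean()
    return float((2 * mu_y * mu_g + c1) * (2 * cov + c2)
                 / ((mu_y ** 2 + mu_g ** 2 + c1) * (var_y + var_g + c2)))


def evaluate_pair(y, g, psnr_mode: str = "peak",
                  ssim_mode: str = "global") -> MetricsRecord:
    y, g = _check_pair(y, g)
    return MetricsRecord(mse=mse(y, g), psnr=psnr(y, g, mode=psnr_mode),
                         ssim=ssim(y, g, mode=ssim_mode), n=int(y.size))


def evaluate_volumes(truth, pred, psnr_mode: str = "peak",
                     ssim_mode: str = "global") -> MetricsRecord:
    """Slice-by-slice metrics on a volume pair, averaged over slices.

    Slices where both images are identically zero background contribute
    MSE 0 / SSIM 1 and are excluded from the PSNR average (their PSNR is
    infinite).
    """
    y = np.asarray(getattr(truth, "data", truth), dtype=np.float64)
    g = np.asarray(getattr(pred, "data", pred), dtype=np.float64)
    if y.shape != g.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {g.shape}")
    mses, psnrs, ssims = [], [], []
    for k in range(y.shape[0]):
        mses.append(mse(y[k], g[k]))
        p = psnr(y[k], g[k], mode=psnr_mode)
        if math.isfinite(p):
            psnrs.append(p)
        ssims.append(ssim(y[k], g[k], mode=ssim_mode))
    return MetricsRecord(
        mse=float(np.mean(mses)),
        psnr=float(np.mean(psnrs)) if psnrs else float("inf"),
        ssim=float(np.mean(ssims)),
        n=int(y.size))
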