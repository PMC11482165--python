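"""Evaluation stack for decorrelation-map predictions.

PSNR here is not the textbook variant: both label and prediction are
first min-max normalized *independently* to the 8-bit grayscale range
[0, 255], and the MSE of those normalized images enters

    PSNR = 10 · log10(255² / MSE_normalized),

which makes the score invariant to positive-affine rescaling of either
argument — deliberate, since decorrelation magnitudes vary with N and
with the arbitrary intensity scale.  SSIM uses the standard form with
k1 = 0.01, k2 = 0.03, L = 255 under an 11×11 Gaussian window.

Evaluation is restricted to the high-signal band from the detected
tissue surface down to 150 px (~750 µm at 5 µm pitch); deeper rows are
noise-dominated.  En-face maximum-intensity projections over depth
bands relative to the surface render the vascular network for visual
and squared-error comparison.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import DecorrelationMap, DegenerateInputError, ValidationError

__all__ = [
    "SSIMParams",
    "MetricsReport",
    "SurfaceDetectionError",
    "normalize_to_gray",
    "psnr",
    "ssim",
    "detect_surface",
    "crop_roi",
    "enface_mip",
    "squared_error_map",
    "evaluate_methods",
]


class SurfaceDetectionError(RuntimeError):
    """No tissue surface found in the B-scan."""


@dataclass(frozen=True)
class SSIMParams:
    """Constants of the structural-similarity index.

    c1 = (k1·L)², c2 = (k2·L)²; the local statistics are taken under a
    Gaussian window of ``window_size`` × ``window_size`` pixels with
    standard deviation ``window_sigma`` (1.5, the conventional choice —
    the window size is the stated 11 × 11).
    """

    k1: float = 0.01
    k2: float = 0.03
    L: int = 255
    window_size: int = 11
    window_sigma: float = 1.5

    @property
    def c1(self) -> float:
        return (self.k1 * self.L) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.L) ** 2


def normalize_to_gray(image: np.ndarray) -> np.ndarray:
    """Min-max scale an image to [0, 255]; invariant to positive-affine maps."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        raise DegenerateInputError("constant image cannot be normalized to grayscale")
    return (image - lo) / (hi - lo) * 255.0


def psnr(label: DecorrelationMap | np.ndarray, prediction: DecorrelationMap | np.ndarray) -> float:
    """Peak SNR in dB on independently grayscale-normalized images.

    Returns ``inf`` when the normalized images coincide (e.g. the
    prediction is a positive-affine transform of the label).
    """
    a = label.values if isinstance(label, DecorrelationMap) else np.asarray(label)
    b = prediction.values if isinstance(prediction, DecorrelationMap) else np.asarray(prediction)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((normalize_to_gray(a) - normalize_to_gray(b)) ** 2))
    # identical-after-normalization inputs (e.g. exact affine relatives) leave
    # only float rounding dust; flag them as infinite rather than ~300 dB
    if mse <= 1e-18 * 255.0**2:
        return np.inf
    return 10.0 * np.log10(255.0**2 / mse)


def _gaussian_window_filter(img: np.ndarray, p: SSIMParams) -> np.ndarray:
    # truncate so the kernel footprint is exactly window_size x window_size
    radius = (p.window_size - 1) // 2
    truncate = radius / p.window_sigma
    return ndimage.gaussian_filter(img, p.window_sigma, truncate=truncate, mode="nearest")

def ssim(label: np.ndarray, prediction: np.ndarray, params: SSIMParams | None = None) -> float:
    """Mean structural similarity of two images on the [0, 255] scale.

    Local means, variances and covariance are computed under the Gaussian
    window; the per-window index

        (2·μx·μy + c1)(2·σxy + c2) / ((μx² + μy² + c1)(σx² + σy² + c2))

    is averaged over all windows fully inside the image.  Symmetric in
    its arguments; equals 1 iff the images are identical.
    """
    params = params or SSIMParams()
    x = np.asarray(label, dtype=np.float64)
    y = np.asarray(prediction, dtype=np.float64)
    if x.shape != y.shape:
        raise ValidationError(f"shape mismatch: {x.shape} vs {y.shape}")
    f = lambda im: _gaussian_window_filter(im, params)
    mx, my = f(x), f(y)
    # Gaussian-weighted (population) second moments
    vx = f(x * x) - mx * mx
    vy = f(y * y) - my * my
    cxy = f(x * y) - mx * my
    c1, c2 = params.c1, params.c2
    s = ((2 * mx * my + c1) * (2 * cxy + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    pad = (params.window_size - 1) // 2
    if s.shape[0] > 2 * pad and s.shape[1] > 2 * pad:
        s = s[pad:-pad, pad:-pad]
    return float(s.mean())


def detect_surface(bscan: np.ndarray, threshold_frac: float = 0.3, smooth_px: float = 2.0) -> int:
    """Depth index of the tissue surface in a B-scan.

    The per-row mean intensity is smoothed along depth; the surface is
    the first row exceeding ``threshold_frac`` of the smoothed maximum.
    """
    profile = np.asarray(bscan, dtype=np.float64).mean(axis=1)
    smoothed = ndimage.gaussian_filter1d(profile, smooth_px)
    thr = threshold_frac * smoothed.max()
    above = np.nonzero(smoothed > thr)[0]
    if above.size == 0 or smoothed.max() <= 0:
        raise SurfaceDetectionError("no row exceeds the surface threshold")
    # require genuine contrast between tissue and the region above it
    if smoothed.min() > 0 and smoothed.max() / smoothed.min() < 1.5:
        raise SurfaceDetectionError("no tissue band: depth profile is nearly flat")
    return int(above[0])


def crop_roi(dmap: DecorrelationMap, surface: int, depth_px: int = 150) -> DecorrelationMap:
    """Restrict a map to rows [surface, surface + depth_px).

    Out-of-bounds crops are clamped to the image with a warning; a crop
    of zero depth is an error.
    """
    if depth_px < 1:
        raise ValidationError("depth_px must be >= 1")
    h = dmap.values.shape[0]
    z0 = max(0, min(surface, h - 1))
    z1 = min(surface + depth_px, h)
    if z0 != surface or z1 != surface + depth_px:
        warnings.warn(
            f"ROI [{surface}, {surface + depth_px}) clamped to [{z0}, {z1}) for depth {h}",
            stacklevel=2,
        )
    return dataclasses.replace(dmap, values=dmap.values[z0:z1].copy())


def enface_mip(
    maps: list[DecorrelationMap],
    z_from: int,
    z_to: int,
    surface: int = 0,
) -> np.ndarray:
    """En-face maximum-intensity projection over a depth band.

    Rows ``[surface + z_from, surface + z_to]`` (inclusive) of each
    slow-axis map contribute; the result is the (n_y × W) X-Y image of
    per-column maxima — the standard rendering of the vascular network.
    """
    if z_to < z_from:
        raise ValidationError("z_to must be >= z_from")
    h = maps[0].values.shape[0]
    z0, z1 = surface + z_from, surface + z_to + 1
    if z0 < 0 or z1 > h or z0 >= z1:
        raise ValidationError(f"depth band [{z0}, {z1}) outside image of depth {h}")
    return np.stack([m.values[z0:z1].max(axis=0) for m in maps])


def squared_error_map(label_mip: np.ndarray, prediction_mip: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-pixel (label − prediction)² and its mean."""
    a = np.asarray(label_mip, dtype=np.float64)
    b = np.asarray(prediction_mip, dtype=np.float64)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    se = (a - b) ** 2
    return se, float(se.mean())


@dataclass
class MetricsReport:
    """Per-location and aggregate scores for a set of methods."""

    rows: list[dict] = field(default_factory=list)
    mip_mse: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def aggregates(self) -> pd.DataFrame:
        df = self.to_dataframe()
        finite = df.replace(np.inf, np.nan)
        return (
            finite.groupby(["method", "n"])[["psnr_db", "ssim"]]
            .mean()
            .reset_index()
            .rename(columns={"psnr_db": "mean_psnr_db", "ssim": "mean_ssim"})
        )

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        agg = self.aggregates()
        agg.insert(2, "y_index", "mean")
        agg = agg.rename(columns={"mean_psnr_db": "psnr_db", "mean_ssim": "ssim"})
        pd.concat([df, agg], ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def evaluate_methods(
    labels: list[DecorrelationMap],
    methods: dict[str, list[DecorrelationMap]],
    surface: int,
    roi_depth_px: int = 150,
    mip_bands: list[tuple[int, int]] | None = None,
    ssim_params: SSIMParams | None = None,
) -> MetricsReport:
    """Score each method's maps against the 10-frame labels.

    Per slow-axis location: PSNR and SSIM inside the cropped ROI.  Per
    method and depth band: MSE between grayscale-normalized en-face MIP
    images.  Method keys are free-form tags such as ``sd_4`` or
    ``unet_se_2``.
    """
    report = MetricsReport()
    ssim_params = ssim_params or SSIMParams()
    lab_roi = [crop_roi(m, surface, roi_depth_px) for m in labels]
    for tag, maps in methods.items():
        if len(maps) != len(labels):
            raise ValidationError(f"method {tag!r}: {len(maps)} maps for {len(labels)} labels")
        n_used = maps[0].n_used
        for lab, pred in zip(lab_roi, maps):
            pred_roi = crop_roi(pred, surface, roi_depth_px)
            try:
                row_psnr = psnr(lab, pred_roi)
                row_ssim = ssim(
                    normalize_to_gray(lab.values),
                    normalize_to_gray(pred_roi.values),
                    ssim_params,
                )
            except DegenerateInputError:
                # a constant map (e.g. an untrained predictor clipped at zero)
                # carries no structure to score
                row_psnr = row_ssim = np.nan
            report.rows.append(
                {
                    "method": tag,
                    "n": n_used,
                    "y_index": lab.y_index,
                    "psnr_db": row_psnr,
                    "ssim": row_ssim,
                }
            )
        for z_from, z_to in mip_bands or []:
            try:
                lab_mip = normalize_to_gray(enface_mip(labels, z_from, z_to, surface)) / 255.0
                pred_mip = normalize_to_gray(enface_mip(maps, z_from, z_to, surface)) / 255.0
                _, mse = squared_error_map(lab_mip, pred_mip)
            except DegenerateInputError:
                mse = np.nan
            report.mip_mse.append(
                {"method": tag, "n": n_used, "band": f"{z_from}:{z_to}", "mip_mse": mse}
            )
    return report
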