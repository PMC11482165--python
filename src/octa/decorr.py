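"""Sliding-window L1-norm speckle decorrelation.

The conventional OCTA baseline: at every pixel the absolute intensity
difference between sequentially acquired B-scans is averaged over the
N − 1 adjacent pairs, then spatially averaged over a small (x × z)
window (6 × 6 by default).  The ground-truth *label* is the same
statistic computed from all 10 co-located B-scans — the best available
estimate of the true decorrelation, used as the regression target for
the networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import BScanBlock, DecorrelationMap

__all__ = [
    "DecorrParams",
    "ParameterError",
    "pairwise_l1",
    "windowed_decorrelation",
    "make_label",
    "box_average",
]

EDGE_POLICIES = ("reflect", "shrink-window", "crop")


class ParameterError(ValueError):
    """Invalid decorrelation parameters."""


@dataclass(frozen=True)
class DecorrParams:
    """Parameters of the windowed decorrelation baseline.

    ``window_x`` × ``window_z`` is the spatial averaging window in
    pixels (x × z); ``n_frames`` is the number N of B-scans consumed,
    meaningful in [2, 10] for 10-frame blocks.  ``edge_policy`` controls
    window behaviour at image borders: ``reflect`` (default; mirror
    padding, same-size output), ``shrink-window`` (average only the
    in-bounds part of the window), or ``crop`` (valid region only).
    """

    window_x: int = 6
    window_z: int = 6
    n_frames: int = 2
    edge_policy: str = "reflect"

    def __post_init__(self) -> None:
        if self.window_x < 1 or self.window_z < 1:
            raise ParameterError("window dimensions must be >= 1")
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.edge_policy not in EDGE_POLICIES:
            raise ParameterError(
                f"edge_policy {self.edge_policy!r} not in {EDGE_POLICIES}"
            )


def pairwise_l1(block: BScanBlock, n_frames: int) -> DecorrelationMap:
    """Mean absolute intensity difference over adjacent frame pairs.

    D(z, x) = (1/(N−1)) · Σ_{t=1}^{N−1} |I_t − I_{t+1}| using the first
    ``n_frames`` frames; no spatial averaging.
    """
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    if n_frames > block.n_frames:
        raise ParameterError(
            f"n_frames={n_frames} exceeds block size N={block.n_frames}"
        )
    frames = block.frames[:n_frames]
    d = np.abs(np.diff(frames, axis=0)).mean(axis=0)
    return DecorrelationMap(values=d, y_index=block.y_index, source="sd", n_used=n_frames)


def box_average(img: np.ndarray, window_z: int, window_x: int, edge_policy: str = "reflect") -> np.ndarray:
    """Uniform box filter with the package's window-anchoring convention.

    For even window sizes there is no centre pixel; output pixel (z, x)
    averages rows z − wz//2 + 1 … z + wz//2 and columns likewise (for
    6 × 6: z−2 … z+3).  ``reflect`` mirrors the image at the border,
    ``shrink-window`` renormalizes by the in-bounds window area, and
    ``crop`` returns only pixels whose window lies fully inside.
    """
    wz, wx = int(window_z), int(window_x)
    if wz > img.shape[0] or wx > img.shape[1]:
        raise ParameterError(
            f"window ({wz}x{wx}) larger than image {img.shape}"
        )
    # scipy's origin-0 window for even size w spans [i - w//2 + 1, i + w//2]
    # measured at the output; origin -1 shifts it to [i - w//2 + 1, i + w//2]
    # in input coordinates, i.e. rows z-2..z+3 for w = 6.
    origin = (-(1 - wz % 2), -(1 - wx % 2))
    if edge_policy == "reflect":
        return ndimage.uniform_filter(img, size=(wz, wx), mode="reflect", origin=origin)
    if edge_policy == "shrink-window":
        num = ndimage.uniform_filter(img, size=(wz, wx), mode="constant", cval=0.0, origin=origin)
        den = ndimage.uniform_filter(
            np.ones_like(img), size=(wz, wx), mode="constant", cval=0.0, origin=origin
        )
        return num / den
    if edge_policy == "crop":
        full = ndimage.uniform_filter(img, size=(wz, wx), mode="constant", cval=0.0, origin=origin)
        z0, x0 = wz // 2 - (1 - wz % 2), wx // 2 - (1 - wx % 2)
        return full[z0 : img.shape[0] - (wz - 1 - z0), x0 : img.shape[1] - (wx - 1 - x0)]
    raise ParameterError(f"unknown edge policy {edge_policy!r}")


def windowed_decorrelation(block: BScanBlock, params: DecorrParams) -> DecorrelationMap:
    """The sliding-window speckle-decorrelation baseline.

    Equals :func:`pairwise_l1` followed by a uniform spatial average over
    the ``window_x`` × ``window_z`` window.  The statistic is positively
    homogeneous: scaling all intensities by k scales the map by k.
    """
    if params.n_frames > block.n_frames:
        raise ParameterError(
            f"n_frames={params.n_frames} exceeds block size N={block.n_frames}"
        )
    raw = pairwise_l1(block, params.n_frames)
    smoothed = box_average(raw.values, params.window_z, params.window_x, params.edge_policy)
    # reflect averaging of non-negative values can produce tiny negative fp dust
    smoothed = np.maximum(smoothed, 0.0)
    return DecorrelationMap(
        values=smoothed, y_index=block.y_index, source="sd", n_used=params.n_frames
    )


def make_label(block: BScanBlock, params: DecorrParams | None = None) -> DecorrelationMap:
    """Ground-truth decorrelation label from all 10 co-located B-scans.

    Identical to :func:`windowed_decorrelation` with ``n_frames = 10``;
    the label uses the same spatial window as the baseline.
    """
    if block.n_frames < 10:
        raise ParameterError(
            f"label requires >= 10 frames, block has {block.n_frames}"
        )
    if params is None:
        params = DecorrParams(n_frames=10)
    else:
        params = DecorrParams(
            window_x=params.window_x,
            window_z=params.window_z,
            n_frames=10,
            edge_policy=params.edge_policy,
        )
    out = windowed_decorrelation(block, params)
    out.source = "label10"
    return out
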