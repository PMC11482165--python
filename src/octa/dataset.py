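"""Instance-label pair construction for network training.

Each training sample pairs an N-channel stack of co-located, normalized
B-scan patches (the *instance*) with the 10-frame decorrelation label
cut from the same spatial coordinates.  Two overlapping patches are
taken per B-scan block along the fast axis; splits are assigned per
volume so no acquisition leaks across train/validation/test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import BScanBlock, DecorrelationMap, OCTVolume, ValidationError, normalize_intensity
from .decorr import DecorrParams, ParameterError, make_label

__all__ = ["PatchSpec", "TrainingPair", "LearningSet", "extract_patches", "build_learning_set"]

ROLES = ("train", "val", "test")


@dataclass(frozen=True)
class PatchSpec:
    """Patch geometry: size, fast-axis overlap and depth window.

    Defaults follow the full-scale recipe (512 × 512 patches with a
    160 px x-overlap); tests and the desk-scale pipeline use smaller
    values.  With ``full_cover`` the second patch is placed at
    ``W − patch_w`` (full fast-axis coverage) instead of honouring the
    stated overlap.
    """

    patch_h: int = 512
    patch_w: int = 512
    overlap_x: int = 160
    z_offset: int = 0
    full_cover: bool = False

    def __post_init__(self) -> None:
        if self.patch_h < 1 or self.patch_w < 1:
            raise ParameterError("patch dimensions must be positive")
        if not (0 <= self.overlap_x < self.patch_w):
            raise ParameterError("overlap_x must satisfy 0 <= overlap_x < patch_w")
        if self.z_offset < 0:
            raise ParameterError("z_offset must be non-negative")

    def x_offsets(self, width: int) -> list[int]:
        if self.patch_w > width:
            raise ParameterError(f"patch_w={self.patch_w} exceeds image width {width}")
        if self.patch_w == width:
            return [0]  # degenerate: one patch spans the full fast axis
        if self.full_cover:
            second = width - self.patch_w
        else:
            second = self.patch_w - self.overlap_x
        if second + self.patch_w > width:
            raise ParameterError(
                f"second patch at x={second} exceeds image width {width}"
            )
        return [0, second] if second != 0 else [0]


@dataclass
class TrainingPair:
    """(N-channel instance patch, 1-channel label patch) plus provenance."""

    instance: np.ndarray  # (n_channels, patch_h, patch_w), in [0, 1]
    label: np.ndarray  # (patch_h, patch_w), >= 0
    y_index: int
    patch_index: int
    volume_id: str = ""
    role: str = "train"

    def __post_init__(self) -> None:
        if self.instance.ndim != 3 or self.label.ndim != 2:
            raise ValidationError("instance must be (N, h, w) and label (h, w)")
        if self.instance.shape[1:] != self.label.shape:
            raise ValidationError("instance and label patch shapes differ")


@dataclass
class LearningSet:
    """Per-split pair collections with split-exclusivity bookkeeping."""

    train: list[TrainingPair] = field(default_factory=list)
    val: list[TrainingPair] = field(default_factory=list)
    test: list[TrainingPair] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {"train": len(self.train), "val": len(self.val), "test": len(self.test)}

    def check_exclusive(self) -> None:
        seen: dict[str, str] = {}
        for role in ROLES:
            for p in getattr(self, role):
                if seen.setdefault(p.volume_id, role) != role:
                    raise ValidationError(
                        f"volume {p.volume_id!r} appears in both "
                        f"{seen[p.volume_id]!r} and {role!r}"
                    )


def extract_patches(
    block: BScanBlock,
    label: DecorrelationMap,
    spec: PatchSpec,
    n_channels: int,
) -> list[TrainingPair]:
    """Cut the two overlapped patches from a normalized block and its label.

    The instance takes the first ``n_channels`` frames of the block; the
    label is cut at identical coordinates.  Both patches share the depth
    window ``[z_offset, z_offset + patch_h)`` and are treated as
    independent samples downstream.
    """
    if n_channels < 1 or n_channels > block.n_frames:
        raise ParameterError(f"n_channels={n_channels} outside [1, {block.n_frames}]")
    h, w = block.shape
    if label.values.shape != (h, w):
        raise ValidationError("label shape does not match block frames")
    if spec.z_offset + spec.patch_h > h:
        raise ParameterError(
            f"patch rows [{spec.z_offset}, {spec.z_offset + spec.patch_h}) exceed depth {h}"
        )
    z0, z1 = spec.z_offset, spec.z_offset + spec.patch_h
    pairs = []
    for i, x0 in enumerate(spec.x_offsets(w)):
        pairs.append(
            TrainingPair(
                instance=block.frames[:n_channels, z0:z1, x0 : x0 + spec.patch_w].copy(),
                label=label.values[z0:z1, x0 : x0 + spec.patch_w].copy(),
                y_index=block.y_index,
                patch_index=i,
            )
        )
    return pairs


def build_learning_set(
    volumes: list[tuple[OCTVolume, str]],
    spec: PatchSpec,
    n_channels: int,
    decorr_params: DecorrParams | None = None,
    volume_ids: list[str] | None = None,
) -> LearningSet:
    """Build train/val/test pairs from role-tagged volumes.

    Labels are the 10-frame windowed decorrelation per block, min-max
    normalized jointly over each volume (one affine map per volume, so
    relative decorrelation contrast between locations is preserved);
    instances are block-normalized intensities.  A volume contributes to
    exactly one split.
    """
    out = LearningSet()
    for k, (vol, role) in enumerate(volumes):
        if role not in ROLES:
            raise ValidationError(f"unknown role {role!r}")
        if vol.n_frames < 10:
            raise ValidationError(
                f"volume {k} has N={vol.n_frames} < 10 frames; cannot build labels"
            )
        vid = volume_ids[k] if volume_ids else f"vol{k}"
        labels = [make_label(b, decorr_params) for b in vol.blocks]
        lo = min(float(l.values.min()) for l in labels)
        hi = max(float(l.values.max()) for l in labels)
        scale = hi - lo if hi > lo else 1.0
        for block, label in zip(vol.blocks, labels):
            norm_label = DecorrelationMap(
                values=(label.values - lo) / scale,
                y_index=label.y_index,
                source="label10",
                n_used=10,
            )
            for p in extract_patches(normalize_intensity(block), norm_label, spec, n_channels):
                p.volume_id = vid
                p.role = role
                getattr(out, role).append(p)
    out.check_exclusive()
    return out
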