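"""Depth-cued maximum intensity projections and multimodal mask fusion.

The depth-cued MIP encodes tissue depth as hue: the volume is reduced to a
stack of grouped MIPs (default: maxima over consecutive 5-slice segments),
the stack is duplicated per color channel, each channel's slices are scaled
by a linear depth ramp — red from 75% (first slice) to 100% (last slice),
green from 0% to 75% — and a final per-channel MIP merges the stack into one
RGB image.  Vessels near the viewer render red; deep vessels trend yellow.

Mask fusion overlays co-registered binary masks from different modalities in
separate color channels (overlap renders additively, e.g. red+green→yellow),
the standard visual QC for multiscale co-registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import BinaryMask, ImageVolume, same_geometry

__all__ = [
    "RGBProjection",
    "grouped_mip",
    "depth_cue_weights",
    "depth_cued_projection",
    "fuse_masks",
    "save_png",
]


@dataclass
class RGBProjection:
    """2D RGB image in [0, 1] with rendering provenance."""

    image: np.ndarray                      # (H, W, 3)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("RGBProjection image must be (H, W, 3)")
        self.image = np.clip(self.image, 0.0, 1.0)


def grouped_mip(vol: ImageVolume, group_size: int = 5, axis: int = 2) -> ImageVolume:
    """Stack of maximum intensity projections over consecutive slice groups.

    Output slice k along ``axis`` is the voxelwise max over input slices
    ``[k*g, (k+1)*g)``; a trailing partial group is max'd as-is (kept, not
    dropped).
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    data = np.moveaxis(vol.voxels, axis, 0)
    n = data.shape[0]
    n_groups = int(np.ceil(n / group_size))
    groups = [
        data[k * group_size : (k + 1) * group_size].max(axis=0) for k in range(n_groups)
    ]
    out = np.moveaxis(np.stack(groups, axis=0), 0, axis)
    spacing = list(vol.spacing)
    spacing[axis] *= group_size
    return ImageVolume(out, tuple(spacing), vol.origin)


def depth_cue_weights(n_slices: int, start_frac: float, end_frac: float) -> np.ndarray:
    """Linear depth ramp ``w_k = start + (end-start) * k/(n-1)``.

    A single slice degenerates to the end value.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    for f in (start_frac, end_frac):
        if not 0.0 <= f <= 1.0:
            raise ValueError("ramp fractions must be in [0, 1]")
    if n_slices == 1:
        return np.array([end_frac])
    k = np.arange(n_slices)
    return start_frac + (end_frac - start_frac) * k / (n_slices - 1)


def depth_cued_projection(
    vol: ImageVolume,
    group_size: int = 5,
    red_ramp: tuple[float, float] = (0.75, 1.0),
    green_ramp: tuple[float, float] = (0.0, 0.75),
    blue_ramp: tuple[float, float] = (0.0, 0.0),
    axis: int = 2,
    normalize: bool = True,
) -> RGBProjection:
    """Depth-cued MIP: grouped MIP stack → per-channel depth ramps → MIP.

    With the default ramps a bright structure in the first slice group
    renders with red:green ≈ 0.75:0 and one in the last group ≈ 1.0:0.75,
    so hue encodes depth along the viewing direction.  ``normalize`` divides
    by the global max so the output uses the full display range.
    """
    stack = grouped_mip(vol, group_size=group_size, axis=axis)
    data = np.moveaxis(stack.voxels, axis, 0).astype(float)  # (n_groups, H, W)
    n = data.shape[0]
    channels = []
    for ramp in (red_ramp, green_ramp, blue_ramp):
        w = depth_cue_weights(n, *ramp)
        channels.append((data * w[:, None, None]).max(axis=0))
    rgb = np.stack(channels, axis=-1)
    peak = rgb.max()
    if normalize and peak > 0:
        rgb = rgb / peak
    return RGBProjection(
        np.clip(rgb, 0.0, 1.0),
        provenance={
            "operation": "depth_cued_projection",
            "group_size": group_size,
            "axis": axis,
            "red_ramp": tuple(red_ramp),
            "green_ramp": tuple(green_ramp),
            "blue_ramp": tuple(blue_ramp),
            "normalized": bool(normalize),
        },
    )


def fuse_masks(
    masks: dict[str, BinaryMask],
    axis: int = 2,
    mode: str = "mip",
    slice_index: int | None = None,
) -> RGBProjection:
    """Fuse co-registered binary masks into an RGB overlay.

    ``masks`` assigns channels by key (``red``/``green``/``blue``) — e.g.
    red = HREM vessels, green = MRI, blue = CT.  All masks must share the
    reference grid geometry.  ``mode='mip'`` projects along ``axis``;
    ``mode='slice'`` renders the given slice.  Overlap is additive per
    channel (red+green → yellow).
    """
    order = ("red", "green", "blue")
    unknown = set(masks) - set(order)
    if unknown:
        raise ValueError(f"unknown channel keys: {sorted(unknown)}")
    ref = next(iter(masks.values()))
    for m in masks.values():
        if not same_geometry(ref, m):
            raise ValueError("masks must share geometry; resample to the reference first")
    channels = []
    for name in order:
        if name in masks:
            data = masks[name].voxels.astype(float)
            if mode == "mip":
                channels.append(np.moveaxis(data, axis, 0).max(axis=0))
            elif mode == "slice":
                if slice_index is None:
                    raise ValueError("mode='slice' requires slice_index")
                channels.append(np.moveaxis(data, axis, 0)[slice_index])
            else:
                raise ValueError(f"unknown mode {mode!r}")
        else:
            shape = np.moveaxis(ref.voxels, axis, 0).shape[1:]
            channels.append(np.zeros(shape))
    return RGBProjection(
        np.stack(channels, axis=-1),
        provenance={"operation": "fuse_masks", "channels": sorted(masks), "mode": mode},
    )


def save_png(projection: RGBProjection, path) -> None:
    """Write an RGB projection as an 8-bit PNG."""
    import imageio.v3 as iio

    img8 = np.floor(projection.image * 255.0 + 0.5).astype(np.uint8)
    iio.imwrite(str(path), img8)
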