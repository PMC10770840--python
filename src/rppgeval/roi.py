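"""Facial region-of-interest handling for frame stacks.

Landmark-based face meshes index facial locations with integer labels; the
forehead and cheek index lists used to build the skin ROI are shipped here
as constants. Landmark *coordinates* (and hence face detection) are outside
this package's scope: callers provide either a boolean pixel mask or
polygon vertices per region, and the three regions are pooled into a single
union before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .traces import RGBTrace

#: Face-mesh landmark indices of the three skin regions used for the ROI.
FOREHEAD_LANDMARKS = (107, 66, 69, 109, 10, 338, 299, 296, 336, 9)
LEFT_CHEEK_LANDMARKS = (118, 119, 100, 126, 209, 49, 129, 203, 205, 50)
RIGHT_CHEEK_LANDMARKS = (347, 348, 329, 355, 429, 279, 358, 423, 425, 280)

ROI_LANDMARKS = {
    "forehead": FOREHEAD_LANDMARKS,
    "left_cheek": LEFT_CHEEK_LANDMARKS,
    "right_cheek": RIGHT_CHEEK_LANDMARKS,
}


def polygon_to_mask(vertices: np.ndarray, frame_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize polygon vertices ``(row, col)`` to a boolean pixel mask."""
    from matplotlib.path import Path as MplPath  # local import; optional extra

    vertices = np.asarray(vertices, dtype=float)
    rr, cc = np.meshgrid(np.arange(frame_shape[0]), np.arange(frame_shape[1]),
                         indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    mask = MplPath(vertices).contains_points(pts).reshape(frame_shape)
    if not mask.any():
        raise DataError("polygon rasterizes to an empty ROI")
    return mask


@dataclass
class ROIMask:
    """Named skin regions resolved to boolean pixel masks.

    ``regions`` maps region name to a 2-D boolean array; all regions must
    share one frame shape and are pooled into a single union mask.
    """

    regions: dict = field(default_factory=dict)
    landmark_indices: dict = field(default_factory=lambda: dict(ROI_LANDMARKS))

    def __post_init__(self) -> None:
        if not self.regions:
            raise DataError("ROIMask needs at least one region")
        shapes = {np.asarray(m).shape for m in self.regions.values()}
        if len(shapes) != 1:
            raise DataError("all ROI regions must share one frame shape")
        for name, m in self.regions.items():
            if not np.asarray(m, dtype=bool).any():
                raise DataError(f"ROI region {name!r} is empty")

    @classmethod
    def from_mask(cls, mask: np.ndarray, name: str = "roi") -> "ROIMask":
        return cls(regions={name: np.asarray(mask, dtype=bool)})

    def union(self) -> np.ndarray:
        masks = [np.asarray(m, dtype=bool) for m in self.regions.values()]
        out = masks[0].copy()
        for m in masks[1:]:
            out |= m
        return out


def roi_mean_trace(frames: np.ndarray, mask: ROIMask | np.ndarray,
                   fps: float) -> RGBTrace:
    """Average the ROI pixels of each frame per color channel.

    ``frames`` has shape ``(n_frames, H, W, 3)``. The three regions are
    pooled into their union and a single mean per channel per frame is
    taken, giving one R, G, B value per frame.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise DataError("frames must have shape (n_frames, H, W, 3)")
    union = mask.union() if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    if union.shape != frames.shape[1:3]:
        raise DataError("frame/mask shape mismatch")
    if not union.any():
        raise DataError("empty ROI: mask covers no pixels")
    means = frames[:, union, :].mean(axis=1)  # (n_frames, 3)
    return RGBTrace(red=means[:, 0], green=means[:, 1], blue=means[:, 2], fs=fps)
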