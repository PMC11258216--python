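"""Refinement of slicewise manual tumor annotations into smooth 3-D masks.

Tumors are outlined slice by slice in one view (axial or coronal), so the
stacked binary mask is smooth in the annotation plane but zigzags in the
orthogonal views.  Refinement treats the mask as a real-valued indicator
field, convolves it with an anisotropic Gaussian whose through-plane sigma
is (by default) larger than the in-plane sigma, and re-binarizes at a
threshold.  The convolution implements a soft voting scheme: a voxel's
refined value aggregates weighted votes from its neighborhood, with the
larger through-plane sigma letting adjacent slices vote on uncertain
boundary voxels.  A threshold of 0.5 is majority voting.

No morphological operators are involved; the kernel is normalized to unit
sum and truncated at 3 sigma, so the refined mask is contained in the
dilation of the input by ceil(3 sigma) per axis.

Also provided: a per-plane boundary-roughness score (mean perimeter-to-area
ratio over slices) to quantify that refinement smooths non-annotation
views, and a rasterizer for LabelMe-style per-slice polygon annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon
from skimage.measure import perimeter as skimage_perimeter

from .spectral_core import PLANES, ConfigurationError

__all__ = [
    "MaskRefineParams",
    "refine_mask",
    "boundary_roughness",
    "rasterize_labelme",
]

_TRUNCATE = 3.0  # kernel support in sigmas


@dataclass(frozen=True)
class MaskRefineParams:
    """Anisotropic Gaussian voting parameters.

    ``sigma_inplane`` applies to the two annotation-plane axes,
    ``sigma_through`` to the axis across slices.  ``annotation_plane`` names
    the view the mask was drawn in (slices are stacked along that plane's
    fixed axis).  Sigmas are in voxels.
    """

    sigma_inplane: float = 1.0
    sigma_through: float = 2.0
    threshold: float = 0.5
    annotation_plane: str = "axial"

    def __post_init__(self):
        if self.sigma_inplane < 0 or self.sigma_through < 0:
            raise ConfigurationError("sigmas must be >= 0")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError("threshold must lie in (0, 1)")
        if self.annotation_plane not in PLANES:
            raise ConfigurationError(
                f"unknown annotation plane {self.annotation_plane!r}"
            )

    @property
    def sigmas_xyz(self) -> tuple[float, float, float]:
        through_axis = PLANES[self.annotation_plane]
        return tuple(
            self.sigma_through if ax == through_axis else self.sigma_inplane
            for ax in range(3)
        )


def refine_mask(raw: np.ndarray, p: MaskRefineParams) -> np.ndarray:
    """Smooth a binary mask by anisotropic Gaussian voting and re-threshold.

    A voxel is kept when the Gaussian-weighted fraction of mask voxels in
    its neighborhood reaches ``p.threshold`` (>=, so 0.5 is "at least half
    the votes").  With all sigmas zero the kernel is the identity and the
    input is returned unchanged.
    """
    raw = np.asarray(raw)
    if raw.ndim != 3:
        raise ValueError("expected a 3-D mask")
    raw = raw.astype(bool)
    if not raw.any():
        raise ValueError("raw mask is empty")
    field = gaussian_filter(
        raw.astype(np.float64), sigma=p.sigmas_xyz, truncate=_TRUNCATE, mode="constant"
    )
    return field >= p.threshold


def boundary_roughness(mask: np.ndarray, plane: str) -> float:
    """Mean per-slice perimeter-to-area ratio in the given view.

    Higher values mean more jagged slice boundaries (zigzag); empty slices
    are skipped.  Used to verify that refinement reduces roughness in the
    non-annotation views.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("expected a 3-D mask")
    if not mask.any():
        raise ValueError("mask is empty")
    axis = PLANES.get(plane)
    if axis is None:
        raise ConfigurationError(f"unknown plane {plane!r}")
    ratios = []
    for k in range(mask.shape[axis]):
        sl = np.take(mask, k, axis=axis)
        area = sl.sum()
        if area == 0:
            continue
        ratios.append(skimage_perimeter(sl, neighborhood=4) / area)
    return float(np.mean(ratios))


def rasterize_labelme(
    annotations: dict[int, dict],
    shape: tuple[int, int, int],
    plane: str = "axial",
) -> dict[str, np.ndarray]:
    """Rasterize per-slice polygon annotations onto a voxel grid.

    ``annotations`` maps a slice index (along the plane's fixed axis) to a
    LabelMe-style record ``{"shapes": [{"label": str, "points": [[u, w],
    ...], "shape_type": "polygon"}]}``.  Point coordinates (u, w) follow the
    array's two in-plane axes in storage order (e.g. (x, y) for an axial
    slice).  Returns one 3-D boolean mask per label.
    """
    axis = PLANES.get(plane)
    if axis is None:
        raise ConfigurationError(f"unknown plane {plane!r}")
    inplane = tuple(s for ax, s in enumerate(shape) if ax != axis)
    masks: dict[str, np.ndarray] = {}
    for index, record in annotations.items():
        if not 0 <= index < shape[axis]:
            raise IndexError(f"slice index {index} out of range for {plane}")
        for shp in record.get("shapes", []):
            if shp.get("shape_type", "polygon") != "polygon":
                continue
            pts = np.asarray(shp["points"], dtype=np.float64)
            if pts.ndim != 2 or pts.shape[0] < 3:
                raise ValueError("polygon needs at least 3 points")
            label = shp.get("label", "tumor")
            if label not in masks:
                masks[label] = np.zeros(shape, dtype=bool)
            uu, ww = draw_polygon(pts[:, 0], pts[:, 1], shape=inplane)
            sl = np.zeros(inplane, dtype=bool)
            sl[uu, ww] = True
            sel = [slice(None)] * 3
            sel[axis] = index
            masks[label][tuple(sel)] |= sl
    if not masks:
        raise ValueError("no polygon annotations found")
    return masks
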