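"""Domain types and I/O for spectral photon-counting micro-CT volumes.

A spectral (multi-energy-bin) micro-CT reconstruction is a 3-D grid of
linear attenuation coefficients (LAC, cm^-1) per energy bin.  Photon-counting
detectors sort photons into contiguous keV bins; the scanner protocol
emulated here counts photons in five bins, (7,20), (20,30), (30,47),
(47,73) and >73 keV, of which only the middle three are used for analysis:
the lowest bin is corrupted by fluorescence escape and the open top bin by
quantum noise.  Those three analysis channels (I1, I2, I3) are the input to
every downstream stage (colorization, ROI metrics, tumor features).

Conventions
-----------
* Arrays are indexed ``[x, y, z, bin]``, 0-based, with x the animal's
  left-right axis, y dorso-ventral and z the scanner (head-tail) axis.
* Stored data is kept in scanner order; the prone-mouse display convention
  (the animal's left shown on the image's right) is applied only when a 2-D
  slice is extracted for display, never to stored voxels.
* Attenuation is in cm^-1 throughout.  Negative values are legal: additive
  reconstruction noise undershoots zero and statistics must see it.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "ConfigurationError",
    "FormatError",
    "EnergyBinning",
    "SpectralVolume",
    "ROISet",
    "PLANES",
    "ORIENTATIONS",
    "read_spectral_volume",
    "write_spectral_volume",
    "read_mask",
    "write_mask",
    "extract_slice",
    "insert_slice",
    "usable_channels",
]


class ConfigurationError(ValueError):
    """Invalid configuration (bad binning, missing sidecar keys, ...)."""


class FormatError(ValueError):
    """On-disk data inconsistent with its sidecar or expected layout."""


#: planes mapped to the array axis that is held fixed
PLANES = {"axial": 2, "coronal": 1, "sagittal": 0}

#: supported display orientations
ORIENTATIONS = ("mouse_prone_display",)

SIDECAR_KEYS = ("edges_keV", "open_top", "usable", "voxel_size_um", "orientation")


@dataclass(frozen=True)
class EnergyBinning:
    """Energy-bin layout of a spectral acquisition.

    Parameters
    ----------
    edges_keV : tuple of float
        Ordered bin boundaries in keV.  With ``open_top=False`` the k-th bin
        is ``(edges[k], edges[k+1])`` and there are ``len(edges) - 1`` bins;
        with ``open_top=True`` a final unbounded bin ``(edges[-1], inf)`` is
        appended, so there are ``len(edges)`` bins.
    open_top : bool
        Whether the last bin is unbounded above.
    usable : tuple of bool
        Per-bin flag marking the analysis channels.  Exactly three bins must
        be usable for the three-channel color/statistics pipeline.
    """

    edges_keV: tuple[float, ...]
    open_top: bool = True
    usable: tuple[bool, ...] = ()

    def __post_init__(self):
        edges = tuple(float(e) for e in self.edges_keV)
        if len(edges) < 2:
            raise ConfigurationError("need at least two bin edges")
        if any(e <= 0 for e in edges):
            raise ConfigurationError("bin edges must be positive (keV)")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigurationError("bin edges must be strictly increasing")
        object.__setattr__(self, "edges_keV", edges)
        usable = tuple(bool(u) for u in self.usable)
        if not usable:
            usable = (True,) * self.n_bins
        if len(usable) != self.n_bins:
            raise ConfigurationError(
                f"usable has {len(usable)} entries for {self.n_bins} bins"
            )
        object.__setattr__(self, "usable", usable)

    @property
    def n_bins(self) -> int:
        return len(self.edges_keV) - 1 + int(self.open_top)

    @property
    def usable_indices(self) -> tuple[int, ...]:
        return tuple(i for i, u in enumerate(self.usable) if u)

    def bin_bounds(self, top_cap_keV: float | None = None) -> list[tuple[float, float]]:
        """(low, high) bounds per bin; the open top bin gets ``top_cap_keV``."""
        bounds = list(zip(self.edges_keV, self.edges_keV[1:]))
        if self.open_top:
            top = np.inf if top_cap_keV is None else float(top_cap_keV)
            if top <= self.edges_keV[-1]:
                raise ConfigurationError("top cap must exceed the last edge")
            bounds.append((self.edges_keV[-1], top))
        return bounds

    @classmethod
    def five_bin_protocol(cls) -> "EnergyBinning":
        """The five-bin photon-counting protocol with bins 2-4 usable.

        Bins (7,20), (20,30), (30,47), (47,73), >73 keV; channels I1..I3 are
        bins 2-4.  The outer bins are excluded (fluorescence escape below
        20 keV, high quantum noise above 73 keV).
        """
        return cls(
            edges_keV=(7.0, 20.0, 30.0, 47.0, 73.0),
            open_top=True,
            usable=(False, True, True, True, False),
        )

    def to_sidecar(self, voxel_size_um: float, orientation: str) -> dict:
        return {
            "edges_keV": list(self.edges_keV),
            "open_top": self.open_top,
            "usable": list(self.usable),
            "voxel_size_um": float(voxel_size_um),
            "orientation": orientation,
        }


@dataclass
class SpectralVolume:
    """A 4-D multi-energy attenuation volume with physical metadata.

    ``data`` is indexed ``[x, y, z, bin]`` and holds LAC values in cm^-1.
    """

    data: np.ndarray
    binning: EnergyBinning
    voxel_size_um: float = 90.0
    orientation: str = "mouse_prone_display"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise FormatError(f"expected 4-D [x,y,z,bin] data, got {self.data.ndim}-D")
        if self.data.shape[3] != self.binning.n_bins:
            raise FormatError(
                f"data has {self.data.shape[3]} bins, binning declares "
                f"{self.binning.n_bins}"
            )
        if min(self.data.shape[:3]) < 1:
            raise FormatError("all spatial dimensions must be >= 1")
        if not float(self.voxel_size_um) > 0:
            raise ConfigurationError("voxel_size_um must be positive")
        if self.orientation not in ORIENTATIONS:
            raise ConfigurationError(f"unknown orientation {self.orientation!r}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("attenuation values must be finite")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_bins(self) -> int:
        return self.data.shape[3]


@dataclass
class ROISet:
    """Named binary masks on the grid of a parent :class:`SpectralVolume`.

    ``labels`` maps each mask name to its role, ``"tumor"`` or
    ``"background_muscle"``.  CNR needs at least one background-muscle mask.
    """

    masks: dict[str, np.ndarray]
    labels: dict[str, str]
    geometry: tuple[int, int, int]

    ROLES = ("tumor", "background_muscle")

    def __post_init__(self):
        self.geometry = tuple(int(s) for s in self.geometry)
        for name, mask in self.masks.items():
            mask = np.asarray(mask).astype(bool)
            if mask.shape != self.geometry:
                raise FormatError(
                    f"mask {name!r} has shape {mask.shape}, grid is {self.geometry}"
                )
            self.masks[name] = mask
        for name, role in self.labels.items():
            if name not in self.masks:
                raise ConfigurationError(f"label for unknown mask {name!r}")
            if role not in self.ROLES:
                raise ConfigurationError(f"unknown ROI role {role!r}")

    def names_with_role(self, role: str) -> list[str]:
        return [n for n, r in self.labels.items() if r == role]

    @property
    def tumor_names(self) -> list[str]:
        return self.names_with_role("tumor")

    @property
    def background_names(self) -> list[str]:
        return self.names_with_role("background_muscle")


# ---------------------------------------------------------------------------
# NIfTI + sidecar I/O
# ---------------------------------------------------------------------------

def _affine(voxel_size_um: float) -> np.ndarray:
    mm = voxel_size_um / 1000.0
    return np.diag([mm, mm, mm, 1.0])


def write_spectral_volume(v: SpectralVolume, path, sidecar=None) -> None:
    """Write a volume as 4-D NIfTI-1 plus a JSON sidecar.

    The canonical layout is a single 4-D file with bin as the 4th dimension.
    ``sidecar`` defaults to ``path`` with a ``.json`` suffix.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    img = nib.Nifti1Image(v.data, _affine(v.voxel_size_um))
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))
    sidecar.write_text(
        json.dumps(v.binning.to_sidecar(v.voxel_size_um, v.orientation), indent=2)
    )


def _load_sidecar(sidecar) -> dict:
    sidecar = Path(sidecar)
    if not sidecar.exists():
        raise ConfigurationError(f"sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in SIDECAR_KEYS if k not in meta]
    if missing:
        raise ConfigurationError(f"sidecar missing keys: {missing}")
    return meta


def read_spectral_volume(path, sidecar) -> SpectralVolume:
    """Read a spectral volume from a 4-D NIfTI file or a per-bin directory.

    A directory must contain one 3-D NIfTI per bin, ordered by sorted file
    name (e.g. ``bin0.nii`` .. ``bin4.nii``).  The bin count is cross-checked
    against the sidecar's binning.
    """
    meta = _load_sidecar(sidecar)
    binning = EnergyBinning(
        edges_keV=tuple(meta["edges_keV"]),
        open_top=bool(meta["open_top"]),
        usable=tuple(meta["usable"]),
    )
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix in (".nii", ".gz") or ".nii" in p.suffixes
        )
        if not files:
            raise FormatError(f"no NIfTI files in directory {path}")
        arrs = []
        for f in files:
            a = np.asarray(nib.load(str(f)).dataobj, dtype=np.float64)
            if a.ndim != 3:
                raise FormatError(f"{f} is not a 3-D per-bin volume")
            arrs.append(a)
        data = np.stack(arrs, axis=-1)
    else:
        data = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
        if data.ndim != 4:
            raise FormatError(f"{path} is not a 4-D spectral volume")
    if data.shape[-1] != binning.n_bins:
        raise FormatError(
            f"data carries {data.shape[-1]} bins but sidecar declares "
            f"{binning.n_bins}"
        )
    return SpectralVolume(
        data=data,
        binning=binning,
        voxel_size_um=float(meta["voxel_size_um"]),
        orientation=str(meta["orientation"]),
    )


def write_mask(mask: np.ndarray, path, voxel_size_um: float = 90.0) -> None:
    mask = np.asarray(mask).astype(np.uint8)
    img = nib.Nifti1Image(mask, _affine(voxel_size_um))
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).dataobj)
    if arr.ndim != 3:
        raise FormatError(f"{path} is not a 3-D mask")
    return arr > 0


# ---------------------------------------------------------------------------
# Slice extraction (display convention applied here, not in storage)
# ---------------------------------------------------------------------------

def _check_plane(plane: str) -> int:
    if plane not in PLANES:
        raise ConfigurationError(f"unknown plane {plane!r}; use {sorted(PLANES)}")
    return PLANES[plane]


def extract_slice(v: SpectralVolume, plane: str, index: int) -> np.ndarray:
    """Extract a 2-D multi-bin slice with the prone-mouse display convention.

    The animal lies prone, so its left side appears on the right of axial and
    coronal images: the x (left-right) axis is mirrored at display time.
    Returned images are ``[row, col, bin]`` with

    * axial (fixed z): rows = y, cols = mirrored x
    * coronal (fixed y): rows = z, cols = mirrored x
    * sagittal (fixed x): rows = z, cols = y (no mirror)
    """
    axis = _check_plane(plane)
    n = v.data.shape[axis]
    if not 0 <= index < n:
        raise IndexError(f"{plane} index {index} out of range [0, {n})")
    if plane == "axial":
        sl = v.data[:, :, index, :]          # [x, y, bin]
        return np.transpose(sl[::-1], (1, 0, 2)).copy()
    if plane == "coronal":
        sl = v.data[:, index, :, :]          # [x, z, bin]
        return np.transpose(sl[::-1], (1, 0, 2)).copy()
    sl = v.data[index, :, :, :]              # [y, z, bin]
    return np.transpose(sl, (1, 0, 2)).copy()


def insert_slice(v: SpectralVolume, plane: str, index: int, image: np.ndarray) -> None:
    """Inverse of :func:`extract_slice`: write a display-convention slice back."""
    axis = _check_plane(plane)
    n = v.data.shape[axis]
    if not 0 <= index < n:
        raise IndexError(f"{plane} index {index} out of range [0, {n})")
    image = np.asarray(image, dtype=np.float64)
    if plane == "axial":
        v.data[:, :, index, :] = np.transpose(image, (1, 0, 2))[::-1]
    elif plane == "coronal":
        v.data[:, index, :, :] = np.transpose(image, (1, 0, 2))[::-1]
    else:
        v.data[index, :, :, :] = np.transpose(image, (1, 0, 2))


def usable_channels(v: SpectralVolume) -> np.ndarray:
    """Project onto the three analysis channels (I1, I2, I3).

    Pure selection in ascending energy order; no value is altered.  Raises
    :class:`ConfigurationError` unless exactly three bins are flagged usable.
    """
    idx = v.binning.usable_indices
    if len(idx) != 3:
        raise ConfigurationError(
            f"need exactly 3 usable bins for channel analysis, got {len(idx)}"
        )
    return v.data[..., list(idx)]
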