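"""K-edge-aware RGB color visualization of three-channel spectral images.

Each pixel of a three-channel spectral image is a vector y = (I1, I2, I3)
of bin attenuations.  Treated as a point in RGB space, the *direction* of y
fixes the displayed color tone while its length fixes the brightness, so a
concentration change of one material rescales the vector without changing
its tone — materials are identified by tone, not intensity.

The basic visualization assigns the channels directly, I_R = I1, I_G = I2,
I_B = I3.  Because the spectral attenuation curves of similar materials are
close, an invertible 3x3 channel transform C is applied to magnify the
spectral differences before display:

    (I_R, I_G, I_B) = C @ (I1, I2, I3).

Invertibility guarantees no information loss and keeps the tone coding
unique: two materials that differ in y still differ in C @ y.  The
``session23`` preset weights inter-channel differences as
I_R = 1.5 (I1 - I2), I_G = 2.5 (I2 - I3), I_B = 0.34 I3; the ``session1``
preset uses [1, 2, 0.3].  Weights are protocol-specific configuration data,
not constants of the method.

Rendering maps transformed values into the true-color [0, 1] display
window: negatives are clamped to zero (a negative channel difference has no
display meaning; the raw transformed values remain available pre-render),
then a multiplicative brightness constant is applied — fixed, or chosen
automatically so a percentile of the positive values maps to 1 — and the
result is clipped.  The constant used is recorded in provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .spectral_core import ConfigurationError

__all__ = [
    "ChannelTransform",
    "RGBImage",
    "TRANSFORM_PRESETS",
    "DegenerateScaleError",
    "rgb_basic",
    "rgb_transform",
    "render",
    "tone",
    "tone_angle_deg",
    "tone_uniqueness_check",
    "ToneReport",
    "save_png",
]


class DegenerateScaleError(ValueError):
    """Automatic brightness cannot be derived (no positive values)."""


#: published weight presets; rows are (R, G, B) mixing weights over (I1, I2, I3)
TRANSFORM_PRESETS: dict[str, list[list[float]]] = {
    "identity": [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
    "session23": [[1.5, -1.5, 0.0], [0.0, 2.5, -2.5], [0.0, 0.0, 0.34]],
    "session1": [[1.0, -1.0, 0.0], [0.0, 2.0, -2.0], [0.0, 0.0, 0.3]],
}

_DET_TOL = 1e-10


@dataclass
class ChannelTransform:
    """An invertible 3x3 channel-mixing matrix plus brightness policy.

    ``brightness_mode`` is ``"fixed_scalar"`` (multiply by
    ``brightness_value``) or ``"percentile_auto"`` (scale so the
    ``brightness_value``-th percentile of positive values maps to 1).
    """

    C: np.ndarray = field(default_factory=lambda: np.eye(3))
    brightness_mode: str = "percentile_auto"
    brightness_value: float = 99.0
    name: str = "custom"

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=np.float64)
        if self.C.shape != (3, 3):
            raise ConfigurationError("channel transform must be 3x3")
        if abs(np.linalg.det(self.C)) <= _DET_TOL:
            raise ConfigurationError("channel transform matrix is singular")
        if self.brightness_mode not in ("fixed_scalar", "percentile_auto"):
            raise ConfigurationError(
                f"unknown brightness mode {self.brightness_mode!r}"
            )
        if self.brightness_mode == "percentile_auto" and not (
            0 < self.brightness_value <= 100
        ):
            raise ConfigurationError("percentile must lie in (0, 100]")

    @classmethod
    def preset(cls, name: str, **kwargs) -> "ChannelTransform":
        if name not in TRANSFORM_PRESETS:
            raise ConfigurationError(
                f"unknown preset {name!r}; available: {sorted(TRANSFORM_PRESETS)}"
            )
        return cls(C=np.array(TRANSFORM_PRESETS[name]), name=name, **kwargs)


@dataclass
class RGBImage:
    """A rendered true-color image with rendering provenance."""

    data: np.ndarray               # [..., 3] in [0, 1]
    transform_name: str
    brightness_constant: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape[-1] != 3:
            raise ConfigurationError("RGB image needs 3 trailing channels")


def rgb_basic(channels: np.ndarray) -> np.ndarray:
    """Basic color assignment: I_R = I1, I_G = I2, I_B = I3 (pure relabeling)."""
    channels = np.asarray(channels, dtype=np.float64)
    if channels.shape[-1] != 3:
        raise ConfigurationError("expected 3 trailing channels")
    return channels.copy()


def rgb_transform(channels: np.ndarray, t: ChannelTransform) -> np.ndarray:
    """Apply the channel transform pixelwise: out = C @ y.

    Linear in y, so tone (vector direction) is invariant under positive
    rescaling of y.  Negative components may arise and are preserved here;
    clamping happens at render time.
    """
    channels = np.asarray(channels, dtype=np.float64)
    if channels.shape[-1] != 3:
        raise ConfigurationError("expected 3 trailing channels")
    return np.einsum("ij,...j->...i", t.C, channels)


def render(pre: np.ndarray, t: ChannelTransform) -> RGBImage:
    """Map pre-render channel values into the [0, 1] true-color window.

    Clamp-then-scale: negatives are zeroed, the brightness constant applied,
    then values clipped to [0, 1].
    """
    pre = np.asarray(pre, dtype=np.float64)
    if not np.all(np.isfinite(pre)):
        raise ConfigurationError("pre-render values must be finite")
    clamped = np.clip(pre, 0.0, None)
    if t.brightness_mode == "fixed_scalar":
        const = float(t.brightness_value)
    else:
        positive = clamped[clamped > 0]
        if positive.size == 0:
            raise DegenerateScaleError(
                "no positive values; automatic brightness undefined"
            )
        ref = float(np.percentile(positive, t.brightness_value))
        if ref <= 0:
            raise DegenerateScaleError("degenerate percentile reference")
        const = 1.0 / ref
    out = np.clip(clamped * const, 0.0, 1.0)
    return RGBImage(out, transform_name=t.name, brightness_constant=const)


def tone(vec: np.ndarray) -> tuple[np.ndarray, float | np.ndarray]:
    """Color tone of a channel vector: unit direction plus display hue.

    The unit vector is computed on the raw (pre-clamp) values — this is the
    quantity whose uniqueness identifies materials.  The hue angle (degrees,
    HSV convention: red 0, green 120, blue 240) is computed on the clamped
    vector, matching what a viewer perceives.  Zero vectors yield a NaN
    sentinel for both.
    """
    vec = np.asarray(vec, dtype=np.float64)
    single = vec.ndim == 1
    v = vec[None, :] if single else vec.reshape(-1, 3)
    norms = np.linalg.norm(v, axis=1)
    unit = np.full_like(v, np.nan)
    nz = norms > 0
    unit[nz] = v[nz] / norms[nz, None]

    clamped = np.clip(v, 0.0, None)
    mx = clamped.max(axis=1)
    mn = clamped.min(axis=1)
    delta = mx - mn
    hue = np.full(len(v), np.nan)
    flat = (delta == 0) & (mx > 0)
    hue[flat] = 0.0
    sel = delta > 0
    r, g, b = clamped[:, 0], clamped[:, 1], clamped[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(
            mx == r, (g - b) / delta,
            np.where(mx == g, 2.0 + (b - r) / delta, 4.0 + (r - g) / delta),
        )
    hue[sel] = (h[sel] * 60.0) % 360.0
    if single:
        return unit[0], float(hue[0])
    shape = vec.shape[:-1]
    return unit.reshape(shape + (3,)), hue.reshape(shape)


def tone_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two channel vectors (tone separation)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


@dataclass
class ToneReport:
    """Pairwise tone separation of material signatures under a transform."""

    angles_deg: dict[tuple[str, str], float]
    collisions: list[tuple[str, str]]
    threshold_deg: float
    transform_name: str

    @property
    def ok(self) -> bool:
        return not self.collisions

    @property
    def min_angle_deg(self) -> float:
        return min(self.angles_deg.values())


def tone_uniqueness_check(
    materials: dict[str, np.ndarray] | list[np.ndarray],
    t: ChannelTransform,
    threshold_deg: float = 3.0,
) -> ToneReport:
    """Verify that material signatures keep distinct tones after transform.

    ``materials`` maps names to 3-vectors of per-channel attenuation (or is a
    plain list).  Signatures are pushed through C, and every pair whose tone
    angle falls below ``threshold_deg`` is flagged as a collision.  Used as a
    transform-tuning diagnostic.
    """
    if not isinstance(materials, dict):
        materials = {f"m{i}": sig for i, sig in enumerate(materials)}
    if len(materials) < 2:
        raise ConfigurationError("need at least two signatures to compare")
    transformed = {
        name: rgb_transform(np.asarray(sig, dtype=np.float64), t)
        for name, sig in materials.items()
    }
    names = list(transformed)
    angles: dict[tuple[str, str], float] = {}
    collisions: list[tuple[str, str]] = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ang = tone_angle_deg(transformed[a], transformed[b])
            angles[(a, b)] = ang
            if not ang >= threshold_deg:  # NaN (zero vector) also collides
                collisions.append((a, b))
    return ToneReport(
        angles_deg=angles, collisions=collisions,
        threshold_deg=threshold_deg, transform_name=t.name,
    )


def save_png(img: RGBImage, path) -> None:
    """Write a rendered RGB image (2-D only) as an 8-bit PNG."""
    if img.data.ndim != 3:
        raise ConfigurationError("PNG export expects a 2-D RGB image")
    arr = np.round(img.data * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(str(path))
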