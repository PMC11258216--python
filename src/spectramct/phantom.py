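"""Synthetic spectral phantom generator for multi-bin micro-CT.

Emulates contrast-enhanced mouse scans so the full analysis chain
(colorization, ROI metrics, mask refinement, tumor discrimination) can be
exercised without scan data.  The attenuation physics is a deliberately
stylized two-term model per material,

    mu(E) = pe_coeff * E^-3 * jump(E) + compton_coeff,

an E^-3 photoelectric term plus an energy-flat Compton term, where
``jump(E)`` multiplies the photoelectric term by a constant factor > 1 at
and above the material's K-edge.  This is not tabulated cross-section data,
but it reproduces the qualitative bin patterns the color method exploits:
soft tissue and bone decrease monotonically with energy, while an
iodine-like agent (K-edge ~33 keV) and a barium-nanoparticle-like agent
(K-edge ~37 keV) are elevated in the bins above their edges.

Two tumor enhancement regimes are modelled as static snapshots:

* ``diffuse_iodine`` — a small-molecule agent leaks through tumor
  vasculature and spreads over the whole tumor volume, mixed uniformly at a
  configured volume fraction;
* ``punctate_np`` — large nanoparticles stay intravascular, so enhancement
  appears as bright vessel dots: a Poisson number of small agent spheres at
  uniform positions inside the tumor ellipsoid.

Reconstruction noise is additive zero-mean Gaussian in the LAC domain,
independent across bins, with per-bin sigma calibrated so the measured
background-muscle SNR (mean/std) hits a configured target.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .spectral_core import (
    ConfigurationError,
    EnergyBinning,
    ROISet,
    SpectralVolume,
)

__all__ = [
    "MaterialSpec",
    "DEFAULT_MATERIALS",
    "SIGNATURE_MATERIALS",
    "material_signatures",
    "bin_attenuation",
    "Ellipsoid",
    "Cylinder",
    "TumorSpec",
    "TumorModel",
    "PhantomConfig",
    "CohortSpec",
    "GroundTruth",
    "build_phantom",
    "build_cohort",
    "default_phantom_config",
    "default_cohort_spec",
    "phantom_config_from_yaml",
    "cohort_spec_from_yaml",
]


# ---------------------------------------------------------------------------
# Materials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialSpec:
    """Parametric attenuation model of one material.

    ``pe_coeff`` is the photoelectric amplitude (cm^-1 keV^3), ``compton_coeff``
    the flat amplitude (cm^-1).  ``kedge_jump`` (> 1) multiplies the
    photoelectric term at and above ``kedge_keV``.
    """

    name: str
    pe_coeff: float
    compton_coeff: float
    kedge_keV: float | None = None
    kedge_jump: float | None = None

    def __post_init__(self):
        if self.pe_coeff < 0 or self.compton_coeff < 0:
            raise ConfigurationError("pe_coeff and compton_coeff must be >= 0")
        if self.kedge_keV is not None:
            if self.kedge_keV <= 0:
                raise ConfigurationError("kedge_keV must be positive")
            if self.kedge_jump is None or self.kedge_jump <= 1:
                raise ConfigurationError("kedge_jump must be > 1 when kedge_keV is set")

    def mu(self, energy_keV: np.ndarray) -> np.ndarray:
        """Linear attenuation coefficient at the given energies (cm^-1)."""
        e = np.asarray(energy_keV, dtype=np.float64)
        pe = self.pe_coeff * e ** -3.0
        if self.kedge_keV is not None:
            pe = pe * np.where(e >= self.kedge_keV, self.kedge_jump, 1.0)
        return pe + self.compton_coeff


# Defaults are stylized fits: the tissue/bone amplitudes put LAC near
# water (~0.38 cm^-1 at 30 keV, ~0.21 at 60 keV) and cortical bone
# (~1.6 / ~0.55 cm^-1); elemental K-edge jump ratios are ~5-6.  Agent
# entries describe the *pure* agent signature; in-vivo voxels mix a small
# volume fraction of it into tissue.
DEFAULT_MATERIALS: dict[str, MaterialSpec] = {
    "air": MaterialSpec("air", pe_coeff=0.0, compton_coeff=1e-4),
    "soft_tissue": MaterialSpec("soft_tissue", pe_coeff=5200.0, compton_coeff=0.18),
    # background muscle is attenuation-matched to the tumors' base tissue so
    # that CNR isolates the contrast-agent enhancement
    "muscle": MaterialSpec("muscle", pe_coeff=5200.0, compton_coeff=0.18),
    "bone": MaterialSpec("bone", pe_coeff=30000.0, compton_coeff=0.38),
    "iodine_agent": MaterialSpec(
        "iodine_agent", pe_coeff=20000.0, compton_coeff=0.05,
        kedge_keV=33.0, kedge_jump=6.0,
    ),
    "barium_agent": MaterialSpec(
        "barium_agent", pe_coeff=18000.0, compton_coeff=0.04,
        kedge_keV=37.0, kedge_jump=6.0,
    ),
}


def bin_attenuation(
    m: MaterialSpec,
    binning: EnergyBinning,
    top_cap_keV: float = 80.0,
    n_points: int = 512,
) -> np.ndarray:
    """Bin-averaged attenuation of a material (cm^-1 per bin).

    Averages mu(E) over each bin by trapezoidal integration on a fine energy
    grid, splitting at the K-edge so the discontinuity is integrated exactly
    on each side.  The open top bin is integrated up to ``top_cap_keV``
    (default 80 keV, a typical tube kVp endpoint).
    """
    out = np.empty(binning.n_bins, dtype=np.float64)
    for b, (lo, hi) in enumerate(binning.bin_bounds(top_cap_keV)):
        pieces = [(lo, hi)]
        k = m.kedge_keV
        if k is not None and lo < k < hi:
            pieces = [(lo, k), (k, hi)]
        total = 0.0
        for a, c in pieces:
            # evaluate strictly inside the piece so the jump side is unambiguous
            e = np.linspace(a, c, n_points)
            mid = 0.5 * (e[:-1] + e[1:])
            if k is not None and c <= k:
                mu = m.pe_coeff * mid ** -3.0 + m.compton_coeff
            elif k is not None and a >= k:
                mu = m.pe_coeff * m.kedge_jump * mid ** -3.0 + m.compton_coeff
            else:
                mu = m.mu(mid)
            total += np.sum(mu * np.diff(e))
        out[b] = total / (hi - lo)
    if np.any(out <= 0):
        raise ConfigurationError(f"material {m.name!r} has non-positive bin attenuation")
    return out


#: the four distinct phantom materials whose color tones must stay unique
SIGNATURE_MATERIALS = ("soft_tissue", "bone", "iodine_agent", "barium_agent")


def material_signatures(
    materials: dict[str, MaterialSpec] | None = None,
    binning: EnergyBinning | None = None,
    names: Sequence[str] = SIGNATURE_MATERIALS,
    top_cap_keV: float = 80.0,
) -> dict[str, np.ndarray]:
    """Per-material 3-vectors of usable-channel bin attenuation (cm^-1).

    The inputs to tone-uniqueness diagnostics: each signature is the
    bin-averaged attenuation restricted to the usable analysis channels.
    """
    materials = materials or DEFAULT_MATERIALS
    binning = binning or EnergyBinning.five_bin_protocol()
    idx = list(binning.usable_indices)
    return {
        name: bin_attenuation(materials[name], binning, top_cap_keV)[idx]
        for name in names
    }


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    material: str

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
        cx, cy, cz = self.center
        rx, ry, rz = self.radii
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0

    def inside_grid(self, shape) -> bool:
        return all(
            c - r >= -0.5 and c + r <= s - 0.5
            for c, r, s in zip(self.center, self.radii, shape)
        )


@dataclass(frozen=True)
class Cylinder:
    """Axis-aligned cylinder (axis = z by default)."""

    center: tuple[float, float, float]
    radius: float
    half_length: float
    material: str
    axis: int = 2

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
        trans = [i for i in range(3) if i != self.axis]
        r2 = sum((grids[i] - self.center[i]) ** 2 for i in trans)
        along = abs(grids[self.axis] - self.center[self.axis])
        return (r2 <= self.radius**2) & (along <= self.half_length)

    def inside_grid(self, shape) -> bool:
        for i in range(3):
            ext = self.half_length if i == self.axis else self.radius
            if self.center[i] - ext < -0.5 or self.center[i] + ext > shape[i] - 0.5:
                return False
        return True


@dataclass(frozen=True)
class TumorSpec:
    """One tumor: an ellipsoid with a contrast-enhancement regime.

    ``agent_fraction`` is the uniform agent volume fraction in the diffuse
    regime.  In the punctate regime, vessel dots of radius
    ``dot_radius_vox`` are placed with an expected count of
    ``dot_density * tumor_volume_voxels`` and carry ``dot_agent_fraction``
    of agent inside the dot.
    """

    name: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    regime: str  # "diffuse_iodine" | "punctate_np"
    agent: str = "iodine_agent"
    agent_fraction: float = 0.015
    dot_agent_fraction: float = 0.25
    dot_radius_vox: float = 2.0
    dot_density: float = 0.009  # expected dots per tumor voxel

    REGIMES = ("diffuse_iodine", "punctate_np")

    def __post_init__(self):
        if self.regime not in self.REGIMES:
            raise ConfigurationError(f"unknown regime {self.regime!r}")

    @property
    def ellipsoid(self) -> Ellipsoid:
        return Ellipsoid(self.center, self.radii, "soft_tissue")


@dataclass(frozen=True)
class TumorModel:
    """Position-free tumor parameters, instantiated per mouse in a cohort."""

    label: str
    regime: str
    agent: str = "barium_agent"
    agent_fraction: float = 0.015
    dot_agent_fraction: float = 0.25
    dot_radius_vox: float = 2.0
    dot_density: float = 0.009

    def at(self, name, center, radii) -> TumorSpec:
        return TumorSpec(
            name=name, center=center, radii=radii, regime=self.regime,
            agent=self.agent, agent_fraction=self.agent_fraction,
            dot_agent_fraction=self.dot_agent_fraction,
            dot_radius_vox=self.dot_radius_vox, dot_density=self.dot_density,
        )


@dataclass
class PhantomConfig:
    """Full description of one synthetic mouse scan.

    ``noise_target_snr`` is the background-muscle SNR (mean/std, per
    channel) the additive noise is calibrated to; ``numpy.inf`` disables
    noise.  All randomness is fixed by ``seed``.
    """

    shape: tuple[int, int, int] = (48, 48, 32)
    voxel_size_um: float = 90.0
    binning: EnergyBinning = field(default_factory=EnergyBinning.five_bin_protocol)
    body: Ellipsoid | None = None
    bone: Cylinder | None = None
    muscle: Cylinder | None = None
    tumors: tuple[TumorSpec, ...] = ()
    noise_target_snr: float = 20.0
    top_cap_keV: float = 80.0
    seed: int = 0
    materials: dict[str, MaterialSpec] = field(
        default_factory=lambda: dict(DEFAULT_MATERIALS)
    )

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if self.noise_target_snr <= 0:
            raise ConfigurationError("noise_target_snr must be positive")
        if self.body is None:
            nx, ny, nz = self.shape
            self.body = Ellipsoid(
                center=(nx / 2, ny / 2, nz / 2),
                radii=(0.48 * nx, 0.45 * ny, 0.47 * nz),
                material="soft_tissue",
            )
        if self.bone is None:
            nx, ny, nz = self.shape
            self.bone = Cylinder(
                center=(0.5 * nx, 0.21 * ny, 0.5 * nz),
                radius=0.06 * nx, half_length=0.44 * nz, material="bone",
            )
        if self.muscle is None:
            nx, ny, nz = self.shape
            self.muscle = Cylinder(
                center=(0.5 * nx, 0.75 * ny, 0.5 * nz),
                radius=0.09 * nx, half_length=0.25 * nz, material="muscle",
            )
        for prim in (self.body, self.bone, self.muscle, *map(lambda t: t.ellipsoid, self.tumors)):
            if not prim.inside_grid(self.shape):
                raise ConfigurationError(
                    f"geometry primitive {prim} extends outside grid {self.shape}"
                )


def _default_tumor_geometry(shape, side: str):
    nx, ny, nz = shape
    xc = 0.3 * nx if side == "left" else 0.7 * nx
    return (xc, 0.5 * ny, 0.5 * nz), (0.17 * nx, 0.19 * ny, 0.25 * nz)


def default_phantom_config(seed: int = 0, shape=(48, 48, 32),
                           noise_target_snr: float = 20.0) -> PhantomConfig:
    """Single-mouse scene: one diffuse iodine-enhanced tumor + muscle ROI."""
    center, radii = _default_tumor_geometry(shape, "left")
    tumor = TumorSpec(
        name="tumor_left", center=center, radii=radii,
        regime="diffuse_iodine", agent="iodine_agent",
    )
    return PhantomConfig(shape=shape, tumors=(tumor,), seed=seed,
                         noise_target_snr=noise_target_snr)


@dataclass
class CohortSpec:
    """A paired-design cohort: every mouse bears one tumor of each model.

    Mirrors a study design where both tumor models grow in the same animal
    and are scanned simultaneously, so per-mouse differences cancel in a
    paired test.  Per-mouse seeds are ``seed + mouse_index``, giving
    reproducible yet independent noise streams.
    """

    n_mice: int = 6
    model_a: TumorModel = field(default_factory=lambda: TumorModel(
        label="high_vascularity", regime="punctate_np", dot_density=0.009))
    model_b: TumorModel = field(default_factory=lambda: TumorModel(
        label="low_vascularity", regime="punctate_np", dot_density=0.0015))
    shape: tuple[int, int, int] = (48, 48, 32)
    voxel_size_um: float = 90.0
    noise_target_snr: float = 20.0
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if self.n_mice < 2:
            raise ConfigurationError("paired testing needs n_mice >= 2")


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    return CohortSpec(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Per-voxel material composition of the noiseless phantom."""

    fractions: dict[str, np.ndarray]   # material name -> volume fraction
    labels: np.ndarray                 # dominant-material index
    label_names: list[str]


def _sphere_mask(shape, center, radius) -> np.ndarray:
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius**2


def build_phantom(cfg: PhantomConfig):
    """Build one synthetic scan.

    Returns ``(SpectralVolume, ROISet, GroundTruth)``.  The noiseless voxel
    value in bin b is the material-fraction-weighted sum of bin-averaged
    attenuations; fractions sum to 1 in every voxel.  Gaussian noise with
    per-bin sigma = noiseless muscle mean / target SNR is then added, so the
    measured background SNR matches the target in expectation.
    """
    shape = cfg.shape
    rng = np.random.default_rng(cfg.seed)

    # material volume fractions, assignment order: air < body < muscle < bone
    # < tumor tissue < agent admixture
    fractions = {name: np.zeros(shape) for name in cfg.materials}
    fractions["air"][:] = 1.0

    def assign(mask, name, frac=1.0):
        """Give `name` the fraction `frac` in `mask`, shrinking what is there."""
        for other in fractions.values():
            other[mask] *= 1.0 - frac
        fractions[name][mask] += frac

    assign(cfg.body.mask(shape), cfg.body.material)
    assign(cfg.muscle.mask(shape), cfg.muscle.material)
    assign(cfg.bone.mask(shape), cfg.bone.material)

    roi_masks: dict[str, np.ndarray] = {"muscle": cfg.muscle.mask(shape)}
    roi_labels: dict[str, str] = {"muscle": "background_muscle"}

    for t in cfg.tumors:
        tmask = t.ellipsoid.mask(shape)
        assign(tmask, "soft_tissue")
        if t.regime == "diffuse_iodine":
            assign(tmask, t.agent, t.agent_fraction)
        else:  # punctate_np: Poisson-count vessel dots, centers uniform in tumor
            tumor_idx = np.argwhere(tmask)
            n_dots = rng.poisson(t.dot_density * len(tumor_idx))
            dot_union = np.zeros(shape, dtype=bool)
            for _ in range(n_dots):
                c = tumor_idx[rng.integers(len(tumor_idx))]
                dot_union |= _sphere_mask(shape, c, t.dot_radius_vox)
            dot_union &= tmask
            if dot_union.any():
                assign(dot_union, t.agent, t.dot_agent_fraction)
        roi_masks[t.name] = tmask
        roi_labels[t.name] = "tumor"

    # noiseless volume from bin-averaged signatures
    bins = {
        name: bin_attenuation(mat, cfg.binning, cfg.top_cap_keV)
        for name, mat in cfg.materials.items()
    }
    data = np.zeros(shape + (cfg.binning.n_bins,))
    for name, frac in fractions.items():
        if frac.any():
            data += frac[..., None] * bins[name]

    # noise calibrated to the target background-muscle SNR
    if np.isfinite(cfg.noise_target_snr):
        mus_mean = data[roi_masks["muscle"]].mean(axis=0)
        sigma = mus_mean / cfg.noise_target_snr
        data = data + rng.normal(0.0, 1.0, data.shape) * sigma

    volume = SpectralVolume(
        data=data, binning=cfg.binning,
        voxel_size_um=cfg.voxel_size_um,
    )
    rois = ROISet(masks=roi_masks, labels=roi_labels, geometry=shape)

    stack = np.stack([fractions[n] for n in cfg.materials], axis=-1)
    gt = GroundTruth(
        fractions=fractions,
        labels=np.argmax(stack, axis=-1).astype(np.int16),
        label_names=list(cfg.materials),
    )
    return volume, rois, gt


def build_cohort(spec: CohortSpec):
    """Build the paired cohort: per mouse, a left model-A and right model-B tumor.

    Returns a list of ``(SpectralVolume, ROISet)`` of length ``n_mice``.
    Tumor mask names are ``tumor_left`` / ``tumor_right``; the ROI label
    table of the report stage maps left to model A and right to model B.
    """
    out = []
    for i in range(spec.n_mice):
        lc, lr = _default_tumor_geometry(spec.shape, "left")
        rc, rr = _default_tumor_geometry(spec.shape, "right")
        cfg = PhantomConfig(
            shape=spec.shape,
            voxel_size_um=spec.voxel_size_um,
            tumors=(
                spec.model_a.at("tumor_left", lc, lr),
                spec.model_b.at("tumor_right", rc, rr),
            ),
            noise_target_snr=spec.noise_target_snr,
            seed=spec.seed + i,
        )
        vol, rois, _ = build_phantom(cfg)
        out.append((vol, rois))
    return out


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def _binning_from_dict(d: dict | None) -> EnergyBinning:
    if not d:
        return EnergyBinning.five_bin_protocol()
    return EnergyBinning(
        edges_keV=tuple(d["edges_keV"]),
        open_top=bool(d.get("open_top", True)),
        usable=tuple(d.get("usable", ())),
    )


def phantom_config_from_yaml(path) -> PhantomConfig:
    """Load a :class:`PhantomConfig` from YAML.

    Recognized keys: shape, voxel_size_um, binning {edges_keV, open_top,
    usable}, noise_target_snr, top_cap_keV, seed and tumors (a list of
    TumorSpec field mappings).  Omitted geometry falls back to the default
    scene.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    tumors = []
    for td in raw.get("tumors", []):
        td = dict(td)
        td["center"] = tuple(td["center"])
        td["radii"] = tuple(td["radii"])
        tumors.append(TumorSpec(**td))
    kwargs = {}
    for key in ("voxel_size_um", "noise_target_snr", "top_cap_keV", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "shape" in raw:
        kwargs["shape"] = tuple(raw["shape"])
    if not tumors and "tumors" not in raw:
        base = default_phantom_config(**{k: v for k, v in kwargs.items()
                                         if k in ("seed", "noise_target_snr")},
                                      shape=kwargs.get("shape", (48, 48, 32)))
        tumors = list(base.tumors)
    return PhantomConfig(binning=_binning_from_dict(raw.get("binning")),
                         tumors=tuple(tumors), **kwargs)


def cohort_spec_from_yaml(path) -> CohortSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in ("n_mice", "voxel_size_um", "noise_target_snr", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "shape" in raw:
        kwargs["shape"] = tuple(raw["shape"])
    for key, name in (("model_a", "model_a"), ("model_b", "model_b")):
        if key in raw:
            kwargs[name] = TumorModel(**raw[key])
    return CohortSpec(**kwargs)
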