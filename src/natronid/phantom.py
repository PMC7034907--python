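"""Synthetic ground-truth μ-volumes emulating the mummy imaging situation.

A phantom is a 3D map of linear attenuation coefficients: a low-μ organic
matrix (the balm), a large bone-like reference region (hydroxyapatite at the
measured bone-mineral density), and small dense mineral inclusions (natron
constituents).  Voxel values are the theoretical μ of each material at the
chosen generation energy, so the whole calibrate→segment→classify chain can
be exercised with known truth.  Realism is added by ``degrade``: a Gaussian
detector PSF (reflective boundaries, so the volume mean is preserved)
followed by additive Gaussian noise on μ — the standard approximation for
reconstructed synchrotron volumes.

``paganin_retrieve`` is a small stand-alone projection-domain operation: the
single-distance phase-retrieval low-pass filter for a homogeneous object,
turning one propagation-distance intensity image into a projected-thickness
map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .attenuation import AttenuationTable, linear_attenuation
from .errors import PhantomSpecError
from .materials import Registry, default_registry

__all__ = [
    "Ellipsoid",
    "Box",
    "PhantomSpec",
    "PhantomVolume",
    "generate_phantom",
    "degrade",
    "realize",
    "mummy_preset",
    "write_volume",
    "read_volume",
    "paganin_retrieve",
]


@dataclass(frozen=True)
class Ellipsoid:
    center: Tuple[float, float, float]  # (z, y, x) voxels
    radii: Tuple[float, float, float]
    material: str

    def bounds(self):
        return tuple((c - r, c + r) for c, r in zip(self.center, self.radii))

    def mask(self, shape) -> np.ndarray:
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        cz, cy, cx = self.center
        rz, ry, rx = self.radii
        return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


@dataclass(frozen=True)
class Box:
    center: Tuple[float, float, float]
    half_sizes: Tuple[float, float, float]
    material: str

    def bounds(self):
        return tuple((c - h, c + h) for c, h in zip(self.center, self.half_sizes))

    def mask(self, shape) -> np.ndarray:
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        out = np.ones((1, 1, 1), dtype=bool)
        for ax, (c, h) in zip((zz, yy, xx), zip(self.center, self.half_sizes)):
            out = out & (np.abs(ax - c) <= h)
        return np.broadcast_to(out, shape)


Primitive = Union[Ellipsoid, Box]


@dataclass
class PhantomSpec:
    """Everything needed to build (and degrade) one phantom, deterministically."""

    shape: Tuple[int, int, int]
    voxel_size_um: float
    background: Union[str, float]  # material name, or an explicit μ in cm⁻¹
    primitives: List[Primitive] = field(default_factory=list)
    psf_sigma: float = 0.0  # voxels
    noise_sigma: float = 0.0  # cm⁻¹
    seed: int = 0

    def __post_init__(self):
        if self.psf_sigma < 0 or self.noise_sigma < 0:
            raise PhantomSpecError("psf_sigma and noise_sigma must be >= 0")
        for p in self.primitives:
            for (lo, hi), n in zip(p.bounds(), self.shape):
                if lo < 0 or hi > n - 1:
                    raise PhantomSpecError(
                        f"primitive {p} extends outside the {self.shape} grid"
                    )


@dataclass
class PhantomVolume:
    """μ-field with congruent integer labels and per-label ground truth.

    Label 0 is background; labels 1..k follow the primitive order.  For a
    clean (unblurred, noiseless) volume every voxel's μ equals its label's
    true μ exactly.
    """

    mu: np.ndarray  # float32, cm⁻¹
    labels: np.ndarray  # uint16
    ground_truth: Dict[int, Dict]  # label -> {"material": name, "mu": value}
    voxel_size_um: float
    energy_keV: float

    def __post_init__(self):
        if self.mu.shape != self.labels.shape:
            raise ValueError("mu and labels must be congruent in shape")


def _material_mu(name_or_mu, energy_keV, table, registry) -> Tuple[str, float]:
    if isinstance(name_or_mu, str):
        mat = registry.get(name_or_mu)
        return name_or_mu, float(linear_attenuation(mat, energy_keV, table))
    return "fixed_mu", float(name_or_mu)


def generate_phantom(
    spec: PhantomSpec,
    energy_keV: float,
    table: AttenuationTable | None = None,
    registry: Registry | None = None,
) -> PhantomVolume:
    """Rasterise the spec into a clean labelled μ-volume at one energy.

    Later primitives overwrite earlier ones on overlap.  Deterministic: the
    clean volume has no random component at all.
    """
    table = table or AttenuationTable.default()
    registry = registry or default_registry()
    bg_name, bg_mu = _material_mu(spec.background, energy_keV, table, registry)
    mu = np.full(spec.shape, bg_mu, dtype=np.float32)
    labels = np.zeros(spec.shape, dtype=np.uint16)
    truth: Dict[int, Dict] = {0: {"material": bg_name, "mu": bg_mu}}
    for k, prim in enumerate(spec.primitives, start=1):
        name, val = _material_mu(prim.material, energy_keV, table, registry)
        m = prim.mask(spec.shape)
        mu[m] = np.float32(val)
        labels[m] = k
        truth[k] = {"material": name, "mu": val}
    return PhantomVolume(mu, labels, truth, spec.voxel_size_um, float(energy_keV))


def degrade(
    vol: PhantomVolume, psf_sigma: float, noise_sigma: float, seed: int
) -> PhantomVolume:
    """Gaussian blur (reflective boundary) then additive Gaussian noise.

    Labels and ground truth are carried through unchanged; (0, 0) is the
    identity.
    """
    if psf_sigma < 0 or noise_sigma < 0:
        raise ValueError("sigmas must be >= 0")
    out = vol.mu.astype(np.float64)
    if psf_sigma > 0:
        out = gaussian_filter(out, sigma=psf_sigma, mode="reflect")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.standard_normal(out.shape) * noise_sigma
    return replace(vol, mu=out.astype(np.float32))


def realize(
    spec: PhantomSpec,
    energy_keV: float,
    table: AttenuationTable | None = None,
    registry: Registry | None = None,
) -> PhantomVolume:
    """generate_phantom + degrade with the spec's own sigmas and seed."""
    vol = generate_phantom(spec, energy_keV, table, registry)
    if spec.psf_sigma > 0 or spec.noise_sigma > 0:
        vol = degrade(vol, spec.psf_sigma, spec.noise_sigma, spec.seed)
    return vol


BONE_LABEL = 1  # the reference ellipsoid is always the first primitive in presets


def mummy_preset(
    seed: int = 42,
    shape: Tuple[int, int, int] = (96, 112, 112),
    n_inclusions: int = 20,
    psf_sigma: float = 0.7,
    noise_sigma: float = 0.01,
) -> PhantomSpec:
    """The default mummy-like phantom.

    A balm matrix (μ ≈ 0.18 cm⁻¹ at 146.1 keV), one large bone-like ellipsoid
    (hydroxyapatite at 1.8 g/cm³) and ``n_inclusions`` small mineral spheres
    (half halite, half nahcolite; radii 3–10 voxels) placed without overlap in
    the balm away from the bone.  Geometry is drawn deterministically from
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    prims: List[Primitive] = [
        Ellipsoid(
            center=(nz / 2, ny * 0.25, nx / 2),
            radii=(nz * 0.36, ny * 0.14, nx * 0.20),
            material="hydroxyapatite",
        )
    ]
    placed: List[Tuple[np.ndarray, float]] = []
    materials = ["halite", "nahcolite"]
    tries = 0
    while len(placed) < n_inclusions:
        tries += 1
        if tries > 20000:
            raise PhantomSpecError("could not place inclusions without overlap")
        r = float(rng.integers(3, 11))
        margin = r + 2.0
        c = np.array(
            [
                rng.uniform(margin, nz - 1 - margin),
                rng.uniform(ny * 0.5 + margin, ny - 1 - margin),
                rng.uniform(margin, nx - 1 - margin),
            ]
        )
        if any(np.linalg.norm(c - c0) < r + r0 + 3.0 for c0, r0 in placed):
            continue
        placed.append((c, r))
        prims.append(
            Ellipsoid(
                center=tuple(c),
                radii=(r, r, r),
                material=materials[(len(placed) - 1) % 2],
            )
        )
    return PhantomSpec(
        shape=shape,
        voxel_size_um=24.37,
        background="balm",
        primitives=prims,
        psf_sigma=psf_sigma,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def write_volume(path, vol: PhantomVolume) -> None:
    """Write μ as a 32-bit float multi-page TIFF, labels as 16-bit TIFF, plus
    a JSON sidecar with voxel size, energy and ground truth."""
    path = Path(path)
    tifffile.imwrite(path, vol.mu, photometric="minisblack")
    tifffile.imwrite(path.with_name(path.stem + "_labels.tif"), vol.labels)
    sidecar = {
        "voxel_size_um": vol.voxel_size_um,
        "energy_keV": vol.energy_keV,
        "ground_truth": {str(k): v for k, v in vol.ground_truth.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_volume(path) -> PhantomVolume:
    path = Path(path)
    mu = tifffile.imread(path).astype(np.float32)
    labels_path = path.with_name(path.stem + "_labels.tif")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if labels_path.exists():
        labels = tifffile.imread(labels_path).astype(np.uint16)
    else:
        labels = np.zeros(mu.shape, dtype=np.uint16)
    voxel, energy, truth = 1.0, float("nan"), {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        voxel = meta.get("voxel_size_um", 1.0)
        energy = meta.get("energy_keV", float("nan"))
        truth = {int(k): v for k, v in meta.get("ground_truth", {}).items()}
    return PhantomVolume(mu, labels, truth, voxel, energy)


_HC_KEV_M = 1.23984193e-9  # hc in keV·m


def paganin_retrieve(
    intensity: np.ndarray,
    delta_beta: float,
    distance_m: float,
    energy_keV: float,
    pixel_um: float,
    mu_cm: float,
) -> np.ndarray:
    """Single-distance phase retrieval for a homogeneous object.

    Applies the low-pass filter ``1 / (1 + π λ D (δ/β) |ν|²)`` (ν the spatial
    frequency in cycles/m) to the normalised intensity ``I/I₀`` recorded at
    propagation distance D, then converts to projected thickness
    ``t = −ln(·)/μ`` (cm).  With δ/β = 0 or D = 0 the filter is the identity
    and the result is the plain Beer–Lambert log conversion.
    """
    I = np.asarray(intensity, dtype=float)
    if np.any(I <= 0):
        raise ValueError("intensity must be strictly positive (I/I0)")
    if min(delta_beta, distance_m, energy_keV, pixel_um) < 0 or mu_cm <= 0:
        raise ValueError("parameters must be positive")
    lam = _HC_KEV_M / energy_keV  # wavelength, m
    d = pixel_um * 1e-6
    fy = np.fft.fftfreq(I.shape[0], d=d)
    fx = np.fft.fftfreq(I.shape[1], d=d)
    nu2 = fy[:, None] ** 2 + fx[None, :] ** 2
    filt = 1.0 / (1.0 + np.pi * lam * distance_m * delta_beta * nu2)
    smoothed = np.fft.ifft2(np.fft.fft2(I) * filt).real
    return -np.log(np.maximum(smoothed, 1e-300)) / mu_cm
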