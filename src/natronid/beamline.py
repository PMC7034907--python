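"""Detected-spectrum simulation for a filtered bending-magnet beamline.

The source follows the universal synchrotron spectral shape
``G1(y) = y ∫_y^∞ K_{5/3}(x) dx`` with ``y = E/E_c``; the photon flux per
unit energy is proportional to ``G1(y)/E``.  The critical energy is either
given directly or derived from the storage-ring energy and bending field as
``E_c[keV] = 0.665 · E[GeV]² · B[T]``.

The beam then passes an ordered stack of attenuating filters
(``T(E) = exp(−Σ μ_i(E) t_i)``) and is detected by an energy-integrating
scintillator/camera chain: the per-energy detection weight is the absorbed
fraction ``1 − exp(−μ_sc(E) t)`` multiplied by the deposited energy ``E``.
The normalised pointwise product of the three terms is the detected spectrum;
its first moment is the "average detected energy" that makes a polychromatic
scan comparable to a monochromatic one.

``beam_hardening_curve`` quantifies how far that monochromatic picture holds:
for a path length L through a material the effective attenuation is
``μ_eff(L) = −ln(Σ w_i e^{−μ(E_i) L})/L`` (limit ``Σ w_i μ(E_i)`` at L=0),
which is non-increasing in L for any spectrum (Jensen); the relative spread
over the path lengths of interest is the beam-hardening severity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import List, Sequence, Tuple

import numpy as np
import yaml
from scipy.integrate import quad
from scipy.special import kv

from .attenuation import AttenuationTable, linear_attenuation
from .errors import DegenerateSpectrumError
from .materials import Material, Registry, default_registry

__all__ = [
    "critical_energy_from_ring",
    "bending_magnet_flux",
    "Filter",
    "Scintillator",
    "BeamlineModel",
    "DetectedSpectrum",
    "filter_transmission",
    "scintillator_response",
    "detected_spectrum",
    "average_detected_energy",
    "beam_hardening_curve",
    "HardeningCurve",
    "beamline_presets",
]


def critical_energy_from_ring(ring_energy_GeV: float, field_T: float) -> float:
    """Bending-magnet critical energy in keV: 0.665 · E² · B."""
    return 0.665 * ring_energy_GeV**2 * field_T


@lru_cache(maxsize=4096)
def _g1_scalar(y: float) -> float:
    if y <= 0:
        raise ValueError("y must be > 0")
    val, _ = quad(lambda x: kv(5.0 / 3.0, x), y, np.inf, limit=200)
    return y * val


def g1(y) -> np.ndarray | float:
    """Universal bending-magnet spectral function, evaluated by quadrature."""
    arr = np.asarray(y, dtype=float)
    out = np.array([_g1_scalar(float(v)) for v in arr.ravel()]).reshape(arr.shape)
    return float(out) if np.isscalar(y) else out


def bending_magnet_flux(critical_energy_keV: float, energies_keV) -> np.ndarray:
    """Relative photon flux per unit energy, ∝ G1(E/E_c)/E."""
    if critical_energy_keV <= 0:
        raise ValueError("critical energy must be > 0")
    e = np.asarray(energies_keV, dtype=float)
    return g1(e / critical_energy_keV) / e


@dataclass(frozen=True)
class Filter:
    material: Material
    thickness_mm: float

    def __post_init__(self):
        if self.thickness_mm < 0:
            raise ValueError("filter thickness must be >= 0")


@dataclass(frozen=True)
class Scintillator:
    material: Material
    thickness_um: float

    def __post_init__(self):
        if self.thickness_um < 0:
            raise ValueError("scintillator thickness must be >= 0")


def filter_transmission(
    filters: Sequence[Filter], energies_keV, table: AttenuationTable | None = None
) -> np.ndarray:
    """exp(−Σ μ_i(E)·t_i); multiplicative and order-independent."""
    e = np.asarray(energies_keV, dtype=float)
    tau = np.zeros_like(e)
    for f in filters:
        tau += linear_attenuation(f.material, e, table) * (f.thickness_mm * 0.1)
    return np.exp(-tau)


def scintillator_response(
    scintillator: Scintillator, energies_keV, table: AttenuationTable | None = None
) -> np.ndarray:
    """Absorbed fraction × deposited energy (energy-integrating detector)."""
    e = np.asarray(energies_keV, dtype=float)
    mu = linear_attenuation(scintillator.material, e, table)
    absorbed = 1.0 - np.exp(-mu * scintillator.thickness_um * 1e-4)
    return absorbed * e


@dataclass(frozen=True)
class DetectedSpectrum:
    """Energy grid (keV) and non-negative weights normalised to sum 1."""

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "energies", np.asarray(self.energies, dtype=float))
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("spectrum weights must be >= 0")
        s = w.sum()
        if not np.isfinite(s) or s <= 0:
            raise DegenerateSpectrumError("spectrum has zero total weight")
        object.__setattr__(self, "weights", w / s)

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.energies, self.weights]),
            delimiter=",",
            header="energy_keV,weight",
            comments="",
        )


_DEFAULT_GRID = (10.0, 400.0, 0.5)


@dataclass
class BeamlineModel:
    """Source + filter stack + scintillator on a common energy grid."""

    critical_energy_keV: float
    filters: List[Filter] = field(default_factory=list)
    scintillator: Scintillator | None = None
    energies: np.ndarray = field(
        default_factory=lambda: np.arange(*_DEFAULT_GRID[:2], _DEFAULT_GRID[2])
    )

    def __post_init__(self):
        if self.critical_energy_keV <= 0:
            raise ValueError("critical energy must be > 0")

    @classmethod
    def from_config(
        cls,
        cfg: dict,
        registry: Registry | None = None,
        energies=None,
    ) -> "BeamlineModel":
        """Build from a preset-style dict (see ``data/beamlines.yaml``)."""
        registry = registry or default_registry()
        src = cfg["source"]
        if "critical_energy_keV" in src:
            ec = float(src["critical_energy_keV"])
        else:
            ec = critical_energy_from_ring(
                float(src["ring_energy_GeV"]), float(src["field_T"])
            )
        filters = [
            Filter(registry.get(f["material"]), float(f["thickness_mm"]))
            for f in cfg.get("filters", [])
        ]
        sc = cfg.get("scintillator")
        scint = (
            Scintillator(registry.get(sc["material"]), float(sc["thickness_um"]))
            if sc
            else None
        )
        kwargs = {}
        if energies is not None:
            kwargs["energies"] = np.asarray(energies, dtype=float)
        return cls(ec, filters, scint, **kwargs)

    @classmethod
    def from_preset(cls, name: str, registry: Registry | None = None) -> "BeamlineModel":
        presets = beamline_presets()
        if name not in presets:
            raise KeyError(f"unknown beamline preset {name!r}; known: {sorted(presets)}")
        return cls.from_config(presets[name], registry)


@lru_cache(maxsize=1)
def beamline_presets() -> dict:
    with resources.files("natronid.data").joinpath("beamlines.yaml").open() as f:
        return yaml.safe_load(f)


def detected_spectrum(
    model: BeamlineModel, table: AttenuationTable | None = None
) -> DetectedSpectrum:
    """Source × filter transmission × detector response, normalised.

    Raises :class:`DegenerateSpectrumError` if the filter stack is opaque on
    the whole grid.
    """
    e = model.energies
    w = bending_magnet_flux(model.critical_energy_keV, e)
    if model.filters:
        w = w * filter_transmission(model.filters, e, table)
    if model.scintillator is not None:
        w = w * scintillator_response(model.scintillator, e, table)
    return DetectedSpectrum(e, w)


def average_detected_energy(spectrum: DetectedSpectrum) -> float:
    """First moment Σ wᵢEᵢ of the detected spectrum, keV."""
    return float(np.sum(spectrum.weights * spectrum.energies))


@dataclass(frozen=True)
class HardeningCurve:
    path_lengths_cm: np.ndarray
    mu_eff: np.ndarray
    max_relative_deviation: float


def beam_hardening_curve(
    spectrum: DetectedSpectrum,
    material: Material,
    path_lengths_cm: Sequence[float],
    table: AttenuationTable | None = None,
) -> HardeningCurve:
    """Effective μ of a material versus traversed path length.

    ``μ_eff(L) = −ln(Σ wᵢ e^{−μ(Eᵢ)L})/L`` for L > 0 and the spectrum-weighted
    mean μ at L = 0.  ``max_relative_deviation`` is the spread of μ_eff over
    the requested path lengths relative to its L=0 value.
    """
    L = np.asarray(path_lengths_cm, dtype=float)
    if np.any(L < 0):
        raise ValueError("path lengths must be >= 0")
    mu = linear_attenuation(material, spectrum.energies, table)
    mu_eff = np.empty_like(L)
    for i, ell in enumerate(L):
        if ell == 0:
            mu_eff[i] = np.sum(spectrum.weights * mu)
        else:
            # log-sum-exp for numerical stability at long paths
            a = -mu * ell
            amax = a.max()
            mu_eff[i] = -(amax + np.log(np.sum(spectrum.weights * np.exp(a - amax)))) / ell
    mu0 = float(np.sum(spectrum.weights * mu))
    dev = float((mu_eff.max() - mu_eff.min()) / mu0) if mu0 > 0 else 0.0
    return HardeningCurve(L, mu_eff, dev)
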