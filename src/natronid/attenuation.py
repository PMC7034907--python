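"""X-ray attenuation of elements, compounds and hydration series.

The physical backbone is a bundled table of elemental mass attenuation
coefficients μ/ρ (cm²/g, total with coherent scattering) on an ascending
energy grid covering 10–500 keV, with explicit double points at the K edges
of Ga, Mo, Gd and Lu.  Compound coefficients follow Bragg additivity,

    μ/ρ(compound, E) = Σ_i w_i (μ/ρ)_i(E),

with ``w_i`` the elemental mass fractions, and per-element values obtained by
log-log linear interpolation on the grid — the standard treatment for smooth
cross sections away from absorption edges.  No extrapolation is performed:
energies outside the grid raise :class:`~natronid.errors.EnergyRangeError`.

Linear attenuation is then μ = ρ · μ/ρ (cm⁻¹).
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources
from typing import Dict, Tuple

import numpy as np

from .errors import EnergyRangeError
from .materials import Composition, HydrationSeries, Material

__all__ = [
    "AttenuationTable",
    "mass_attenuation",
    "linear_attenuation",
    "hydration_series_mu",
]


class AttenuationTable:
    """Per-element μ/ρ on an energy grid, with log-log interpolation.

    Parameters
    ----------
    data :
        Mapping element symbol → ``(energies_keV, mu_over_rho_cm2_g)`` arrays,
        energies strictly increasing, values strictly positive.
    """

    def __init__(self, data: Dict[str, Tuple[np.ndarray, np.ndarray]]):
        self._log: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        self._range: Dict[str, Tuple[float, float]] = {}
        for el, (e, mu) in data.items():
            e = np.asarray(e, dtype=float)
            mu = np.asarray(mu, dtype=float)
            if np.any(np.diff(e) <= 0):
                raise ValueError(f"{el}: energy grid must be strictly increasing")
            if np.any(mu <= 0) or np.any(e <= 0):
                raise ValueError(f"{el}: energies and mu/rho must be positive")
            self._log[el] = (np.log(e), np.log(mu))
            self._range[el] = (float(e[0]), float(e[-1]))

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "AttenuationTable":
        """The bundled elemental table."""
        raw: Dict[str, Tuple[list, list]] = {}
        path = resources.files("natronid.data").joinpath("elements_mu_rho.csv")
        with path.open() as f:
            for row in csv.DictReader(f):
                e, m = raw.setdefault(row["element"], ([], []))
                e.append(float(row["energy_keV"]))
                m.append(float(row["mu_over_rho_cm2_g"]))
        return cls({el: (np.array(e), np.array(m)) for el, (e, m) in raw.items()})

    @property
    def elements(self):
        return sorted(self._log)

    def energy_range(self, element: str) -> Tuple[float, float]:
        return self._range[element]

    def elemental(self, element: str, energy_keV) -> np.ndarray | float:
        """μ/ρ of one element at one or more energies (keV), interpolated."""
        if element not in self._log:
            raise KeyError(f"element {element!r} not in attenuation table")
        e = np.asarray(energy_keV, dtype=float)
        lo, hi = self._range[element]
        if np.any(e < lo) or np.any(e > hi):
            raise EnergyRangeError(
                f"energy out of tabulated range [{lo}, {hi}] keV for {element}"
            )
        loge, logmu = self._log[element]
        out = np.exp(np.interp(np.log(e), loge, logmu))
        return float(out) if np.isscalar(energy_keV) else out


def mass_attenuation(comp: Composition, energy_keV, table: AttenuationTable | None = None):
    """Mass attenuation coefficient of a compound, cm²/g (Bragg additivity)."""
    table = table or AttenuationTable.default()
    e = np.asarray(energy_keV, dtype=float)
    out = np.zeros_like(e, dtype=float)
    for el, w in comp.mass_fractions().items():
        out += w * table.elemental(el, e)
    return float(out) if np.isscalar(energy_keV) else out


def linear_attenuation(mat: Material, energy_keV, table: AttenuationTable | None = None):
    """Linear attenuation coefficient μ = ρ · (μ/ρ), cm⁻¹."""
    return mat.density * mass_attenuation(mat.composition, energy_keV, table)


def hydration_series_mu(
    series: HydrationSeries, energy_keV, table: AttenuationTable | None = None
) -> Tuple[float, float]:
    """μ (cm⁻¹) at the two endpoints of a hydration series.

    Returns
    -------
    (mu_anhydrous, mu_decahydrate)
        Each endpoint uses its own composition *and* its own bundled density
        (e.g. sodium carbonate: 2.54 g/cm³ anhydrous, 1.44 g/cm³ as the
        decahydrate).
    """
    anh, deca = series.endpoints()
    return (
        linear_attenuation(anh, energy_keV, table),
        linear_attenuation(deca, energy_keV, table),
    )
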