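"""Effective-energy calibration and candidate-mineral scoring.

A polychromatic reconstruction is made quantitative by finding the effective
monochromatic energy: the energy at which the theoretical μ of a reference
material of known density (here cortical bone mineral, hydroxyapatite at
1.8 g/cm³) equals the μ actually measured in the volume.  Since μ(E) is
strictly decreasing for edge-free materials in the 50–300 keV band, the
inversion is a bracketed Brent root find.

Candidate minerals are then scored at that energy: each candidate's
theoretical μ (a scalar, or an endpoint interval for a hydration series) is
compared against the measured μ interval [average − tol, maximum + tol]; a
candidate is *compatible* when the intervals intersect.  The verdict is
"consistent with natron" as soon as at least one natron constituent is
compatible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

from scipy.optimize import brentq

from .attenuation import AttenuationTable, hydration_series_mu, linear_attenuation
from .errors import NoRootError
from .materials import Candidate, HydrationSeries, Material

__all__ = [
    "CalibrationResult",
    "CandidateScore",
    "MeasuredAttenuation",
    "effective_energy_from_reference",
    "candidate_table",
    "classify_measurements",
]

DEFAULT_BRACKET = (50.0, 300.0)


@dataclass(frozen=True)
class CalibrationResult:
    effective_energy_keV: float
    reference: Material
    measured_mu: float
    residual: float
    bracket_keV: Tuple[float, float]


def effective_energy_from_reference(
    measured_mu: float,
    reference: Material,
    bracket_keV: Tuple[float, float] = DEFAULT_BRACKET,
    table: AttenuationTable | None = None,
    mu_tol: float = 1e-6,
) -> CalibrationResult:
    """Invert μ(reference, E) = measured_mu for E on a bracket.

    Requires μ(reference, ·) to be strictly decreasing on the bracket (true
    for edge-free materials above 50 keV) and ``measured_mu`` to lie inside
    the attainable interval [μ(E_max), μ(E_min)]; otherwise raises
    :class:`NoRootError` reporting that interval.
    """
    lo, hi = bracket_keV
    mu_hi = linear_attenuation(reference, lo, table)  # μ at E_min: largest
    mu_lo = linear_attenuation(reference, hi, table)  # μ at E_max: smallest
    if not (mu_lo <= measured_mu <= mu_hi):
        raise NoRootError(
            f"measured mu {measured_mu:.6g} /cm not attainable by "
            f"{reference.name} on [{lo}, {hi}] keV; attainable interval is "
            f"[{mu_lo:.6g}, {mu_hi:.6g}] /cm",
            mu_min=mu_lo,
            mu_max=mu_hi,
        )

    def f(e: float) -> float:
        return linear_attenuation(reference, e, table) - measured_mu

    energy = brentq(f, lo, hi, xtol=1e-6, rtol=8.9e-16)
    residual = f(energy)
    if abs(residual) > mu_tol:
        raise NoRootError(
            f"root residual {residual:.3g} exceeds tolerance {mu_tol:g}"
        )
    return CalibrationResult(float(energy), reference, measured_mu, float(residual), (lo, hi))


@dataclass
class CandidateScore:
    """Theoretical μ of one candidate and its match against measurement."""

    name: str
    mu: Union[float, Tuple[float, float]]  # scalar, or (low, high) for a series
    delta_to_average: Optional[float] = None
    delta_to_maximum: Optional[float] = None
    compatible: Optional[bool] = None

    @property
    def mu_interval(self) -> Tuple[float, float]:
        if isinstance(self.mu, tuple):
            return (min(self.mu), max(self.mu))
        return (self.mu, self.mu)

    def mu_display(self) -> str:
        if isinstance(self.mu, tuple):
            return f"{self.mu[0]:.4g}-{self.mu[1]:.4g}"
        return f"{self.mu:.4g}"


def candidate_table(
    candidates: Sequence[Candidate],
    energy_keV: float,
    table: AttenuationTable | None = None,
) -> List[CandidateScore]:
    """Theoretical μ of each candidate at one energy (the μ column).

    Hydration series contribute an (anhydrous, decahydrate) pair; solids a
    scalar.
    """
    scores: List[CandidateScore] = []
    for cand in candidates:
        if isinstance(cand, HydrationSeries):
            mu = hydration_series_mu(cand, energy_keV, table)
            scores.append(CandidateScore(cand.name, (float(mu[0]), float(mu[1]))))
        else:
            scores.append(
                CandidateScore(cand.name, float(linear_attenuation(cand, energy_keV, table)))
            )
    return scores


@dataclass(frozen=True)
class MeasuredAttenuation:
    """Measured inclusion statistics: average and maximum μ (cm⁻¹)."""

    average_mu: float
    maximum_mu: float
    per_inclusion: Optional[Tuple[float, ...]] = None

    def __post_init__(self):
        if self.maximum_mu < self.average_mu:
            raise ValueError("maximum mu must be >= average mu")


@dataclass
class ClassificationReport:
    scores: List[CandidateScore]
    measured: MeasuredAttenuation
    tolerance: float
    verdict: str

    @property
    def compatible_names(self) -> List[str]:
        return [s.name for s in self.scores if s.compatible]


def classify_measurements(
    measured: MeasuredAttenuation,
    scores: Sequence[CandidateScore],
    tolerance: float,
) -> ClassificationReport:
    """Flag candidates whose theoretical μ intersects the measured interval.

    The measured interval is [average − tolerance, maximum + tolerance];
    widening the tolerance can only add compatible candidates (monotone).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if measured is None:
        raise ValueError("measurement set is empty")
    lo = measured.average_mu - tolerance
    hi = measured.maximum_mu + tolerance
    flagged: List[CandidateScore] = []
    for s in scores:
        mlo, mhi = s.mu_interval
        flagged.append(
            CandidateScore(
                name=s.name,
                mu=s.mu,
                delta_to_average=float(min(abs(measured.average_mu - m) for m in (mlo, mhi))
                                       if not (mlo <= measured.average_mu <= mhi) else 0.0),
                delta_to_maximum=float(min(abs(measured.maximum_mu - m) for m in (mlo, mhi))
                                       if not (mlo <= measured.maximum_mu <= mhi) else 0.0),
                compatible=bool(mhi >= lo and mlo <= hi),
            )
        )
    verdict = (
        "consistent with natron"
        if any(s.compatible for s in flagged)
        else "not consistent with natron"
    )
    return ClassificationReport(flagged, measured, tolerance, verdict)
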