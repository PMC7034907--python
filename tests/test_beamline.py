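"""Bending-magnet source, filter stack, detector response, beam hardening."""

import numpy as np
import pytest

from natronid.beamline import (
    BeamlineModel,
    DetectedSpectrum,
    Filter,
    Scintillator,
    average_detected_energy,
    beam_hardening_curve,
    beamline_presets,
    bending_magnet_flux,
    critical_energy_from_ring,
    detected_spectrum,
    filter_transmission,
    g1,
    scintillator_response,
)
from natronid.errors import DegenerateSpectrumError


def test_critical_energy_formula():
    # 6 GeV in a 0.85 T bend -> ~20 keV
    assert critical_energy_from_ring(6.0, 0.85) == pytest.approx(20.4, abs=0.2)


def test_flux_positive_with_exponential_tail():
    e = np.array([15.0, 40.0, 100.0, 200.0, 400.0])
    flux = bending_magnet_flux(20.0, e)
    assert np.all(flux > 0)
    assert np.all(np.diff(flux[1:]) < 0)
    assert flux[-1] / flux.max() < 1e-5


def test_g1_peak_location():
    """Brute-force maximisation: the universal function peaks near y=0.29."""
    y = np.arange(0.05, 1.0, 0.005)
    vals = g1(y)
    assert 0.25 < y[np.argmax(vals)] < 0.34


def test_flux_critical_energy_scaling():
    """flux(E; 2Ec) = flux(E/2; Ec) / 2 (pure shape rescaling)."""
    e = np.linspace(20.0, 200.0, 19)
    lhs = bending_magnet_flux(40.0, e)
    rhs = bending_magnet_flux(20.0, e / 2.0) / 2.0
    np.testing.assert_allclose(lhs, rhs, rtol=1e-9)


@pytest.fixture(scope="module")
def cu_filter(registry):
    return Filter(registry.get("copper"), 12.0)


def test_zero_filters_transmit_everything(table):
    e = np.linspace(20.0, 300.0, 30)
    np.testing.assert_array_equal(filter_transmission([], e, table), np.ones_like(e))


def test_cu_transmission_increases_with_energy(cu_filter, table):
    e = np.linspace(50.0, 300.0, 120)
    t = filter_transmission([cu_filter], e, table)
    assert np.all(np.diff(t) > 0)


def test_stacked_filter_squares_transmission(cu_filter, table):
    e = np.linspace(50.0, 300.0, 40)
    single = filter_transmission([cu_filter], e, table)
    double = filter_transmission([cu_filter, cu_filter], e, table)
    np.testing.assert_allclose(double, single**2, rtol=1e-10)


def test_filter_order_invariance(registry, table):
    e = np.linspace(30.0, 300.0, 40)
    a = Filter(registry.get("molybdenum"), 0.3)
    b = Filter(registry.get("copper"), 12.0)
    np.testing.assert_allclose(
        filter_transmission([a, b], e, table),
        filter_transmission([b, a], e, table),
        rtol=1e-14,
    )


def test_scintillator_zero_thickness(registry, table):
    e = np.linspace(20.0, 300.0, 20)
    resp = scintillator_response(Scintillator(registry.get("luag"), 0.0), e, table)
    np.testing.assert_array_equal(resp, np.zeros_like(e))


def test_scintillator_monotone_in_thickness(registry, table):
    e = np.linspace(20.0, 390.0, 100)
    thin = scintillator_response(Scintillator(registry.get("luag"), 200.0), e, table)
    thick = scintillator_response(Scintillator(registry.get("luag"), 2000.0), e, table)
    assert np.all(thick >= thin)


def test_luag_absorbed_fraction_decreases_above_k_edge(registry, table):
    # Lu K edge sits at 63.3 keV; above it the absorbed fraction falls with E
    sc = Scintillator(registry.get("luag"), 2000.0)
    e = np.linspace(80.0, 300.0, 100)
    absorbed = scintillator_response(sc, e, table) / e
    assert np.all(np.diff(absorbed) < 0)


def test_detected_spectrum_normalised(table):
    model = BeamlineModel.from_preset("body_24um")
    s = detected_spectrum(model, table)
    assert np.all(s.weights >= 0)
    assert s.weights.sum() == pytest.approx(1.0, abs=1e-9)


def test_opaque_stack_is_degenerate(registry, table):
    model = BeamlineModel.from_preset("body_24um")
    model.filters = [Filter(registry.get("copper"), 20000.0)]
    with pytest.raises(DegenerateSpectrumError):
        detected_spectrum(model, table)


def test_filtration_hardens_the_beam(table):
    """Filtering shifts the average detected energy upward."""
    filtered = BeamlineModel.from_preset("body_24um")
    unfiltered = BeamlineModel(filtered.critical_energy_keV, [], filtered.scintillator)
    assert average_detected_energy(detected_spectrum(filtered, table)) > \
        average_detected_energy(detected_spectrum(unfiltered, table))


def test_adding_edge_free_filters_never_softens(registry, table):
    """Over a grid of Al/Cu additions the average detected energy never drops."""
    base = BeamlineModel.from_preset("head_53um")
    base_avg = average_detected_energy(detected_spectrum(base, table))
    for mat, mm in [("aluminium", 1.0), ("aluminium", 10.0), ("copper", 0.5),
                    ("copper", 2.0), ("copper", 10.0)]:
        more = BeamlineModel(
            base.critical_energy_keV,
            base.filters + [Filter(registry.get(mat), mm)],
            base.scintillator,
        )
        avg = average_detected_energy(detected_spectrum(more, table))
        assert avg >= base_avg - 1e-9


def test_monochromatic_spectrum_has_constant_mu_eff(registry, table):
    s = DetectedSpectrum(np.array([100.0, 146.1, 200.0]), np.array([0.0, 1.0, 0.0]))
    curve = beam_hardening_curve(s, registry.get("water"), [0.0, 1.0, 3.0, 6.0], table)
    np.testing.assert_allclose(curve.mu_eff, curve.mu_eff[0], rtol=1e-12)
    assert curve.max_relative_deviation == pytest.approx(0.0, abs=1e-12)


def test_hardening_monotone_for_random_spectra(registry, table):
    """μ_eff is non-increasing in path length (Jensen), any spectrum."""
    rng = np.random.default_rng(7)
    e = np.linspace(60.0, 300.0, 49)
    water = registry.get("water")
    L = np.linspace(0.0, 8.0, 17)
    for _ in range(100):
        w = rng.random(e.size) ** 3
        curve = beam_hardening_curve(DetectedSpectrum(e, w), water, L, table)
        assert np.all(np.diff(curve.mu_eff) <= 1e-9)


def test_body_scan_average_in_expected_band(table):
    s = detected_spectrum(BeamlineModel.from_preset("body_24um"), table)
    assert 120.0 <= average_detected_energy(s) <= 160.0


def test_body_scan_hardening_negligible_for_water(registry, table):
    """<3% μ_eff spread over 0-6 cm of water when filtered; >10% unfiltered."""
    model = BeamlineModel.from_preset("body_24um")
    water = registry.get("water")
    L = np.linspace(0.0, 6.0, 13)
    filtered = beam_hardening_curve(detected_spectrum(model, table), water, L, table)
    assert filtered.max_relative_deviation < 0.03
    bare = BeamlineModel(model.critical_energy_keV, [], model.scintillator)
    unfiltered = beam_hardening_curve(detected_spectrum(bare, table), water, L, table)
    assert unfiltered.max_relative_deviation > 0.10


def test_all_presets_resolve(table):
    for name in beamline_presets():
        s = detected_spectrum(BeamlineModel.from_preset(name), table)
        assert 50.0 < average_detected_energy(s) < 200.0


def test_spectrum_csv_export(tmp_path, table):
    s = detected_spectrum(BeamlineModel.from_preset("body_24um"), table)
    out = tmp_path / "spectrum.csv"
    s.to_csv(out)
    data = np.loadtxt(out, delimiter=",", skiprows=1)
    assert data.shape[1] == 2
    assert data[:, 1].sum() == pytest.approx(1.0, abs=1e-6)
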